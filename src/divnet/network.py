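"""Dynamic cross-correlation maps and the derived residue interaction network.

The DCCM entry for residues i, j is the normalized covariance of their
displacement vectors about the mean structure,

    C_ij = <Δr_i · Δr_j> / sqrt(<|Δr_i|²> <|Δr_j|²>),

averaged over frames. Pairs whose |C_ij| reaches a correlation cutoff become
edges of an undirected graph with information-theoretic weight
w_ij = −ln|C_ij|, on which closeness, betweenness and degree centralities
identify communication-critical residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .traj import ResidueId, SuperpositionResult

__all__ = [
    "DCCM",
    "ResidueGraph",
    "CentralityTable",
    "compute_dccm",
    "build_graph",
    "closeness",
    "betweenness",
    "degree",
    "centrality_table",
    "rank_top",
]


@dataclass
class DCCM:
    matrix: np.ndarray  # (N, N), symmetric, unit diagonal, entries in [-1, 1]
    residue_ids: list[ResidueId]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("DCCM must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("DCCM must be symmetric")
        if np.abs(m).max() > 1 + 1e-12:
            raise ValueError("DCCM entries must lie in [-1, 1]")
        if not np.allclose(np.diag(m), 1.0, atol=1e-12):
            raise ValueError("DCCM diagonal must be 1")
        self.matrix = m

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per unordered residue pair."""
        iu, ju = np.triu_indices(self.n, k=1)
        return pd.DataFrame(
            {
                "res_i": [str(self.residue_ids[i]) for i in iu],
                "res_j": [str(self.residue_ids[j]) for j in ju],
                "c_ij": self.matrix[iu, ju],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        header = "\t".join(str(r) for r in self.residue_ids)
        np.savetxt(path, self.matrix, delimiter="\t", header=header,
                   comments="", fmt="%.10g")


@dataclass
class ResidueGraph:
    """Thresholded correlation network with −ln|C| edge weights."""

    graph: nx.Graph  # nodes are residue indices; 'weight' = -ln|C_ij|
    residue_ids: list[ResidueId]
    adjacency: np.ndarray  # 0/1 symmetric
    correlation_cutoff: float

    @property
    def n(self) -> int:
        return len(self.residue_ids)

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            (
                str(self.residue_ids[i]),
                str(self.residue_ids[j]),
                d["c_ij"],
                d["weight"],
            )
            for i, j, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["res_i", "res_j", "c_ij", "w_ij"])


def compute_dccm(sup: SuperpositionResult) -> DCCM:
    """Cross-correlation matrix of Cα displacement vectors.

    Raises if any residue has zero total fluctuation (the normalization
    denominator vanishes).
    """
    coords = sup.aligned.coordinates
    if coords.shape[0] < 2:
        raise ValueError("DCCM needs at least 2 frames")
    delta = coords - coords.mean(axis=0, keepdims=True)
    # cov_ij = <Δr_i · Δr_j>, dot product over x,y,z, mean over frames
    cov = np.einsum("fik,fjk->ij", delta, delta) / coords.shape[0]
    var = np.diag(cov)
    dead = np.flatnonzero(var <= 0)
    if dead.size:
        rid = sup.aligned.residue_ids[dead[0]]
        raise ValueError(
            f"residue {rid} has zero fluctuation; correlation undefined"
        )
    c = cov / np.sqrt(np.outer(var, var))
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return DCCM(c, list(sup.aligned.residue_ids))


def build_graph(
    dccm: DCCM, correlation_cutoff: float = 0.5, weight_log_base: float = np.e
) -> ResidueGraph:
    """Threshold |C_ij| at the cutoff and weight kept edges by −log|C_ij|.

    Anti-correlated pairs are kept at the same strength as correlated ones
    (the magnitude carries the communication, the sign only its phase).
    """
    if not 0.0 < correlation_cutoff < 1.0:
        raise ValueError(
            f"correlation_cutoff must lie in (0, 1), got {correlation_cutoff}"
        )
    n = dccm.n
    absc = np.abs(dccm.matrix)
    adj = (absc >= correlation_cutoff).astype(int)
    np.fill_diagonal(adj, 0)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.nonzero(np.triu(adj, k=1))
    log_scale = np.log(weight_log_base)
    for i, j in zip(iu, ju):
        w = -np.log(absc[i, j]) / log_scale
        g.add_edge(int(i), int(j), weight=float(w), c_ij=float(dccm.matrix[i, j]))
    return ResidueGraph(g, list(dccm.residue_ids), adj, correlation_cutoff)


def closeness(rg: ResidueGraph) -> np.ndarray:
    """Closeness CC(v) = (n−1)/Σ_j g(v, v_j) over the node's own component.

    Isolated nodes score 0.
    """
    if rg.n == 0:
        raise ValueError("empty graph")
    # wf_improved=False is exactly the per-component (n_comp-1)/Σ d convention
    cc = nx.closeness_centrality(rg.graph, distance="weight", wf_improved=False)
    return np.array([cc[i] for i in range(rg.n)])


def betweenness(rg: ResidueGraph) -> np.ndarray:
    """Fraction of shortest paths through each node, endpoints excluded,
    normalized by the n(n−1)/2 node pairs of the whole graph."""
    if rg.n == 0:
        raise ValueError("empty graph")
    raw = nx.betweenness_centrality(rg.graph, weight="weight", normalized=False)
    pairs = rg.n * (rg.n - 1) / 2.0
    return np.array([raw[i] / pairs for i in range(rg.n)])


def degree(rg: ResidueGraph) -> np.ndarray:
    """Number of incident edges (row sums of the 0/1 adjacency)."""
    if rg.n == 0:
        raise ValueError("empty graph")
    return rg.adjacency.sum(axis=1).astype(int)


@dataclass
class CentralityTable:
    table: pd.DataFrame  # residue, betweenness, closeness, degree
    residue_ids: list[ResidueId]

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def centrality_table(rg: ResidueGraph) -> CentralityTable:
    df = pd.DataFrame(
        {
            "residue": [str(r) for r in rg.residue_ids],
            "residue_number": [r.number for r in rg.residue_ids],
            "betweenness": betweenness(rg),
            "closeness": closeness(rg),
            "degree": degree(rg),
        }
    )
    return CentralityTable(df, list(rg.residue_ids))


def rank_top(
    table: CentralityTable, k: int = 15
) -> dict[str, list[str] | list]:
    """Top-k residues per centrality measure, descending, ties broken by
    ascending residue number; also reports the overlap across all measures."""
    if k < 1:
        raise ValueError("k must be >= 1")
    out: dict[str, list] = {}
    for measure in ("betweenness", "closeness", "degree"):
        ordered = table.table.sort_values(
            [measure, "residue_number"], ascending=[False, True]
        )
        out[measure] = ordered["residue"].head(k).tolist()
    out["overlap"] = sorted(
        set(out["betweenness"]) & set(out["closeness"]) & set(out["degree"])
    )
    return out
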