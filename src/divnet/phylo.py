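"""Alignments, p-distances, neighbor-joining, and per-site substitution counts.

Distance estimation uses the p-distance (proportion of differing sites under
pairwise gap deletion). Trees are built by Saitou–Nei neighbor-joining with a
deterministic tie rule, and per-site substitution counts on a cluster subtree
are minimum-change (parsimony) counts computed by unit-cost dynamic
programming, which is exact on arbitrary (including multifurcating) trees and
treats gaps as missing data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = frozenset("-.?X")

__all__ = [
    "AMINO_ACIDS",
    "Alignment",
    "DistanceMatrix",
    "p_distance",
    "distance_matrix",
    "neighbor_joining",
    "fitch_site_changes",
    "tree_length",
    "read_tree",
    "write_tree",
]


@dataclass
class Alignment:
    """Rectangular amino-acid alignment; rows are taxa, columns are sites."""

    taxa: list[str]
    data: np.ndarray  # (n_taxa, n_sites) of single characters

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype="<U1")
        if self.data.ndim != 2:
            raise ValueError("alignment data must be 2-D (taxa × sites)")
        if self.data.shape[0] != len(self.taxa):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.taxa)} taxon names"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        try:
            idx = self.taxa.index(taxon)
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in alignment") from None
        return self.data[idx]

    def subset(self, taxa: Sequence[str]) -> "Alignment":
        rows = [self.taxa.index(t) for t in taxa]
        return Alignment(list(taxa), self.data[rows])

    @classmethod
    def from_sequences(cls, records: Iterable[tuple[str, str]]) -> "Alignment":
        names, seqs = [], []
        for name, seq in records:
            names.append(name)
            seqs.append(list(seq.upper()))
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        return cls(names, np.array(seqs, dtype="<U1"))

    @classmethod
    def read_fasta(cls, path: str | Path) -> "Alignment":
        from Bio import SeqIO

        return cls.from_sequences(
            (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
        )

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, row in zip(self.taxa, self.data):
                fh.write(f">{name}\n{''.join(row)}\n")


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape does not match taxa")
        self.matrix = m

    def write_phylip(self, path: str | Path) -> None:
        lines = [f"{len(self.taxa)}"]
        for name, row in zip(self.taxa, self.matrix):
            lines.append(name.ljust(10) + " ".join(f"{d:.8f}" for d in row))
        Path(path).write_text("\n".join(lines) + "\n")


def _gap_mask(row: np.ndarray) -> np.ndarray:
    return np.isin(row, list(GAP_CHARS))


def p_distance(a: Alignment, taxon_i: str, taxon_j: str) -> float:
    """Proportion of differing sites among positions where neither taxon
    has a gap (pairwise deletion)."""
    ri, rj = a.row(taxon_i), a.row(taxon_j)
    usable = ~(_gap_mask(ri) | _gap_mask(rj))
    n = int(usable.sum())
    if n == 0:
        raise ValueError(
            f"no comparable (gap-free) sites between {taxon_i!r} and {taxon_j!r}"
        )
    return float((ri[usable] != rj[usable]).sum() / n)


def distance_matrix(a: Alignment) -> DistanceMatrix:
    n = a.n_taxa
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = p_distance(a, a.taxa[i], a.taxa[j])
    return DistanceMatrix(list(a.taxa), m)


# ---------------------------------------------------------------------------
# Neighbor-joining


def neighbor_joining(d: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor-joining.

    Deterministic: ties in the Q criterion are broken by the
    lexicographically smallest pair of subtree labels (a subtree is labelled
    by its smallest leaf name). Negative branch lengths are clamped to zero
    with the deficit transferred to the sister branch, so path lengths
    between joined nodes are preserved.
    """
    m = np.asarray(d.matrix, dtype=float)
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = len(d.taxa)
    if n < 2:
        raise ValueError("neighbor-joining needs at least 2 taxa")

    ns = dendropy.TaxonNamespace(d.taxa)
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes: dict[int, dendropy.Node] = {}
    labels: dict[int, str] = {}
    for i, name in enumerate(d.taxa):
        node = dendropy.Node(taxon=ns.get_taxon(name))
        nodes[i] = node
        labels[i] = name

    dist = {
        (i, j): m[i, j] for i in range(n) for j in range(i + 1, n)
    }

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    active = list(range(n))
    next_id = n

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        k = len(active)
        r = {i: sum(get(i, j) for j in active if j != i) for i in active}
        best = None
        best_key = None
        best_q = np.inf
        tol = 1e-10 * max(1.0, np.abs(m).max())
        for ai in range(k):
            for aj in range(ai + 1, k):
                i, j = active[ai], active[aj]
                q = (k - 2) * get(i, j) - r[i] - r[j]
                key = tuple(sorted((labels[i], labels[j])))
                if q < best_q - tol or (
                    abs(q - best_q) <= tol and (best_key is None or key < best_key)
                ):
                    best_q, best, best_key = q, (i, j), key
        i, j = best  # type: ignore[misc]
        dij = get(i, j)
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = dij - li
        li, lj = clamp_pair(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        u = next_id
        next_id += 1
        nodes[u] = parent
        labels[u] = min(labels[i], labels[j])
        for x in active:
            if x in (i, j):
                continue
            dux = (get(i, x) + get(j, x) - dij) / 2.0
            dist[(x, u) if x < u else (u, x)] = dux
        active = [x for x in active if x not in (i, j)] + [u]

    if len(active) == 3:
        a, b, c = active
        la = (get(a, b) + get(a, c) - get(b, c)) / 2.0
        lb = get(a, b) - la
        lc = get(a, c) - la
        center = dendropy.Node()
        for node_id, length in ((a, la), (b, lb), (c, lc)):
            center.add_child(nodes[node_id])
            nodes[node_id].edge.length = max(length, 0.0)
        tree.seed_node = center
    else:  # exactly 2
        a, b = active
        root = nodes[a]
        root.add_child(nodes[b])
        nodes[b].edge.length = get(a, b)
        tree.seed_node = root

    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Per-site minimum substitution counts


def fitch_site_changes(
    a: Alignment,
    tree: dendropy.Tree,
    cluster_taxa: Sequence[str],
    alphabet: str = AMINO_ACIDS,
) -> np.ndarray:
    """Minimum number of substitutions per site on the cluster subtree.

    The tree is restricted to ``cluster_taxa`` first. Gap or unknown leaf
    characters contribute no cost for any state (missing data). Unit-cost
    dynamic programming over states gives the exact parsimony minimum.
    """
    cluster_taxa = list(cluster_taxa)
    if len(cluster_taxa) < 2:
        raise ValueError("a cluster needs at least 2 taxa to count changes")
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = set(cluster_taxa) - leaf_labels
    if missing:
        raise ValueError(f"taxa not in tree: {sorted(missing)}")

    sub = tree.extract_tree_with_taxa_labels(
        labels=cluster_taxa, suppress_unifurcations=True
    )
    n_states = len(alphabet)
    index = {ch: i for i, ch in enumerate(alphabet)}
    n_sites = a.n_sites
    inf = np.inf

    cost: dict[int, np.ndarray] = {}
    for node in sub.postorder_node_iter():
        if node.is_leaf():
            row = a.row(node.taxon.label)
            c = np.full((n_sites, n_states), inf)
            for s, ch in enumerate(row):
                k = index.get(ch)
                if k is None:  # gap / unknown: any state at no cost
                    c[s, :] = 0.0
                else:
                    c[s, k] = 0.0
        else:
            c = np.zeros((n_sites, n_states))
            for child in node.child_nodes():
                cc = cost.pop(id(child))
                # stay in the child's state, or pay one change from its best
                c += np.minimum(cc, cc.min(axis=1, keepdims=True) + 1.0)
        cost[id(node)] = c

    root_cost = cost[id(sub.seed_node)]
    return root_cost.min(axis=1).astype(int)


def tree_length(tree: dendropy.Tree) -> float:
    """Sum of branch lengths (missing lengths count as zero)."""
    return float(
        sum(e.length or 0.0 for e in tree.preorder_edge_iter() if e.length)
    )


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path), schema="newick", suppress_rooting=True,
        unquoted_underscores=True,
    )
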