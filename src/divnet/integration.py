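"""Joining per-site divergence posteriors with per-residue network centrality.

Alignment columns are mapped onto structure residues through the structure's
own (gapped) row of the alignment, both score families are min-max normalized
to [0, 1], their association is summarized by Pearson and Spearman
coefficients, and "hotspot" residues — simultaneously high in divergence
posterior and in a centrality measure, and close to the diagonal of the
normalized scatter — are flagged per measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phylo import GAP_CHARS, Alignment

__all__ = [
    "map_alignment_to_structure",
    "normalize_scores",
    "correlate",
    "IntegrationTable",
    "build_integration_table",
    "select_hotspots",
]

CENTRALITY_MEASURES = ("betweenness", "closeness", "degree")


def map_alignment_to_structure(
    a: Alignment, structure_taxon: str, residue_ids: Sequence
) -> dict[int, object]:
    """Map alignment columns (0-based) to structure residue ids.

    The k-th non-gap column of the structure taxon's row maps to the k-th
    residue id; gap columns stay unmapped.
    """
    row = a.row(structure_taxon)
    nongap = np.flatnonzero(~np.isin(row, list(GAP_CHARS)))
    if len(nongap) != len(residue_ids):
        raise ValueError(
            f"ungapped length of {structure_taxon!r} is {len(nongap)} but the "
            f"structure has {len(residue_ids)} residues"
        )
    return {int(col): residue_ids[k] for k, col in enumerate(nongap)}


def normalize_scores(values: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; constant input is an error."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise ValueError("cannot normalize a constant score vector")
    return (values - lo) / (hi - lo)


def correlate(q_norm: np.ndarray, centrality_norm: np.ndarray) -> dict:
    """Pearson and Spearman coefficients between paired residue scores."""
    q = np.asarray(q_norm, dtype=float)
    c = np.asarray(centrality_norm, dtype=float)
    if q.shape != c.shape or q.ndim != 1:
        raise ValueError("inputs must be paired 1-D vectors")
    if len(q) < 3:
        raise ValueError("need at least 3 pairs")
    if q.std() == 0 or c.std() == 0:
        raise ValueError("zero variance in one input; correlation undefined")
    return {
        "pearson": float(stats.pearsonr(q, c).statistic),
        "spearman": float(stats.spearmanr(q, c).statistic),
        "n": int(len(q)),
    }


@dataclass
class IntegrationTable:
    """Per-residue divergence score vs centralities, raw and normalized."""

    table: pd.DataFrame  # residue, q, q_norm, <m>, <m>_norm per measure
    unmapped_sites: list[int]  # 0-based alignment columns with no residue

    def correlations(self) -> dict[str, dict]:
        return {
            m: correlate(
                self.table["q_norm"].to_numpy(),
                self.table[f"{m}_norm"].to_numpy(),
            )
            for m in CENTRALITY_MEASURES
        }

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def build_integration_table(
    site_posterior: np.ndarray,
    site_to_residue: Mapping[int, object],
    centrality: pd.DataFrame,
) -> IntegrationTable:
    """Join site posteriors to the centrality table through the site map.

    ``centrality`` needs a ``residue`` column plus the three measures; sites
    without a mapped residue are reported separately, residues without a
    mapped site are dropped.
    """
    site_posterior = np.asarray(site_posterior, dtype=float)
    unmapped = [s for s in range(len(site_posterior)) if s not in site_to_residue]
    rows = []
    cent = centrality.set_index(centrality["residue"].astype(str))
    for site, residue in site_to_residue.items():
        key = str(residue)
        if site >= len(site_posterior) or key not in cent.index:
            continue
        rec = {"residue": key, "site": site + 1, "q": site_posterior[site]}
        for m in CENTRALITY_MEASURES:
            rec[m] = float(cent.loc[key, m])
        rows.append(rec)
    if len(rows) < 2:
        raise ValueError("fewer than 2 residues joined; cannot normalize")
    df = pd.DataFrame(rows).sort_values("site", ignore_index=True)
    df["q_norm"] = normalize_scores(df["q"].to_numpy())
    for m in CENTRALITY_MEASURES:
        df[f"{m}_norm"] = normalize_scores(df[m].to_numpy())
    return IntegrationTable(df, unmapped)


def select_hotspots(
    table: IntegrationTable,
    q_min: float = 0.5,
    c_min: float = 0.5,
    band: float = 0.15,
) -> dict[str, list[str]]:
    """Residues high in both normalized scores and near the diagonal.

    A residue is flagged for a measure iff q_norm ≥ q_min, the measure's
    normalized centrality ≥ c_min, and |q_norm − centrality_norm| ≤ band.
    """
    for name, val in (("q_min", q_min), ("c_min", c_min)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if band < 0:
        raise ValueError("band must be non-negative")
    df = table.table
    out: dict[str, list[str]] = {}
    for m in CENTRALITY_MEASURES:
        cn = df[f"{m}_norm"]
        mask = (df["q_norm"] >= q_min) & (cn >= c_min) & (
            (df["q_norm"] - cn).abs() <= band
        )
        out[m] = df.loc[mask, "residue"].tolist()
    return out
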