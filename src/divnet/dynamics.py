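"""Essential dynamics: PCA of superposed Cartesian Cα coordinates.

Frames are flattened to 3N-vectors, centered on the mean structure, and
decomposed by SVD; eigenvalues of the 3N×3N covariance are the squared
singular values over (frames − 1). The leading components are the collective
motion modes, and the variance fraction per rank is the scree curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .traj import SuperpositionResult

__all__ = ["PCAResult", "pca"]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray       # descending, Å², full spectrum
    variance_fraction: np.ndarray  # sums to 1 over the full spectrum
    projections: np.ndarray        # (frames, n_components)
    components: np.ndarray         # (n_components, 3N) orthonormal rows
    mean_structure: np.ndarray     # 3N vector

    @property
    def cumulative_fraction(self) -> np.ndarray:
        return np.cumsum(self.variance_fraction)

    def top3_fraction(self) -> float:
        """Cumulative variance captured by the first three components."""
        return float(self.cumulative_fraction[min(2, len(self.eigenvalues) - 1)])

    def scree_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.eigenvalues) + 1),
                "eigenvalue": self.eigenvalues,
                "fraction": self.variance_fraction,
                "cumulative": self.cumulative_fraction,
            }
        )

    def projection_frame(self) -> pd.DataFrame:
        k = min(3, self.projections.shape[1])
        df = pd.DataFrame(
            self.projections[:, :k], columns=[f"PC{i + 1}" for i in range(k)]
        )
        df.insert(0, "frame", np.arange(1, len(df) + 1))
        return df

    def write_csv(self, scree_path: str | Path, proj_path: str | Path) -> None:
        self.scree_frame().to_csv(scree_path, index=False)
        self.projection_frame().to_csv(proj_path, index=False)


def pca(sup: SuperpositionResult, n_components: int | None = None) -> PCAResult:
    """Principal components of the superposed trajectory.

    ``n_components`` must not exceed min(3N, frames − 1); the variance
    fractions are always computed over the full spectrum so they sum to 1.
    """
    coords = sup.aligned.coordinates
    n_frames, n_res, _ = coords.shape
    if n_frames < 2:
        raise ValueError("PCA needs more than one frame")
    max_rank = min(3 * n_res, n_frames - 1)
    if n_components is None:
        n_components = max_rank
    if not 1 <= n_components <= max_rank:
        raise ValueError(
            f"n_components must be in [1, {max_rank}], got {n_components}"
        )
    x = coords.reshape(n_frames, -1)
    mean = x.mean(axis=0)
    xc = x - mean
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    eig = s**2 / (n_frames - 1)
    total = eig.sum()
    if total <= 0:
        raise ValueError("trajectory has zero variance; PCA undefined")
    frac = eig / total
    proj = xc @ vt[:n_components].T
    return PCAResult(
        eigenvalues=eig,
        variance_fraction=frac,
        projections=proj,
        components=vt[:n_components],
        mean_structure=mean,
    )
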