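import numpy as np
import pytest

from divnet.traj import ResidueId, Trajectory


def make_pdb_text(frames: np.ndarray) -> str:
    """Minimal multi-model PDB with one Cα per residue."""
    lines = []
    for m, frame in enumerate(frames, start=1):
        lines.append(f"MODEL     {m:4d}")
        for i, (x, y, z) in enumerate(frame, start=1):
            lines.append(
                f"ATOM  {i:5d}  CA  ALA A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def toy_frames() -> np.ndarray:
    """3 frames × 4 residues, small deterministic displacements."""
    rng = np.random.default_rng(42)
    base = np.zeros((4, 3))
    base[:, 0] = 3.8 * np.arange(4)
    return base[None] + 0.3 * rng.standard_normal((3, 4, 3))


@pytest.fixture
def toy_pdb(tmp_path, toy_frames):
    path = tmp_path / "toy.pdb"
    path.write_text(make_pdb_text(toy_frames))
    return path


@pytest.fixture
def toy_trajectory(toy_frames) -> Trajectory:
    ids = [ResidueId("A", i + 1, "ALA") for i in range(4)]
    return Trajectory(toy_frames.copy(), ids)


def random_trajectory(n_frames: int, n_residues: int, seed: int,
                      scale: float = 0.5) -> Trajectory:
    rng = np.random.default_rng(seed)
    base = np.zeros((n_residues, 3))
    base[:, 0] = 3.8 * np.arange(n_residues)
    coords = base[None] + scale * rng.standard_normal((n_frames, n_residues, 3))
    ids = [ResidueId("A", i + 1, "ALA") for i in range(n_residues)]
    return Trajectory(coords, ids)
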