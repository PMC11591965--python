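"""Cα coordinate trajectories: IO, rigid-body superposition, RMSD and RMSF.

Coordinates are in Å throughout. A residue is identified by
``(chain, number, name)`` taken from the first model of a PDB file, or by
synthetic labels for plain-XYZ input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, NamedTuple, Sequence

import numpy as np

__all__ = [
    "ResidueId",
    "Trajectory",
    "SuperpositionResult",
    "TrajectoryError",
    "read_trajectory",
    "write_trajectory",
    "superpose",
    "rmsd_series",
    "rmsf_profile",
]


class TrajectoryError(ValueError):
    """Malformed trajectory input (inconsistent models, bad coordinates...)."""


class ResidueId(NamedTuple):
    chain: str
    number: int
    name: str

    def __str__(self) -> str:  # e.g. "A:42:ALA"
        return f"{self.chain}:{self.number}:{self.name}"


@dataclass
class Trajectory:
    """Ordered frames of Cα coordinates, shape (n_frames, n_residues, 3)."""

    coordinates: np.ndarray
    residue_ids: list[ResidueId]
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TrajectoryError(
                f"coordinates must have shape (frames, residues, 3), "
                f"got {self.coordinates.shape}"
            )
        if self.coordinates.shape[1] != len(self.residue_ids):
            raise TrajectoryError(
                f"{self.coordinates.shape[1]} residues in coordinates but "
                f"{len(self.residue_ids)} residue ids"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise TrajectoryError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class SuperpositionResult:
    aligned: Trajectory
    reference: np.ndarray  # (n_residues, 3)
    per_frame_rmsd: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        dev = self.aligned.coordinates - self.reference[None, :, :]
        self.per_frame_rmsd = np.sqrt((dev**2).sum(axis=2).mean(axis=1))


def _default_residue_ids(n: int) -> list[ResidueId]:
    return [ResidueId("A", i + 1, "ALA") for i in range(n)]


# ---------------------------------------------------------------------------
# IO


def _scan_pdb_models(lines: Sequence[str]) -> list[int]:
    """Per-model Cα counts, so a mismatch can be reported by MODEL number."""
    counts: list[int] = []
    current = 0
    saw_model = False
    for line in lines:
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            current = 0
        elif rec == "ENDMDL":
            counts.append(current)
        elif rec in ("ATOM", "HETATM") and line[12:16].strip() == "CA":
            current += 1
    if not saw_model:  # single implicit model
        return [current]
    return counts


def _read_pdb(path: Path) -> Trajectory:
    from biotite.structure.io.pdb import PDBFile

    lines = path.read_text().splitlines()
    counts = _scan_pdb_models(lines)
    if not counts or all(c == 0 for c in counts):
        raise TrajectoryError(f"no Cα atoms found in {path}")
    if len(set(counts)) > 1:
        ref = counts[0]
        bad = next(i for i, c in enumerate(counts) if c != ref)
        raise TrajectoryError(
            f"inconsistent Cα count across models in {path}: MODEL {bad + 1} "
            f"has {counts[bad]} atoms, MODEL 1 has {ref}"
        )

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)  # AtomArrayStack
    ca = stack[:, stack.atom_name == "CA"]
    first = ca[0]
    ids = [
        ResidueId(str(c), int(r), str(n))
        for c, r, n in zip(first.chain_id, first.res_id, first.res_name)
    ]
    return Trajectory(np.asarray(ca.coord, dtype=float), ids)


def _write_pdb(traj: Trajectory, path: Path) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = traj.n_residues
    arr = struc.AtomArray(n)
    arr.coord = traj.coordinates[0]
    arr.chain_id = np.array([r.chain for r in traj.residue_ids])
    arr.res_id = np.array([r.number for r in traj.residue_ids])
    arr.res_name = np.array([r.name for r in traj.residue_ids])
    arr.atom_name = np.array(["CA"] * n)
    arr.element = np.array(["C"] * n)
    stack = struc.stack([arr] * traj.n_frames)
    stack.coord = traj.coordinates.astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def _read_xyz(path: Path) -> Trajectory:
    """Multi-frame XYZ: blocks of (natoms, comment, natoms×'LABEL x y z')."""
    lines = [ln for ln in path.read_text().splitlines()]
    frames: list[np.ndarray] = []
    labels: list[str] = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].split()[0])
        except ValueError as exc:
            raise TrajectoryError(
                f"{path}: expected atom count at line {pos + 1}"
            ) from exc
        block = lines[pos + 2 : pos + 2 + n]
        if len(block) < n:
            raise TrajectoryError(
                f"{path}: frame {len(frames) + 1} truncated "
                f"({len(block)} of {n} atom lines)"
            )
        coords = np.empty((n, 3))
        frame_labels = []
        for k, ln in enumerate(block):
            parts = ln.split()
            frame_labels.append(parts[0])
            coords[k] = [float(x) for x in parts[1:4]]
        if frames and n != frames[0].shape[0]:
            raise TrajectoryError(
                f"{path}: frame {len(frames) + 1} has {n} atoms, "
                f"frame 1 has {frames[0].shape[0]}"
            )
        if not frames:
            labels = frame_labels
        frames.append(coords)
        pos += 2 + n
    if not frames:
        raise TrajectoryError(f"{path}: no frames found")
    ids = [ResidueId("A", i + 1, lab) for i, lab in enumerate(labels)]
    return Trajectory(np.stack(frames), ids)


def _write_xyz(traj: Trajectory, path: Path) -> None:
    out: list[str] = []
    for f in range(traj.n_frames):
        out.append(str(traj.n_residues))
        out.append(f"frame {f + 1}")
        for rid, (x, y, z) in zip(traj.residue_ids, traj.coordinates[f]):
            out.append(f"{rid.name} {x:.3f} {y:.3f} {z:.3f}")
    path.write_text("\n".join(out) + "\n")


def read_trajectory(
    path: str | Path, format: Literal["pdb", "xyz"] | None = None
) -> Trajectory:
    """Read a Cα trajectory from a multi-model PDB or a multi-frame XYZ file.

    Frames are returned in file order; residue identities come from the
    first model. Only Cα atoms are kept from PDB input.
    """
    path = Path(path)
    if format is None:
        format = "pdb" if path.suffix.lower() in (".pdb", ".ent") else "xyz"
    if format == "pdb":
        return _read_pdb(path)
    if format == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unknown trajectory format {format!r}")


def write_trajectory(
    traj: Trajectory, path: str | Path, format: Literal["pdb", "xyz"] | None = None
) -> None:
    path = Path(path)
    if format is None:
        format = "pdb" if path.suffix.lower() in (".pdb", ".ent") else "xyz"
    if format == "pdb":
        _write_pdb(traj, path)
    elif format == "xyz":
        _write_xyz(traj, path)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


# ---------------------------------------------------------------------------
# Superposition


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rigid superposition of one frame onto a target."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return (mobile - mc) @ rot.T + tc


def superpose(
    traj: Trajectory,
    reference: Literal["mean", "first", "none"] = "mean",
    *,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> SuperpositionResult:
    """Rigid-body fit of every frame onto a common reference.

    ``reference="mean"`` iterates Kabsch fits against the running mean
    structure until the mean moves by less than ``tol`` Å (the conventional
    choice when fluctuations about ⟨r⟩ are wanted); ``"first"`` fits each
    frame onto frame 1, the convention for deviation-from-start RMSD plots.
    ``"none"`` applies no fitting and references the mean structure — for
    trajectories already expressed in a common frame (e.g. simulated
    fluctuation fields), where fitting would absorb collective modes that
    resemble rigid-body motion into the superposition.
    """
    if traj.n_frames < 2:
        raise TrajectoryError("superposition needs at least 2 frames")
    if traj.n_residues < 3:
        raise TrajectoryError(
            "rotation is underdetermined with fewer than 3 residues"
        )
    coords = traj.coordinates
    if reference == "none":
        out = Trajectory(coords.copy(), list(traj.residue_ids), traj.frame_times)
        return SuperpositionResult(aligned=out, reference=coords.mean(axis=0))
    ref = coords[0].copy()
    aligned = np.stack([_kabsch(frame, ref) for frame in coords])
    if reference == "mean":
        for _ in range(max_iter):
            new_ref = aligned.mean(axis=0)
            aligned = np.stack([_kabsch(frame, new_ref) for frame in coords])
            shift = np.abs(new_ref - ref).max()
            ref = new_ref
            if shift < tol:
                break
        ref = aligned.mean(axis=0)
    elif reference != "first":
        raise ValueError(f"unknown reference mode {reference!r}")
    out = Trajectory(aligned, list(traj.residue_ids), traj.frame_times)
    return SuperpositionResult(aligned=out, reference=ref)


def rmsd_series(sup: SuperpositionResult) -> np.ndarray:
    """Per-frame RMSD (Å) to the superposition reference."""
    dev = sup.aligned.coordinates - sup.reference[None, :, :]
    return np.sqrt((dev**2).sum(axis=2).mean(axis=1))


def rmsf_profile(sup: SuperpositionResult) -> np.ndarray:
    """Per-residue RMSF (Å): time-RMS displacement about the mean position."""
    coords = sup.aligned.coordinates
    mean = coords.mean(axis=0)
    dev = coords - mean[None, :, :]
    return np.sqrt((dev**2).sum(axis=2).mean(axis=0))


def write_profile_tsv(values: np.ndarray, labels: Sequence, path: str | Path,
                      key: str = "index", value: str = "value") -> None:
    lines = [f"{key}\t{value}"]
    lines += [f"{lab}\t{v:.10g}" for lab, v in zip(labels, values)]
    Path(path).write_text("\n".join(lines) + "\n")
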