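"""Ground-truth-labeled synthetic inputs for every pipeline stage.

Two generators:

* ``simulate_trajectory`` draws Gaussian Cα fluctuations whose expected
  sample cross-correlation matrix equals a prescribed target. Fluctuations
  are isotropic — the same residue-residue correlation applies independently
  to the x, y and z displacement components — so the displacement-vector
  dot-product correlation reproduces the target exactly in expectation.

* ``simulate_two_cluster_alignment`` emulates the two-state site model of
  type-I functional divergence: each site is F1 (independently drawn rates in
  the two clusters) with probability ``theta_true`` and F0 (one shared rate)
  otherwise; site rates are gamma distributed, and characters evolve along
  each cluster tree by a Poisson number of substitutions per branch, each to
  a uniformly chosen different residue. The substitution model is a
  deliberate Jukes–Cantor-style stand-in: the divergence estimator only uses
  event counts, not exchangeabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .phylo import AMINO_ACIDS, Alignment
from .traj import ResidueId, Trajectory

__all__ = [
    "TrajectorySpec",
    "EvolutionSpec",
    "LabeledAlignment",
    "simulate_trajectory",
    "simulate_two_cluster_alignment",
    "balanced_tree",
    "hub_correlation_matrix",
    "write_truth_tsv",
    "read_truth_tsv",
]


@dataclass
class TrajectorySpec:
    """Gaussian-fluctuation trajectory with a prescribed residue DCCM."""

    n_residues: int
    n_frames: int
    target_correlation: np.ndarray
    fluctuation_scale: float = 1.0  # Å
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.fluctuation_scale <= 0:
            raise ValueError("fluctuation_scale must be positive")
        c = np.asarray(self.target_correlation, dtype=float)
        if c.shape != (self.n_residues, self.n_residues):
            raise ValueError(
                f"target_correlation must be {self.n_residues}×{self.n_residues}"
            )
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("target_correlation must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-10):
            raise ValueError("target_correlation must have unit diagonal")
        if np.abs(c).max() > 1 + 1e-10:
            raise ValueError("target_correlation entries must lie in [-1, 1]")
        w = np.linalg.eigvalsh(c)
        if w.min() < -1e-8:
            raise ValueError(
                f"target_correlation is not positive semidefinite "
                f"(min eigenvalue {w.min():.3g})"
            )
        self.target_correlation = c


def simulate_trajectory(spec: TrajectorySpec) -> Trajectory:
    """Sample a trajectory whose DCCM converges to the target correlation.

    Residues sit on a 3.8 Å-spaced backbone; frame f adds a zero-mean
    Gaussian displacement with Cov = scale²·target per Cartesian component.
    Same spec and seed give bit-identical output.
    """
    c = spec.target_correlation
    w, v = np.linalg.eigh(c)
    factor = v * np.sqrt(np.clip(w, 0.0, None))  # factor @ factor.T == c
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_frames, 3, spec.n_residues))
    disp = (z @ factor.T) * spec.fluctuation_scale  # (F, 3, N)
    base = np.zeros((spec.n_residues, 3))
    base[:, 0] = 3.8 * np.arange(spec.n_residues)
    coords = base[None, :, :] + disp.transpose(0, 2, 1)
    ids = [ResidueId("A", i + 1, "ALA") for i in range(spec.n_residues)]
    return Trajectory(coords, ids)


# ---------------------------------------------------------------------------
# Two-cluster alignments


@dataclass
class EvolutionSpec:
    """Two-cluster F0/F1 site model with gamma-distributed rates."""

    n_sites: int
    theta_true: float
    tree1: dendropy.Tree | str
    tree2: dendropy.Tree | str
    alpha: float = 0.5   # gamma shape of the site-rate distribution
    beta: float = 0.5    # gamma rate (mean site rate alpha/beta = 1)
    alphabet_size: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")
        if not 0.0 <= self.theta_true <= 1.0:
            raise ValueError("theta_true must lie in [0, 1]")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not 2 <= self.alphabet_size <= len(AMINO_ACIDS):
            raise ValueError(
                f"alphabet_size must be in [2, {len(AMINO_ACIDS)}]"
            )
        self.tree1 = _as_tree(self.tree1)
        self.tree2 = _as_tree(self.tree2)
        for label, tree in (("tree1", self.tree1), ("tree2", self.tree2)):
            leaves = list(tree.leaf_node_iter())
            if not leaves:
                raise ValueError(f"{label} has no leaves")
            for e in tree.preorder_edge_iter():
                if e.length is not None and e.length < 0:
                    raise ValueError(f"{label} has a negative branch length")


def _as_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(
        data=str(tree), schema="newick", preserve_underscores=True
    )


@dataclass
class LabeledAlignment:
    """Simulated alignment plus the latent truth used to generate it."""

    alignment: Alignment
    cluster_membership: dict[str, int]  # taxon -> 1 | 2
    site_state: np.ndarray              # 'F0' | 'F1' per site
    site_rates: np.ndarray              # (n_sites, 2): rate in each cluster

    def cluster_taxa(self, cluster: int) -> list[str]:
        return [t for t, c in self.cluster_membership.items() if c == cluster]


def _evolve(
    tree: dendropy.Tree,
    rates: np.ndarray,
    rng: np.random.Generator,
    alphabet_size: int,
) -> dict[str, np.ndarray]:
    """Poisson substitutions per branch; each event jumps to a uniformly
    chosen different state. Returns integer state vectors per leaf."""
    n_sites = len(rates)
    states: dict[int, np.ndarray] = {}
    leaf_states: dict[str, np.ndarray] = {}
    root = tree.seed_node
    states[id(root)] = rng.integers(0, alphabet_size, n_sites)
    for node in tree.preorder_node_iter():
        if node is root:
            st = states[id(root)]
        else:
            parent = states[id(node.parent_node)]
            b = node.edge.length or 0.0
            n_events = rng.poisson(rates * b)
            st = parent.copy()
            for step in range(int(n_events.max(initial=0))):
                mask = n_events > step
                jumps = rng.integers(1, alphabet_size, int(mask.sum()))
                st[mask] = (st[mask] + jumps) % alphabet_size
            states[id(node)] = st
        if node.is_leaf():
            leaf_states[node.taxon.label] = st
    return leaf_states


def simulate_two_cluster_alignment(
    spec: EvolutionSpec,
    site_states: np.ndarray | None = None,
    rate_overrides: dict[int, tuple[float, float]] | None = None,
) -> LabeledAlignment:
    """Simulate an alignment over both cluster trees with truth labels.

    ``site_states`` optionally fixes the latent F0/F1 labels (e.g. to plant
    divergent sites at chosen positions); otherwise each site is F1 with
    probability ``theta_true``. ``rate_overrides`` maps 0-based site indices
    to explicit (rate1, rate2) pairs — such sites are labeled F1 whenever the
    two rates differ, guaranteeing divergence at planted sites instead of
    leaving it to the luck of independent draws.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sites
    if site_states is None:
        is_f1 = rng.random(n) < spec.theta_true
    else:
        site_states = np.asarray(site_states)
        if site_states.shape != (n,):
            raise ValueError("site_states must have one label per site")
        is_f1 = site_states == "F1"

    shared = rng.gamma(spec.alpha, 1.0 / spec.beta, n)
    indep1 = rng.gamma(spec.alpha, 1.0 / spec.beta, n)
    indep2 = rng.gamma(spec.alpha, 1.0 / spec.beta, n)
    rate1 = np.where(is_f1, indep1, shared)
    rate2 = np.where(is_f1, indep2, shared)
    if rate_overrides:
        for site, (r1, r2) in rate_overrides.items():
            if not 0 <= site < n:
                raise ValueError(f"rate override for out-of-range site {site}")
            rate1[site], rate2[site] = r1, r2
            is_f1[site] = r1 != r2

    leaves1 = _evolve(spec.tree1, rate1, rng, spec.alphabet_size)
    leaves2 = _evolve(spec.tree2, rate2, rng, spec.alphabet_size)
    overlap = set(leaves1) & set(leaves2)
    if overlap:
        raise ValueError(f"taxon names shared between clusters: {sorted(overlap)}")

    letters = np.array(list(AMINO_ACIDS[: spec.alphabet_size]))
    taxa: list[str] = []
    rows: list[np.ndarray] = []
    membership: dict[str, int] = {}
    for cluster, leaves in ((1, leaves1), (2, leaves2)):
        for name in sorted(leaves):
            taxa.append(name)
            rows.append(letters[leaves[name]])
            membership[name] = cluster

    return LabeledAlignment(
        alignment=Alignment(taxa, np.array(rows)),
        cluster_membership=membership,
        site_state=np.where(is_f1, "F1", "F0"),
        site_rates=np.column_stack([rate1, rate2]),
    )


# ---------------------------------------------------------------------------
# Canned building blocks


def balanced_tree(
    n_leaves: int, branch_length: float = 0.15, prefix: str = "t"
) -> dendropy.Tree:
    """Balanced binary tree (n_leaves a power of two), equal branch lengths."""
    if n_leaves < 2 or n_leaves & (n_leaves - 1):
        raise ValueError("n_leaves must be a power of two >= 2")

    def newick(lo: int, hi: int) -> str:
        if hi - lo == 1:
            return f"{prefix}{lo + 1}:{branch_length}"
        mid = (lo + hi) // 2
        return f"({newick(lo, mid)},{newick(mid, hi)}):{branch_length}"

    mid = n_leaves // 2
    s = f"({newick(0, mid)},{newick(mid, n_leaves)});"
    return dendropy.Tree.get(
        data=s, schema="newick", preserve_underscores=True
    )


def hub_correlation_matrix(
    n_residues: int,
    hub_indices: list[int] | np.ndarray,
    hub_loading: float = 0.92,
    background_loading: float = 0.65,
) -> np.ndarray:
    """One-factor correlation matrix with designated hub residues.

    Hubs load strongly on a shared collective mode, the rest weakly, so
    hub–other correlations (hub·background) clear a 0.5 cutoff while
    other–other correlations (background²) stay below it. PSD by
    construction: C = llᵀ + diag(1 − l²).
    """
    loadings = np.full(n_residues, background_loading)
    loadings[np.asarray(hub_indices, dtype=int)] = hub_loading
    c = np.outer(loadings, loadings)
    np.fill_diagonal(c, 1.0)
    return c


def planted_rate_contrast(
    alpha: float, beta: float, lo: float = 0.02, hi: float = 0.98
) -> tuple[float, float]:
    """A strongly divergent (rate1, rate2) pair for planted F1 sites: the
    ``hi`` and ``lo`` quantiles of the site-rate gamma itself, so planted
    rates stay within the distribution the other sites are drawn from."""
    from scipy.stats import gamma as gamma_dist

    return (
        float(gamma_dist.ppf(hi, alpha, scale=1.0 / beta)),
        float(gamma_dist.ppf(lo, alpha, scale=1.0 / beta)),
    )


def write_truth_tsv(labeled: LabeledAlignment, path: str | Path) -> None:
    lines = ["site\tstate\trate1\trate2"]
    for s, (state, (r1, r2)) in enumerate(
        zip(labeled.site_state, labeled.site_rates), start=1
    ):
        lines.append(f"{s}\t{state}\t{r1:.10g}\t{r2:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth_tsv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (site_state, site_rates) as written by ``write_truth_tsv``."""
    states: list[str] = []
    rates: list[tuple[float, float]] = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        _, state, r1, r2 = line.split("\t")
        states.append(state)
        rates.append((float(r1), float(r2)))
    return np.array(states), np.array(rates)
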