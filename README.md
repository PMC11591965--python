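# divnet

Residue correlation networks from Cα trajectories, integrated with type-I
functional divergence between paralogous gene clusters.

## The problem

After a gene duplication, some alignment sites stop sharing an evolutionary
rate between the two descendant clusters (type-I functional divergence):
sites conserved in one paralog drift in the other. Independently, molecular
dynamics portrays a protein as a communication network: residues whose Cα
displacements are correlated exchange "information", and residues central to
that network (high closeness, betweenness, degree) are candidates for
functionally critical positions. This package implements both analyses and
their intersection — residues that are simultaneously network-central and
evolutionarily divergent ("hotspots") — for researchers studying enzyme
families such as the alcohol dehydrogenases where duplication and functional
specialization are intertwined.

## The model

**Network side.** For superposed Cα coordinates r_i(t), the dynamic
cross-correlation map (DCCM) is

    C_ij = ⟨Δr_i · Δr_j⟩ / √(⟨|Δr_i|²⟩ ⟨|Δr_j|²⟩),   Δr_i(t) = r_i(t) − ⟨r_i⟩.

Pairs with |C_ij| ≥ cutoff (default 0.5) become edges weighted
w_ij = −ln|C_ij|; closeness CC(v) = (n−1)/Σ_j g(v, v_j), betweenness
b_i = [Σ_{s<t} g_ist/n_st] / [n(n−1)/2] and degree ΣA_ij are computed on the
weighted graph. Essential-dynamics PCA of the same coordinates gives the
collective motion modes and their variance fractions.

**Evolution side.** Per-site substitution counts X₁, X₂ on the two cluster
trees (minimum-change parsimony) accumulate over total evolutionary times
T₁, T₂ with site rates λ ~ Gamma(α, β). The coefficient of divergence is

    θ = 1 − r_λ,   r_λ = Cov(λ₁, λ₂)/√(Var λ₁ · Var λ₂),

estimated by moments with a Poisson correction (Var(λ)T² = Var X − E X),
plus a simulation-based calibration that removes the bias parsimony counting
introduces in r_λ. Each site gets a posterior probability of divergence

    P(F1 | X₁, X₂) = θ·Q₁(X₁)Q₂(X₂) / [(1−θ)·K₁₂(X₁,X₂) + θ·Q₁(X₁)Q₂(X₂)],

with Q the negative-binomial (gamma-Poisson) count marginal and K₁₂ the
shared-rate joint; both are closed forms evaluated in log space.

**Integration.** Posteriors are mapped onto structure residues, min-max
normalized against the normalized centralities, and residues that are high
on both axes and near the diagonal of the normalized scatter are flagged as
hotspots.

Everything is validated on synthetic data with known truth
(`divnet.synthetic`): Gaussian trajectories with a prescribed target DCCM,
and two-cluster alignments with labeled F0/F1 sites — see
`docs/methods.md` for the generators' assumptions and limits.

## Worked example

```python
from divnet import synthetic as syn
from divnet.divergence import TypeIDivergence

tree1 = syn.balanced_tree(8, 0.1, "c1_")
tree2 = syn.balanced_tree(8, 0.1, "c2_")
spec = syn.EvolutionSpec(n_sites=2000, theta_true=0.3,
                         tree1=tree1, tree2=tree2, seed=42)
lab = syn.simulate_two_cluster_alignment(spec)

model = TypeIDivergence.from_alignment(
    lab.alignment, spec.tree1, spec.tree2,
    lab.cluster_taxa(1), lab.cluster_taxa(2),
)
res = model.fit(seed=0)
print(res.summary())
```

```
Type-I Functional Divergence (gamma-Poisson moment estimator)
==============================================================
sites                               2000
method                        calibrated
count-corr. inflation             1.3599
T1, T2                            1.4000      1.4000
r_lambda                          0.6781
theta (1 - r_lambda)              0.3219
theta bootstrap SE                0.0369
gamma shape (cluster 1)           1.1025
gamma rate  (cluster 1)           1.3821
gamma shape (cluster 2)           1.1025
gamma rate  (cluster 2)           1.3821
sites with posterior>0.5             137
==============================================================
```

The simulation planted θ = 0.3; the calibrated estimate is 0.32 ± 0.04. The
`count-corr. inflation` line is the simulated factor by which raw parsimony
counts overstate the between-cluster rate correlation (here ≈1.36 — the
uncalibrated estimate would have been θ ≈ 0.08). `res.posterior` holds the
per-site P(F1 | X₁, X₂); `res.top_sites(15)` ranks candidate divergent
sites.

The network side mirrors it:

```python
from divnet import network, traj

target = syn.hub_correlation_matrix(12, [3])   # residue 4 is a planted hub
tr = syn.simulate_trajectory(syn.TrajectorySpec(12, 2000, target, seed=0))
sup = traj.superpose(tr, reference="none")     # already in a common frame
rg = network.build_graph(network.compute_dccm(sup), correlation_cutoff=0.5)
top = network.rank_top(network.centrality_table(rg), k=3)
print(top["closeness"])                        # -> ['A:4:ALA', 'A:2:ALA', 'A:9:ALA']
```

The planted hub ranks first on closeness (and on betweenness and degree).

A config-driven CLI chains the stages through plain files —
`divnet all --config config.yaml`, or stage by stage
(`simulate`, `rmsd`, `dccm`, `network`, `pca`, `nj`, `counts`, `diverge`,
`integrate`), each writing a checksummed manifest.

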