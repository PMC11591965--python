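# Methods

## Scope and shape

The package couples two independent measurements of residue importance — a
correlation-network view of a Cα trajectory and a site-rate divergence view
of a two-cluster protein alignment — and intersects them. The statistical
core, type-I divergence estimation, is exposed as a model/results pair
(`TypeIDivergence` → `TypeIDivergenceResults` with `summary()`); the
surrounding stages (trajectory handling, DCCM/centralities, PCA, distances
and trees, integration) are plain functional modules, since they transform
data rather than fit it.

## Trajectory analysis

Frames are rigid-body fitted by least squares (SVD-based Kabsch). The default
reference is the converged mean structure (tolerance 1e-6 Å, ≤50 iterations),
because the fluctuation statistics (DCCM, RMSF, PCA) are defined about ⟨r⟩;
a first-frame mode serves deviation-from-start RMSD plots. A third mode,
`reference="none"`, performs no fitting: it exists for simulated fluctuation
fields, which are generated directly in a common frame. This matters more
than it may appear — per-frame centering exactly removes any collective mode
with uniform loadings (it is indistinguishable from a rigid translation), so
superposing a simulated trajectory whose target correlation contains a global
factor destroys precisely the structure being validated. Real MD data, which
has genuine rigid-body drift, should keep the default.

DCCM entries are the frame-averaged dot products of displacement vectors,
normalized per residue pair; the diagonal is set to exactly 1 and the matrix
is symmetrized against floating-point asymmetry. A residue with zero total
fluctuation makes the normalization undefined and raises an error naming the
residue.

Edges of the residue network are pairs with |C_ij| above a correlation
cutoff. The cutoff defaults to 0.5 and is configuration-exposed; taking the
magnitude treats anti-correlated motion as communication of equal strength,
the standard convention in correlation-network work. Edge weights are
−ln|C_ij| (natural log; the base is configurable and only rescales shortest
paths uniformly). Note the adjacency is *defined* by the cutoff: a literal
"any nonzero weight is an edge" rule would connect nearly every pair, since
finite sampling makes no correlation exactly zero.

Centrality conventions: closeness is computed per connected component with
the component-local node count ((n_c − 1)/Σ d), isolated nodes scoring 0;
betweenness excludes endpoints and is normalized by the global n(n−1)/2 pair
count (a 3-node path's middle node scores 1/3); degree is the adjacency row
sum. Rankings break ties by ascending residue number.

Essential-dynamics PCA runs on mean-centered flattened coordinates via SVD
(equivalent to eigendecomposition of the 3N×3N covariance with ddof 1, but
stable when frames < 3N). Variance fractions are always computed over the
full spectrum, so they sum to 1 regardless of how many components are
retained. No mass weighting: all sites are Cα.

## Evolutionary analysis

Distances are p-distances with pairwise gap deletion. Neighbor joining is
the standard Saitou–Nei agglomeration; ties in the Q criterion are broken by
the lexicographically smallest pair of subtree labels (a subtree is labeled
by its smallest leaf), making the output deterministic, and negative branch
lengths are clamped to zero with the deficit moved to the sister branch so
path lengths are preserved. On additive inputs the algorithm is exact; the
test suite verifies topology and lengths to 1e-10 against randomly generated
trees.

Per-site change counts use unit-cost dynamic programming over states
(Sankoff), which equals Fitch parsimony on binary trees but remains exact on
multifurcations and after subtree extraction; gap/unknown characters
contribute zero cost for every state (missing data). The counter sits behind
a narrow seam (`fitch_site_changes`) so model-based counters can be swapped
in. T₁, T₂ are branch-length sums of the cluster subtrees.

### The divergence model

Counts are modeled as X | λ ~ Poisson(λT) with λ ~ Gamma(α, β) shared
between clusters at constrained (F0) sites and drawn independently at
divergent (F1) sites; the prior P(F1) = θ = 1 − r_λ. The count marginal
Q(i) and the shared-rate joint K₁₂(i, j) have negative-binomial-type closed
forms; both are computed through log-gamma functions, and the test suite
checks them against adaptive quadrature of the defining integrals (1e-8)
and for normalization.

Moment estimation: Var(λ)T² = Var(X) − E[X] (the Poisson correction),
Cov(λ₁, λ₂)T₁T₂ = Cov(X₁, X₂), r_λ their correlation, θ clipped to [0, 1].
The gamma is fitted by moments; by default a single (α, β) is fitted from
the two clusters' averaged moment estimates — the marginal rate distribution
is the same gamma under both F0 and F1, so this is consistent at any θ and
stabilizes small-sample fits. A separate-gamma mode keeps per-cluster
marginals (K₁₂ retains the pooled gamma). The θ standard error comes from a
seeded site bootstrap (default 200 replicates).

**Parsimony calibration.** The Poisson correction is exact when counts are
conditionally Poisson, but parsimony counts are not: they saturate (a
k-taxon cluster can show at most k−1 changes) and are conditionally
underdispersed, most severely at the high-rate sites that carry most of the
rate-variance signal. The result is an inflation of the raw count
correlation above r_λ — around 1.2–1.4 for 8-taxon clusters — that does not
vanish as branch lengths shrink, because the probability that two
substitution events interact on the tree depends on the topology, not the
branch scale. Plain moment estimation therefore underestimates θ severely
on alignment-derived counts.

The calibrated estimator (default whenever cluster trees are available)
removes this bias by measuring it: constraint-only (θ = 0) data are
re-simulated on the same trees and pushed through the same parsimony
counter, giving the inflation factor I₀ directly, and the observed
correlation is divided by it. This is valid because Cov(X₁, X₂) scales with
(1 − θ) while the corrected variances are θ-free, so the inflation is a
single multiplicative factor at every θ. Because the gamma fitted from the
data is itself attenuated, the calibration gamma is first adjusted by one
multiplicative self-consistency step (simulate at the fitted values, refit,
invert the distortion). Defaults: 3 adjustment and 4 calibration replicates
of the observed number of sites. The estimator remains a moment estimator;
no likelihood is maximized. On the reference conditions (2000 sites, 8+8
taxa, balanced trees with 0.1-substitution branches), the acceptance tests
recover mean θ̂ within ±0.07 of θ ∈ {0, 0.3, 0.7}.

Posteriors use the fitted θ with a Laplace-type shrinkage
θ* = (nθ̂ + 1)/(n + 2) — negligible away from the boundary, but preventing a
boundary estimate (sampling noise at small n) from collapsing every
posterior to exactly 0 or 1 and erasing the per-site evidence. The reported
θ̂ itself is not shrunk, and the standalone `site_posterior` function applies
no shrinkage (θ = 0 and θ = 1 give exactly 0 and 1).

## Integration

Alignment columns map to structure residues through the structure taxon's
gapped row (k-th non-gap column ↦ k-th residue). Posteriors and the three
centralities are min-max normalized over the mapped residues; association is
summarized by Pearson and Spearman coefficients. A residue is a hotspot for
a measure iff q_norm ≥ q_min, centrality_norm ≥ c_min and
|q_norm − centrality_norm| ≤ band (defaults 0.5 / 0.5 / 0.15). The diagonal
band operationalizes "high on both axes, in proportion"; all three constants
are configuration-exposed since no canonical values exist. In the planted
validation scenario, recovery is assessed on the union of the three
measures: betweenness alone splits credit among redundant hubs (each
non-hub pair routes through whichever hub offers the cheapest path), a real
property of winner-take-all shortest-path counting, so closeness and degree
drive the union.

## Synthetic data: what it emulates and what it does not

**Trajectories.** Residues sit on a 3.8 Å-spaced backbone; each frame adds
an independent zero-mean Gaussian displacement whose residue-residue
covariance equals scale² × target-correlation, applied independently and
identically to x, y and z. Because the displacement components are
isotropic, the dot-product DCCM converges to the target exactly; the
generator factorizes the target by eigendecomposition, so any positive
semidefinite correlation matrix (including singular ones) is accepted.
Defaults: fluctuation scale 1 Å. The planted-hub construction is a
one-factor model (hub loading 0.92, background 0.65): hub–other
correlations (0.60) clear the 0.5 cutoff, other–other correlations (0.42)
stay below it, and positive semidefiniteness holds by construction. Not
emulated: temporal autocorrelation (frames are i.i.d.), anisotropic or
position-dependent fluctuations, rigid-body drift, and any force-field
physics. Passing tests therefore demonstrate estimator correctness on the
stated statistical model, not realism of protein dynamics.

**Alignments.** Each site is F1 with probability θ (or as planted); F0
sites share one Gamma(α, β) rate across clusters, F1 sites draw two
independent rates. Characters evolve along each cluster tree with a Poisson
number of events per branch and uniform replacement among the other 19
amino acids — a Jukes–Cantor-style stand-in chosen because the divergence
model constrains only event counts, never exchangeabilities (the true
substitution matrix underlying the published site counts is unknown). Root
states are uniform. Defaults: α = β = 0.5 (strong among-site rate
heterogeneity with mean rate 1, typical of protein families), balanced
8-leaf cluster trees with 0.1-substitution branches (T = 1.4 per cluster:
informative counts at moderate parsimony saturation, inside the calibrated
estimator's validated regime). Planted divergent sites take the 98th and
2nd percentile of the same gamma as their two rates — maximal contrast that
stays within the rate distribution. Not emulated: indels (gaps only enter
via hand-built fixtures), rate autocorrelation along the sequence, and
selection on specific residues.

## Numerical choices

- All gamma-Poisson probabilities in log space; factorials via log-gamma.
- DCCM clipped to [−1, 1] and symmetrized; exact unit diagonal enforced.
- NJ Q-criterion ties resolved within a 1e-10 relative tolerance window.
- PCA uses SVD of the centered frame matrix; covariance ddof = 1.
- Moment corrections use ddof = 1 sample variances.
- Bootstrap replicates whose corrected variance goes non-positive are
  dropped and counted (`n_bootstrap_failed`).
- Seeds: every stochastic routine takes an explicit seed; the CLI records
  seeds in per-stage manifests; internal seed derivation stays below 2³¹.

## Known limitations

- The calibrated θ estimator assumes the generator's substitution process
  is an adequate proxy for the process that produced the real alignment;
  model mismatch there propagates into the inflation factor.
- Parsimony counts remain biased inputs for the *posterior* (the gamma fit
  uses the same corrected moments); posteriors are therefore best treated
  as a ranking, which is how the integration stage consumes them.
- Betweenness-based hotspot flags are unreliable when several hubs offer
  redundant routes (see above).
- Closeness on disconnected graphs is component-local; comparing closeness
  across components of very different sizes is not meaningful.
- The DCD binary trajectory format is not parsed; multi-model PDB and plain
  XYZ only.
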