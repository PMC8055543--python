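# Methods

## Model networks

Cell-contact maps are modelled as bond-diluted triangular lattices in the
plane. A full patch of side `L` has rows alternating `L` and `L − 1` nodes
(row spacing √3/2, odd rows offset by ½), so `N = L² − ⌊L/2⌋` and every
bond has unit length; `L = 7, 10, 11, 15, 16, 18, 19, 25, 35` give the
reference sizes `N = 46, 95, 116, 218, 248, 315, 352, 613, 1208`. Nodes are
never removed by dilution, only bonds, so the gc normalization always uses
the full node count.

**Connectivity conventions.** The mean connectivity is ⟨C⟩ = 2M/N. Two
boundary-corrected maxima are provided. The quadratic correction evaluated
at an explicit integer side, (8 + 16(L−2) + 6(L−2)²)/N, is available as
`max_connectivity(L, N)` and via `connectivity_report(..., boundary="rows")`.
The package default evaluates the same correction at the real-valued side
√N, which collapses to ⟨C⟩Max,N = 6 − 8/√N and coincides with the actual
full-patch 2M/N to a fraction of a percent; under it a fully bonded patch
has ⟨k⟩ = 1 exactly and ⟨k⟩ is the bond-occupation probability. All
criticality statistics use this convention; it is the one under which the
finite-size critical points land at their quoted values (⟨C⟩ ≈ 3.9 ↔
k ≈ 0.68 at N = 1208). Dilution targets are specified as ⟨C⟩ (or as k times
the full-patch ⟨C⟩), with exactly `M_full − round(target·N/2)` bonds
removed, leaving a residual of at most 2/N.

**Correlated dilution.** Spatially correlated bond loss (the model of
desynchronized-division clusters) removes bonds in chains: after removing
bond *e*, with probability λ the next removal is drawn uniformly from the
*vicinity* of *e* — bonds whose midpoints lie within ℓ (default ℓ = l₀ = 1)
of *e*'s midpoint, membership precomputed on the undiluted geometry — and
with probability 1 − λ the chain restarts at a uniformly random surviving
bond. An exhausted vicinity relocates the chain to a random already-removed
vicinity bond; relocation is capped at 64 hops (then the chain restarts at
random) to guarantee termination in fully eroded regions — for λ ≤ 0.9 the
cap is effectively never reached. Chains carve contiguous holes of mean
size ~1/(1 − λ).

## Rigidity

Generic 2D rigidity is decided combinatorially by the (2,3) pebble game
(numba-compiled). Each node holds two pebbles; an edge is accepted as an
independent constraint when four pebbles can be gathered on its endpoints.
Floppy modes follow the Maxwell count F = 2N − 3 − |independent edges| for
a connected network; disconnected inputs are counted per component (three
trivial motions per component of ≥ 2 nodes, two per isolated node).

Maximal rigid clusters are grown from each unassigned independent edge:
with three pebbles pinned on its endpoints, a node belongs to the cluster
iff no free pebble is reachable from it in the pebble digraph (searches
blocked at the pinned endpoints). A failed search certifies its entire
visited set rigid; a successful one certifies only its root floppy, so the
decomposition is independent of probe order (asserted in tests). Because
rigid clusters are connected induced subgraphs, candidates are enumerated
by frontier growth from the base edge, which makes the decomposition
near-linear in practice (≈ 2 ms at N = 1208 near criticality). Clusters
have at least three nodes (a bare bond leaves its endpoints floppy); a node
may sit in several clusters as a shared joint. The whole machinery is
validated edge-for-edge and pair-for-pair against a numerical rank oracle
on the generic rigidity matrix (singular values below 1e−8 of the largest
treated as zero) over hundreds of random frameworks.

**Giant vs finite clusters.** The order parameter gc is the largest
cluster's node fraction, as plotted in gc curves. For cluster-size
*statistics* the pool consists of the sizes of clusters that do **not**
span the patch (reaching within half a bond length of both extremes along
either axis; the tolerance also absorbs positional jitter). Below the
transition nothing is excluded; above it the percolating cluster(s) drop
out. This is the convention under which the variance peak, its location
drift with N, and the mean cluster size are mutually consistent; excluding
"the largest cluster per replica" instead suppresses the variance
divergence by an order of magnitude. A single-axis variant is available
(`axis=1` is the force-transmission direction of the shear protocol).

## Criticality statistics

- **Sweeps**: per (N, k, replica), a fresh dilution and decomposition;
  default grid 50 equidistant k in [0.2, 1], 50 replicas; each replica's
  seed derives from one ensemble seed, so sweeps are bit-reproducible.
- **Critical point**: the variance of the pooled finite-cluster sizes
  peaks near the transition; the estimate is the interpolated argmax
  (parabola through the three points around the discrete maximum). The
  gc-crossing estimator instead interpolates where mean gc first exceeds
  0.5; it is far less noisy (gc is bounded) and is the reference for the
  mechanics comparison. Measured locations: k_c ≈ 0.67–0.68 at N = 1208,
  ≈ 0.72–0.73 at N = 95 (the small-size drift is a boundary effect), and
  gc-crossings extrapolate against N^(−1/2) to ≈ 0.66, the isostatic point
  2/3 of the infinite triangular lattice.
- **Power-law fit**: discrete maximum likelihood with Hurwitz-zeta
  normalization on the tail s ≥ s_min (default 3, the minimal rigid
  cluster); degenerate or undersized samples raise `EstimationError`. The
  estimator recovers planted exponents within 0.1 at 10⁴ samples.
- **Variance scaling**: two-stage — the peak is localized on a near-critical
  grid, then the peak variance and mean are re-estimated from dedicated
  replicas at the localized point. Reading the maximum straight off the
  sweep would inflate the estimate (selection bias on a heavy-tailed
  fourth-moment statistic); the grid's coarseness biases it down. The
  re-estimated σ_c² + ⟨s_c⟩² grows linearly in N.
- **λ fit**: candidate correlation strengths are ranked by the base-2
  Jensen–Shannon divergence between the observed pooled finite-cluster
  size distribution and simulated cohorts matched in network sizes (and,
  optionally, per-network connectivities — pinning them removes
  connectivity-sampling noise). Distributions are compared on log-spaced
  size classes: the distributions are heavy-tailed and the correlation
  signature lives in the tail, which per-size bins would underweight. At
  the realistic cohort size (95 networks) the recovery of a planted
  λ = 0.47 scatters by about one 0.15 grid step; tests therefore assert
  median recovery over several seeded cohorts.

### Known discrepancies

Two published statistics of the near-critical cluster-size distribution do
not reproduce under this (rank-oracle-validated) decomposition, under any
of the pooling conventions examined:

- the discrete-MLE exponent at s_min = 3 measures γ̂ ≈ 3.1–3.3, not 2.5:
  the distribution's head (s = 3, 4) is steeper than its tail (log-binned
  tail slope ≈ 2.1), and the head dominates the likelihood;
- the variance-growth coefficient measures ≈ 0.8–1.3, not 2. The two are
  one finding: σ_c² ∼ N/(3 − γ_eff) with γ_eff ≈ 2.2 matches both the
  measured slope and the tail exponent.

The *qualitative* claims — a heavy-tailed p(s) at criticality, a
size-independent ⟨s⟩ ≈ 4, and σ_c² ∝ N — all hold. The package reports the
measured values rather than the published ones.

## Spring-network mechanics

Bonds are Hookean springs (K = 1, rest length = initial length) on
overdamped nodes, ρ dx/dt = ΣK(l − l₀)r̂ with ρ = 1 (only ratios matter in
steady state), integrated by explicit Euler with δt ≤ 0.1ρ/K enforced
(default 0.1). The bottom row is clamped; the top row is displaced by
δx = 0.01 in one step and held (step-and-relax; linearity is verified by
halving δx). The transmitted force F₀ is the late-time average (final 10%
of steps) of the lateral force on the clamped row. The horizon is
calibrated so a fully connected N ≈ 248 patch reaches force stationarity:
Te = 6000 steps (600 time units) at the default δt.

Viscosity enters through bond turnover: each step, every bond resets its
rest length to its current length with probability 1 − exp(−1/τ), τ in
integration steps (healing without connectivity change). For the viscosity
readout the top row is driven at constant velocity v = δx/(Te δt) for
Te + 5τ steps and η = F₀/v from the late-time force; above the transition
η ∝ τK (the τ = Te vs 2Te ratio measures ≈ 2.1–2.3, slightly above 2
because the larger τ sits deeper in the quasi-static regime). Elastic F₀
and viscous η switch on at the same connectivity, within one grid step of
the topological gc-crossing — the central topology-predicts-mechanics
statement.

## Adhesion model

For a symmetric doublet the printed 3D area formulas are used as given
(A_cc = π[R_c sin(θe/2)]², A_cf = 2πR_c²[1 + cos(θe/2)] per cell,
E = 2γ_cf A_cf + γ_cc A_cc); minimizing E over θe under per-cell volume
conservation reproduces α = cos(θe/2) exactly, which the tests verify by
dense scan.

The 4-cell rhombus is two-dimensional: equal-area cells are discs truncated
by the midplane chord of each contact, which sits at distance Rα from the
centre and therefore satisfies the doublet angle relation at the rims.
Cell centres form a rhombus whose sides equal the touching distance 2Rα;
the default shape is the equilateral two-triangle rhombus (sharp-vertex
half-angle 30°, configurable). Each cell's radius is rescaled to conserve
its isolated-disc area — exact, since the truncated shape is similar in the
radius; before any junction all four cells are congruent, afterwards the
three-contact cells are a few percent larger and shared interfaces are kept
from the nominal symmetric construction (an approximation that does not
affect the threshold, which is a pre-junction quantity). A tricellular
junction is declared when two chords of one cell cross inside its disc
(rim endpoints within 10⁻³R), which collapses the central interstitial gap
and creates the short-diagonal contact; the 4-node contact graph is then
handed unchanged to the pebble game. The threshold is α* = cos(sharp
half-angle): 0.866 for the default geometry, reported with the sweep's
grid step (0.005) as uncertainty, and invariant under uniform rescaling.
Only contact-count topology feeds the rigidity call; contact lengths are
exact clipped chords. Hysteresis on re-increasing α and many-cell
disordered aggregates are out of scope.

## Tissue observables

- **Contact maps**: ⟨C⟩ = 2·contacts/cells; ⟨k⟩ by the same boundary
  conventions as lattices (default 6 − 8/√N; the integer-side variant
  infers L = round(√(N + ⌊√N⌋/2))). Maps exported from model lattices
  report identical numbers.
- **MSRD**: squared change of the 3D inter-nucleus distance of a cell pair
  between two timepoints; invariant under rigid co-translation. Time units
  follow the input table (the default generators use minutes).
- **SHC**: with n of N nuclei dividing, the two-stage binomial null
  (quadrant assignment ~ B(1/4), division ~ B(q = n/N)) has per-quadrant
  std ½√(n(1−q)); the SHC is the sample variance (ddof = 1) of the four
  absolute z-scores. No divisions → missing, never zero. The uniform
  synthetic generator is calibrated against a direct simulation of this
  null.
- **Aspiration viscosity**: slopes are fit on the longest window whose
  linear fit reaches R² ≥ 0.98 (windows scanned longest-first over a
  coarse start grid, ≥ 8 samples); the retraction slope falls back to 0
  when no such window exists (flat recovery — the aspiration rate then
  dominates). η = R_p ΔP/(3π(L̇asp + L̇ret)), Pa·s for µm and Pa inputs.
  Planted viscosities spanning 10²–10⁵ Pa·s are recovered within 5% at
  0.5% deformation noise; at ≳1% noise the R² gate starts rejecting
  shallow retraction phases and the estimate degrades gracefully toward
  the aspiration-only formula (+ΔP/(ΔP−P_c) bias).

## Synthetic cohorts

The generators emulate the *statistical* structure of the experimental
recordings, not their imaging detail. A cohort is a set of contact maps
(default 92 for the wild-type-like condition, 95 for the correlated
Chk1-like one, matching the real sample counts) whose sizes are drawn
around ⟨N⟩ ≈ 100 (sd 15, clipped to [40, 250]) and whose normalized
connectivity follows a piecewise-linear schedule at 10-minute resolution:
0.85 an hour before spreading, minimum 0.60 at onset, recovery to 0.80 an
hour after, with per-network noise (sd 0.02). Bond loss is uncorrelated
(λ = 0) for the wild-type-like condition and correlated with λ = 0.47 for
the Chk1-like one. Positional jitter (sd 0.1 l₀) is applied after the
topology is fixed — rigidity is purely topological. Aspiration traces are
forward-simulated from the creep-slope formulas with the experimental
protocol constants (R_p = 17.5 µm, ΔP = 150 Pa, 3-min aspiration, 0.5-s
sampling); division maps draw from the two-stage binomial null or a
Dirichlet-skewed clustered variant. Every generator is bit-reproducible
from its spec (which includes the seed) and returns its ground truth.

What the generators do *not* emulate: real contact maps are not diluted
triangular lattices (coordination disorder, cell-size heterogeneity,
segmentation error), connectivity trajectories differ across embryos, and
division-driven bond loss is imposed statistically rather than simulated
mechanistically. Passing recovery tests therefore demonstrates estimator
correctness under the model's assumptions, not performance on real images.

## Problem sizes and reproducibility

Acceptance-grade computations use: 31-point near-critical grids with 30
replicas at N = 1208; 36-point grids with 300 replicas at N = 95 (small
lattices are cheap and the peak location converges only around 300);
50-point full-range grids with 30 replicas for gc-crossings; 60
near-critical L = 35 lattices for the exponent pool; 150 dedicated
replicas per size for peak-variance re-estimation; 20 replicas per
connectivity for mechanics curves (8 for the viscous ones). One master
seed drives every ensemble through `numpy.random.SeedSequence`; identical
seeds give identical tables byte for byte.
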