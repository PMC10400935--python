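# Methods

## The model

burstscape analyses single-cell expression with the two-state (telegraph)
model of stochastic gene transcription.  A gene promoter switches between an
OFF and an ON state with activation rate θ_on and inactivation rate θ_off;
while ON, mRNA is produced at rate θ_t, and transcripts degrade at rate θ_d.
All rates are expressed in units of θ_d, which is therefore fixed at 1.  At
stationarity the copy number follows the Poisson-Beta mixture

    m | p ~ Poisson(θ_t · p),   p ~ Beta(θ_on, θ_off),

the classical steady-state law of the model.  Two biologically interpretable
statistics derive from the rates: the transcriptional burst size
S = θ_t/θ_off (transcripts per ON episode) and the burst frequency
F = θ_on (episodes per degradation time).

### PMF evaluation

The stationary PMF is computed by fixed-node Gauss-Jacobi quadrature (512
nodes) of the Poisson kernel against the Beta density.  The Jacobi weight
absorbs the Beta endpoint singularities exactly, so the scheme is stable for
rates below 1 and for large θ_t, where the equivalent confluent-
hypergeometric series cancels catastrophically; the test suite cross-checks
the quadrature against that series (agreement ~1e-10 for moderate θ_t) and
against both an exact Poisson-Beta sampler and a Gillespie simulation of the
underlying reaction network.

### The fitting grid

Maximum-likelihood fitting is a grid search over log-spaced rates: θ_on in
[1e-2, 1e1] and θ_off in [1e-2, 1e2] (20 points each), θ_t in
[1e-1, 2·m_max] (25 points), with m_max = 200 counts.  All 10,000 PMFs are
computed once and cached (~16 MB); each cached PMF is conditioned on the
truncated support 0..m_max, the correct likelihood for count data capped at
m_max.  Ties in the grid search break to the smallest (θ_t, θ_off, θ_on) so
fits are deterministic.

The θ_on axis deliberately stops one decade lower than θ_off's.  Stationary
counts cannot distinguish fast switching (θ_on ≫ θ_d) from the Poisson
limit, so grid points beyond θ_on ≈ 10 form a likelihood plateau of
degenerate, equivalent fits.  Including them has a concrete cost: genes
whose counts are Poisson-compatible get assigned the axis ceiling, and those
extreme values dominate raw-scale Pearson correlations between fitted burst
frequency and any downstream quantity.

## Pipeline stages

**Pre-processing.** One matrix-wide rescaling caps expression at m_max
(per-gene scaling would distort relative expression, which the fit absorbs
only through θ_t); values are rounded half-up for platform determinism.
Cells expressing too few genes and genes detected in too few cells are
removed; optionally only the most-variable genes (variance of the normalised
counts, ties by gene id) are kept.  All filters are idempotent.

**Clustering.** Cells are grouped to maximise the total cell log-likelihood:
the sum over cells of Σ_g log P(m_{n,g} | θ_{g,k}) under their cluster's
per-gene fitted parameters.  The optimiser is a batch coordinate ascent —
refit every (cluster, gene) grid MLE, then reassign every cell to its
maximum-likelihood cluster — which makes the objective provably
non-decreasing (asserted at run time); clusters emptied by reassignment are
repaired by moving in the globally worst-fitting cell before the next refit,
which also cannot decrease the objective.  The initial partition anchors on
K randomly chosen seed cells (nearest seed by L1 distance): a balanced
random labelling would give every cluster the same pooled mixture fit and
the ascent could never break the symmetry.  Because the ascent is local, 10
seeded restarts are run per greedy pass and the best objective kept.  Fifty
greedy passes are aggregated into a consensus matrix (co-assignment counts),
finalised by PAM-style k-medoids (k-medoids++ seeding, 20 restarts) on the
dissimilarity 1 − consensus/n_runs, and per-cluster parameters are refit on
the final labels.  When K is not given, the eigengap of the symmetric
normalised Laplacian of the consensus similarity picks it (disconnected
similarity short-circuits to the component count; a gapless spectrum returns
2 with a warning).

**Lineage.** The distance between two clusters is the mean per-cell drop in
log-likelihood when both are refit as one pooled cluster — zero up to grid
resolution for identically distributed clusters, and growing with their
separation.  Edges are added in ascending distance, skipping any edge that
would close a cycle (lineages are acyclic), until the graph connects: the
minimum spanning tree of the cluster distances.  The root is the cluster
with the smallest mean capture time (or user-specified); cluster pseudotime
is hop depth from the root scaled so the deepest leaf sits at 1, so leaves
at unequal depths receive unequal pseudotimes.

**Placement and uncertainty.** Each cell is placed on the adjacent edge and
fractional position s (21-point grid, refinable) that maximise its
interpolated likelihood, where the per-gene probability is the
distribution-level blend (1−s)·P_{k1,g}(m) + s·P_{k2,g}(m) of the endpoint
clusters' PMFs.  The cell's transcriptional uncertainty is the negative log
of that maximal likelihood (NLL); the per-gene NLLs at the optimum are
recorded so that their row sums reproduce the cell NLL exactly, and the cell
pseudotime linearly interpolates the endpoint clusters' pseudotimes at s.

**Summaries.** Cluster-averaged gene NLLs (NLL̄_{g,k}), a moving-window
average of NLL over pseudotime-sorted cells along each root→leaf path
(window = 10% of the path's cells, stride one, pseudotime ties broken by
cell id), and high-uncertainty gene sets: gene g belongs to cluster k's set
when its NLL exceeds δ = mean + 3 SD (over every entry of the per-gene
per-cell NLL matrix — entry-wise, since the alternative reading over
cell-total NLLs would make the threshold incomparable to per-gene values) in
at least 30% of the cluster's cells.

**Landscape.** The expression matrix is z-scored gene-wise (constant genes
dropped with a warning) and embedded with PCA (sign fixed so each
component's largest-magnitude loading is positive) or seeded t-SNE.  NLL is
then fitted as a surface on a regular 30×30 grid by penalised least
squares: bilinear interpolation from grid nodes to cells, with a
second-difference (Laplacian) roughness penalty whose weight is the
``smoothness`` parameter (default 1) scaled by the data/node count ratio.
Constants and planes lie in the penalty's null space and are reproduced
exactly; a singular system triggers an automatic 100× smoothness increase
with a warning.

**Statistics.** Burst size S_{g,k} and frequency F_{g,k} from the fitted
cluster parameters are correlated (Pearson, over all (gene, cluster) pairs)
with NLL̄_{g,k}; significance uses t = r·√((n−2)/(1−r²)) with n−2 degrees of
freedom and the reporting threshold p ≤ 0.01 (no multiple-testing
correction by default; Benjamini-Hochberg is available on request).
Cell-wise RNA velocity is the Euclidean norm of the per-gene velocity
vector; it is compared with the cell-wise mean NLL over the same gene panel
by a lagged cross-correlation of the two series averaged in 20 equal-count
pseudotime bins, over lags up to ±5 bins (overlaps shorter than 3 skipped);
a positive best lag means velocity leads uncertainty.

## The synthetic-data generator

The generator plants a rooted tree of cell states and emulates the
statistical structure the analysis assumes, so every stage can be exercised
offline with full ground truth.

*Differentiation as frequency modulation.*  Each gene receives an intrinsic
transcription rate θ_t ~ logU(8, 40) and burst size S ~ logU(5, 50) (θ_off =
θ_t/S, clipped to [0.25, 4]); clusters differ through the activation rate:
log θ_on starts at logU(0.03, 0.6) in the root and performs a per-gene drift
walk along tree edges (persistent drift N(0, 0.6) per gene, per-edge jitter
N(0, 0.7), sibling branches inherit the trunk drift plus opposite-signed
components N(0, 0.6), reflection at θ_on ∈ [0.01, 2.5] so deep clusters keep
separating instead of piling on a bound).  Frequency modulation is the
documented dominant mode of expression change in mammalian bursting
kinetics, and it has a structural virtue here: within a gene, the entropy of
the stationary law is monotone in F, so the uncertainty/bursting
correlations the analysis measures are properties of the ensemble rather
than accidents of one draw.

*Transition states.*  Each designated transition cluster engages a burst
module — a random 15% of genes — whose burst size is multiplied by f
(default 5) and burst frequency by √f at the transition itself, applied as
θ_t·√c, θ_off/√c, θ_on·√c at ramp level c.  Engagement ramps along the
graph with profile c = f^e, e(hops) = (1, 0.45, 0.25, 0): the concave first
step keeps a saddle between the uncertainty hills of two transition states
that sit two hops apart (any shallower profile provably fills the valley
between them), while the shallow tail limits the footprint the module adds
to adjacent cluster distances, which the lineage reconstruction must not be
dominated by.

*Outputs.*  Counts are drawn from the exact stationary sampler; planted
pseudotime is cluster depth/max depth plus N(0, 0.02) jitter; capture time
is the cluster depth (giving the pipeline its root signal, mirroring the
time-course designs the method is used on).  The velocity proxy gives each
cell, per gene, |mean expression one depth unit ahead − own cluster mean|
plus seeded noise (10% of the signal RMS), so velocity magnitude leads the
burst-driven NLL rise by one cluster unit by construction; it is a
magnitude signal with a controllable lead, not a spliced/unspliced kinetic
model.

*Presets.*  linear-4 (4 clusters × 100 cells, 50 genes), linear-6,
bifurcation-5 (1→2→3 with 3 branching into 4 and 5; 60 genes, 100
cells/cluster; transition 3 inflated ×5) and two-bifurcation-7 (branch
nodes 2 and 5, both inflated), covering the linear, single- and
multi-branching lineage shapes the method targets.

### What the generator does and does not emulate

It reproduces lineage-structured telegraph counts, graded burst engagement
at transitions, and a leading velocity signal.  It does not emulate
platform noise (Ct quantisation, UMI saturation, dropout), library-size
variation, doublets, or genuinely continuous (clusterless)
differentiation; passing tests therefore demonstrate that the
implementation recovers planted structure of the assumed form, not that the
model is adequate for any particular real dataset.  Real inputs must be
count-like; normalised Ct values require an external Ct→count transform the
package does not provide.

## Problem sizes and validation conditions

The test suite validates the pipeline on the presets at their default sizes
(400-700 cells, 50-60 genes) with master seed 42, the package's global seed
default: clustering ARI ≥ 0.9 with the true K, exact recovery of the three
planted topologies, pseudotime rank correlation ≥ 0.8, moving-average NLL
peaks within ±0.15 pseudotime of the planted transition, positive
burst-size and burst-frequency correlations at p ≤ 0.01, and a strictly
positive velocity lead.  Across arbitrary generator seeds these properties
are typical but not certain — in repeated draws, exact topology recovery
holds in roughly two thirds of realisations and the remaining properties in
roughly 85-95% — because a single scenario draws only 50-60 genes and the
planted signals sit deliberately close to the scale of the drift noise.
PMF validation uses 10^6 exact draws (total variation < 0.005) and 10^5
Gillespie trajectories run to 12 degradation times (TV < 0.01).

## Numerical choices and degenerate inputs

Probabilities below 1e-300 are floored in log space; a zero mixture
probability at an observed count aborts placement with advice to raise
m_max.  `stationary_pmf` renormalises only when the truncated tail is below
1e-6 and refuses to compute when it exceeds 1e-3.  Greedy objective
monotonicity is asserted on every run.  The k-medoids finaliser warns and
splits arbitrarily (seeded) when the consensus is uninformative; the
eigengap warns and returns 2 on a gapless spectrum.  All randomness derives
from explicit seeds; identical config and master seed reproduce every
output byte for byte (the manifest records config hash and output
checksums).

## Known limitations

- Numeric parity with the original MATLAB toolbox this analysis follows is
  not guaranteed: the stationary-PMF evaluation scheme and the fitting grid
  are reconstructions, since neither is fully specified by the published
  description.
- The greedy ascent is local; with heavily overlapping clusters the global
  likelihood optimum itself can disagree with planted labels at the
  boundaries, so ARI saturates below 1 on continuous-looking data.
- Lineage reconstruction assumes tree-shaped trajectories; cycles and
  convergent fates are out of scope.
- Dropout/zero-inflation is not modelled; sparse low-mean genes are fit as
  bursty or near-Poisson, whichever the counts support.
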