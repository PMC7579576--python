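# Methods

## The analysis in one paragraph

Resting-state ROI time series are band-pass filtered to the slow BOLD band
(0.01–0.08 Hz), correlated pairwise (Pearson), and binarized into an
undirected graph.  Per subject, eleven network indicators are computed
from the binary adjacency matrix (plus the Dunn index from the weighted
correlation matrix).  Two groups are compared indicator-by-indicator with
a one-sided Mann–Whitney test (direction = larger mean rank) and a
two-group Brown–Forsythe variance test; in the clinical group, eight
quality-of-life dimensions are correlated with the indicators and modeled
by bidirectional AIC-stepwise linear regression.  The hypothesis the
pipeline operationalises is an inverse relation: more complex, less stable
connectivity goes with lower QoL.

## Connectivity construction

- **Band-pass.** Order-4 Butterworth, applied forward and backward
  (`sosfiltfilt`) so the filter is zero-phase: phase shifts would bias the
  subsequent correlations.  Rows are demeaned first; the upper cutoff must
  lie below the Nyquist frequency 1/(2·TR) (0.25 Hz at TR = 2 s).
- **Thresholding.** Every network formula here is written for binary
  a_ij, so graphs are binary and undirected.  The default rule is
  proportional: keep the ⌊0.2·m⌋ largest positive correlations of the
  m = n(n−1)/2 pairs (55 edges for 24 ROIs).  Fixing density makes group
  differences attributable to topology rather than to edge count — the
  trade-off is that mean degree and the density complexity index become
  constants across subjects of equal n (they are excluded from
  correlation tables, and the stepwise search skips them as
  rank-deficient).  An absolute threshold is available, as is
  magnitude-based thresholding (`use_absolute_correlation`) for users who
  want anti-correlations to count as edges; by default they never do.
- **Ties** at the density cutoff are broken by lexicographic ROI index,
  so a rerun is bit-identical.

## Indicator conventions

Where a convention was genuinely open, the choice is listed here and
implemented behind an explicit option where it matters:

- Local clustering of nodes with degree < 2 is 0 (the usual convention).
- Path lengths average **finite distances only**; nodes that reach no
  other node are excluded and counted in a diagnostics field
  (`n_isolated`).  On connected graphs the characteristic path length
  (mean of per-node means) and the mean path length (mean over unordered
  pairs) coincide; they diverge only on disconnected graphs, which is why
  both are reported.
- SD of path length uses the sample (n−1) denominator.
- Modularity uses the link-proportion matrix e with e_uu the within-module
  edge fraction and half of each between-module fraction on each of e_uv,
  e_vu, so Σe = 1 and Q = Σ_u[e_uu − (Σ_v e_uv)²] equals the standard
  Newman form.  The partition behind the reported Q comes from a
  deterministic search: greedy agglomerative modularity maximization plus
  a seeded local-move/merge refinement (strictly positive modularity gains
  only, so it provably terminates) restarted from singleton and random
  coarse initializations (4 restarts by default), scored by the package's
  own Q, with the trivial single-module partition as a floor (so Q ≥ 0
  always).
  On every enumerable graph tested (n ≤ 8, all set partitions) the search
  attains the global maximum.
- The small-worldness reference is an ensemble of degree-preserving
  double-edge-swap rewirings (10·|E| swap attempts per null, 100 nulls by
  default).  Sources admitting no swap (e.g. complete graphs) return the
  source itself with a degenerate flag, which yields S = 1 exactly —
  consistent with the closed form.
- **Complexity** is implemented as the normalized density complexity
  κ = 4ρ(1−ρ), ρ = 2|E|/(n(n−1)): zero for empty and complete graphs,
  maximal at half density, a minimal measure of "nodes plus alternative
  paths".  The source analysis names the concept without a formula, so no
  numeric agreement with its values is claimed; the indicator is pluggable.
- **Entropy** is the Shannon entropy (bits) of the empirical degree
  distribution — the most common graph entropy in this literature; same
  caveat and pluggability as complexity.
- **Dunn index**: ROIs are clustered by average-linkage hierarchical
  clustering on the distance 1 − r (not 1 − |r|), cut at k = 3 clusters to
  mirror the three DMN subnetworks; Dunn = (min between-cluster
  distance)/(max within-cluster diameter).  All-singleton clusterings
  return an ∞ sentinel.  k and the distance are configurable.

## Statistical layer

- **Mann–Whitney from summary statistics.** Group sizes and mean ranks
  determine the rank sum W (rounded to the nearest attainable
  half-integer, since printed mean ranks are rounded), then
  U = W − n(n+1)/2 and z = (U − n₁n₂/2)/√(n₁n₂(n₁+n₂+1)/12), one-sided in
  the direction of the larger mean rank, with **no continuity and no tie
  correction** — exactly this variant, with p-values truncated (not
  rounded) at three decimals, reproduces the published significance column
  the package bundles.  Tie-corrected, continuity-corrected and exact
  (full enumeration, n₁+n₂ ≤ 12) variants are available behind flags.
  The exact one-sided p is the proportion of the C(n₁+n₂, n₁) group
  assignments whose rank sum is at least the observed one; by exhaustive
  enumeration its gap to the approximation is below 0.05 for all untied
  configurations once both groups have ≥ 5 members (worst case 0.045 at
  5+5), but not at 4 per group (0.061) — a property of the statistic, not
  of the implementation.
- **Variance comparison** is the Brown–Forsythe variant of Levene's test
  (one-way ANOVA on absolute deviations from group medians,
  df = (1, n₁+n₂−2)); mean-centering is an option.  If every value equals
  its group center the statistic is undefined and flagged with a W = ∞
  sentinel.
- **Correlation flags** follow the reporting convention `*` p < 0.05,
  `**` p < 0.001, two-sided t-based p-values.
- **Stepwise models.** Bidirectional search from the intercept-only
  model, one addition or deletion per step, minimizing AIC (R² is
  reported, never used for selection); the intercept-only outcome is
  valid.  Duplicate predictor columns are dropped to one copy and
  rank-deficient candidates skipped with a note.  The search loop uses a
  fast least-squares AIC identical (tested to 1e-12) to the statsmodels
  convention used for the final reported fit.  No multiple-testing
  correction is applied anywhere, matching the analysis being
  reimplemented.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes,
not fMRI physics:

- **Signal model**: x_t = φ x_{t−1} + e_t with Gaussian innovations drawn
  from a block covariance (unit diagonal, r_within inside each of the
  three subnetworks, r_between across), stationary start, plus white
  measurement noise.  Uniform AR(1) coloring leaves the cross-ROI
  correlation matrix equal to that of the innovations, so the planted
  connectivity is exactly controllable; defaults are φ = 0.3 and noise SD
  0.5.
- **Defaults as study conditions**: 22 + 22 subjects, 24 ROIs (6 + 6 + 12),
  220 volumes at TR = 2 s.  Control subjects draw r_within ~ N(0.45,
  0.04²) and r_between ~ N(0.10, 0.03²) (truncated to the PSD-valid
  region); the clinical group draws from N(0.55, 0.12²) and N(0.20,
  0.09²) — higher means (hyper-connectivity) and 3× the spread (greater
  inter-individual variability).  The source study reports no effect
  sizes for these parameters; the values are this package's choices,
  picked once to give realistic graph densities of detectable but not
  trivial group separation, and are not estimates of the study.
- **QoL scores** are unbounded reals: dimension = intercept + Σ
  slope·indicator + Gaussian noise.  No instrument bounds are enforced —
  the downstream analysis is scale-free and bounds would complicate the
  planted linear model.
- **Seeding**: one cohort seed expands to per-subject streams via
  `SeedSequence` spawn keys, so adding or removing subjects never changes
  the other subjects' draws; every stochastic step in the pipeline is
  reproducible from a single top-level seed.

What the generator does **not** emulate: hemodynamic response shape,
motion artifacts, scanner drift, spatial autocorrelation, non-Gaussian
BOLD marginals, or item-level QoL psychometrics.  Passing tests therefore
show that the *statistical machinery* behaves correctly under the assumed
structure, not that the scientific conclusions transfer to real
recordings.

## Problem sizes used in the checks

The verification suite uses sizes chosen to keep each check exhaustive or
well-powered: brute-force oracle comparison on 200 random graphs with
n ≤ 12; full partition enumeration up to n = 8 (4140 partitions); 50
exact-vs-approximate test pairs; 100 runs of 100 subjects for
planted-effect recovery with 8-null small-world ensembles (the ensemble
size only adds Monte-Carlo noise to one candidate predictor); 100
replicates of 22 + 22 for variance-detection power.  The acceptance
script's synthetic run uses the default cohort with 30 nulls per subject.

## Known limitations

- The binary-graph indicator values are not comparable to the source
  analysis's printed group means (its estimator was evidently weighted or
  otherwise different: a printed clustering mean of 0.93 with SD 1.39 is
  impossible for binary graphs on [0, 1]); the package reproduces the
  *statistical reconstruction* of that analysis, and its printed
  significance column, exactly.
- Fixed-density thresholding makes density-derived indicators constant
  across equal-sized subjects (see above).
- The exact Mann–Whitney path enumerates all assignments and is capped at
  n₁+n₂ ≤ 12 by design.
- Louvain/greedy modularity search is heuristic; optimality is verified
  exhaustively only for n ≤ 8.
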