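# Methods

`dsskit` quantifies drug sensitivity from multi-dose viability screens the
way ex vivo drug sensitivity and resistance testing (DSRT) programs do:
normalize plate readouts to percent growth inhibition, fit a logistic
dose-response model per sample x drug pair, integrate the fitted curve above
an activity threshold into a drug sensitivity score (DSS), and feed the
resulting score matrices into cohort-level analyses (differential scoring
against healthy controls, responder sub-group detection, response-profile
clustering, kinase addiction scoring).

## Response normalization

Raw per-well readouts (e.g. CellTiter-Glo luminescence) are mapped to
percent growth inhibition against per-plate controls:

    inhibition% = 100 * (neg - raw) / (neg - pos)

where `neg` is the negative (DMSO vehicle) control mean and `pos` the
positive (kill, benzethonium chloride) control mean. Values are clipped to
[0, 100]: readouts above the vehicle control (growth stimulation) count as
0 % inhibition, so all downstream scores are non-negative. Technical
replicates are collapsed to the per-concentration median. Equal control
means make a plate unusable and raise an error rather than a warning.

## Four-parameter logistic model

The per-curve model, in log10-concentration space `x = log10(conc/nM)`:

    R(x) = R_min + (R_max - R_min) / (1 + 10^(s (m - x)))

* `R_min`, `R_max` - bottom/top asymptotes, % inhibition, `0 <= R_min <= R_max <= 100`
* `m = log10(IC50)` - the *relative* IC50: the dose at the midpoint between
  the curve's own asymptotes
* `s > 0` - slope at the IC50; positivity makes "inhibition rises with
  dose" structural. Genuinely decreasing series fit to a flat line
  (`R_min ~ R_max`), which scores 0 unless the plateau is active.

Fitting is bounded nonlinear least squares (scipy `least_squares`, TRF) with
an analytic Jacobian. Bounds: asymptotes in [0, 100]; `m` within the tested
log10 window widened by 2 (IC50 extrapolation capped at 100x beyond the
tested range, since IC50 estimates outside the window are unstable);
`s in [0.1, 10]`. Initialization is deterministic: asymptotes from the
observed min/max, `m` from the dose nearest the observed half-maximum,
multi-start over `s in {0.5, 1, 2}` plus one data-driven start from a
linear regression of `log10((R_max - y)/(y - R_min))` on `x`; the lowest
residual sum of squares wins, ties resolved toward the earlier start, so
repeated fits are bit-identical. If every start fails, a coarse
deterministic `(m, s)` grid supplies parameters with `converged = False`.
Flat curves (response range below 1e-8) skip optimization entirely:
`R_min = R_max = mean`, `m` pinned mid-window, `s = 1` - any `m` is
unidentifiable there and the score depends only on the asymptotes. No
point weighting is applied.

Identifiability caveat: with a 5-point, 1-decade-spaced dilution grid, a
very steep curve (`s ~ 5`) whose midpoint sits within half a decade of the
window edge leaves at most two informative points, and parameters are no
longer pinned by the data; the parameter-recovery suite therefore exercises
midpoints at least one dilution step inside the window (`m in [1, 3]` on a
`[0, 4]` grid), where noiseless recovery is exact to well below 1e-6.

## Drug sensitivity scores

With an activity threshold `A_min` (% inhibition; default 10, read as the
baseline noise level of the normalized readout, configurable) and a scoring
window `[x_lo, x_hi]` (defaults to each curve's tested range; a fixed
cohort-wide window makes scores comparable across drugs tested on different
ranges), the integral response is

    I = int_{x1}^{x2} (R(x) - A_min) dx,

with `x2 = x_hi` and `x1` the fitted curve's crossing of `A_min` (clamped to
the window; `I = 0` if `R_max <= A_min`). The integral is evaluated in
closed form via the antiderivative

    F(x) = (R_min - A_min) x + (R_max - R_min)/(s ln 10) * ln(1 + 10^(s(x-m))),

computed with `logaddexp` so large `s(x-m)` cannot overflow. A property
suite checks the closed form against adaptive quadrature of
`max(0, R(x) - A_min)` to 1e-6 relative tolerance across the parameter
space. The crossing `x1` uses the fitted curve, not the first measured dose
above threshold, consistent with the continuous-model reading.

The three score variants, all on a 0-100 scale:

    DSS1 = 100 I / ((100 - A_min)(x_hi - x_lo))
    DSS2 = DSS1 * log10(max(R_max, 1)) / 2
    DSS3 = DSS2 * (x2 - x1) / (x_hi - x_lo)

`DSS1` is the normalized area (100 iff fully inhibiting over the whole
window). `DSS2` multiplies by `log10(R_max)/log10(100)`: 1 at full efficacy,
shrinking toward 0 for low-plateau curves, penalizing compounds effective at
partial inhibition only; `R_max` is clamped to >= 1 before the logarithm.
`DSS3` additionally scales by the fraction of the window over which the
curve is active, penalizing activity confined to the top doses. By
construction `DSS3 <= DSS2 <= DSS1` and all three vanish exactly when
`I = 0`. These two normalizers are this package's algebraic interpretation
of the verbal contracts for the variants ("penalize low top asymptote",
"penalize narrow active window"); both live in a single formula layer
(`dsskit.scoring.dss`) so an alternative algebra is a one-function change.

Comparators: the discrete Activity Area `AA = sum_i max(0, resp_i)/100`
(0 with no activity, `n_doses` at complete inhibition everywhere) and the
relative IC50 `10^m` (reported missing for curves never reaching `A_min`).

Differential scoring (dDSS) subtracts, per drug, the mean score of the
control samples from every sample's score - controls included, so control
dDSS values sum to zero per drug and their spread shows control-to-control
variability. Drugs whose controls are all missing come back missing rather
than silently un-centered.

## Responder sub-group detection

For each drug, the per-sample score distribution is tested for positive
skewness: the moment estimator `g1 = m3 / m2^(3/2)` (uncorrected, matching
the R "moments" convention; a bias-corrected variant is a documented
switch away) with D'Agostino's normalizing transformation providing a
one-sided right-tail p-value (requires n >= 8; delegated to
`scipy.stats.skewtest`, with the exactly-symmetric case mapped to z = 0
explicitly). If the test is significant at `alpha` (default 0.05), the
responders are the minimal right tail whose removal renders the remaining
distribution non-significant: the maximum value is peeled and the rest
re-tested until `p >= alpha` or fewer than 8 values remain. Membership is
therefore always a top-k prefix of the sorted scores and is tied directly
to the detection statistic. Across drugs, Benjamini-Hochberg FDR is
reported alongside raw p-values (raw is primary). Responders vs the rest
are additionally compared with the Wilcoxon rank-sum test (exact null when
both groups have n <= 20 without ties, otherwise normal approximation with
midranks, tie and continuity corrections).

## Metric evaluation harness

Given external activity labels per curve, each response metric is scored by
AUROC via the rank formula (ties counted half; IC50-like metrics are
negated first so "lower is active" orients correctly). Differences between
two correlated AUROCs computed on the same curves use DeLong's paired test
through placement values; degenerate variance (e.g. identical score
vectors) returns p = 1 with zero difference instead of dividing by zero.

## Response-profile clustering

Drug profiles (dDSS across samples) are compared with the Spearman
dissimilarity `d = 1 - rho` (pairwise-complete ranks; pairs overlapping in
fewer than 3 samples get the maximum observed distance as a conservative
separation; a constant profile is an error naming the drug). Ward linkage
runs directly on these dissimilarities - the classic un-squared dialect
(`hclust ward.D`), appropriate because a rank-based distance has no
Euclidean embedding; it is obtained exactly by feeding `sqrt(d)` to the
squared-dialect solver and squaring the merge heights. Partitions come from
an adaptive branch cut: walking from the root, a merge splits into two
clusters only if both branches hold at least `min_cluster_size` items
(default 3, mirroring the exclusion of mechanism classes below 3 drugs) and
the branches are internally tight relative to their join (every child's
merge height below `(1 - gap)` times the parent's, `gap = 0.5`).
Structureless trees stay a single cluster and undersized branches are
absorbed into their sibling, so the cut needs no fixed height. This is a
deliberately reduced variant of dynamic dendrogram cutting: the adaptive
height/size criteria are kept, the medoid (PAM) refinement stage is not,
and unlike heuristic implementations the result is fully deterministic.

Agreement with mechanism-of-action (MoA) classes uses pair-counting
indices - Rand, Hubert-Arabie adjusted Rand, Jaccard, Fowlkes-Mallows -
computed from the contingency table (validated against brute-force pair
enumeration and scikit-learn). The gain of one metric's partition over
another against the MoA reference is tested by permutation: item labels are
shuffled within each observed partition independently (cluster sizes
preserved), paired differences of the shuffled index values form the null,
and the empirical p is the fraction of null differences at least as large
as observed (default 10,000 permutations; reference classes under 3 drugs
are dropped first; the seed is a required argument).

## Kinase addiction scoring (KISS)

Given a binary drug x kinase selectivity matrix (affinity matrices are
binarized at a threshold, default "targets" below 1000 nM), a sample's KISS
for kinase `k` averages its dDSS over the `n_k` inhibitors that target `k`
and whose cohort distribution passed the one-sided skewness filter
(`p < alpha`) - the eligibility restricts the sum to selectively responding
inhibitors. Averaging (rather than raw summing) keeps kinases with
different inhibitor coverage comparable and preserves rankings whenever
coverage is equal; the divisor is a single switch (`aggregate="sum"`
restores the raw sum). Kinases with no eligible targeting inhibitor are
absent from the profile, not zero. Skewness eligibility is computed on the
dDSS distribution (the differential score is what "selective" refers to).
The addiction network keeps kinases with KISS above a threshold (default 5,
optionally intersected with an expressed-kinase list) and joins pairs whose
selectivity columns correlate (midrank Spearman) above 0.5; export is SIF
or GraphML rather than rendered graphics.

## Synthetic cohorts

The generator emulates the screen geometry the scores were designed for:
5-point 10-fold dilution series spanning a 10,000-fold range (default
1-10,000 nM), or the 8-point CCLE-style grid
(2.5, 8, 25, 80, 250, 800, 2530, 8000 nM); additive Gaussian noise on
inhibition (default sd 5 %), clipped to [0, 100]; a cohort of 22 patient
samples and 4 healthy controls by default. Ground truth is drawn score-
first: each drug gets a background response level (uniform on [12, 18])
around which samples scatter uniformly within +/- 6 score units; drugs
sharing a planted MoA class draw that scatter from a shared per-sample
latent factor so their profiles correlate; planted responders sit tightly
(+/- 1) at level + effect (default +25) - the "distinct outlier group"
structure the responder screen targets. Each cell's curve parameters are
then solved so the noiseless curve scores exactly its target - bisection
on the top asymptote, falling back to shifting the cell's half-max point
toward lower doses when even a full-efficacy curve cannot reach the target
under the drug's shape. Every generator is a pure function of (spec, seed).

Three background choices are deliberate. The band sits clear of the score
floor at 0: floor-pinned score distributions have a compressed left tail,
which reads as spurious positive skewness and would make the responder
screen fire on undisturbed drugs. The biological scatter (half-width 6)
dominates the technical noise of a fitted score (sd ~ 2 under the default
geometry, with occasional larger excursions from 5-dose fits): a
background whose spread is comparable to the score noise inherits the
noise's heavy tails and inflates the false-detection rate of the skewness
screen. And the scatter stays well below the planted effect (+25), so a
responder sub-group is a genuinely distinct outlier mode rather than the
upper fringe of the background - the structure the right-tail peel is
designed to isolate. What the generator does *not* emulate:
plate spatial/edge artifacts, batch effects, heavy-tailed or multiplicative
noise, correlated noise across doses, and real polypharmacology (planted
MoA classes are cleanly separated). Passing recovery tests on this
synthetic data therefore demonstrates the statistical machinery under the
stated geometry and noise model, not robustness to assay artifacts.

## Numerical and design choices

* Scores are deterministic; every stochastic operation (permutation test,
  generators) requires an explicit seed and is reproducible to the digit.
* The closed-form integral is validated against quadrature at 1e-6 relative
  tolerance; forward/inverse logistic evaluation round-trips at 1e-9.
* Exact-zero skewness maps to z = 0 / p = 0.5 (the underlying scipy routine
  substitutes y = 1 at exactly 0, a measure-zero case for real data).
* Wilcoxon: exact branch only without ties and both n <= 20; otherwise
  midranks + tie correction + continuity correction.
* The pipeline writes a manifest (package version, config hash, seed, stage
  status) and keeps partial outputs with a FAILED marker on stage failure.
* Problem sizes in the validation suites (200 curves for parameter
  recovery, 10,000 null replicates for the skewness-test calibration, 100
  cohorts for responder recovery, 500 replicates at 1,000 permutations for
  permutation-p uniformity) are chosen so the full suite completes in
  minutes on one CPU while keeping Monte-Carlo error well below the margins
  being asserted.

## Known limitations

* The DSS2/DSS3 normalizer algebra is this package's interpretation of the
  variants' verbal contracts; alternative published algebras can be swapped
  in by editing one function.
* Confidence intervals on fitted parameters and scores are out of scope.
* IC50 values at the extrapolation cap (100x outside the window) are
  reported as-is but are boundary estimates, not measurements.
* The dynamic branch cut is a reduced, deterministic variant; it will not
  reproduce every partition of the full hybrid dynamic tree cut algorithm.
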