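# Methods

`painpath` implements the statistical machinery used to dissociate two
routes by which experimental manipulations change reported pain: a
nociceptive route indexed by a multivariate brain signature that tracks
stimulus temperature, and a self-regulatory route carried by a two-region
mediator chain (an accumbens-like region m1 feeding a prefrontal-like
region m2) that tracks the regulation instruction.  Because no suitable
dataset is public, the package ships a first-class synthetic-data module
whose ground truth encodes that dissociation, and every inferential claim
the package makes is validated by recovering it.

## Task design generator

Each simulated subject completes nine runs.  Five passive runs (1, 2, 4,
8, 9) deliver 55 stimulations over temperature levels 1–5 (44.3–48.3 °C,
1 °C apart), 11 per level, such that within those runs every ordered pair
of levels (self-pairs included) occurs as a consecutive transition exactly
twice, and the five runs start on five distinct levels (runs 2 and 8 start
on levels 4 and 2).  Runs 5 and 6 replay the run-4 and run-8 sequences
shifted one level up (45.3–49.3 °C).  Runs 3 and 7 are regulation runs
(regulate-up/-down, order alternating across subjects) with ten trials,
two per level 1–5, in a shared order.

The transition constraint is solved exactly rather than by rejection
sampling on sequences: the 55 passive trials define a directed multigraph
on five nodes containing two copies of every ordered pair — 50 edges with
in- and out-degree 10 everywhere, hence Eulerian.  A random Eulerian
circuit (Hierholzer's algorithm with shuffled adjacency) is cut into five
10-edge trails; cut positions are rotated until the five trail starts are
distinct levels, and a fresh circuit is drawn if no rotation works (in
practice a handful of circuits suffice; the construction is bounded and
raises if it ever fails, which would indicate a bug rather than an
infeasible constraint).  Each node is then visited 10 (edge entries) + 1
(trail start) = 11 times, so the 11-per-level count holds by construction.
Whether transitions should also be counted across run boundaries is not
determined by the printed counts; within-run counting is the only reading
under which 5 runs × 10 transitions = 25 pairs × 2, and is adopted.

## Generative model

For subject *s*, each path coefficient is drawn once from a normal
distribution around its population value (SDs in
`GroundTruthParams.between_subject_sd`).  Per trial, with temperature
centered at 46.3 °C (mid-range; centering moves only intercepts) and
regulation coded +1/0/−1:

    sig    = α_s + a_s·temp + ε,            ε ~ N(0, 1.5)
    m1     = d1_s·reg + ε,                  ε ~ N(0, 0.5)
    m2     = d2_s·m1 + ε,                   ε ~ N(0, 0.5)
    rating = μ_s + βt_s·temp + c′_s·reg + b_s·(sig − α_s) + b3_s·m2 + ε,
                                            ε ~ N(0, 8), clipped to [0, 100]
    decision = 1 iff rating > 50

The signature never sees `reg` and the m1→m2 chain never sees `temp`; the
two systems are separately modifiable by construction.  Defaults
(`GroundTruthParams`): μ = 48, βt = 7 per °C, c′ = 5, a = 2.5 signature
units per °C, b = 1.6 rating units per signature unit, d1 = −1,
d2 = +0.8, b3 = −4.  The chain signs mirror the reported phenomenology —
regulate-up suppresses m1, m1 drives m2 positively, m2 predicts reduced
pain — so the chain's indirect effect d1·d2·b3 = +3.2 is positive, adding
to the direct effect.  Magnitudes were chosen once so that ratings stay in
the interior of the 0–100 scale (<1 % of trials censored at the default
operating point) while every path remains comfortably detectable at 30
subjects; they are study conditions, not tuning knobs.

Censoring note: clipping a bounded rating scale induces a small real
temperature-by-regulation interaction even when none is generated.  The
interaction-calibration test therefore runs at interior-of-scale effect
sizes; on real bounded scales the same artifact would be present in the
data themselves.

### Volumetric embedding

`simulate_voxel_brain` embeds the scalar series in a small grid (default
≤ 30³, ellipsoidal mask) with three disjoint cubic clusters carrying the
signature, m1 and m2 signals through voxel-specific loadings
(~N(1, 0.2²)), independent N(0, 1) noise elsewhere.  The returned
signature weight map is the signature-cluster loading vector normalized so
that the noise-free pattern response of a trial volume equals the trial's
scalar signature value exactly.  No spatial autocorrelation, physiological
noise or motion is simulated; spikes are idealized whole-volume offsets.

### BOLD series

`simulate_timeseries` builds one run as the sum of per-trial 12.5-s
boxcars convolved with the canonical HRF and scaled by per-trial
amplitudes, plus linear drift, Gaussian noise, and optional spike volumes.
Trial timing follows the task: 18 s initial fixation, 12.5 s stimulation,
4.5–8.5 s pre-rating jitter, 11 s rating, 5–9 s inter-trial interval;
jitters are uniform over the stated ranges (ranges, not distributions, are
what the task specifies).

## Single-trial GLM

The canonical HRF is a difference of gamma densities parameterized by
time-to-peak: response mode 6 s, undershoot mode 16 s (unit scale, so
shapes 7 and 17), undershoot ratio 1/6, 32-s support, peak-normalized to 1.
Parameterizing by mode rather than the shape-6/16 convention keeps the
kernel's argmax at the nominal 6 s.

The beta-series design has one HRF-convolved regressor per stimulation
epoch, a single regressor pooling the rating epochs, and a nuisance block:
intercept, centered linear drift, a discrete-cosine high-pass set with
180-s cutoff (⌊2T/180⌋ terms, the DCT equivalent of the cited filter,
kept inside one least-squares fit), optional spike indicator columns, and
optional user-supplied columns (e.g. 24-column movement blocks, which the
package accepts but never computes — no raw motion exists at desk scale).
Fixation is the implicit baseline.  Estimation is OLS; no prewhitening is
applied because nothing more is specified for the single-trial model.

Per-trial collinearity is quantified by VIF_j = 1/(1 − R²_j) from
regressing trial column *j* on all other columns; trials with VIF > 2.5
are flagged for exclusion, after spike columns are in the model (whether
the original pipeline computed VIFs before or after adding spike
regressors is unstated; after is adopted since spikes are part of the
design the beta is estimated under).

Outlier volumes: slice-wise means and SDs are concatenated per volume,
Mahalanobis distances to the sample centroid referred to χ² with one df
per retained feature, and a volume is flagged only when significant under
both Bonferroni and Benjamini–Hochberg at α = 0.05 — the intersection is
the stricter of the two corrections.  Singular feature covariances get
ridge shrinkage (1e-6 of the mean diagonal) with a warning; constant
features are dropped.

## Pattern expression

The signature response of a beta image is the dot product of the image
with the signature's voxel weights over its mask; sub-region ("local")
responses restrict the sum to labelled voxels and add up exactly to the
whole-pattern response when the labels partition the mask.  Vectorization
order is fixed (Fortran order, slowest axis last) for reproducible
serialization — the dot product itself is order-invariant.  In-mask voxels
missing from an image contribute zero and are counted in a warning; no
resampling is ever attempted, grids and affines must match exactly.
Sphere ROIs average raw beta values at voxels whose world-space centers
lie within the radius (inclusive) of the given coordinate — voxel-center
inclusion is the simplest auditable rule.

## Multilevel GLM

Behavioral models are two-stage: per subject, OLS (ratings) or
maximum-likelihood logistic (pain/no-pain decisions) on regulation code,
centered temperature and their interaction over non-excluded trials; then,
per coefficient, OLS of the subject estimates on an intercept plus
between-subject covariates (e.g. regulation-run order coded ±1), with a
two-tailed t test of the intercept on n − q degrees of freedom.  This is
the summary-statistics reading of "multilevel GLM", consistent with group
t statistics on n − 1 df.  Logistic subjects with a single outcome class
or with separation (diverging coefficients, |β| > 15, or non-convergence)
are excluded from the group stage.  The group stage is unweighted by
default; precision weighting is available in the mediation machinery.

Voxel-wise second-level maps use iteratively reweighted least squares with
Tukey's bisquare (c = 4.685, MAD scale) per voxel; non-convergence falls
back to OLS with a per-voxel flag.

## Mediation

For the two-path model, three per-subject OLS fits give the total effect
*c* (y~x), path *a* (m~x), and paths *b*, *c′* (y~x+m), with covariates
entered as columns in every equation; c − c′ = a·b holds exactly without
covariates and is asserted to 1e-8.  The three-path chain adds one fit:
b1 (m1~x), b2 (m2~x+m1), b3 (y~x+m1+m2), indirect effect b1·b2·b3.

Product variances use Var(ab) = a²v_b + b²v_a + v_a·v_b (second order;
exact for independent normal estimates — the first-order form is available
by flag) and, for three paths, the first-order multivariate delta under
independence, Var ≈ (b2b3)²v1 + (b1b3)²v2 + (b1b2)²v3.  The printed source
formulas were unavailable, so both forms are validated against
million-draw Monte-Carlo product variances (within 3 % and 10 %
respectively) rather than treated as transcriptions.

Second level: subject rows [a, b, c′, c, a·b] (or [b1, b2, b3, product])
are combined by inverse-variance weights, 1/(within-subject OLS variance +
between-subject variance by method of moments), a pragmatic stand-in for
the cited empirical-Bayes procedure; an unweighted mode exists and both
are exercised in tests.  Weights are fixed at point estimates across
bootstrap draws.  Inference is by joint resampling of subject rows
(multinomial counts, equivalent in distribution to index resampling and
vectorizable across voxels): per draw the weighted column means are
recomputed; the two-tailed p is twice the smaller tail share, floored at
2/n_boot.

Small-sample correction: the raw percentile rule is anticonservative at
n ≈ 30 (measured type-I ≈ 7.6 % at nominal 5 %, the familiar t-versus-z
narrowness of bootstrap dispersions).  The package therefore applies
Efron's expanded-percentile correction coherently: tail shares map through
a normal quantile onto a Student t with n − 1 df scaled by √(n/(n−1)) for
p-values, CI quantile levels are expanded by the matching factor, and the
reported SE is the bootstrap SD times the same expansion, so "p < α",
"CI excludes zero" and the significance flag always agree.  After the
correction the measured type-I error is ≈ 5–6 % and 2-SE recovery coverage
≈ 95 %.

Three-path mediation is declared only when both criteria pass: joint
significance (b1, b2, b3 each significant at α) and the bootstrap
product-of-coefficients test.  The conjunction is never looser than either
criterion alone.

### Voxel-wise search

With x, y and optionally one fixed mediator specified, every in-mask voxel
is tried as the free mediator (two-path; or first/second mediator in the
chain).  First-level fits run per voxel and subject; the group bootstrap
is vectorized across voxels with a shared resampling realization.
Zero-variance voxels are skipped and recorded.  A single-voxel mask
reproduces the scalar pipeline to numerical identity.  For thresholding,
the cluster-forming primary threshold applies to the product-of-
coefficients p-map and the joint-significance criterion applies at the
conventional α; surviving voxels are cluster-filtered at the Monte-Carlo
extent threshold.

## Cluster-extent correction

Intrinsic smoothness is estimated per axis from the variance of spatial
first differences relative to the field variance inside the mask:
FWHM = 2√(ln 2)·h·σ/sd(Δ) for voxel size h, whose white-noise floor is
h·√(2 ln 2) ≈ 1.18 h.  The Monte-Carlo threshold draws Gaussian fields at
that smoothness (white noise smoothed on a padded grid, renormalized to
unit variance inside the mask), applies the two-tailed primary threshold,
and records the maximum face-connected (6-neighbor) cluster size.  The
minimum surviving extent is the smallest k with P(max ≥ k) ≤ α estimated
from the simulated maxima — on integer sizes this is the (1 − α) quantile
pushed past ties, which is what actually controls the FWER of the
"size ≥ k" decision rule.  Face connectivity is stricter than the
nearest-neighbor default of some tools; extents here are therefore
conservative relative to those, and the choice is configurable in
principle by relabeling with a different structuring element.  Positive
and negative excursions are labelled separately so opposite-signed
clusters never merge.

## Problem sizes and orchestration

The pipeline default is 20 subjects, 2,000 bootstrap draws, a 12³ search
grid and 1,000 Monte-Carlo iterations — sizes chosen so a full run
completes in seconds while every stage remains well-powered; the
replication studies use 30 subjects × ~97 trials, 50-replicate recovery
and dissociation studies, a 500-replicate type-I study, and a 500-field
FWER closed loop.  All stage seeds derive from one root seed via
`SeedSequence`, making runs byte-reproducible; reports store every stage
seed so each p-value is traceable.

## What passing tests do and do not show

The synthetic generator is linear, Gaussian, and censoring-light, with
mediator chains that are exactly dissociated and voxel noise that is
spatially independent.  Passing recovery and dissociation tests therefore
demonstrates the correctness and calibration of the estimators under the
model they assume — not robustness to autocorrelated BOLD noise,
physiological artifacts, inter-subject misalignment, non-linear
psychometrics, or mediator chains that are only approximately separable.
The FWER machinery is validated on stationary Gaussian fields; real
residual fields are non-stationary and the extents it returns for them
inherit the usual caveats of Gaussian-field Monte-Carlo corrections.

## Known limitations

- OLS only at the first level; no prewhitening or slice-timing/motion
  correction (preprocessing is out of scope; movement regressors are
  accepted as inputs).
- The two-stage multilevel model is not a simultaneous mixed model; with
  very unbalanced trial counts a full random-effects fit would differ.
- The bootstrap's expanded-percentile correction targets the mean-type
  statistics used here; it is not a general BCa implementation.
- Sphere ROIs use voxel-center inclusion; partial-volume weighting is not
  attempted.
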