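# Methods

This note records the models, parameter choices and numerical conventions
behind `morphoscreen`, and what the synthetic-data generator does and does
not emulate.

## The screening model

A screen consists of strains laid out on plates, imaged at three time-points
after a lysis-inducing β-lactam is added. Each strain's response is
summarised as an 18-dimensional phenotypic profile: the proportions of six
population categories — intact, normal, round, elongated, small, deformed —
at each time-point, with every proportion computed over the *whole*
population including lysed cells. Two identities hold exactly by
construction and are enforced throughout:

* normal + round + elongated + small + deformed = intact,
* intact + lysed = 1.

The category order within a profile block is frozen as
(intact, normal, round, elongated, small, deformed), time-points ascending.

## Synthetic data generator

The generator defines the study conditions for every test in the package.

**Cell geometry.** Rods are spherocylinders; round cells ellipses with
aspect ≤ 1.25; deformed cells rods with a circular mid-cell bulge
(bulge diameter ≈ 1.7 × width); lysed cells are rods with a smoothly
modulated, ragged outline. Default sizes (px, at ≈ 0.16 µm/px):
normal 24 ± 3 × 9 ± 0.7, small 14 ± 1.8 × 8 ± 0.6, elongated 55 ± 9,
round ⌀ ≈ 16 ± 2, deformed 32 ± 5. Intact cells have contrast
(background − cell)/background ≈ 0.45 ± 0.05; lysed ghosts 0.12 ± 0.025.
Per-class size distributions are free parameters of this artifact (chosen as
plausible for exponential-phase rod-shaped bacteria at 40× magnification),
not measured values.

**Optics.** Phase contrast is approximated as dark bodies on a bright
background (level 0.55 of full scale) with a thin bright halo rim (2 px,
height ∝ contrast), a random linear shading gradient (±4 %) and additive
Gaussian noise (σ = 1.5 %). No point-spread or diffraction model is
attempted; the approximation is sufficient to exercise enhancement,
permissive thresholding and shape pruning, which is its purpose.

**Trajectories.** The wild type lyses quickly: intact fraction
0.88 → 0.45 → 0.15 across the three time-points, with round/deformed cells
transiently accumulating. Mutant archetypes perturb the curve in logit
space over the exclusive partition (lysed + 5 morphologies): `fast_lysis`
(extreme but correlation-preserving → T²-type deviation), `slow_lysis`
(breaks the time-correlation → SPE-type), `stable_bulge` (round + deformed
accumulate), `filament` (elongated accumulates).

**Nuisance structure.** Three components, all shared identically by
wild-type replicate wells and "null" mutants (so nulls are exchangeable
with the reference):

* per-plate batch offsets — additive logit shifts, σ = 0.25 per category;
* a per-well scalar *response-speed* factor (σ = 0.5) scaling a fixed
  time-profile on the lysed logit: wells run slightly ahead of or behind the
  mean lysis kinetics. This gives the wild-type profile covariance genuine
  low-rank structure, as real screens have;
* iid logit noise per strain (σ = 0.08) and per well/time-point (σ = 0.08).

Per-well cell density is log-normal (σ = 0.45) around 40 cells/frame,
truncated to [4, 150]; the acquisition policy (9 images when the pilot frame
shows < 15 cells, else 4) partially compensates sparse wells. The resulting
per-well totals are ≈ 179 ± 81 cells, matching the count dispersion reported
for real screens of this design.

**What the generator does not emulate:** optical physics, cell motion and
time-lapse identity (populations are resampled per time-point), touching or
aggregated cells beyond the configured overlap tolerance, debris or
non-cellular objects, and spatial (row/column) plate effects. Passing tests
therefore demonstrate correctness of the *analysis machinery* under
controlled conditions, not robustness to every real-microscopy artifact.

**Modes.** `simulate_screen(render=True)` draws pixels for every frame (used
for demonstration screens and segmentation scoring); `render=False` draws
per-cell class labels directly from the same trajectories (used for the
large calibration and recovery suites, where rendering ~40 000 wells would
be pointless for the statistics being tested). Both modes share one RNG
stream per run, so a seed fixes the whole screen.

## Segmentation

`enhance` auto-detects polarity (cells dark vs bright), applies mild CLAHE
(clip 0.01, tile 64, blended 50/50 with the input to preserve the
ghost/background ordering) and a black top-hat with a disk of radius 15 px
(larger than half the widest cell, so whole cells survive while shading and
halos are removed). `binarize` thresholds at median + 4 robust SDs
(MAD-based) of the enhanced image — deliberately permissive so that
low-contrast lysed ghosts are captured; non-cell specks are left to the
pruning stage. `prune` drops components outside [40, 6000] px², below
solidity 0.5, above aspect 12, or touching the border (default policy:
discard; their descriptors would be truncated). Touching cells are *not*
split — in liquid suspension cells stay separated, and merged blobs are
removed by the aspect/area criteria instead. Contours are extracted at the
0.5 level of the padded mask (sub-pixel, closed, counter-clockwise in
(x = col, y = row) axes, 0-based origin at the top-left pixel centre).

## The 54 descriptors

The feature inventory is fixed at 22 shape + 10 Fourier + 12 intensity +
10 microenvironment = 54, in a frozen order (`FEATURE_NAMES`). Length and
width come from the minimum-area bounding rectangle of the arc-length
resampled contour (lightly smoothed, window 5, to suppress rasterization
bias); cells with solidity < 0.8 (bent) fall back to a medial-axis estimate
(width = 2 × median medial radius, length = area/width). Curvature is
normalized by perimeter/2π so a circle scores 1. Fourier descriptors are
`|F_k|/|F_1|`, k = 2…11, of the complex contour resampled to 128 points:
dropping F₀ removes translation, the |F₁| division removes scale, magnitudes
remove rotation and starting point. Intensity moments/quantile ratios
(skewness, kurtosis, (mean−median)/sd, IQR/sd) are affine-invariant; raw
statistics are covariant. The microenvironment annulus is a 3 px dilation
minus the mask, with neighbouring cells' pixels excluded; an empty annulus
yields a zero sentinel plus a warning.

## Classification

**PLS-DA** (lysed vs intact): single-response NIPALS with deflation on
autoscaled features, y ∈ {0, 1}, 3 components by default, decision threshold
0.5 (ties to the positive class). With all components the model equals
least-squares regression on the autoscaled data — used as an oracle test.
Constant columns are dropped with a warning; autoscaling statistics are
frozen from training data.

**SIMCA** (normal/small/elongated/round, reject = deformed): one PCA per
class on class-autoscaled data with k = 1, 1, 3, 2 components for
elongated, normal, round, small respectively. The membership distance is

    d = SD²/mean_train(SD²) + OD²/mean_train(OD²),

with SD² the Mahalanobis score distance and OD² the orthogonal residual;
the acceptance limit is the empirical 95th percentile of d over the class
training set (α = 0.05), so ≈ 95 % of in-class data is accepted by
construction. No class accepts → deformed; several accept → smallest
reduced distance d/limit wins (logged). Cross-validation is stratified
7-fold, seeded.

## Profiles, batch correction, QC

Batch correction centers and scales each of the 18 profile variables to unit
SD *within each plate separately*, using all wells on the plate (mutants +
controls). This is a monotone per-variable transform, so within-plate rank
orders are preserved. Zero-variance variables are left centered with a
warning. QC fails a well with < 50 cells in total or > 150 cells in any
frame (both thresholds inclusive on the passing side); failed wells are
excluded from profiles and listed for repetition — there is no imputation
anywhere.

## Reference model and control limits

The wild-type profiles (after batch correction) are autoscaled and
decomposed by PCA. The number of retained components k defaults to the
smallest k explaining ≥ 90 % of variance (a declared, overridable rule —
reported in every output). For a profile with scores t: T² = Σ t_j²/λ_j,
SPE = ‖x − x̂‖². The operative decision rule is empirical: wild-type scores
are computed by resubstitution, and a strain is flagged when either
statistic strictly exceeds the wild-type 99th percentile. Percentiles use
linear interpolation between order statistics at plotting positions
i/(n + 1) (the Weibull rule), chosen because it makes the exceedance
probability of a fresh in-control profile unbiased — the property the
flagging rule relies on. Theoretical limits are provided for diagnostics:
T² ~ k(n²−1)/(n(n−k)) · F(k, n−k); SPE ~ g·χ²_h with g = θ₂/θ₁,
h = θ₁²/θ₂, θ_i = Σ_{j>k} λ_j^i.

Two calibration facts worth stating explicitly. First, each empirical
99th-percentile limit achieves its nominal 1 % level on exchangeable null
strains; the either-statistic union is therefore ≈ 2 % by construction
(two near-independent 1 % tests), and that is the expected false-positive
background of the screen. Second, with a small reference cohort (a few
hundred profiles) resubstitution limits are optimistically biased — fresh
nulls exceed them at ~3–6 % when k ≈ 12 — which is an inherent property of
the resubstitution design at that sample size, not an implementation defect;
the calibration suite therefore measures the limits against a large
reference cohort, while the recovery suite runs the screen-scale design
(276 wild-type replicates) where detection power, not null calibration, is
the question.

## Clustering and enrichment

k-means uses greedy spread-out (k-means++) seeding with 50 restarts and a
fixed seed; k is chosen to maximize the mean silhouette width over a scanned
range (default 2…8), with "no cluster structure" reported when no k achieves
a positive mean silhouette. The 2-D PCA embedding fixes signs by making the
largest-magnitude loading of each component positive. Fisher's exact test is
two-tailed with the convention "sum of the probabilities of all tables (same
margins) no more likely than the observed" — oracle-tested against explicit
hypergeometric enumeration. The enrichment background is the flagged-strain
set; no multiple-testing correction is applied by default (p < 0.05), with
Benjamini–Hochberg available as an option.

## Problem sizes used by the test- and acceptance-suites

Chosen as the package's own working sizes: segmentation fidelity on
12 frames × 15 cells; classifier training at the reference set sizes
(3 745 + 1 650 cells for the intact/lysed stage, 595/376/332/258 for the
morphology classes); limit calibration on 10 000 null strains against a
30 000-profile reference; the recovery screen at 4 150 strains (150 planted
deviants of three archetypes) + 276 wild-type replicates on 3 plates.

## Known limitations

* The 54-descriptor inventory satisfies the documented block structure and
  invariances, but individual formulas are artifact-defined — no claim is
  made that they match any particular instrument vendor's definitions.
* Resubstitution control limits at small reference-cohort sizes are
  optimistic (see above); a leave-one-out option would reduce this at extra
  cost and is not currently implemented.
* Segmentation assumes separated cells; heavy aggregation is out of scope by
  design (merged blobs are discarded, biasing counts in crowded wells).
* The generator resamples populations per time-point, so it cannot be used
  to validate single-cell tracking.
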