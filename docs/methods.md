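# Methods

This note records the models, parameter choices and numerical conventions
behind `aggrefinger`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Coordinate and unit conventions

Localization coordinates are camera pixels (107 nm/px by default), 0-based,
origin at the centre of pixel (0, 0). Per-axis localization precision is
stored in pixels (`lpx`, `lpy`), pooled as their mean and converted to nm
for filtering. All reported lengths and areas are in nm and nm² after
multiplication by the pixel size. Because a px→nm round trip can perturb
the last bits of a value that is exactly on the 30 nm precision boundary,
the pooled precision is rounded to 10⁻⁶ nm before the strict `< 30 nm`
comparison.

## Diffraction-limited counting

A field of view is reduced to one image by a pixel-wise mean over its last
40 frames (shorter stacks are averaged in full); trailing-frame averaging
suppresses uncorrelated camera noise while surface-bound particles are
static. Detection is deliberately simple and two-knobbed, mirroring how
such thresholds are optimized against positive and negative control wells:
Gaussian smoothing (σ = 1 px), a robust background threshold at
median + k·1.4826·MAD with k = 5, local maxima with a 3 px minimum
separation, and an intensity-weighted sub-pixel centroid in a 7 px window.
The threshold is background-relative, so detections are invariant to
additive offsets; counts are monotone non-increasing in k. Spots whose
measurement window crosses the image border are excluded from intensity
measurement (unbiased windows) but still counted. Count scaling divides by
(tissue weight × protein concentration), since both inflate the material
loaded; the scaled unit is spots per (mg × mg/ml).

On synthetic fields with 10 well-separated spots at SNR ≈ 10 (peak
amplitude 100 photons over a 100-photon baseline with Poisson shot noise
and 2-photon read noise), pooled recall and precision exceed 0.99 and
centroids land within 0.25 px of truth. An isolated noise peak above 5
robust SDs appears roughly once per twenty 256² fields; we keep k = 5
because the assay's dynamic range favours sensitivity, and background
counts are reported against isotype controls rather than subtracted.

## Colocalization and its chance estimate

Two channels are matched by Euclidean distance within 4 px; candidate pairs
are accepted greedily by ascending distance, one-to-one, with ties broken
toward lower spot indices (deterministic). The chance-match rate is
estimated by mirroring channel B's x-coordinates about the image's vertical
axis (x → width − 1 − x) and re-matching: the transform preserves density
and y-structure while destroying true correspondence. An axis-swap
alternative is available in configuration. For independent uniform channels
the chance proportion agrees with the Poisson void expectation
1 − exp(−ρπr²) to within Monte-Carlo uncertainty at the spot densities used
here (tens of spots per 512² field); one-to-one matching introduces a
contention deficit that only becomes visible at much higher densities.

## Super-resolved morphometrics

The chain is: discard the first 300 frames (pre-equilibrium blinking);
keep localizations with pooled precision strictly below 30 nm; estimate
drift by splitting the acquisition into 10 temporal blocks, rendering each
as a 2-D histogram (30 nm bins) and cross-correlating against the first
block with parabolic sub-bin peak interpolation, then subtracting the
piecewise-linearly interpolated trace. This first-block-referenced
correlation is a simplification of fully redundant (all-pairs)
cross-correlation; it recovers a 10 px terminal displacement injected over
5000 frames to within ~2% on typical fields, and its zero-drift noise floor
is well under 0.1 render bins. Blocks without localizations inherit
interpolated shifts.

Aggregates are isolated with DBSCAN at ε = 0.5 px and minPts = 5 (pixel
units; ε ≈ 53 nm). The implementation is scikit-learn's; a hand-written
O(n²) density-reachability oracle reproduces its labels exactly on random
instances and serves as the independent reference in tests.

Each cluster is rasterized onto a 5.35 nm grid (camera pixel / 20) and
reduced to a single 8-connected region by dilation (disc r = 1), closing
(r = 2) and erosion (r = 3); the largest component is kept, and if erosion
empties the mask the dilated occupied bins are restored. These radii were
calibrated once against the generator's ground truth: localization
precision extends a rod's rasterized blob by roughly 2σ (~25 nm) beyond
each tip, and the net one-bin erosion surplus trims approximately that
much, making the skeleton length estimator approximately unbiased across
50–500 nm (per-length mean recovery 0.86–1.07 at σ = 12 nm) instead of
20–55% long. All radii and the render pixel remain configuration values.

Measurements on the mask: area = bin count × (5.35 nm)²; perimeter from the
region's boundary approximation; eccentricity and axis lengths from the
ellipse with the same second central moments (image convention, e ∈ [0, 1));
length as the skeleton's summed branch distance — the topological skeleton's
pixel graph summed edge-by-edge (1 per orthogonal step, √2 per diagonal,
skipping diagonals that shortcut an orthogonal corner). "Smoothed length"
and skeleton length are treated as the same quantity. Density is exactly
n_localizations / area, so density × area reproduces the count.

Known behaviour at the extremes: for 50 nm rods the mask is only a few bins
long, individual measurements are strongly quantized, and only the mean
over many particles is accurate; eccentricity of 100 nm rods sits just
above the 0.9 fibrillar threshold on average (0.91–0.92), with individual
particles scattering to either side.

## Subpopulations and donor profiles

Category flags use inclusive thresholds — long: length ≥ 100 nm; fibrillar:
e ≥ 0.9; dense: ≥ 0.01 loc/nm² (sparse is its complement); bright: scaled
intensity ≥ 0.9 — the inclusive boundary being the documented choice where
">" and "≥" conventions collide. Spot intensities are min-max scaled to
[0, 1] by the batch maximum (per region × extract panel), which makes the
0.9 A.U. bright cut meaningful. Donor profiles average technical-replicate
means (three replicates by default); proportions are computed over all of a
donor's aggregates. The radar count feature normalizes each donor's mean
count by the maximum donor count within the panel, so exactly one donor per
panel scores 1.

## Cohort statistics

Cumulative distributions are made averageable across donors by evaluating
the nearest-rank quantile at 101 proportions (0, 0.01, …, 1). Distribution
comparisons draw matched-n subsamples (default 1000) without replacement
from each population, apply the asymptotic two-sample KS test, and repeat
(default 100 bootstrap draws), reporting the median statistic and median p;
matching n removes the sample-size bias of raw KS comparisons between
cohorts of very different sizes. How to combine p across repeats is a
genuine design gap; the median is reported because it is stable and reduces
to the single-test p when the populations are not larger than the
subsample. In that regime the null rejection rate is exactly calibrated
(measured 0.043–0.05 at α = 0.05); with much larger populations the
median-p summary becomes mildly conservative. Holm–Bonferroni is used for
per-cohort families and plain Bonferroni for per-population comparisons;
family membership is always an explicit argument. Mean comparisons use
Welch's unequal-variance t; relative proportions use a one-sample t against
1 with Bonferroni multiplication.

## Disease-signature LDA

One observation per donor × region (replicate means), 15 features: mean
count, area, eccentricity, perimeter, minor and major axis, localization
count, length, density, scaled intensity, and the proportions bright,
pSER-colabelled, fibrillar, long and sparse. Features are z-scored before
fitting because they mix nm, counts and proportions. Classes are the
combined region-cohort labels. The discriminants solve the generalized
symmetric eigenproblem S_b v = λ (S_w + 10⁻⁶·tr(S_w)/p · I) v; the ridge
keeps the within-class scatter invertible at small donor numbers.
Explained-variance ratios are normalized eigenvalues (non-increasing);
coefficient signs are fixed by making each discriminant's largest-magnitude
loading positive, and contribution rankings order features by |coefficient|
with ties broken alphabetically. scikit-learn's LDA is used only as an
independent cross-check in the test suite.

## Proteomics

Protein-group tables are filtered to non-contaminants (flag column plus
accession prefixes, including keratins) quantified by at least two
peptides, one unique. Channels are normalized by their reference sample's
summed abundance rescaled to the grand mean of reference sums — a pooled
per-run reference for the total proteome, per-channel references for the
affinity-captured aggregate fraction. Per-case ratios divide by the mean
control abundance; the aggregate-fraction ratio is divided by the same
protein's total-proteome ratio, cancelling proteome-wide disease effects
so only aggregate-specific enrichment remains. Proteins must be quantified
in at least one case in both fractions, and a zero control mean drops the
protein with a reason code. The one-sample test operates on log₂ corrected
ratios against 0 — the same orientation as testing the ratio against 1 but
symmetric in variance. Volcano calls use |log₂| > 1 and
−log₁₀ p > 1.3 (−log₁₀ 0.05). Spike-ins with a true corrected log₂ of 2 at
10% CV and 5 cases are recovered to within ±0.1 on average and called
correctly in 100% of simulations; null proteins produce essentially no
false calls at these thresholds.

## The synthetic generator

The generator emulates: Gaussian point-spread puncta on a Poisson +
Gaussian camera noise model; localization clouds sampled from parametric
shapes — rods as line segments with a Gaussian transverse profile (20 nm
FWHM, the fibril-like case) and globules as uniform discs — jittered by
per-axis Gaussian precision (default 12 nm, matching the post-filter mean
of real acquisitions), with uniform background localizations, uniform frame
assignment and optional cumulative linear drift; donor cohorts (defaults:
3 control, 2 SOD1-disease, 5 TDP-disease donors × 2 regions × 3 technical
replicates) whose aggregate-level morphometrics are drawn from donor-level
distributions with the disease effect directions — TDP aggregates longer,
more eccentric and sparser, counts raised in cerebellum and lowered in
frontal cortex; and two-fraction TMT-style tables with log-normal
abundances, pooled-mean reference channels and spiked fold changes.
Per-aggregate localization counts are not a published quantity; the default
of ~2 localizations per nm of backbone (200 for a 150 nm rod) is a
configuration choice. A separate calibrated fixture
(`synthetic.calibrated_cohort_fixture`) with 10 donors per cohort and
cohort means separated by about two between-donor SDs defines the
discriminant-recovery benchmark.

Not emulated: photoswitching kinetics and repeated blinking of single
emitters (localization counts are independent draws, not blink trains),
EMCCD gain statistics, illumination inhomogeneity, multi-emitter fitting
artefacts, chromatic offsets between channels, or donor-level biological
covariates (age, post-mortem interval). Passing recovery tests therefore
demonstrates the correctness of the measurement chain on idealized inputs
— unbiasedness of the length estimator, calibration of tests, recovery of
known effects — not robustness to every artefact of real acquisitions.

## Benchmark problem sizes

Sizes were chosen to keep each benchmark to a couple of minutes on one
CPU: detection uses 20 fields of 256² px with 10 spots; rod recovery 40
clouds per length at 7 lengths; clustering 50 random instances of up to
200 points; KS calibration 1000 null comparisons with populations of
exactly 1000 (see above); LDA 60 donor × region observations; proteomics
100 simulated experiments of 100 proteins; drift one 5000-frame field with
four aggregates and background.
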