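# Methods

This note documents the models, numerical choices and limitations behind
`chromadiet`.  It covers the two analysis pathways — chromatic scene
statistics and simulated colour psychophysics — and the synthetic-data
generators that stand in for data that cannot be redistributed.

## Colour spaces

All chromatic computation happens in the MacLeod–Boynton (MB) diagram,
`l = L/(L+M)`, `s = S/(L+M)`, reached from linear camera/display RGB through
a measured 3×3 RGB→LMS calibration matrix.  The calibration matrix absorbs
the choice of cone fundamentals; two diagram conventions (a discrimination
space centred on equal-energy white and a stimulus space centred on
Illuminant C with contrast-equating axis scalings) are represented as two
`DiagramConfig` values rather than two code paths.  The axis-scaling
constants of the stimulus space are device- and fundamental-specific; the
shipped defaults (`data/default_diagram.json`) set them to 1.0 and record
the white points used, and every study run re-emits its resolved
configuration, so no published number in this package depends on a hidden
constant.  Angles are degrees in [0, 360) at the API surface, radians
internally; an exactly achromatic point has undefined hue and carries a NaN
sentinel.

Pixels with `L+M <= 0` after calibration have no chromaticity; they are
returned as NaN rows and counted (`n_invalid`), never silently dropped.

## Scene statistics

* **RAW filtering.**  A pixel is excluded when any channel is strictly below
  15 (sensor noise dominates the chromaticity estimate) or strictly above
  15000 (sensor saturation clips it); values equal to the bounds are kept.
  A pixel failing both tests (possible across channels) is counted once, as
  dark, so kept + dark + saturated always equals the pixel count — this
  conservation is asserted by a property test.
* **Subsampling.**  Every fifth image is kept by taking indices k−1, 2k−1, …,
  the rule that yields floor(n/5) images and reproduces all three of the
  study design's per-site counts exactly.
* **s.d. ellipse.**  Mean-centred covariance eigendecomposition; radii are
  square roots of eigenvalues (ddof = 1), orientation is the major
  eigenvector's angle folded to [0, 180).  Collinear clouds yield minor
  radius 0 and a degenerate flag.
* **Log axis ratio.**  Cardinal variances are normalised per image (dividing
  each axis by its sample s.d. about the mean); the diagonal radii are then
  the s.d.s of the centred cloud projected on the ±45° unit directions, and
  the statistic is their natural log ratio.  For a Gaussian cloud with unit
  cardinal variances and correlation c this equals 0.5·ln((1−c)/(1+c)),
  which the tests use as a closed-form oracle.  Projected s.d.s are used
  rather than intersecting the fitted ellipse outline: the two agree exactly
  for Gaussian clouds and the former is directly oracle-checkable.  Natural
  log is used throughout; sign and zero point, which carry the inferential
  content, are base-invariant.  A pooled-per-site normalisation variant is
  available (`normalize="pooled"`) since per-image vs pooled normalisation
  is a genuine analysis choice; per-image is the default.
* **Wedge saturations.**  The hue circle is tiled by 16 wedges of 22.5°; axis
  k pools the wedge centred on its pole at 22.5°(k−1) with the opponent
  wedge.  Intervals are half-open on the upper edge so each chromatic pixel
  falls in exactly one axis pair; achromatic pixels belong to none.  Empty
  wedge pairs yield NaN (with a warning), not 0, to avoid biasing means.

## Simulated discrimination experiment

The generative observer responds to a target at saturation `t` on axis a with

    P(correct) = g + (1 − g − λ) · logistic(β (ln t − ln α_a)),

with guess rate g = 0.25 (4AFC), lapse λ, slope β on the log-saturation
axis, and per-axis midpoint α_a given by the radius of the observer's
ground-truth ellipse along that axis.  The staircase starts at the gamut
ceiling `s_max`, multiplies saturation by 0.5 after a correct and 1.5 after
an incorrect response (clamped at `s_max`), and stops after 18 reversals — a
reversal being a trial whose step direction differs from the previous
step's; the first trial has no direction.  A session randomly interleaves
the 8 axes' staircases, drawing uniformly among unfinished ones; each axis
runs two consecutive staircases, the second continuing from the first's
final level by default (`second_start="restart"` is available).  A trial-cap
guard (default 1500, roughly ten times a typical track) aborts pathological
runs with the log attached.  This staircase's equilibrium sits at the 36.9%
point — slightly below the 45% criterion and only just above the guess
floor, which matters for estimator design (below).

**Threshold extraction.**  Per axis, a logistic psychometric function on ln
saturation is fit with g fixed and λ free in [0, 0.2]; the threshold is the
saturation at which the *fitted* curve (lapse included) reaches 45% correct,
a criterion robust to high lapse rates.  Adaptive-track data concentrate
near one performance level and constrain β and λ weakly; a plain ML fit
therefore produces occasional extreme slopes and badly extrapolated
thresholds.  The default estimator (`method="bayes"`) instead integrates a
posterior over a (ln α, ln β, λ) grid — 81 × 29 × 9 points spanning the data
range ± 1.5 log units, β from 0.7 to 15, λ to 0.2 — under weakly
informative priors: ln β ~ N(ln 3, 0.6²) (forced-choice detection slopes on
a log axis cluster roughly between 1.5 and 6) and λ/0.2 ~ Beta(1, 20)
(small lapse rates strongly favoured).  The reported threshold is the
posterior mean of the log 45% saturation.  A penalised-ML mode
(`method="map"`, L-BFGS-B from three starts) and an unpenalised ML mode
(`regularize=False`) are retained.  Data with fewer than two distinct
levels or only one response outcome are flagged unfittable rather than
crashed on, and the experiment pipeline excludes observers whose ellipse
cannot be formed — mirroring participant-level exclusion practice.

**Discrimination ellipse and perceptual log axis ratio.**  The 8 threshold
points (threshold × unit direction) are fit by an origin-centred conic
x^T A x = 1 in linear least squares ([x², 2xy, y²]·[a,b,c] = 1), which is
exact whenever the points lie on an ellipse; origin-centring reflects the
stimuli being radial excursions from the white point.  For the log axis
ratio the points are first rescaled so the mean cardinal thresholds are 1
per axis (the discrimination analogue of cardinal-variance normalisation),
refit, and the statistic is the log ratio of the fitted radii along −45°
and +45°.  Because threshold errors are multiplicative, the default refit
refines the algebraic conic solution by least squares on *log radii* in a
Cholesky parametrisation (A = LLᵀ, guaranteeing positive definiteness);
this is exact on ellipse-consistent inputs and noticeably more stable on
noisy ones.  The statistic is invariant to uniform scaling of all 8
thresholds.  Note that 8 arbitrary positive thresholds are generally *not*
consistent with any single origin-centred conic, so intuitive values read
off raw threshold ratios are only exact when the thresholds derive from an
actual ellipse; the tests construct their oracles accordingly.

**CVD screen.**  The ratio of mean cardinal-l to mean cardinal-s thresholds;
outliers within a group are flagged by Tukey fences (1.5 × IQR), a
conventional default since no sharper criterion is standard.

**Recovery performance and a known limitation.**  With the study design's
two 18-reversal staircases per axis (~70 trials), 100 simulated observers'
45% thresholds are recovered with a median relative error of ~12–13%.  The
rank order of observers' true vs fitted log axis ratios correlates at
Spearman ρ ≈ 0.85–0.90.  This is an information limit of the design rather
than an estimator defect: the staircase equilibrium (36.9%) lies barely
above the 25% guess floor, so runs of lucky guesses carry tracks far below
threshold with only weak mean-reversion, and the Cramér–Rao bound for the
log threshold (~0.16 with slope and lapse known, ~0.19 with them free)
propagates to a log-axis-ratio residual s.d. of ~0.23 against a
between-observer spread of ~0.42.  Per-axis ML, penalised ML, grid
posteriors, joint fits sharing slope and/or lapse across axes, and
uncertainty-based axis exclusion were all evaluated; none robustly improves
on the per-axis grid posterior.

## Mondrian stimuli

Rectangles with integer edge lengths uniform between 2% and 17% of the crop
size are dropped at uniform positions on a canvas 1.5× the crop per side,
until the central crop is fully painted (cap 5000 elements) — cropping a
fully painted canvas is what guarantees no edge or background artefacts.
Each element's hue is drawn uniformly from the axis's two complementary
poles, its saturation uniformly on [0, s_max] (the gamut-limited ceiling),
and its luminance uniformly within ±50% of the 55 cd·m⁻² mean (the jitter
distribution is not otherwise constrained; uniform is assumed).  Element
count per stimulus is an emergent property of the coverage rule, not a
parameter.  Rendering is chromaticity-referenced — channels are (x, y,
luminance) in the scaled diagram — so validation (axis purity, size and
luminance bounds, coverage) is exact; `preview_rgb` provides a
display-referred preview that makes no colorimetric claim.  Generation is
bit-reproducible from the seed.

## Preference analysis

Ranking sessions are simulated as iterated best choice: at each step the
remaining stimulus with the highest strength + fresh Gaussian noise is
removed and assigned the next rank (rank 1 = most preferred); infinite
noise yields uniform permutations and zero noise the deterministic strength
order.  Mean ranks conserve a grand mean of 4.5 exactly.  The permutation
null replaces every trial with an independent uniform permutation — the
strictest reading of "random responding" — and the band is the 2.5th/97.5th
percentile of per-stimulus mean ranks over 10 000 permutations
(participant-count and trial-count preserved).  Correlations between
preference and environment curves use Spearman's rho (scipy, mid-ranked
ties) on negated mean ranks so that larger = more preferred.  Differences
between two correlations sharing the preference vector are interval-
estimated by Zou's method for overlapping dependent correlations, with the
inter-environment correlation computed from the two environment curves;
the implementation's Monte-Carlo coverage at nominal 95% is ≥ 93–95% on
trivariate normal data (n = 50).  Note the interval's width does not shrink
fully to zero in the perfect-dependence limit because the sampling
correlation between the two estimates is itself approximated.

## Synthetic data: what it emulates and what it does not

Scene images are bivariate-normal chromaticity clouds (default s.d. 0.02
per cardinal axis around (l, s) = (0.66, 1.0)) rendered through the inverse
of a well-conditioned synthetic calibration at uniform random intensities
(L+M between 500 and 8000 on the 14-bit scale), then quantised to integers;
planted fractions of under- and over-exposed pixels exercise the filters.
The analysis consumes only second moments and wedge means, which are
analytic under normality — that is why a normal cloud suffices as the
planted model.  Quantisation limits chromaticity round trips to ~1e−4;
an unquantised rendering path exists for exact round-trip testing.  Not
emulated: spatial structure, temporal autocorrelation of consecutive
frames, demosaicing, white-balance behaviour, or gamut geometry of real
cameras — so passing tests certify the statistical pipeline, not camera
handling.

Simulated observers draw a log-normal overall sensitivity (median ellipse
radius 0.08 in normalised saturation units, σ = 0.2), an axis ratio uniform
on [1, 2.5], a uniform orientation, slope 3.5 and lapse uniform on
[0, 0.05].  The slope is the package's realism choice for a forced-choice
detection task (log-axis logistic slopes of roughly 3–4); the uniform
orientation spreads planted log axis ratios symmetrically around zero,
which is deliberately broader than human populations (predominantly
blue–yellow biased) to exercise both signs.

Preference populations apply the ranking model above to a planted strength
curve; with moderate noise the recovered mean-rank order matches the curve
exactly (rank correlation 1 in tests).

## Reproducibility

Every stochastic routine takes an explicit `numpy.random.Generator` or
seed; pipelines re-emit their resolved configuration; CSV outputs are
deterministic given config and seed.  `scripts/acceptance.py --seed N --out
results.json` recomputes the headline quantities from scratch at problem
sizes chosen to finish in well under a minute (10⁵-pixel clouds, one
320×320 rendered scene, 100 observers, 10⁴ permutations, 80 Mondrian
stimuli, 10³ Zou replicates).
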