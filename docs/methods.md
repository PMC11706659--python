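# Methods

## Sensor and calibration model

The package assumes a *linear* camera response: a surface of reflectance `r`
photographed under multiplicative illumination/exposure gain `g` produces a
pixel value `g·r·D + ε`, with `D` a fixed dynamic-range constant and `ε`
additive sensor noise.  Calibration anchors each image to an in-frame grey
standard of known reflectance `R_s` (default 0.18): per channel,

    L(p) = pixel(p) / mean(standard pixels) × 100·R_s,

so the standard reads `100·R_s = 18` on the 0–100 luminance scale and any
gain common to the scene and the standard — illumination, shutter, ISO —
cancels exactly.  ISO variation is therefore treated as pure gain.  Inputs
are linear 16-bit TIFF or 8-bit PNG; an optional inverse-sRGB step
linearises gamma-encoded input before anchoring (RAW demosaicing is out of
scope — the linearity assumption replaces it).  Single-standard linear
scaling is used throughout; no dark-level subtraction or multi-exposure
handling is attempted, as a single grey reference identifies only the gain.

The standard is rejected if any of its pixels sit at the sensor ceiling
(threshold configurable from the default 0%), since a clipped reference no
longer encodes the illumination.  Spatial scale comes from the standard's
known physical length; a batch is analysed at the *minimum* px/mm of its
images so no image is up-scaled, and an image whose scale deviates from the
batch median by more than 25% (relative, configurable) is flagged as an
outlier.  The outlier rule is the package's own convention; it is reported
on each row, never silently applied, and the stats stage excludes flagged
rows with a logged count.

## Stripe metrics

Metrics are computed over a supplied ROI mask (the fish trunk, hand-drawn in
practice; masks are authoritative and no automatic head/fin exclusion is
attempted).  Mean luminance uses the long-wave (red) channel — the channel a
fish luminance mechanism is thought to draw on — while the stripe-peak
histogram uses the combined greyscale, the unweighted mean of the channel
luminances.  This channel mismatch mirrors the measurement convention the
pipeline reproduces; both channels are configurable.

The ROI histogram of a striped body is bimodal.  Peaks are found on a
256-bin histogram over [0, 100] after a 3-bin moving-average smooth, with a
minimum peak separation of 10 bins; these defaults are exposed in
`HistogramConfig`.  The two highest qualifying maxima give `L_min` (lower)
and `L_max` (higher), reported as **bin centres** — the value a histogram
maximum read-off gives — rather than interpolated vertices.  Ties between
equal-height candidates are broken toward the pair with the largest
separation, then toward the lower bin index; this tie rule is part of the
contract.  Fewer than two qualifying peaks raises `UnimodalHistogramError`,
which batch processing records as a flagged row with empty `L_min`, `L_max`,
`C_W` (mean luminance is still reported).  Weber contrast
`C_W = (L_max − L_min)/L_min` requires `L_min > 0` and refuses swapped
inputs rather than returning a negative contrast.

Bin-centre quantisation bounds the accuracy of recovered peaks at half a
bin width (≈ 0.2 luminance units) for noise-free input and one bin under
realistic noise; a true stripe luminance lying near a bin edge may resolve
to either adjacent centre.  The derived `C_W` inherits this quantisation
(≈ ±4% at `L_min` = 9), which is why contrast recovery is assessed as a
Monte-Carlo mean over seeds rather than per image.

## Gaussian GLMs, AICc and contrasts

Candidate models are Gaussian linear models over categorical predictors
(arena colour, stimulus, session), fitted by ordinary least squares with
treatment coding against the alphabetically first level (contrasts are
coding-invariant).  The log-likelihood is evaluated at the ML variance
RSS/n, `logL = −n/2·(log(2π·RSS/n) + 1)`, and the parameter count `k`
includes the residual variance, so the intercept-only model has `k = 2` —
the convention under which the full experiment-2 model (2 arenas, 3 stimuli,
11 sessions, arena×stimulus interaction) has `k = 17`.  Model comparison
uses `AICc = −2 logL + 2k + 2k(k+1)/(n−k−1)`, defined only for `n > k + 1`.
All candidates are fitted on identical complete-case rows, otherwise
likelihoods are not comparable and the builder raises.  A model is
*supported* when its ΔAICc ≤ 2 **and** its AICc is more than 2 units below
the null model's; among supported models the one with fewest parameters is
preferred; ΔAICc ties below 1e-8 are flagged, never silently ordered.

Post hoc pairwise contrasts use estimated marginal means: model predictions
averaged over the levels of the other categorical predictors with equal
weights, differenced and tested against the pooled unbiased residual
variance on `n − p` denominator degrees of freedom.  P-values are
Tukey-adjusted via the studentized range distribution by default
(`bonferroni` and `none` are options); the adjustment choice is documented
configuration because only inequality thresholds are typically reported for
such contrasts.  When the model contains an interaction involving the
contrasted factor, the equal-weight averaging still applies and a warning is
issued, since marginal means then mask level-dependent effects.  The
implementation was checked against an independent normal-equations solution
in the test suite; fitting itself delegates to `statsmodels.OLS` on a design
matrix built here.

The Pearson test between dark- and light-stripe luminance reports `r`,
`df = n − 2` and the two-sided p-value from `t = r·√((n−2)/(1−r²))`.

## Synthetic data: what it emulates and what it does not

`generate_fish_image` renders an elliptical body carrying alternating
horizontal stripes (the orientation of a zebrafish's pattern) of two
reflectance classes, an 18% grey patch, a uniform background, multiplicative
gain and additive Gaussian sensor noise truncated at 0 and the 16-bit
ceiling (the saturated fraction is reported so tests can require zero
clipping).  Defaults: 240×320 px at 8 px/mm, body semi-axes 14×5 mm, five
2-mm stripe cycles, reflectances 0.09/0.27 (calibrated luminances 9 and 27,
true `C_W = 2.0`), gain 1, noise s.d. 260 pixel units ≈ 1 luminance unit,
`D = 26000` (leaving 16-bit headroom up to gain ≈ 2.5).  An optional flag
applies sRGB encoding to exercise the decoder path; the default is the
linear regime the calibration assumes.

`generate_metric_table` draws per-fish rows from an explicit Gaussian linear
model: `μ_i = grand mean + arena effect·1[white] + stimulus effect + session
effect`; mean luminance is `N(μ_i, σ²)` and the stripe pair `(L_min, L_max)`
is bivariate normal centred at `μ_i ∓ separation/2` with common s.d. σ and
correlation ρ, with `C_W` *derived* from the pair, never sampled against its
definition.  No published effect sizes exist in physical units for this
design, so the defaults are chosen once for realism and test power: grand
mean 18 (the standard's luminance), stripe separation 18 (stripe means 9 and
27, matching the image generator), residual s.d. 1.5, ρ = 0.53 (the
correlation observed in comparable data), arena effect +6 for white, and a
2×3 factorial of 11 fish per cell assigned cyclically across 11 sessions;
`exp2_like_spec()` reduces one cell to 10 fish, giving the 65-row layout
with contrast df 61 and correlation df 63.

The generator emulates geometry, calibration physics and design structure —
not real fish.  It omits body curvature and shading, iridescence, fin and
eye artefacts, non-uniform illumination, focus blur and segmentation error.
Passing tests therefore demonstrate that the *operators* are correct and
well-calibrated under their stated model, not that real photographs satisfy
that model.

## Acuity simulation

A viewer of acuity `A` cycles/degree at distance `d` resolves on-target
periods down to `P_min = 2·d·tan(1/(2A)°)` (cm converted to mm).  Perception
is a Gaussian low-pass with `σ = c·P_min/(2π)` in target-space mm
(converted to px via the image's scale), reflect padding at the borders.
The width factor `c` defaults to 2.45 so that a grating at the acuity-limit
period retains `exp(−c²/2) ≈ 4.97% < 5%` of its modulation — the Gaussian
MTF at frequency `1/P` is `exp(−2π²σ²/P²) = exp(−c²/2)`.  Before metrics are
recomputed the ROI is eroded by 3σ (via a Euclidean distance transform) so
boundary pixels that mix body and background are excluded; if nothing
survives the erosion the pattern is treated as fully blended (no peaks,
mean over the original ROI).  `contrast_vs_distance` records a fully
blended pattern as perceived contrast 0, making the curve non-increasing in
distance.  Acuity values are user inputs with a placeholder default of
1 cycle/degree — no species estimate is asserted as fact, reflecting how
little is known of the relevant predators' vision.

## Pipeline and reproducibility

`run_experiment` executes the stages in order (simulate, calibrate, measure,
stats, acuity), each reading the previous stage's artifacts, so partial
reruns reuse upstream outputs; any stage error halts the run naming the
stage.  Every artifact gets a JSON manifest (inputs, resolved-config hash,
seed, version) and the resolved config is written at run start; identical
(config, seed) pairs yield byte-identical CSVs.  The stats stage accepts any
per-fish CSV with the metric columns, so externally measured tables can be
refitted directly.  The simulate stage ties small reflectance offsets to the
arena and social labels so downstream selection has real effects to find;
these offsets are demonstration plumbing, not empirical claims.

## Problem sizes and numerical choices

Simulation-based checks use 50 seeded fish for stripe recovery, 1000
simulated tables (n = 32 each) for selection power, 2000 replicates of the
65-row table for correlation recovery, and 20 fish × 8 log-spaced distances
for the acuity monotonicity property — sizes at which Monte-Carlo error is
far below the tolerances being asserted while the whole suite runs in
seconds.  Degenerate inputs are errors, not warnings: empty ROIs and
standard regions, non-positive gains and scales, `n ≤ k + 1` in AICc,
rank-deficient designs (reported with the aliased columns), constant input
to the correlation test.  The mean sample correlation at ρ = 0.53, n = 65
carries the expected small-sample bias `−ρ(1−ρ²)/(2n) ≈ −0.003`, within the
tolerance used.

## Known limitations

- Peak locations are quantised to bin centres; sub-bin peak interpolation is
  deliberately not performed.
- The combined-greyscale channel equals the long-wave channel for the
  single-channel synthetic images, so the channel mismatch is structural
  rather than numerically consequential in the bundled simulations.
- The acuity module is a parameterised emulation of distance-dependent
  blending, not a model of any particular visual system (no chromatic
  acuity, no optical attenuation in water).
- Mixed-effects models are out of scope; session enters as a fixed effect.
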