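# Methods

This note documents the models and procedures gazesal implements, the
parameters that matter, the design choices made where the method was
genuinely open, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## Coordinate system and visual angles

Gaze coordinates are screen pixels, origin top-left, x rightward, y
downward, 0-based. All conversions to degrees go through `ScreenGeometry`
(default: 345 × 259 mm display at 650 mm viewing distance, 120 or 300 Hz).
Angles are computed from the metric chord on the screen over the viewing
distance, `θ = atan(d_mm / D)` — the small-excursion approximation that is
standard for displacement-driven thresholds. Under it the full display
width subtends 2·atan(172.5/650) ≈ 29.7°. The error relative to exact
eccentricity-dependent angles grows with distance from the screen centre
(≈ 0.8% at 5° eccentricity); all detection thresholds operate on local
displacements where it is negligible.

## Gaze-event identification

The pipeline is a velocity-threshold (I-VT) classifier with the following
stages and defaults:

1. **Binocular combination** — gaze and pupil are the mean over valid eyes;
   both-invalid samples become missing. The combination rule is a
   convention (validity-aware mean), chosen as standard practice.
2. **Smoothing** — a centred 20-sample moving average (missing samples
   excluded, edge windows shrink), followed by a spatial pass that averages
   each sample with the window members within 8 mm of it, suppressing
   sub-scale structure. The smoothing kernel class (moving average) and the
   temporal-then-spatial order are implementation choices; the two scales
   (20 samples, 8 mm) are the analysis parameters. For noise-free
   benchmark streams the smoothing stage can be disabled
   (`detect_fixations(..., smooth=False)`) since it intentionally blurs
   transition timing.
3. **Gap interpolation** — gaps (runs of missing samples flanked by valid
   ones) are filled linearly when the missing-data duration
   (n_missing × sample period) is ≤ 100 ms *and* the flanking positions are
   ≤ 1° apart. Boundary gaps are never filled. "Gap duration" is defined as
   the duration of missing data, not the flank-to-flank bridge time.
4. **Velocity** — per-sample angular displacement over the inter-sample
   interval, from consecutive samples without additional differentiation
   filters (simplest faithful reading; a Savitzky–Golay stage could be
   slotted in front). Each sample is classified by the *smaller* of its
   incoming and outgoing velocity: a sample that has already arrived at a
   stable location starts the fixation even though the transition into it
   was fast. This keeps onsets sample-exact; an instantaneous displacement
   with no intervening saccade sample still splits fixations via an
   explicit check on the incoming velocity.
5. **Thresholds** — fixation requires velocity strictly < 20°/s; merging
   requires centroid separation strictly < 0.5° (iterated left-to-right
   until stable, merged centroid = duration-weighted mean, RMS recomputed
   over pooled member samples); the validity filter keeps duration
   strictly > 100 ms and RMS dispersion strictly < 1°. All strict
   inequalities follow the rule wordings ("less than", "longer than").

The measured boundaries (bisection through the public API; see
`gazesal.verify` and `scripts/acceptance.py`) reproduce all five printed
parameters.

## Frame features

**Physical salience (spectral residual).** Frames are converted to
grayscale, downscaled to 64 px width (the method's canonical working
width), Fourier transformed; the residual of the log-amplitude spectrum
after subtracting its 3×3 local mean is back-projected with the original
phase; the squared magnitude is Gaussian-smoothed (σ = 2.5 at the working
scale), upscaled, and min–max normalised to [0, 1]. Log-amplitude is
computed as log(1 + A): synthetic frames can contain exact spectral zeros
(box functions) whose raw log would explode the residual. Constant frames
map to all zeros (no non-redundant information). The implementation is
checked against an independent straight-line recomputation to 1e-6.

**Motion salience (Gaussian-mixture background subtraction).** Per pixel,
K = 5 Gaussians with learning rate α = 0.002, match threshold 2.5 SD,
background weight fraction 0.9, initial variance 15 (on the 0–255
intensity scale) — the common defaults of this background-subtraction
family; α is the analysis parameter. Foreground evidence is the minimum
normalised distance to the background components, clipped at the match
threshold and scaled to [0, 1]. The model is reset at every scene cut so
motion evidence never leaks across scenes. A freshly revealed background
region (where a moving object used to be) stays salient until the model
absorbs it — inherent to the method at small α.

**Luminance.** sRGB piecewise linearisation (threshold 0.04045) rather
than a pure 2.2 power, configurable; Rec.709 weights on linear channels.
The local-luminance map is a Gaussian blur with σ = 10 px of the full
frame (the σ unit was ambiguous; full-frame pixels chosen, configurable)
and kernel extent 10% of the frame size per axis, implemented as the
truncation radius. Per-frame summaries are the map mean × 100 (percent of
maximum possible).

## Scene pipeline

Scenes are camera-cut segments labelled human / non-human; each scene's
analyzable window is its first 5000 ms (shorter scenes keep their full
duration). Fixations belong to the scene containing their onset; one
straddling a cut is truncated at the cut. Feature values are the grid
value at the fixation-centroid pixel of the temporally nearest frame —
the raw pixel value, not a neighbourhood statistic (the matching rule was
unspecified; pixel lookup is the minimal reading, and off-screen centroids
become missing rather than errors). AOI hits are the same lookup in binary
masks, defined only for human scenes; the face flag is the social-attention
outcome, aggregated to participant × scene × time-bin proportions
(`aggregate_face_gaze`) and modelled linearly rather than logistically,
matching the "proportion of gaze locations" outcome definition. The
per-participant available-data covariate is retained fixation time divided
by total investigated scene time, in percent. Age-restricted scenes carry
a flag consumed as a covariate or filter in the model stage.

## Pupillometry

Cleaning follows current pupillometry preprocessing recommendations, since
the upstream description names only the outcome: plausible range 1–9 mm;
dilation-speed outliers removed where the absolute sample-to-sample speed
exceeds median + 16 × MAD; gaps ≤ 250 ms interpolated linearly; a 3-sample
running-median smooth; traces with > 90% of samples lost are flagged
unusable. All constants are configurable.

Standardisation divides by the participant's mean diameter, so the trace
is dimensionless with mean exactly 1. The per-fixation response is the
mean standardised pupil over [onset + 200, offset + 400] ms. The shift
wording ("shifted by 200–400 ms based on the subsequent fixation time
point") is ambiguous; the window reading — front of the fixation shifted
by the minimum latency, back by the maximum — is the default, and a fixed
300 ms lag is available via `fixed_lag_ms`.

The temporal decomposition bins responses into 20 × 250 ms bins over the
5000 ms window (bin width was unstated; 250 ms gives stable bin counts at
both sampling rates), builds participant × scene mean profiles
(missing bins mean-imputed for the decomposition only), and retains the
first two principal directions, varimax-rotated. The rotated vectors are
orthonormal (rotation of orthonormal directions); explained variance is
carried separately. The component with the earlier squared-loading
centroid is PR1 (early), the other PR2 (late); per-fixation weighted
responses are response × loading at the fixation's bin.

## Mixed models

The analysis model is `y = Xβ + Z_p u_p + Z_s u_s + e` with independent
random intercepts for participant and scene (random slopes omitted by
design: they are reported not to converge at the study's scale).
Continuous outcome and predictors are z-scored on the analysis sample, so
coefficients are standardized β; two-level factors are deviation-coded
(−0.5/+0.5: ASD/human = +0.5), so main effects average over the other
factor's levels. Time-in-scene enters as an orthogonalised third-degree
polynomial, with group × time and category × time interactions; when
PR1/PR2 enter as predictors the polynomial is dropped (they already carry
the temporal weighting). The face-gaze model is restricted to human scenes
and drops the category factor (constant there).

Estimation is profiled REML over the variance ratios, with all linear
algebra through the q × q capacitance matrix (Woodbury identities), so a
fit costs O(q³) per likelihood evaluation regardless of the number of
observations; ML refits back likelihood-ratio model comparisons.
Satterthwaite denominator df for a contrast L are
`2 (L C L')² / (g' A g)`, with g the numeric gradient of the contrast
variance in the variance components and A the inverse observed REML
information (numeric Hessian; pseudo-inverse at boundary fits, df clipped
to [1, n − p]). Since every term is a single column under this coding,
per-term F = t². The implementation is cross-validated against
lmerTest (df, SEs, p to ~4 decimals) and statsmodels MixedLM (restricted
likelihood, β) in the test suite.

Group matching is greedy 1:1 nearest-neighbour without replacement on
pooled-standardized variables, pairs accepted in order of increasing
Euclidean distance, rejecting any pair beyond the 0.4 SD caliper on any
single variable. Symptom covariates are imputed by group-wise predictive
mean matching (regression on age and perceptual IQ within group, donor =
observed case with the nearest prediction), with an imputation flag per
column; the upstream method was unnamed, and PMM keeps imputations inside
the observed support. FDR adjustment is Benjamini–Hochberg within an
analysis family (the primary family has three analyses; the family is
constructed per hypothesis across models, configurable).

Power is simulated from a fitted template: outcomes are drawn from the
template's design with its estimated variance components and the tested
coefficient forced to the target β, refit, and tested; power is the
rejection fraction with a Clopper–Pearson 95% CI.

## Synthetic data: what it emulates, and what it does not

The generator plants, with recorded ground truth: fixation sequences
(lognormal-ish durations 150–900 ms, consecutive centroids > 1.5° apart,
20–40 ms linear saccades), within-fixation Gaussian jitter (the jitter SD
is a free parameter — within-fixation noise is not characterised
upstream; default 2 px), blinks as contiguous invalid runs targeting a
configured invalid fraction, and a pupil trace as participant baseline +
stimulus-locked responses delayed by a configurable latency (default
300 ms). The pupil impulse response is a unit-peak gamma kernel
(t_max = 930 ms, shape 10.1 — the standard pupillometry convention); a
step kernel is available for latency-inspection tests. Videos are frame
stacks with one static high-contrast patch, one moving patch with a
bouncing linear trajectory, and, in human scenes, a schematic person with
nested eyes/mouth ⊂ face ⊂ body AOI masks. Frames are stored as numbered
PNGs plus a JSON manifest when written to disk (codec-free and
deterministic). Cohort covariates follow the study-like distribution
shapes (age 6–30, perceptual IQ ≈ 100 ± 17, large group differences on
symptom scores) with missing-completely-at-random symptom cells.

A separate record-level simulator (`synth.records`) draws fixation-record
tables directly from the statistical model with variance components
σ²_participant = 0.15, σ²_scene = 0.10, σ²_residual = 0.75 (unit total
variance, so planted coefficients are standardized β). Repeated-fit
studies (bias, type-I, power) run on it at scaled-down sizes — bias at
40/40 participants × 20 scenes, type-I and power at 20/20 × 10 scenes with
200 replicates — rather than the study's 166/166 × 85 × 1000.

What the generator does **not** emulate: photorealistic or semantic
content (no faces that compete with salience through meaning), audio,
smooth pursuit, eccentricity-dependent noise, pupillary light reflex
dynamics, site or calibration differences. Passing tests therefore show
that the *pipeline* recovers what was planted under the stated noise
model — not that the scientific effects exist in real data, and not that
real-data preprocessing corner cases (e.g. tracker-specific artefacts)
are covered.

## Numerical choices and degenerate inputs

Constant frames normalise to zero maps. Variance floors (1.0 on the 0–255
scale) keep mixture components proper. REML optimisation is Nelder–Mead
on log variance ratios from three starts; boundary fits (a ratio
collapsing to 0) are handled by the stable Cholesky form of the
capacitance matrix and pseudo-inverse information. The empty fixation
table, the all-missing stream, zero-frame scenes, non-nested model
comparisons, entirely missing covariates, and sampling rates outside
{120, 300} Hz raise explicit errors or produce typed empty outputs as
documented per function.

## Known limitations

- The chord-angle approximation understates large eccentric displacements.
- Satterthwaite df rely on numeric derivatives; at hard variance
  boundaries the df are clipped rather than profiled.
- The face-gaze proportion model is linear, not binomial; proportions near
  0/1 with few fixations per cell violate homoscedasticity.
- The spectral-residual map's min–max normalisation makes values
  comparable only within a frame, which is what the percent-of-maximum
  summaries assume.
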