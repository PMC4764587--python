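# Methods

This note documents the models implemented in `actsense`, the choices made
where the design was genuinely open, and what the synthetic-data experiments
do and do not establish.

## Stimulus model

Images are samples of a zero-mean, unit-variance 2D Gaussian process with a
separable squared-exponential covariance, evaluated on a 77×77 grid spanning
27.8° of visual angle per axis (image-centered coordinates, extent
[−13.9°, +13.9°]).  Pattern types: patchy `PA` λ=(1.39°, 1.39°), stripy
horizontal `SH` (4.63°, 0.91°), stripy vertical `SV` (0.91°, 4.63°); the
category prior is P(patchy) = ½ with the two stripy orientations equally
likely, i.e. a (½, ¼, ¼) type prior.  Functions with any value outside
[−4, 4] are rejected and redrawn, which pulls the marginal SD slightly below
1 (≈0.95 empirically) — the observer model ignores this truncation, as the
generative description it inverts is the untruncated GP.

Sampling exploits separability: with per-axis factors B_h B_hᵀ = K_h and
B_v B_vᵀ = K_v, the draw Z = B_v G B_hᵀ (G i.i.d. standard normal) has the
full Kronecker covariance.  The axis factors are eigendecompositions with
eigenvalues clipped at zero, because SE Gram matrices on 77 points are
numerically rank deficient; the covariance distortion is below 1e-7.

Displayed pixel values are read from the 77×77 generation grid by
nearest-node lookup (ties to the lower index).  The 770×770 spline-rendered
raster and the 0.18° Gaussian aperture of the display affect visualization
only; the observer consumes one scalar per revealing.

## Ideal observer

Given revealings D = {z, x} the observer computes GP marginal likelihoods
N(z; 0, K_θ + σ_p²I) per type (log-space, Cholesky with adaptive jitter
10⁻¹⁰→10⁻⁶ as a fallback for σ_p ≈ 0 with coincident locations) and the
category posterior under the (½, ¼, ¼) prior.  Parameters:

- σ_p ≥ 0 — perception-noise SD on each revealed value (value units; drawn
  once per revealing, persisting — rescanning is outside the model).
- prior bias — `scale` α (dimensionless) multiplies, or `offset` Δ (degrees)
  shifts, all six length scales; `none` is veridical.  Biased scales must stay
  positive.
- β ≥ 0 — softmax slope on the log posterior ratio (natural log; the base
  would only rescale β).
- κ ∈ [0, 1] — lapse rate; choice probability (1−κ)σ(β·LPR) + κ/2.

Category information after k revealings is 1 − H₂(P(patchy|D)) in bits.

## Active sensor

The BAS score of a candidate x\* is the mutual information between the unseen
(perceived) pixel value z\* and the category c, computed in its predictive
form H[z\*|x\*,D] − Σ_c P(c|D) H[z\*|x\*,c,D].  The category-conditional
predictives are Gaussian mixtures (one component for P, two
likelihood-weighted components for S) with the +σ_p² observation variance
included.  Entropies use the pairwise-overlap Jensen lower bound

    H ≥ −Σᵢ wᵢ log₂ Σⱼ wⱼ N(μᵢ; μⱼ, σᵢ² + σⱼ²),

the default for simulations; an exact mode integrates the mixture entropies by
trapezoid quadrature on a shared grid (±8 SD, 2001 nodes), and an independent
oracle computes the equivalent "expected reduction in category entropy" form.
Sharing one quadrature grid across all entropy terms makes the two exact forms
agree to ~1e-9 bits; the mutual-information identity is tested to 1e-6.

Scores are evaluated on a 110×110 cell-centered grid over the image; the next
intended fixation is the argmax, with ties (within 1e-12) broken uniformly at
random.  With no observations the score surface is exactly flat, so the first
fixation of a simulated trial is a uniform random grid point.

Inhibition of return *emerges* rather than being imposed: at a revealed
location the type-conditional predictives nearly coincide, so the score is
close to zero.  It is exactly zero only when the value at that point is pinned
by its own observation (a single revealing, or σ_p → 0).  With larger σ_p and
spatially correlated revealing sets, refixating draws a fresh perception-noise
sample and is genuinely informative (up to ~0.07 bits at σ_p = 0.5 in
practice), so occasional refixations by the greedy policy are a property of
the model, not an artifact.

## Saccadic variability and bias

Executed saccades decompose the intended displacement into tangential and
orthogonal axes and add amplitude-dependent Gaussian noise plus a tangential
bias, each linear in amplitude d: SD_tan = 0.13·d + 0.41°, SD_orth =
0.011·d + 0.38°, |bias| = 0.23·d + 0.37° (calibration-experiment regression
values).  The sign convention of the printed bias regression is ambiguous, so
the model stores signed coefficients and the measured preset is switchable;
the default applies the bias as undershoot.  Executed locations are clipped to
the image extent, preserving the intent (resampling is reserved for the random
strategy, whose out-of-image draws are redrawn).  A zero-length intended
saccade has no direction and is executed exactly.

The calibration fit mirrors the measurement procedure: exclude trials with
fixation drift > 0.56° or endpoints closer to the non-cued target, estimate
per-eccentricity SDs as 1.4826×MAD and bias as the median tangential error,
and regress each on target distance (eccentricities 1.39, 2.78, 5.56, 8.34°).
The misdirection rule mildly truncates the error distribution when targets are
close relative to the noise — visible as a small downward bias of the fitted
SD at the smallest eccentricity; this is a property of the exclusion rule
itself.

## Revealing strategies

- `bas` / `max_entropy`: greedy argmax of the full score or of its first
  (total-entropy) term; selection conditions on the *perceived* values and the
  observer's (possibly biased) model; saccade noise applies when a model is
  supplied.
- idealized sensor: `bas` run with σ_p = 0.17, no prior bias, no saccade
  noise, observing displayed values (σ_p = 0.17 still regularizes the GP
  math) — the upper-bound revealing generator of the passive condition.
- `anti_bas`: the same sensor run against a decoy image of a randomly chosen
  wrong type; the recorded trial reveals the real image.
- `random`: isotropic Gaussian, SD 9.27°, resampled into the image.  Note the
  resampling truncates each marginal at ±1.5σ, so the realized per-axis SD is
  ≈6.88° (closed-form truncated normal), not 9.27°.
- heuristics: resample a reference pool of fixations by revealing order, by
  MAP pattern type (ties broken patchy-first, the prior argmax), or by both.
  In the synthetic pipeline the pool is built from simulated noisy-BAS trials,
  standing in for participant trials.

Simulated datasets are balanced over revealing counts {5, 10, 15, 20, 25} and
over categories (½, ¼, ¼ by type), or uniformly over types where per-type
sample size matters; per-trial seeds are recorded so any trial can be
re-simulated bit-identically.

## Observer fitting

The choice likelihood marginalizes the unknown perceived values by Monte
Carlo: per trial, n_sims redraws of perception noise around the displayed
values, the softmax/lapse probability of the recorded choice averaged over
redraws, probabilities floored at 1/(10·n_sims).  One fixed noise tensor is
reused at every parameter setting (common random numbers), making the MC
likelihood a smooth deterministic function of the parameters; n_sims = 500
reproduces the original fitting setting, 100 is the desk-scale default.

Fitting combines a grid over (σ_p, α or Δ) with box-constrained L-BFGS over
(β, κ) at every node (analytic gradients, warm-started along the grid, 3-start
refinement at the winning node).  Default grids: σ_p ∈ [0.1, 1.5] step 0.1;
α ∈ [0.5, 2] step 0.1; Δ ∈ [−0.5°, 1.5°] step 0.05° (the original grid used
0.01° for Δ; the step is an argument).  Six variants — {no bias, α, Δ} ×
{lapse, no lapse} — are compared by BIC = k·ln(n_trials) − 2·lnL; the
κ-in/κ-out pairs share the grid of cached likelihood-ratio arrays.

Identifiability: with 600 random-revealing trials the lapse rate is *not*
identifiable — the softmax slope absorbs it almost exactly, so BIC prefers the
lapse-free model even when κ = 0.1 generated the data.  Lapse identification
requires strong-evidence trials (near-saturated posteriors, as produced by
active sensing).  Similarly, the offset and scale bias forms are barely
distinguishable from short trials.  The model-recovery experiment therefore
generates from the three-parameter offset variant using trials at the task's
maximum of 25 revealings; the parameter-recovery experiment fits the
offset+lapse variant to data generated from it and recovers (σ_p, Δ, κ) within
(one grid step, 0.2°, 0.05).

## Density maps, correlations, information curves, efficiency

Density maps: per trial, revealings are translated so their centroid is at the
image center; counts are binned at 770×770, reweighted so every trial
contributes as if it had 25 revealings and types are equally frequent,
smoothed with an isotropic Gaussian (SD 20 bins ≈ 0.73°), and normalized.
Mean correction subtracts the unweighted mean of the three type maps; the
conventional display scale sets the peak of the mean map to 1.

Split-half correlations: pooled (trial-centered) revealing locations per type
are split randomly in half (equal counts per type), each half binned and
smoothed with a 1.5° kernel, mean-corrected within half; within-type = mean of
the 3 same-type correlations across halves, across-type = mean of the 6
different-type ones; repeated (default 1000×) for means, SDs, percentile CIs
and sign p-values.  Correlation maps are binned at 154×154 (0.18° bins, ~8×
finer than the kernel — the correlation is insensitive to the bin size at this
ratio, and the original bin resolution for this analysis is not specified).
Revealings are weighted inversely to their order frequency so each revealing
number contributes equally — the pooled "bar" statistic; the per-revealing
curves use cumulative (order ≤ n) locations at constant sample size.  A
participant-vs-model mode draws the two halves from two different datasets.

Information curves: for each trial the perceived values are redrawn n_sims
times (default 200) around the displayed values and the cumulative
1 − H₂(P(patchy|D₁..k)) recorded for every prefix k.  All prefixes of one
(trial, type) share a single Cholesky factor — with whitened residuals
a = L⁻¹z, the k-prefix quadratic form is the running sum of aⱼ² and the
log-determinant the running sum of log Lⱼⱼ² — so the whole curve costs one
factorization per type.  Curves report mean ± SEM across trials; the
simulation replicates are kept as the bootstrap unit.

Efficiency: cumulative Weibulls I_s(n) = 1 − exp(−(n/a_s)^b) are fitted
jointly by least squares with the shape b shared across strategies; the
efficiency of s₁ relative to s₂ is a_{s₂}/a_{s₁}; 95% CIs come from refitting
on bootstrap resamples of the simulation replicates (default 200).

## Synthetic-study conditions and problem sizes

The generator's defaults are the task's stated conditions: three pattern types
as above, 5–25 revealings in steps of 5 (balanced), equiprobable categories,
saccade calibration at four eccentricities.  The reference noisy observer used
across the analyses is σ_p = 0.5, Δ = +0.6°, β = 1.5, κ = 0.05 — the scale of
the published participant fits; the idealized sensor uses σ_p = 0.17.  Test
and acceptance problem sizes are chosen for a desk-scale run: 200 paired
trials per strategy (25 revealings, n_sims = 200) for the efficiency ordering;
600 25-revealing trials per dataset and 20 datasets (n_sims = 50, Δ grid step
0.2°, σ_p step 0.2) for model recovery; 600 trials with n_sims = 100 for
parameter recovery; 200
trials per type for the split-half signature; 500 images for the stimulus
statistics.

## What the synthetic experiments do and do not show

The simulations emulate the structure of the gaze-contingent task: GP images,
revealing-by-revealing belief updates, strategy-dependent fixation placement,
saccadic scatter, softmax/lapse choices.  They do not emulate real human data:
no fixation-duration effects, no rescanning, no spatial biases for cardinal
directions or screen center, no learning across sessions, and perception noise
that is exactly Gaussian and i.i.d. across revealings.  Passing tests
therefore establish the internal correctness and statistical power of the
pipeline under its own generative assumptions — not that those assumptions fit
any particular dataset.  Published headline quantities that depend on the
original participants' eye-tracking data (per-participant parameter tables,
BIC tables, efficiency ratios near 2.9/2.5/1.45) are not reproducible here;
the same code paths are instead validated on synthetic stand-ins.

## Known limitations

- The Jensen bound is a lower bound used *inside* a difference of entropies;
  the resulting score can be slightly negative far from all observations and
  its argmax can deviate from the exact-mode argmax when the surface is nearly
  flat (e.g. a saturated posterior).
- Greedy, single-step lookahead only; no planning over fixation sequences.
- Dense GP algebra throughout (n ≤ 25 revealings); not suitable for hundreds
  of observations.
- The efficiency fit assumes the Weibull family with a shared shape fits every
  strategy's curve; strategies with qualitatively different saturation (e.g.
  random at very low information) stretch this assumption, which is why ratios
  are reported with bootstrap CIs.
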