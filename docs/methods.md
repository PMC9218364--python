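# Methods

This note documents the models implemented in `melsum`, their assumptions,
the defaults and why they were chosen, and what the synthetic-data tests do
and do not establish about real data.

## Spectral model

**Primaries.** The five-primary photostimulator is represented by Gaussian
spectral power distributions with the instrument's published peak
wavelengths and full widths at half maximum (456/10, 488/11, 540/10,
594/14, 633/15 nm).  Only peak and FWHM are published for the LED +
interference-filter primaries, so a unimodal Gaussian is the natural
minimal model; the FWHM→σ conversion is σ = FWHM/2.3548.

**Receptor sensitivities.** The five classes (L, M, S cones; rods;
melanopsin) are generated from the Govardovskii A1 visual-pigment nomogram
(α- plus β-band) with λmax = 558, 530, 420, 500 and 480 nm.  The nomogram
is analytic, so no spectral tables need to be shipped or downloaded; any
other template (or measured fundamentals) can be substituted through
`build_receptor_set` or the CSV import in `melsum.io`.  Pre-receptoral
filtering is *not* modelled spectrally; individual-observer calibration
(e.g. the output of heterochromatic flicker photometry) enters only as an
optional per-class diagonal scaling.

**Troland normalisation.** Photopic retinal illuminance is defined as the
sum of L- and M-cone excitations with a 2:1 L:M ratio.  Normalisation
constants are therefore chosen so that a flat (equal-energy) spectrum at
1 photopic troland excites the classes by exactly (2/3, 1/3, 1, 1, 1); this
holds for *any* template family and makes all excitations
troland-referenced.  Scotopic trolands for a fixed background chromaticity
are exactly proportional to photopic trolands; the constant is supplied as
an anchor pair, default (200 Ph Td, 498 Sc Td) for the orange adapting
field, giving e.g. 3000 Ph Td → 7470 Sc Td.

**Bleaching.** Steady-state photopigment bleach uses the saturating form
p = I/(I + I₀) with half-bleach constant I₀ = 10^4.5 photopic trolands.
This reproduces the canonical rhodopsin numbers for the light levels of
interest — ≈0.6 % bleach at 200 Td, ≈6 % at 2000 Td, and ≈80 % of pigment
still available at 8000 Td — which is the quantitative basis for the claim
that rod vision at high photopic levels is not bleach-limited.

## Silent substitution

The excitation matrix `E` (class × primary) is assembled by quadrature of
sensitivity × SPD; a 5×5 LU solve gives the primary-domain modulation for
any requested per-class signed Michelson contrast vector, with contrasts
defined on excitation extrema, C = (Emax − Emin)/(Emax + Emin).  No
regularisation is used (the system is square and well conditioned; its
condition number is reported).  Primary outputs are normalised to [0, 1];
infeasible demands are flagged with the largest feasible multiplier, never
clipped, since clipping would silently break the silencing.

**Working point.** The adapting background is the gamut knob: the package's
`study_background` maximises the smallest achievable isolating contrast
over the melanopsin, rod and joint-cone directions (deterministic
multi-start Nelder–Mead on log-weights), then normalises every primary's
range so the background sits mid-range.  Under the nomogram model the
optimum is an orange-appearing background (relative excitations
l ≈ 0.80, m ≈ 0.20, s ≈ 0.015, r ≈ 0.27, i ≈ 0.16) with ≈20 % melanopsin
and rod gamut — enough for the study's 17 % melanopsin and 15 % rod
measurement contrasts.  The instrument's own published chromaticity
(l = 0.755, m = 0.244, s = 0.107, r = 0.345, i = 0.265) lies on this
model's gamut boundary (its exact realisation requires a negative red
primary weight); `nearest_feasible_background` finds the closest
non-negative mixture, which matches the published relative excitations to
within ≈0.01.  The difference reflects the unfiltered nomogram
sensitivities, not the solver.

**Intrusion.** What a perturbed observer sees in a nominal-observer
solution is evaluated by rebuilding the receptor set with independently
jittered pigment peaks (default Gaussian sd 1 nm, configurable — the
perturbation ensemble used for the instrument's published tolerance bounds
of ≤0.3 % rod and ≤1.5 % cone contrast is not public) and recomputing the
contrasts of the solution endpoints.

## Stimulus engine

Stimuli are defined in receptor-contrast space and rendered per frame
through the solver, so non-targeted excitations are constant by
construction.  Durations follow the protocol: 1000 ms for f ≥ 1 Hz, one
full period below.  Frames default to 200 Hz and always span a whole
number of cycles, so time-averaged excitation equals the background
exactly (adaptation constancy) and amplitude/phase recover exactly by
quadrature projection.  Combined two-class conditions are scaled in
threshold units (each component a multiple of that observer's own
threshold, ratios 0.5:1 to 1.2:1) with the second component phase-delayed
by the offset.  Temporal white noise modulates (l, m, s, r) with
independent uniform per-frame contrasts within ±40 % while melanopsin
contrast is identically zero; the refresh (50 Hz) and amplitude
distribution are not published and are configuration knobs.  Frames that
would leave the primary range are resampled and counted — at the default
working point roughly one accepted frame in eight, a sign that joint 40 %
four-class noise sits near the gamut edge.

## Psychometrics

Frequency-of-seeing data (default 6–7 levels × 24 stimulus + 6 catch
trials) are fitted with the two-parameter Weibull after Abbott guessing
correction, p_adj = (p − γ)/(1 − γ), with γ pooled over the session's
catch trials (whether the original analysis pooled per level or per
session is unstated; pooling is the lower-variance choice).  Estimation
maximises the Bernoulli likelihood of the corrected counts (the exact
optimisation criterion used originally is unstated; least squares on
proportions is available as an option).  The lapse rate is fixed at zero
and the threshold α is the 63.21 % point of the corrected function.
Degenerate data (all-yes, all-no, fewer than four levels) raise explicit
errors rather than returning unidentifiable fits.  At the study's trial
counts, simulation shows mean recovery bias below 5 % for both α and β.

## Summation analysis

Threshold ratios use the convention that the combined psychometric
function's abscissa carries the rod contrast for melanopsin+rod and
rod+cone combinations and the cone contrast for melanopsin+cone; TR is
computed per repeat against the same observer's matched individual
threshold.

**Models.** Probability summation is a phase-flat TR = n (facilitation
index 20·log10(1/n) dB).  Vector summation uses the phasor magnitude
TR(φ) = 1/√(x² + y² − 2xy·cos(φ − φ_xy)): maximal threshold elevation at
φ = φ_xy, facilitation half a cycle away.  The typeset source equation is
ambiguous about the radical; the square-root (vector-magnitude) form is
the default because the amplitude of two summed sinusoids is
√(x² + y² ± 2xy cos Δ), and the squared reading is available as a switch.
Exact cancellation (x = y, φ = φ_xy) propagates as a flagged infinity and
is excluded from least squares.  Note (x, y) enter symmetrically, so the
two sensitivities are exchangeable in the fit; recovery checks compare
order-free.

**Fitting.** The global fit shares one φ_xy across observers with
per-observer sensitivities (the same mechanism is assumed to mediate the
same condition in all observers), minimising summed squared TR residuals
by damped least squares with multi-start over φ.  Classification follows
the study's rule: per observer, a one-way repeated-measures ANOVA of TR
across the five phases (repeats as blocks, df = 4, 8); if the majority of
observers show no phase dependence at α = 0.05 the condition is
probability summation, otherwise vector summation; goodness of fit is a
χ² on SEM-standardised residuals (good fit: p > 0.05).

**RM-ANOVA.** The ANOVA, Mauchly's sphericity test and Bonferroni pairwise
comparisons are delegated to pingouin and verified in the test suite
against a definitional sums-of-squares oracle.  Mauchly's W is undefined
when blocks ≤ conditions − 1 (singular covariance — true of the study's
own 5 × 3 layout); it is then reported as NaN with a validity flag.  No
sphericity correction is applied when Mauchly is non-significant;
Greenhouse–Geisser ε is available from the underlying fit.

**Summation squares.** Contrast-ratio points are classified against their
initial threshold-unit ratio lines: within tolerance (default 5–8 %) no
interaction, above them inhibition, below facilitation, with the deviation
from the 45° diagonal indicating which pathway is affected more.

## Temporal contrast sensitivity and adaptation

The TCSF is summarised by a difference of Gaussians on log10 frequency,
S = A·[G(μ, σ) − w·G(μ, cσ)], with fixed surround weight w = 0.3 and width
ratio c = 2.0 and three free parameters (A, μ, σ) — the published analysis
names exactly three free parameters without defining the surround, so the
fixed constants are configuration-exposed.  This family produces both
low-pass (melanopsin-like) and band-pass (rod/cone-like) shapes; it is
negative beyond ≈1.8σ of the centre, so sampled frequencies should stay
within the positive band.  Fits minimise relative residuals (sensitivities
span decades).  CFF is the highest frequency at which the fitted
sensitivity still reaches 1/criterion, found by grid bracketing plus root
refinement; it is monotone in the criterion by construction.  TVI slopes
are least-squares fits of log10 ΔI vs log10 I per illumination branch,
with an optional two-segment breakpoint search; Ferry–Porter is a linear
fit of CFF against log10 illuminance.

## Synthetic observer

The generative model reproduces the study layout: 3 observers × {200,
2000} Td × six conditions × five phases (0–120°) × 3 repeats, 24 + 6
trials at each of seven levels spanning 0.4–2× the cell's true threshold.
Generative parameters default to the published group means (e.g. 1 Hz,
200 Td thresholds α_i = 9.9 %, α_R = 7.6 %, α_LMS = 5.3 %; melanopsin+rod
vector truth x = 1.0, y = 0.2, φ = 30.4°; melanopsin+cone probability
n = 0.9).  At 10 Hz there is no melanopsin-directed cell (the modulation
is imperceptible there), and melanopsin+rod switches to probability
summation — so the synthetic study reproduces the inhibitory-to-
facilitatory transition end to end.  Between-observer variability is
log-normal jitter on thresholds with 10 % coefficient of variation
(SEM-scale); the false-alarm rate defaults to 3 %, a typical catch-trial
rate (the measured rates are unpublished).  Combined-condition thresholds
are the denominator pathway's threshold times the model TR at the cell's
phase.

**What passing tests show — and don't.**  The simulations share the
analysis pipeline's parametric assumptions exactly (true Weibull
psychometric functions, independent trials, stationary thresholds,
noise-free phase control).  Recovery and model-selection results therefore
validate the estimation machinery at the study's problem sizes, not the
models' adequacy for real observers; sequential effects, learning,
fatigue, lapses and criterion drift are all absent by design.  Note the
model-selection accuracy under a true phase-flat TR is bounded near
1 − α per observer by construction (the ANOVA's false-positive rate);
majority voting across three observers raises it well above 95 %.

## Problem sizes and numerical choices

The default full synthetic study is ≈68 000 trials and 324 Weibull fits
(seconds on one core); batteries in the test suite use 100 seeded
replicates (psychometric and DoG recovery), 100 synthetic TR-level studies
(selection and global-phase recovery) and 1000 random systems (solver vs
least-squares oracle).  The TR-level batteries draw multiplicative noise
of 5 % per repeat, matching the SEM scale of the published thresholds.
Optimisers: Nelder–Mead on log-parameters for the Weibull likelihood
(multi-start over slope), bounded trust-region least squares for the
summation and DoG fits (multi-start over phase and spread).  All
randomness flows through numpy Generators seeded from a single master
seed; identical configurations reproduce byte-identical outputs.

## Known limitations

* The receptor model is an unfiltered pigment-template approximation;
  absolute intrusion magnitudes and gamut limits are indicative, not
  instrument-accurate (no lens/macular filtering, no individual
  calibration applied by default).
* The melanopsin spectral function is a 480 nm nomogram; the in-situ
  effective curve may differ slightly.
* The published scotopic-troland values are reproduced by anchor scaling,
  not recomputed from measured primary calibrations.
* Vector-summation sensitivities (x, y) are identified only up to
  exchange, and φ_xy only modulo 360°.
* The Mauchly χ² degrees of freedom printed in the original report do not
  all match the standard k(k−1)/2 − 1 formula; the standard formula is
  implemented.
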