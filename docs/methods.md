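# Methods notes

## Signal model

Each transient is a sum of damped complex exponentials sampled at
1/`spectral_width_hz`. A resonance of time-domain amplitude A and Lorentzian
FWHM f decays as `exp(-pi f t)`; its absorption-mode area is A/2 regardless
of linewidth, which is the bookkeeping identity the simulator's oracle tests
rely on. Spectra approximate the continuous Fourier transform
(`fftshift(fft(fid)) * dwell`, first FID point halved so the discrete area
matches A/2 without a broad baseline pedestal); the ppm axis is anchored at
water (4.68 ppm) and stored high-to-low.

Edit-state amplitude factors (OFF/ON): NAA 1.0/0.5, Cr and Cho 1.0/1.0, Glx
0.5/1.0 (two components at 3.71/3.79 ppm), GABA+ 0.0/1.0. The resulting DIFF
areas are GABA+ `g/2` (with `g = amp_gaba / (1 - mm_fraction)` honouring the
co-edited macromolecule share, default 50%), Glx `amp_glx/4`, NAA
`-amp_naa/4`. These factors are a desk-scale stand-in for coupled-spin
evolution: they reproduce the canonical DIFF phenomenology (positive GABA+
and Glx, inverted NAA) but carry no J-coupling physics, so green tests
establish pipeline correctness, not editing-efficiency realism.

Task modulation multiplies Glx by `1 + task_glx_frac` (default 0.06) and
GABA+ by `1 + task_gaba_frac` on task-ON transients; an optional
`early_bin_boost` adds to the fraction when T_S-A < 183 ms. The boost
defaults to 0 so the pooled ON increase equals `task_glx_frac` exactly; set
it to ~0.055 (with `task_glx_frac` ~0.042) to emulate a 9.7% first-bin /
6% pooled profile.

BOLD enters as line *narrowing*: instantaneous FWHM =
`base_fwhm_hz - bold_narrowing_hz * h(t)` where h is the dual-gamma HRF
(gamma(6,1) − gamma(16,1)/6, 32 s support, unit peak; note the positive
lobe's mode is at delay − dispersion = 5 s) convolved with trial impulses
and normalised to peak 1. On top of this sit: Gaussian linewidth jitter
(`fwhm_noise_sd_hz`, default 0.15 Hz) emulating respiratory/cardiac B0
modulation — without it the fitted linewidth series is unrealistically
smooth and any MAD-based cleaning rule degenerates; linear frequency drift;
motion spikes (frequency ~N(0, 5 Hz), phase ~N(0, 20°), amplitude factor
~N(1, 0.2) — the amplitude part is what registration cannot repair and the
spike nuisance regressor exists for); a 2-step phase cycle implemented as
receiver sign alternation with a small sign-locked baseline offset; complex
Gaussian noise (`noise_sd` 1.0, giving single-transient NAA spectral SNR of
roughly 50, i.e. a well-shimmed 18 mL voxel at 3 T).

## Preprocessing choices

*Registration* estimates one frequency/phase pair per transient by matched
filtering against the pointwise-median FID of its group (edit-ON metabolite,
edit-OFF metabolite, water), two passes with the template rebuilt once. For
a trial frequency the optimal phase is analytic, so the search is 1-D:
coarse 1 Hz scan over ±20 Hz, then bounded Brent. Corrections are pure
modulations and cannot change amplitudes.

*Condition GLM*: for every spectral point, complex values across metabolite
transients of one edit state are regressed on condition indicators plus
centred nuisance columns (phase-cycle step, spike flag, standardised |Δf|,
|Δφ|). Centring makes the condition coefficients nuisance-adjusted condition
means; empty conditions (the outer T_S-A bins, by design of the jitter
range) are reported absent, never as zero spectra. Nuisance columns whose
raw variation is below measurement resolution (0.05 Hz / 0.5°) are dropped:
standardising them would promote lineshape-tracking artifacts — which
correlate with the task through the BOLD linewidth trace — into the design
and visibly bias the condition contrast.

*Reference deconvolution* divides the target FID by the normalised magnitude
envelope of the water reference and multiplies by an ideal Gaussian decay of
the requested FWHM, with the pointwise gain capped at `1/floor_frac`
(default 20×). The cap, rather than an envelope floor, keeps the operation
exactly idempotent on already-matched lineshapes while still bounding noise
amplification. The pipeline deconvolves each condition spectrum against the
*condition-matched* wref average (task-ON spectra against task-ON wrefs):
the water line carries the same BOLD narrowing as the metabolites, and a
run-average reference leaves a systematic ON/OFF lineshape mismatch worth
~2% of the Glx estimate.

## Quantification

Fit windows and shapes: GABA+ Gaussian on 2.79–3.55 ppm; Glx two Gaussians
with shared width and a shared centre shift, pinned at 3.71/3.79 ppm, on
3.45–4.10 ppm (free per-component centres measurably inflate the noisier
task-ON fits); inverted NAA Lorentzian on 1.80–2.25 ppm; edit-OFF NAA/Cr/Cho
Lorentzians with one shared linear baseline on 1.8–3.5 ppm. All fits are
`scipy.optimize.curve_fit` with bounds; non-convergence flags the estimate
rather than raising. SNR is the fitted NAA amplitude over twice the real-part
SD in 9.5–10.5 ppm. The serial filter applies linewidth (30/12 Hz), then
strict SNR (< 20), then 5 × unscaled-MAD outliers among survivors; MAD = 0
means no rejections. Institutional units are
`area / water_area * K` with K = 2500, chosen once so the default
healthy-control Glx sits near 15 i.u.; no tissue or relaxation corrections.

## BOLD estimation

Water spectra are fitted with a shared-width pseudo-Voigt
(`eta*L + (1-eta)*G`) on a linear baseline. Cleaning invalidates level
outliers (5 × MAD) and both neighbours of any first-difference beyond 3 ×
MAD of first differences; invalid samples are excluded, never interpolated.
The cleaned series is regressed on the HRF event regressor plus intercept
and a standardised linear drift; ΔFWHM_water is the negated regressor
coefficient, so positive values mean stronger BOLD (activation narrows the
line). Fewer than 10 valid samples marks the estimate unreliable.

## Statistics

* `skipped_spearman`: bivariate outliers are points exceeding the 1.5-IQR
  box-plot rule on the projection onto *any* direction through the
  minimum-covariance-determinant centre and a data point; Spearman and a
  1000-resample percentile bootstrap CI are computed on the retained points.
  The union-over-directions rule typically flags a few legitimate edge
  points along with a gross outlier; this matches the behaviour of the
  standard implementations it is cross-checked against.
* OLS models drop observations with |DFFITS| > 2√(k/n) in a single pass and
  refit; at clean Gaussian n≈100 this screen removes ~5–8% of rows — that is
  a property of the threshold, not of the data. Diagnostics (Jarque-Bera,
  White LM, White two-moment) below p = 0.05 attach a model-suitability
  warning, never a silent failure.
* The mixed model uses a random intercept per subject; the 2.5 × MAD
  residual filter operates on **marginal** residuals (observation minus the
  fixed-effects prediction). Filtering conditional residuals instead trims
  the core of the within-subject contrast distribution (2.5 × unscaled MAD
  ≈ 1.7 σ for Gaussian noise) and measurably inflates the task-term type-I
  error; with marginal residuals the filter removes outlying subjects
  roughly symmetrically across conditions and Wald inference stays near
  nominal (~7% at n = 51/51).
* The percent task effect divides the task coefficient by the intercept
  evaluated at the sample means of fGM and age — i.e. the fitted task-OFF
  reference-group mean. The raw intercept (fgm = age = 0) is an extrapolation
  whose noise dominates at small cohort sizes.
* Holm adjustment is the step-down maximum with monotonicity, capped at 1,
  applied within each analysis family (behavioural contrasts; the
  correlation battery).

## Cohort generator

`CohortConfig` states effects on the measured (i.u.) scale and derives truth
amplitudes through the documented unit constants. Defaults describe the
modelled study: 51 + 51 subjects age-matched within ±4 years, baseline Glx
15 i.u. with a −2.2 i.u. patient offset and 1 i.u. between-subject SD, a 6%
task-locked Glx increase in both groups, BOLD–Glx coupling −0.38 (controls)
/ +0.16 (patients) i.u. per fMRI-Z unit, patient PANSS and antipsychotic-dose
(DDD) distributions with a +0.147 i.u./DDD GABA+ slope, and weaker, more
variable BOLD in patients. The table always carries direct noisy readouts of
the metabolite truths (`measurement_noise_iu`, 0.3 i.u.) so the statistical
battery can be exercised without spectra; a pipeline run overwrites these
columns with spectroscopy-derived estimates. Behavioural performance uses a
right-skewed RT model (Gaussian + exponential tail, 60 ms congruency
penalty) with lower accuracy for incongruent trials and for patients.

What the generator does **not** emulate: coupled-spin (J-evolution) spectra,
eddy currents, coil combination, frequency-selective suppression profiles,
non-white noise, or realistic inter-regional covariate structure. Green
recovery tests therefore establish that the pipeline recovers the parameters
of *this* generative family at realistic SNR, not scanner fidelity.

## Numerical conventions and degenerate inputs

Half-open ppm and T_S-A intervals are lower-inclusive (bin edges at
[100, 183, 267, 350] ms, open at both ends). All-zero FIDs are marked
unusable and excluded from registration templates. MAD is unscaled (no
1.4826) everywhere. MADs at numerical-noise level (noiseless data) disable
the respective filter. Random streams derive from one root seed via
`SeedSequence`; per-subject integer seeds are drawn below 2^31. Identical
(config, seed) pairs reproduce schedules, FIDs, tables and manifests
bit-identically.
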