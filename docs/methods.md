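# Methods

## Scope and data model

The package estimates cardiac output (CO, L/min) and systemic vascular
resistance (SVR, dyn·s·cm⁻⁵) from finger photoplethysmogram (PPG) features
plus routine measurements. SVR is defined from mean arterial pressure (MAP,
mmHg), central venous pressure (CVP, mmHg) and CO as
`SVR = 80·(MAP − CVP)/CO`. Seven base features per subject — the normalized
low-frequency power LF_NU, normalized mid-frequency power MF_NU and LF/HF
ratio of the PPG variability spectrum, the normalized pulse width PW, heart
rate HR, MAP, and MAP/HR — are expanded with x², x³ and natural log to 28
indexed regressors (index = base index + 7 per transform block; logarithm
base configurable). Named feature pools restrict the search space: `all`,
`only_ppg` (drops HR/MAP-derived indices), `exclude_ppgv` (drops the
spectral indices), `only_linear` (1–7), and `only_pw` (7, 14, 21, 28 — the
pulse-width transform family, since the transformed widths compete as
single-feature models).

## PPG feature extraction

**Beat detection.** Peaks are picked on a 0.5–10 Hz band-passed (3rd-order
Butterworth, forward-backward) copy with `scipy.signal.find_peaks`, an
adaptive prominence threshold (25% of the 5–95 percentile spread) and a
0.3 s refractory period; fiducials are then refined on the raw waveform
(peak = local maximum, onset trough = minimum between consecutive peaks).
Beats with non-positive amplitude or out-of-range width are discarded and
counted. Two rejection rules guard degenerate input: a flat signal has no
peak candidates, and broadband noise is rejected when less than 25% of the
signal variance survives the cardiac band-pass (a pulsatile waveform keeps
essentially all of its variance there; white noise at 200 Hz keeps ~10%).
A simpler noise-floor comparison against the median successive difference
was rejected because refining peaks on the raw waveform inflates apparent
amplitudes of pure noise.

**Pulse width.** The width of one pulse at half its trough-to-peak
amplitude, with linear interpolation at the two half-amplitude crossings
(sub-sample accuracy), normalized by the beat's own peak-to-peak interval.
The width is invariant to gain and offset of the waveform. The per-subject
PW feature is the median over beats.

**Variability series and spectrum.** The default variability series is the
per-beat trough-to-peak amplitude at the peak times (a baseline series —
trough values at trough times — is also available). The irregular series is
cubic-spline interpolated onto a uniform 2 Hz grid (Nyquist 1 Hz > 0.45 Hz
upper band edge) and mean-removed. The PSD is a Welch estimate: 128 s Hann
segments, 50% overlap, per-segment linear detrend, giving < 0.01 Hz
resolution within a 10-minute recording — enough to separate the 0.04 Hz
band edge. With a rectangular window and no detrend the integrated density
matches the series variance (Parseval), which the tests verify.

**Band features.** Band powers are trapezoidal integrals over LF
(0.04–0.145 Hz), MF (0.08–0.145 Hz, a sub-band of LF) and HF
(0.145–0.45 Hz), with interpolated band edges so adjacent bands tile
exactly. Default normalization: `lf_nu = LF/(LF+HF)`, `mf_nu = MF/(LF+HF)`
(total-power normalization is available as an option); `lf_hf = LF/HF`,
undefined (error) when HF power is zero. Under the default convention
`lf_nu + HF/(LF+HF) = 1` exactly.

## Regression and stepwise selection

Weights solve the ones-augmented least-squares problem through the
Moore-Penrose pseudoinverse (minimum-norm solution; the residual is
orthogonal to the column space). Model error is MSE with denominator n.
The partial F-statistic for a one-feature change between nested models is
`(SSE_reduced − SSE_full)/(SSE_full/(n − p_full))` with `p_full` counting
all parameters of the larger model including the intercept, referred to
F(1, n − p_full).

Stepwise search starts from the intercept-only model. Entry: among
candidates significant at `alpha` (default 0.05, the 95% confidence level),
the largest F enters; ties break toward the lower feature index for
determinism. After every addition, removal is attempted repeatedly: the
selected feature with the smallest insignificant partial F (exit alpha =
entry alpha by default) leaves. The search stops when neither operation is
significant. Numerical guards: candidates producing a rank-deficient design
are skipped with a warning; a feature removed in a pruning pass may not
re-enter on the immediately following addition step; a hard cap of 50
iterations per pool feature bounds pathological cycling.

A property worth stating plainly: with ~27 null candidates each tested at
the 5% level, the probability that *no* spurious feature ever enters is
roughly 0.95^27 ≈ 0.25 for independent candidates (higher, ~0.5–0.7, for
the correlated transform blocks used here). Per-candidate-alpha stepwise
selection therefore frequently returns a small superset of a planted
feature set rather than the exact set; the planted feature itself is
essentially always found. The histogram consensus of the validation stage
exists precisely to stabilize this.

## Nested leave-one-out cross-validation

Outer loop: withhold one subject. Inner loop: over the remaining n−1
subjects, run stepwise selection n−1 times (each leaving one further
subject out), accumulating HIST1 (selection count per feature index) and
HIST2 (count per model size). Consensus: k = the mode of HIST2 (ties toward
the smaller size), features = the k most frequent in HIST1 (ties toward the
lower index); if fewer than k features were ever selected, all
ever-selected features are used. The consensus model is refit on the n−1
training subjects and predicts the withheld one. The withheld subject takes
no part in selection or training, so perturbing its target cannot change
its fold's model (tested). Subjects are processed in sorted `subject_id`
order, making results row-order invariant. Outputs: one held-out prediction
per subject, per-fold models, pooled histograms (summing to n·(n−1) inner
runs), and the held-out MSE.

## Agreement reporting

Differences are taken as estimated − measured (so an estimator that runs
low has negative bias); s.d. uses the n−1 denominator; precision is
1.96·s.d.; limits of agreement are bias ± precision; r is the Pearson
correlation of measured with the cross-validated estimates; percentage
error is 100·precision / mean of measured. Report rounding follows clinical
convention: CO to two decimals, SVR to the nearest integer, percentage
error to the nearest percent, all half-away-from-zero; a correlation with
zero-variance input is reported as undefined rather than raised, so a
perfect estimator still produces a report row.

## Synthetic data

**Waveforms.** A PPG recording is a periodic train of symmetric unimodal
pulses (Gaussian, triangular or rectangular; no dicrotic notch — notch
features are out of scope) at a configurable heart rate, with per-beat peak
amplitude modulated as `1 + Σ depth_k·sin(2π f_k t)`, sinusoidal baseline
wander, and additive white Gaussian noise. Defaults emulate the study
conditions: 600 s at 200 Hz, 84 bpm, normalized width 0.35, modulation
tones at 0.10 and 0.30 Hz, a 0.25 Hz (15 breaths/min) baseline component,
noise s.d. 0.005 relative to unit pulse amplitude. `pulse_width_frac` is a
*realized* target: for wide pulses the tails of neighbouring beats raise
the inter-beat trough and shrink the measured half-amplitude width below
the isolated-pulse closed form (e.g. a Gaussian sized by FWHM =
2√(2 ln 2)σ realizes ≈0.456 at a 0.5 target), so the shape parameter is
calibrated by root-finding on the rendered periodic train. Ghost beats are
rendered beyond both edges so edge pulses are not attenuated. Same seed and
configuration ⇒ bit-identical samples.

**Cohorts.** Base features are drawn independently per subject from
truncated normals (strictly positive; LF_NU capped at 0.95; the
(LF_NU, MF_NU) pair redrawn until MF_NU < LF_NU since MF is a sub-band).
Vitals use the study cohort moments — HR 84, MAP 78, CVP 14.5 (per-subject
s.d. = reported standard error × √48). The PPG feature moments are not
reported for the original cohort and are set to plausible values (LF_NU
0.55 ± 0.15, MF_NU 0.30 ± 0.10, PW 0.35 ± 0.08). By default LF/HF is
derived as `lf_nu/(1 − lf_nu)` — the identity that holds when both come
from one spectrum — keeping feature-level cohorts consistent with
signal-level simulation (an independent draw is available). The target is
`intercept + Σ w_j·φ_j + N(0, noise_sd²)` over the planted transformed
features; when the intercept is not given it is calibrated against a fixed
large reference draw so the expected target equals the cohort mean (5.7
L/min or 926 dyn·s·cm⁻⁵). Default planted models: CO on log(LF_NU) and
log(PW) with weights (−1.5, −2.2) and noise s.d. 1.2 L/min; SVR on
log(LF/HF) with weight 200 and noise s.d. 215 — sized so the planted signal
explains roughly a quarter of the target variance, matching the ~0.5
held-out correlations of the study setting. Rows violating positivity
(target ≤ 0, MAP ≤ CVP, or back-solved CO ≤ 0 when the target is SVR) are
redrawn. The SVR column is always stored as `80·(MAP − CVP)/CO` so the
identity holds bit-exactly whichever column was generated.

**What the generator does not emulate:** motion artifact, ectopic beats,
beat-to-beat timing jitter (off by default so spectral targets stay
analytic), ventilator interaction, dicrotic notches, and any real
covariance structure among the base features. Passing tests therefore
demonstrate correctness of the algorithms under known generative
conditions, not clinical performance on ICU recordings.

## Problem sizes and numerical choices

Test and acceptance runs are sized for a single CPU: full nested
leave-one-out at n = 48 appears once in the acceptance script per target
and once in the test suite; calibration and honesty sweeps use n = 16–24
cohorts over 3–20 seeds; the stepwise recovery sweep uses 100 cohorts at
n = 200; the F-test calibration uses 2000 replicates at n = 48. Monte-Carlo
tolerances follow the statistic's standard error (e.g. the type-I rate is
asserted within ±0.015 of 0.05 at 2000 replicates). Half-amplitude
crossings, band edges and intercept calibration are all interpolated or
root-found rather than snapped to grids; SSE comparisons use a relative
tolerance of 1e-9 to absorb pseudoinverse round-off.

## Known limitations

- The stepwise entry test is not multiplicity-corrected (by design — it
  mirrors the stated 95% confidence rule), so selected sets are frequently
  small supersets of the true support; consensus across folds mitigates
  but does not eliminate this.
- Published percentage-error cells are reproduced from the printed
  difference s.d. values; one printed cell (CO, linear-features-only, 55%)
  is a percentage point below the value its own printed s.d. implies
  (1.96·1.62/5.7 = 55.7%), an inconsistency of the source table's rounding
  that the reproduction reports as 56%.
- Beat detection is designed for clean synthetic morphology; it has no
  artifact repair and is not validated on pathological waveforms.
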