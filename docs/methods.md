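# Methods

## The audit in brief

A voxel timeseries y(t) is compared with the end-tidal CO2 regressor x(t)
via lagged Pearson correlation r(l) = corr(y(t), x(t - l)) over
l = -30..0 s in 0.5 s steps. The peak over lags gives rmax and the voxel
latency; the peak correlation is variance-stabilised as
zmax = atanh(rmax) * sqrt(N - 3) with N the number of overlapping samples
at the peak lag (overlap changes with the lag because correlations are
computed on trimmed overlap, never on zero-padded series). Negative lags
mean the fMRI signal *leads* the recorded CO2 trace; this is the expected
physiological regime because the gas analyser reports CO2 roughly 15 s
after it leaves the lungs (tube transit), while the brain's vascular
response follows arterial CO2 within a few seconds. Voxels whose peak sits
at a lag-range extreme are not local maxima and are excluded from all
summaries. Latency maps are normalised by subtracting the median latency
of valid grey-matter voxels, which removes the subject-specific transport
delay and leaves relative timing (e.g. the white-matter delay).

Per run the association is summarised as (i) the percentage of brain-mask
voxels with valid zmax above a threshold and (ii) mean rmax^2 (variance
explained, %) over valid voxels. Breath-hold analyses use the fixed
one-tailed threshold z = 3.09 (p = 0.001). Resting analyses use an
empirical threshold per contrast: phase-randomised surrogates of one
subject's regressor (Fourier magnitudes kept, phases uniform; DC and
Nyquist bins kept real, so mean and variance are preserved exactly) are
paired with voxels drawn from the other subjects' brains, the full
peak-over-lags-plus-Fisher-z statistic is computed for each pairing, and
the pooled distribution's 95th percentile is the threshold. Surrogate
thresholds are not built for breath-hold regressors: surrogates of a
task-locked series keep the task's spectral line and stay correlated with
the original, so the null would be invalid.

## Signal model of the synthetic generator

The generator emulates the acquisition the audit is designed for:

- CO2 recording. A breath is a smooth cycle rising from an inspiratory
  floor (2 mmHg) to the end-tidal value over the exhale half-period and
  falling back during inhalation, so each exhale ends in one unambiguous
  end-tidal peak. In breath-hold mode, breathing stops inside the four
  14 s hold windows, arterial CO2 ramps linearly to +8 mmHg over the hold
  (CO2 accumulates during apnoea) and washes out exponentially (tau =
  12 s) during recovery breathing; the cued post-hold exhale produces the
  elevated peak. In resting mode the end-tidal envelope is baseline
  (40 mmHg) plus a band-limited Gaussian process (SD 2 mmHg) whose power
  lies entirely below 0.05 Hz. The emitted trace is the mouth-side
  waveform delayed by a configurable gas-analyser transport time (default
  15 s), so recovered lags have a known truth.
- Vascular driver. The ground-truth driver is the detrended end-tidal
  envelope convolved with the canonical two-gamma HRF using a unit-area
  kernel, keeping mmHg units. A voxel with coupling gain a
  (fraction/mmHg) and vascular delay L sees a fractional signal change
  a * driver(t - L); sub-TR delays are realised by interpolating the
  50 Hz driver at the volume mid-times (k + 1/2) TR.
- BOLD runs: S = S0 (1 + a * driver(t - L)) + Gaussian noise.
- Diffusion runs: S(b,t) = S0 exp(-TE/T2(t)) exp(-b ADC(t)) with the
  schedule [0, 0, 200, 1000, 200, 1000, ...] s/mm2. The vascular
  modulation enters through the spin-echo amplitude exp(-TE/T2(t)),
  sampled once per interleaved pair at the pair midpoint so that it is a
  factor *common* to the two b-values of a pair — the premise of the
  T2-suppression mechanism. (Sampling it per volume instead would break
  the exact cancellation for any modulation faster than 2 TR; the pair
  midpoint is also the ADC timestamp, so the two conventions agree at the
  resolution the ADC series can represent.) A neural ADC response a(t),
  when supplied, modulates ADC(t) the same way, so the recovered ADC
  equals adc_baseline * (1 + a) exactly at pair resolution. An optional
  IVIM pseudo-diffusion compartment adds f * exp(-b D*) with f static.
- Noise is additive Gaussian on magnitude, not Rician: the SNR regimes of
  interest are high enough for the Gaussian approximation and it keeps
  variance oracles analytic.

## Default study conditions (the cohort)

Chosen once from the acquisition geometry and standard physiology, with
voxelwise spread so threshold crossings are graded rather than all-or-none:

| parameter | default | why |
| --- | --- | --- |
| grid / voxel | 20 x 20 x 10 at 2.8 mm | desk-scale stand-in for partial-brain coverage |
| S0, TE, T2 | 500, 105 ms, 80 ms | spin-echo EPI at 3 T with the long compensated-waveform TE |
| ADC baseline | 7.5e-4 mm2/s | brain-tissue ADC |
| breath-hold delta | 8 mmHg | typical end-tidal rise after a 14 s hold |
| transport delay | 15 s (+/- 1 s between subjects) | nasal-cannula gas-analyser transit |
| GM gain | 0.8 %/mmHg, Gamma(shape 3) across voxels | breath-hold BOLD responses of a few percent |
| WM gain | half of GM | weaker white-matter reactivity |
| diffusion T2 gain | 0.75 x the BOLD gain | spin echo is less susceptibility-sensitive than gradient echo |
| GM / WM latency | 2.0 / 4.5 s | white matter responds up to ~3 s later |
| noise SD | 25 (BOLD), 6 (diffusion) | image SNR 20 for BOLD; diffusion series land below that after T2 and diffusion attenuation |
| neural ADC response | 0 | breath-holding is a non-neuronal stimulus; ADC-regressor correlation should be pure leakage/chance |

With these conditions the expected ordering of respiratory association is
BOLD > b200 > b1000 > ADC: BOLD has the full signal level and twice the
samples of each diffusion sub-series; b200 and b1000 share the same
relative T2 modulation but the b1000 signal is ~2x smaller against the
same noise floor; the ADC ratio cancels the modulation entirely.

## pETCO2 processing choices

- All Butterworth filters are applied forward-backward (zero phase). A
  causal filter would add its group delay to every latency estimate.
- Operations run detrend-then-convolve; the HRF kernel is the Glover-type
  two-gamma form t^6 e^-t minus (1/6) t^16 e^-t (peak at 6 s, undershoot
  trough after 10 s), 32 s long, peak-normalised (scale is inert for
  correlation).
- Peak review is automatic: a peak is rejected when it falls below a
  3-peak moving median of peak heights by more than max(3 x 1.4826 x MAD,
  2 mmHg). The rule is deliberately one-sided and short-windowed: a
  partial exhale can only *under*-read pETCO2, post-breath-hold peaks are
  genuinely elevated and must survive, and slow resting envelope
  excursions span many breaths whereas erroneous breaths are isolated.
  The 2 mmHg floor is the scale of normal breath-to-breath variability.
  A symmetric variant (`side="both"`) and the window/floor remain
  parameters, and the provenance of every regressor records that the rule
  replaced manual review.
- The envelope is held constant beyond the first/last peak (no
  extrapolated trends at run edges), and envelope recovery is judged
  against the piecewise-linear interpolation of the true peak values:
  end-tidal CO2 is only observable at exhalations, so the continuous
  arterial curve (e.g. the unobserved apex of the hold ramp) is not the
  measurable truth.

## Numerical and procedural details

- Lag-map peak ties break toward the lag closest to the range midpoint
  (-15 s), minimising boundary bias; exact ties are the only case.
- ADC pairing uses only (b200 at t, b1000 at t + TR) pairs — no sliding
  pairs, which would correlate adjacent ADC samples — timestamped at the
  pair midpoint. Non-positive signal ratios are flagged (NaN + invalid
  mask) and excluded voxel-timepoint-wise from correlations, never
  clipped. All correlation code is NaN-aware.
- Fisher z uses the per-voxel overlap at the peak lag (a fixed-N variant
  is a flag); |r| is clipped 1e-15 away from 1 before atanh.
- Spatial smoothing uses a normalised discrete Gaussian
  (sigma = FWHM / 2.3548 / voxel) on the whole volume, then re-masks; the
  temporal high-pass re-adds the voxel mean so tSNR stays interpretable.
- Residual permutation in the noise-amplification control permutes whole
  volumes with one seeded permutation shared by all voxels, preserving
  the spatial noise covariance (an independent per-voxel permutation is
  available behind a flag).
- Surrogate-null voxels are drawn without replacement per
  (reference, donor) pair from the donor brain mask, and the pairing
  cycles surrogates through the pooled draw, giving one zmax per
  surrogate per reference subject; boundary-peak pairings are excluded
  exactly as in the voxelwise maps. The empirical threshold is the
  linearly interpolated order statistic.
- The CSF partial-volume estimator moves a CSF fraction delta into the
  tissue compartments proportionally to their fractions and evaluates the
  two-point ADC of the mixture signal sum_i f_i exp(-b D_i) before and
  after (defaults D_csf = 3.0e-3, D_gm = 0.8e-3, D_wm = 0.75e-3 mm2/s).
  The delta is absolute fraction points by default, with a relative
  interpretation behind a flag, since either reading of a reported CSF
  volume-fraction change is defensible.

## Problem sizes

End-to-end checks run the default 8-subject breath-hold cohort on a
20 x 20 x 10 grid with 192 volumes — 4,000 voxels is enough for stable
percent-significant medians while keeping a full cohort analysis under a
minute. Surrogate calibration uses 400-750 surrogates x voxels across 3-4
resting subjects; the false-positive tolerance widens by the binomial
confidence interval at the simulated sample count, reducing to the
nominal band as counts grow. The production defaults (5000 x 5000)
remain the configured values in `PipelineConfig`.

## What passing tests do and do not show

The generator produces exactly the physics the method assumes: a
multiplicative T2 modulation common to both b-values, linear coupling to
the HRF-convolved envelope, Gaussian noise, and a rigid timing chain. On
real data the cancellation can be degraded by cross-terms with
susceptibility-induced background gradients (mitigated at acquisition,
not modelled here), motion-correlated signal, Rician noise at low SNR,
partial-volume CSF dynamics, and imperfect interleave timing. Passing
tests therefore validate the analysis pipeline and its statistics, not
the acquisition physics. Also out of scope: k-space/EPI simulation,
multi-echo combination, external denoisers (the generator's truth
signal/residual split stands in for a denoised/residual pair),
registration, and group analysis in a standard space (the synthetic
cohort shares one grid).
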