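# adcfmri

Vascular-contamination audit for ADC-fMRI.

Apparent diffusion coefficient fMRI (ADC-fMRI) computes an ADC timeseries
from two interleaved diffusion weightings,

```
ADC(t) = -1/(b2 - b1) * ln( S(b2, t + dt) / S(b1, t) ),      b = 200, 1000 s/mm2
```

where each diffusion-weighted signal follows
`S(b,t) = S0 * exp(-TE/T2(t)) * exp(-b * ADC(t))`. Because the
T2/BOLD-weighting enters both b-values as a common multiplicative factor,
it cancels in the ratio — the contrast should therefore reflect
neuromorphological (microstructural) coupling rather than neurovascular
coupling. Whether that cancellation actually holds in practice is tested
here with a respiratory challenge: end-tidal CO2 (pETCO2) is a potent,
non-neuronal vasodilatory driver, so any residual correlation between
pETCO2 and an fMRI contrast measures its vascular contamination.

The package is for researchers working with diffusion-fMRI or
cerebrovascular-reactivity data. It implements the full audit as a
library plus CLI:

- **`synth`** — ground-truth-known generator: breath-hold (4 x
  [18 s rest, 14 s hold, 16 s rest]) and resting (14 min 40 s) CO2
  recordings with a gas-analyser transport delay, motion tables, and
  BOLD / interleaved-diffusion 4D runs with voxelwise coupling gains and
  latencies (longer in white matter), optional IVIM compartment, and
  additive thermal noise.
- **`physio`** — raw expired-CO2 trace to regressor: 1 Hz fourth-order
  zero-phase Butterworth low-pass, end-tidal peak detection with an
  automatic outlier rule, linear interpolation to the 50 Hz pETCO2
  envelope, cubic detrend, convolution with the canonical two-gamma HRF.
- **`contrast`** — interleaved-run splitting (b200/b1000 sub-series),
  the two-point ADC series with invalid-ratio flagging, and a
  three-compartment CSF partial-volume ADC-change estimator.
- **`conditioning`** — 4 mm FWHM spatial smoothing, 0.01 Hz high-pass,
  Power framewise displacement and motion QC (reject if max displacement
  > 1 voxel or mean FD > 0.2 mm), the noise-amplification control
  (volume-permuted residuals at 4x/8x/16x), image SNR and temporal SNR.
- **`lagmap`** — voxelwise Pearson correlation against the regressor over
  lags -30..0 s in 0.5 s steps, peak correlation and latency maps,
  Fisher `zmax = atanh(rmax) * sqrt(N - 3)`, exclusion of lag-boundary
  peaks, grey-matter-median latency normalisation, correlation profiles.
- **`surrogate`** — phase-randomisation surrogates (magnitudes preserved,
  phases uniform) and the leave-one-subject-out empirical null of zmax,
  giving contrast-specific one-tailed p < 0.05 thresholds; breath-hold
  analysis instead uses the fixed z = 3.09 (p = 0.001).
- **`stats`** — percent-significant and variance-explained summaries, map
  similarity (Fisher-z of voxelwise correlation) within/between subjects
  and across conditions, Mann-Whitney U contrast comparisons with
  Bonferroni correction.
- **`pipeline` / `cli`** — YAML-configured orchestration
  (`adcfmri simulate | physio | adc | condition | xcorr | null | stats | report`)
  with seeded, byte-reproducible outputs.

## Worked example

One synthetic breath-hold subject, audited across all four contrasts:

```python
import numpy as np
from adcfmri import conditioning, contrast, lagmap, physio, stats, synth

# one synthetic breath-hold subject (4 epochs of 18 s rest / 14 s hold / 16 s rest)
subject = synth.make_subject("sub-01", synth.CohortParams(grid=(20, 20, 10)), seed=11)

# expired CO2 -> detrended, HRF-convolved pETCO2 regressor at 50 Hz
regressor = physio.process_co2(subject.co2_trace)

# the four analysis series from the two acquired runs
bold = conditioning.condition_run(subject.runs["BOLD"])
b200, b1000 = (conditioning.condition_run(r)
               for r in contrast.split_dfmri(subject.runs["dfMRI"]))
adc = conditioning.condition_run(
    contrast.compute_adc_series(subject.runs["dfMRI"]).as_run(subject.runs["dfMRI"]))

zthr = stats.breathhold_zthresh()          # 3.09  (p = 0.001, one-tailed)
for name, run in [("BOLD", bold), ("b200", b200), ("b1000", b1000), ("ADC", adc)]:
    xmap = lagmap.xcorr_map(run, regressor, mask=subject.masks["brain"])
    pct = stats.percent_significant(xmap, subject.masks["brain"], zthr)
    r2 = stats.mean_variance_explained(xmap)
    print(f"{name:>5}: {pct:5.1f}% voxels with zmax > {zthr:.2f}, "
          f"mean variance explained {r2:5.1f}%")

xmap = lagmap.xcorr_map(bold, regressor, mask=subject.masks["brain"])
norm, shift = lagmap.normalize_latency(xmap, subject.masks["GM"])
wm = np.median(norm.latency_s[subject.masks["WM"] & norm.valid])
print(f"GM median latency shift {shift:+.1f} s; WM lags GM by {wm:+.1f} s")
```

Output:

```
 BOLD:  99.0% voxels with zmax > 3.09, mean variance explained  38.1%
 b200:  84.5% voxels with zmax > 3.09, mean variance explained  27.2%
b1000:  50.8% voxels with zmax > 3.09, mean variance explained  13.2%
  ADC:   1.1% voxels with zmax > 3.09, mean variance explained   2.5%
GM median latency shift -12.5 s; WM lags GM by +2.5 s
```

Reading the numbers: BOLD is saturated with respiratory signal; the two
raw diffusion series retain a weaker but clear vascular association
(shared T2-weighting, attenuated at the higher b-value by its lower
signal level); the ADC series is at the false-positive floor — the ratio
cancelled the vascular modulation. The grey-matter median latency shift
(-12.5 s) absorbs the gas-analyser transport delay, and white matter
responds 2.5 s after grey matter, matching the generator's truth.

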