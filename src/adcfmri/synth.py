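"""Ground-truth-known synthetic physiology and fMRI runs.

Everything downstream of acquisition is testable without any download: the
generator emulates (i) the breath-hold paradigm (4 epochs of 18 s rest,
14 s hold, 16 s rest), (ii) resting breathing whose end-tidal envelope has
power confined below 0.05 Hz, (iii) vascular coupling with a longer delay
in white matter than grey matter, and (iv) interleaved diffusion-weighted
signals

    S(b, t) = S0 * exp(-TE / T2(t)) * exp(-b * ADC(t)),

with an optional IVIM pseudo-diffusion compartment and additive Gaussian
thermal noise. T2(t) carries the vascular (BOLD-like) modulation, so the
two b-value series share a multiplicative factor that cancels exactly in
the two-point ADC -- the mechanism under audit.

The recorded CO2 trace is the mouth-side waveform delayed by a
configurable gas-analyser transport delay (default 15 s), so recovered
latencies have a known truth: the correlation peak for a voxel with
vascular delay L sits at lag L - transport_delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contrast import FmriRun
from .errors import ParameterError
from .physio import REGRESSOR_FS_HZ, RawCO2Trace, hrf_kernel, polynomial_detrend

DEFAULT_TIMINGS_S = (18.0, 14.0, 16.0)
DEFAULT_TRANSPORT_DELAY_S = 15.0
RESTING_DURATION_S = 880.0  # 14 min 40 s
RESTING_ENVELOPE_CUTOFF_HZ = 0.04  # keeps all envelope power below 0.05 Hz


@dataclass(frozen=True)
class BreathHoldParadigm:
    """Timing of the cued breath-hold task.

    The baseline period contains the trailing cued 2 s inhale + 2 s exhale;
    the recovery period contains the leading cued 2 s exhale.
    """

    n_epochs: int
    baseline_s: float
    hold_s: float
    recovery_s: float

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ParameterError("n_epochs must be >= 1")
        for name in ("baseline_s", "hold_s", "recovery_s"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")

    @property
    def epoch_duration_s(self) -> float:
        return self.baseline_s + self.hold_s + self.recovery_s

    @property
    def run_duration_s(self) -> float:
        return self.n_epochs * self.epoch_duration_s

    def hold_windows(self) -> list[tuple[float, float]]:
        """[(start, end)] of each breath-hold, in scan time."""
        return [
            (
                k * self.epoch_duration_s + self.baseline_s,
                k * self.epoch_duration_s + self.baseline_s + self.hold_s,
            )
            for k in range(self.n_epochs)
        ]

    def hold_indicator(self, fs_hz: float) -> tuple[np.ndarray, np.ndarray]:
        """Boxcar hold indicator sampled at ``fs_hz`` over the run."""
        n = int(round(self.run_duration_s * fs_hz))
        t = np.arange(n) / fs_hz
        box = np.zeros(n)
        for start, end in self.hold_windows():
            box[(t >= start) & (t < end)] = 1.0
        return t, box


@dataclass(frozen=True)
class RestingParadigm:
    """Free-breathing run of a given duration (default 14 min 40 s)."""

    duration_s: float = RESTING_DURATION_S

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ParameterError("duration must be positive")

    @property
    def run_duration_s(self) -> float:
        return self.duration_s


def generate_breathhold_paradigm(
    n_epochs: int = 4, timings_s: tuple[float, float, float] = DEFAULT_TIMINGS_S
) -> BreathHoldParadigm:
    """Breath-hold paradigm from epoch count and (baseline, hold, recovery)."""
    baseline, hold, recovery = timings_s
    return BreathHoldParadigm(n_epochs, baseline, hold, recovery)


@dataclass
class CO2Truth:
    """Ground truth accompanying a generated CO2 trace.

    Times are mouth-side (scan-anchored): the emitted raw trace is this
    physiology delayed by ``transport_delay_s``.
    """

    envelope_times_s: np.ndarray
    envelope_mmHg: np.ndarray
    peak_times_s: np.ndarray
    peak_values_mmHg: np.ndarray
    baseline_mmHg: float
    transport_delay_s: float
    hold_windows_s: list


def _resting_envelope(n: int, fs_hz: float, sd_mmHg: float, cutoff_hz: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Zero-mean band-limited (< cutoff) Gaussian fluctuation."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    spec[freqs >= cutoff_hz] = 0.0
    spec[0] = 0.0
    fluct = np.fft.irfft(spec, n)
    sd = fluct.std()
    if sd > 0:
        fluct *= sd_mmHg / sd
    return fluct


def generate_co2_trace(
    spec: BreathHoldParadigm | RestingParadigm,
    breath_period_s: float = 4.0,
    petco2_baseline_mmHg: float = 40.0,
    hold_delta_mmHg: float = 8.0,
    fs_hz: float = 100.0,
    seed: int | None = None,
    resting_sd_mmHg: float = 2.0,
    transport_delay_s: float = DEFAULT_TRANSPORT_DELAY_S,
    pre_s: float = 20.0,
    post_s: float = 40.0,
    recovery_tau_s: float = 12.0,
    inspiratory_floor_mmHg: float = 2.0,
) -> tuple[RawCO2Trace, CO2Truth]:
    """Simulate an expired-CO2 recording with known end-tidal truth.

    Breath-hold mode: the end-tidal envelope is the baseline plus, after
    each hold, a ``hold_delta_mmHg`` step decaying with ``recovery_tau_s``;
    no exhalation peaks occur inside hold windows and the first post-hold
    peak (the cued exhale) is elevated by the hold delta. Resting mode: the
    envelope is a band-limited random process with all power below 0.05 Hz.

    The breath waveform is a piecewise cycle rising smoothly from the
    inspiratory floor to the end-tidal value over the exhale half-period,
    then falling back over the inhale half-period, giving one unambiguous
    end-tidal peak per exhale.
    """
    if fs_hz < 10:
        raise ParameterError("CO2 sampling rate must be >= 10 Hz")
    if not 2.0 <= breath_period_s <= 10.0:
        raise ParameterError("breath period must be within [2, 10] s")
    run_s = spec.run_duration_s
    holds: list[tuple[float, float]] = []
    if isinstance(spec, BreathHoldParadigm):
        if spec.hold_s > run_s:
            raise ParameterError("hold duration exceeds the run duration")
        holds = spec.hold_windows()

    rng = np.random.default_rng(seed)
    t0 = -pre_s - transport_delay_s  # mouth time of the first emitted sample
    t1 = run_s + post_s - transport_delay_s
    n = int(round((t1 - t0) * fs_hz)) + 1
    t = t0 + np.arange(n) / fs_hz

    # ground-truth end-tidal envelope on a 50 Hz mouth-time grid
    n_env = int(round((t1 - t0) * REGRESSOR_FS_HZ)) + 1
    env_t = t0 + np.arange(n_env) / REGRESSOR_FS_HZ
    if holds:
        # arterial CO2 accumulates during apnoea: linear ramp to +delta over
        # the hold, exponential washout during recovery breathing
        env = np.full(n_env, petco2_baseline_mmHg)
        for h_start, h_end in holds:
            ramp = (env_t >= h_start) & (env_t < h_end)
            env[ramp] += hold_delta_mmHg * (env_t[ramp] - h_start) / (h_end - h_start)
            after = env_t >= h_end
            env[after] += hold_delta_mmHg * np.exp(-(env_t[after] - h_end) / recovery_tau_s)
    else:
        env = petco2_baseline_mmHg + _resting_envelope(
            n_env, REGRESSOR_FS_HZ, resting_sd_mmHg, RESTING_ENVELOPE_CUTOFF_HZ, rng
        )

    # breath cycle schedule: regular breathing, suspended during holds, with
    # the cued exhale starting exactly at each hold end
    exhale_s = breath_period_s / 2.0
    cycle_starts = []
    c = t0
    while c + breath_period_s <= t1:
        blocking = next(
            (h for h in holds if c < h[1] and c + breath_period_s > h[0]), None
        )
        if blocking is not None:
            c = blocking[1]
            continue
        cycle_starts.append(c)
        c += breath_period_s

    w = np.full(n, inspiratory_floor_mmHg)
    peak_times = []
    peak_values = []
    for cs in cycle_starts:
        pk_t = cs + exhale_s
        pk_v = float(np.interp(pk_t, env_t, env))
        peak_times.append(pk_t)
        peak_values.append(pk_v)
        i0 = int(np.ceil((cs - t0) * fs_hz))
        i1 = min(int(np.floor((cs + breath_period_s - t0) * fs_hz)), n - 1)
        tau = t[i0 : i1 + 1] - cs
        shape = np.where(
            tau < exhale_s,
            0.5 - 0.5 * np.cos(np.pi * tau / exhale_s),
            0.5 + 0.5 * np.cos(np.pi * (tau - exhale_s) / (breath_period_s - exhale_s)),
        )
        w[i0 : i1 + 1] = inspiratory_floor_mmHg + (pk_v - inspiratory_floor_mmHg) * shape

    trace = RawCO2Trace(w, fs_hz, start_offset_s=t0 + transport_delay_s)
    truth = CO2Truth(
        envelope_times_s=env_t,
        envelope_mmHg=env,
        peak_times_s=np.asarray(peak_times),
        peak_values_mmHg=np.asarray(peak_values),
        baseline_mmHg=petco2_baseline_mmHg,
        transport_delay_s=transport_delay_s,
        hold_windows_s=holds,
    )
    return trace, truth


@dataclass
class VascularDriver:
    """Detrended, HRF-convolved end-tidal truth on a 50 Hz mouth-time grid.

    Units are mmHg (the HRF kernel is unit-area normalised, so a slow
    1 mmHg envelope change drives a 1 mmHg driver change); a voxel with
    coupling gain a (fraction/mmHg) and delay L sees a fractional signal
    change a * driver(t - L).
    """

    times_s: np.ndarray
    values_mmHg: np.ndarray

    def delayed(self, times_s: np.ndarray, delay_s: float) -> np.ndarray:
        return np.interp(times_s - delay_s, self.times_s, self.values_mmHg)


def vascular_driver(truth: CO2Truth, detrend_order: int = 3) -> VascularDriver:
    """Build the ground-truth vascular driver from the CO2 envelope truth."""
    kernel = hrf_kernel(dt_s=1.0 / REGRESSOR_FS_HZ, normalize="area") / REGRESSOR_FS_HZ
    detrended = polynomial_detrend(truth.envelope_mmHg, detrend_order)
    values = np.convolve(detrended, kernel)[: truth.envelope_mmHg.size]
    return VascularDriver(times_s=truth.envelope_times_s, values_mmHg=values)


@dataclass
class GroundTruth:
    """Per-voxel coupling truth and signal-model constants for one run.

    vascular_amplitude : fractional signal change per mmHg of driver, per voxel.
    latency_field : vascular delay in seconds, per voxel (>= 0).
    neural_adc_response : optional fractional ADC change, broadcastable to
        (*grid, n_volumes); None means a flat ADC.
    """

    vascular_amplitude: np.ndarray
    latency_field: np.ndarray
    noise_sigma: float = 25.0
    S0: float = 500.0
    TE_s: float = 0.105
    T2_baseline_s: float = 0.080
    adc_baseline: float = 7.5e-4
    ivim_fraction: float = 0.0
    ivim_dstar: float = 10e-3
    neural_adc_response: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vascular_amplitude = np.asarray(self.vascular_amplitude, dtype=float)
        self.latency_field = np.asarray(self.latency_field, dtype=float)
        if np.any(self.latency_field < 0):
            raise ParameterError("latency_field must be non-negative")
        if not 0.0 <= self.ivim_fraction < 1.0:
            raise ParameterError("ivim_fraction must be in [0, 1)")
        if self.adc_baseline <= 0:
            raise ParameterError("adc_baseline must be positive")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be non-negative")


def make_b_schedule(n_vols: int, b_low: float = 200.0, b_high: float = 1000.0,
                    n_b0: int = 2) -> np.ndarray:
    """Acquisition order: ``n_b0`` b = 0 volumes, then alternating low/high."""
    if n_vols <= n_b0:
        raise ParameterError("schedule needs more volumes than the b = 0 lead-in")
    b = np.empty(n_vols)
    b[:n_b0] = 0.0
    b[n_b0::2] = b_low
    b[n_b0 + 1 :: 2] = b_high
    return b


def _delayed_driver_matrix(
    truth: GroundTruth, driver: VascularDriver, times_s: np.ndarray
) -> np.ndarray:
    """(*grid, n_t) driver values delayed by the per-voxel latency field."""
    lat = truth.latency_field
    uniq, inv = np.unique(lat, return_inverse=True)
    table = np.stack([driver.delayed(times_s, d) for d in uniq])  # (n_uniq, n_t)
    return table[inv.reshape(lat.shape)]


def generate_fmri_run(
    contrast: str,
    truth: GroundTruth,
    driver: VascularDriver,
    TR_s: float,
    n_vols: int,
    seed: int | None = None,
    b_schedule: np.ndarray | None = None,
    masks: dict | None = None,
    voxel_size_mm: float = 2.8,
) -> FmriRun:
    """Simulate a BOLD or interleaved diffusion run from the ground truth.

    Volume sample times are the acquisition mid-times (k + 1/2) TR;
    sub-TR latencies are realised by interpolating the 50 Hz driver.
    BOLD: S = S0 (1 + a * driver(t - L)) + noise. Diffusion: the vascular
    modulation enters through the spin-echo amplitude exp(-TE/T2(t)) as a
    factor common to every b-value, the neural response through ADC(t), and
    perfusion through a static IVIM compartment.
    """
    if contrast not in ("BOLD", "dfMRI"):
        raise ParameterError("contrast must be 'BOLD' or 'dfMRI'")
    grid = truth.vascular_amplitude.shape
    if truth.latency_field.shape != grid:
        raise ParameterError("latency_field and vascular_amplitude grids differ")
    rng = np.random.default_rng(seed)
    times = (np.arange(n_vols) + 0.5) * TR_s

    if contrast == "BOLD":
        if b_schedule is not None:
            raise ParameterError("a BOLD run takes no b-value schedule")
        D = _delayed_driver_matrix(truth, driver, times)  # (*grid, n_t)
        amp = truth.vascular_amplitude[..., None]
        signal = truth.S0 * (1.0 + amp * D)
        b = None
    else:
        if b_schedule is None:
            b_schedule = make_b_schedule(n_vols)
        b = np.asarray(b_schedule, dtype=float)
        if b.shape != (n_vols,):
            raise ParameterError("b_schedule length must equal n_vols")
        # the T2 (vascular) modulation varies on haemodynamic timescales, so
        # it is sampled once per interleaved pair -- at the pair midpoint,
        # which is also the ADC timestamp -- and is therefore a factor
        # common to the two b-values of a pair (the T2-suppression premise)
        driver_times = times.copy()
        n_lead = 0
        while n_lead < n_vols and b[n_lead] == 0:
            n_lead += 1
        pair_of = n_lead + 2 * ((np.arange(n_lead, n_vols) - n_lead) // 2)
        mid = 0.5 * (times[pair_of] + times[np.minimum(pair_of + 1, n_vols - 1)])
        driver_times[n_lead:] = mid
        D = _delayed_driver_matrix(truth, driver, driver_times)
        amp = truth.vascular_amplitude[..., None]
        modulation = 1.0 + amp * D
        adc = truth.adc_baseline
        if truth.neural_adc_response is not None:
            a_t = np.broadcast_to(np.asarray(truth.neural_adc_response, dtype=float),
                                  grid + (n_vols,))
            # like the T2 factor, the neural response is held constant within
            # a pair (value at the pair's lead volume), so the two-point ADC
            # recovers adc_baseline * (1 + a) exactly at pair resolution
            pair_sample = np.arange(n_vols)
            pair_sample[n_lead:] = pair_of
            adc_t = adc * (1.0 + a_t[..., pair_sample])
        else:
            adc_t = np.broadcast_to(np.full(grid + (1,), adc), grid + (n_vols,))
        spin_echo = np.exp(-truth.TE_s / truth.T2_baseline_s) * modulation
        f = truth.ivim_fraction
        attenuation = (1.0 - f) * np.exp(-b * adc_t) + f * np.exp(-b * truth.ivim_dstar)
        signal = truth.S0 * spin_echo * attenuation

    if truth.noise_sigma > 0:
        signal = signal + rng.normal(0.0, truth.noise_sigma, size=signal.shape)
    return FmriRun(
        data=signal,
        TR_s=TR_s,
        contrast=contrast,
        volume_times_s=times,
        b_schedule=b,
        masks={} if masks is None else masks,
        voxel_size_mm=voxel_size_mm,
    )


def jitter_for_mean_fd(target_fd_mm: float) -> float:
    """Translation-jitter SD giving a target mean FD.

    For iid zero-mean Gaussian jitter of SD s on the three translations,
    E|diff| per axis = 2 s / sqrt(pi), so mean FD = 6 s / sqrt(pi).
    """
    return target_fd_mm * np.sqrt(np.pi) / 6.0


def generate_motion(
    n_vols: int,
    drift_mm: float = 0.0,
    jitter_mm: float = 0.0,
    spikes: list[tuple[int, float]] | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Seeded (n_vols, 6) motion table: linear drift + white jitter + spikes.

    Drift accrues linearly on the x translation over the run; jitter is iid
    Gaussian on the three translations; each spike (volume, amplitude_mm)
    adds a one-volume x-translation excursion. Rotations stay zero.
    """
    if n_vols < 2:
        raise ParameterError("need at least 2 volumes")
    rng = np.random.default_rng(seed)
    motion = np.zeros((n_vols, 6))
    motion[:, 0] += np.linspace(0.0, drift_mm, n_vols)
    if jitter_mm > 0:
        motion[:, :3] += rng.normal(0.0, jitter_mm, size=(n_vols, 3))
    for vol, amp in spikes or []:
        motion[vol, 0] += amp
    return motion


# ---------------------------------------------------------------------------
# Default synthetic cohort: the study conditions used for end-to-end checks.
# ---------------------------------------------------------------------------

@dataclass
class CohortParams:
    """Study conditions for the default synthetic cohort.

    Gains are fractional signal change per mmHg of HRF-convolved pETCO2.
    The spin-echo (diffusion) T2 coupling is weaker than the gradient-echo
    (BOLD) coupling; white matter couples at half the grey-matter gain and
    responds 2.5 s later. The neural ADC response is zero: breath-holding
    is a non-neuronal stimulus, so any ADC-regressor correlation in the
    cohort is vascular leakage or chance.
    """

    n_subjects: int = 8
    grid: tuple[int, int, int] = (20, 20, 10)
    voxel_size_mm: float = 2.8
    condition: str = "breathhold"  # or "resting"
    n_epochs: int = 4
    timings_s: tuple[float, float, float] = DEFAULT_TIMINGS_S
    resting_duration_s: float = RESTING_DURATION_S
    TR_bold_s: float = 1.0
    TR_dfmri_s: float = 1.0
    TR_bold_resting_s: float = 1.1
    TR_dfmri_resting_s: float = 1.1
    S0: float = 500.0
    TE_s: float = 0.105
    T2_baseline_s: float = 0.080
    adc_baseline: float = 7.5e-4
    ivim_fraction: float = 0.0
    ivim_dstar: float = 10e-3
    noise_sigma_bold: float = 25.0
    noise_sigma_dfmri: float = 6.0
    gm_gain_per_mmHg: float = 0.008
    wm_gain_per_mmHg: float = 0.004
    gain_gamma_shape: float = 3.0
    spin_echo_gain_ratio: float = 0.75
    gm_latency_s: float = 2.0
    wm_latency_s: float = 4.5
    hold_delta_mmHg: float = 8.0
    petco2_baseline_mmHg: float = 40.0
    resting_sd_mmHg: float = 2.0
    transport_delay_s: float = DEFAULT_TRANSPORT_DELAY_S
    transport_delay_jitter_s: float = 1.0
    breath_period_s: float = 4.0
    breath_period_jitter_s: float = 0.6


@dataclass
class Subject:
    """One synthetic subject: CO2 recording + one BOLD and one dfMRI run."""

    subject_id: str
    co2_trace: RawCO2Trace
    co2_truth: CO2Truth
    driver: VascularDriver
    runs: dict  # contrast -> FmriRun ('BOLD', 'dfMRI')
    truths: dict  # contrast -> GroundTruth
    masks: dict
    transport_delay_s: float


def default_masks(grid: tuple[int, int, int]) -> dict:
    """Brain covers the grid; GM is the anterior half, WM the posterior."""
    brain = np.ones(grid, dtype=bool)
    gm = np.zeros(grid, dtype=bool)
    gm[:, : grid[1] // 2, :] = True
    wm = brain & ~gm
    return {"brain": brain, "GM": gm, "WM": wm}


def make_subject(
    subject_id: str,
    params: CohortParams,
    seed: int,
    contrasts: tuple[str, ...] = ("BOLD", "dfMRI"),
) -> Subject:
    """Generate one subject under the cohort study conditions."""
    rng = np.random.default_rng(seed)
    masks = default_masks(params.grid)
    delay = params.transport_delay_s + rng.uniform(
        -params.transport_delay_jitter_s, params.transport_delay_jitter_s
    )
    period = float(
        np.clip(
            params.breath_period_s
            + rng.uniform(-params.breath_period_jitter_s, params.breath_period_jitter_s),
            2.0,
            10.0,
        )
    )
    baseline = params.petco2_baseline_mmHg + rng.normal(0.0, 2.0)
    if params.condition == "breathhold":
        paradigm: BreathHoldParadigm | RestingParadigm = generate_breathhold_paradigm(
            params.n_epochs, params.timings_s
        )
        TR_bold, TR_dfmri = params.TR_bold_s, params.TR_dfmri_s
    elif params.condition == "resting":
        paradigm = RestingParadigm(params.resting_duration_s)
        TR_bold, TR_dfmri = params.TR_bold_resting_s, params.TR_dfmri_resting_s
    else:
        raise ParameterError(f"unknown condition {params.condition!r}")
    trace, truth = generate_co2_trace(
        paradigm,
        breath_period_s=period,
        petco2_baseline_mmHg=baseline,
        hold_delta_mmHg=params.hold_delta_mmHg,
        seed=int(rng.integers(2**31)),
        resting_sd_mmHg=params.resting_sd_mmHg,
        transport_delay_s=delay,
    )
    driver = vascular_driver(truth)

    gain = np.where(masks["GM"], params.gm_gain_per_mmHg, params.wm_gain_per_mmHg)
    shape = params.gain_gamma_shape
    amp = rng.gamma(shape, gain / shape)
    latency = np.where(masks["GM"], params.gm_latency_s, params.wm_latency_s)

    runs: dict = {}
    truths: dict = {}
    run_duration = paradigm.run_duration_s
    if "BOLD" in contrasts:
        gt = GroundTruth(
            vascular_amplitude=amp,
            latency_field=latency,
            noise_sigma=params.noise_sigma_bold,
            S0=params.S0,
            TE_s=params.TE_s,
            T2_baseline_s=params.T2_baseline_s,
            adc_baseline=params.adc_baseline,
        )
        n_vols = int(round(run_duration / TR_bold))
        runs["BOLD"] = generate_fmri_run(
            "BOLD", gt, driver, TR_bold, n_vols,
            seed=int(rng.integers(2**31)), masks=masks,
            voxel_size_mm=params.voxel_size_mm,
        )
        truths["BOLD"] = gt
    if "dfMRI" in contrasts:
        gt = GroundTruth(
            vascular_amplitude=params.spin_echo_gain_ratio * amp,
            latency_field=latency,
            noise_sigma=params.noise_sigma_dfmri,
            S0=params.S0,
            TE_s=params.TE_s,
            T2_baseline_s=params.T2_baseline_s,
            adc_baseline=params.adc_baseline,
            ivim_fraction=params.ivim_fraction,
            ivim_dstar=params.ivim_dstar,
        )
        n_vols = int(round(run_duration / TR_dfmri))
        if (n_vols - 2) % 2:
            n_vols -= 1
        runs["dfMRI"] = generate_fmri_run(
            "dfMRI", gt, driver, TR_dfmri, n_vols,
            seed=int(rng.integers(2**31)), masks=masks,
            voxel_size_mm=params.voxel_size_mm,
        )
        truths["dfMRI"] = gt
    return Subject(
        subject_id=subject_id,
        co2_trace=trace,
        co2_truth=truth,
        driver=driver,
        runs=runs,
        truths=truths,
        masks=masks,
        transport_delay_s=delay,
    )


def make_cohort(params: CohortParams | None = None, seed: int = 0,
                contrasts: tuple[str, ...] = ("BOLD", "dfMRI")) -> list[Subject]:
    """Seeded cohort of subjects under identical study conditions."""
    if params is None:
        params = CohortParams()
    if params.n_subjects < 1:
        raise ParameterError("cohort needs at least one subject")
    root = np.random.default_rng(seed)
    subject_seeds = root.integers(2**31, size=params.n_subjects)
    return [
        make_subject(f"sub-{i + 1:02d}", params, int(s), contrasts)
        for i, s in enumerate(subject_seeds)
    ]
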