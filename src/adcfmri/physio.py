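"""End-tidal CO2 (pETCO2) regressor construction.

The expired-CO2 pressure trace recorded by a gas analyser is converted into
the regressor used for all fMRI correlations in four steps: zero-phase
low-pass filtering at 1 Hz, end-tidal (exhalation) peak detection with an
automatic outlier rule, linear interpolation between peaks to form the
pETCO2 envelope resampled to 50 Hz, and cubic detrending followed by causal
convolution with the canonical two-gamma haemodynamic response function
(HRF).

All filtering is forward-backward (zero phase): this pipeline measures
latencies, so filters must not themselves introduce lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import DataError, ParameterError

#: Common sampling rate of every pETCO2 envelope and regressor (Hz).
REGRESSOR_FS_HZ = 50.0


@dataclass
class RawCO2Trace:
    """Uniformly sampled expired-CO2 pressure.

    Parameters
    ----------
    values : ndarray
        CO2 partial pressure in mmHg.
    fs_hz : float
        Sampling rate in Hz.
    start_offset_s : float
        Time of the first sample relative to the first fMRI volume
        (scan-trigger anchored). Negative when recording starts before
        the scan, as is standard practice.
    """

    values: np.ndarray
    fs_hz: float
    start_offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs_hz <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs_hz}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ParameterError("CO2 trace must be a 1-D array with >= 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("CO2 trace contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def time_s(self) -> np.ndarray:
        return self.start_offset_s + np.arange(self.n) / self.fs_hz

    @property
    def duration_s(self) -> float:
        return (self.n - 1) / self.fs_hz


@dataclass
class PetCO2Regressor:
    """Detrended, HRF-convolved end-tidal envelope at 50 Hz, zero-mean.

    ``sample`` linearly interpolates the regressor at arbitrary times and
    reports which of those times fall inside the recorded support, which is
    how the lag-mapping stage trims its per-lag overlap.
    """

    values: np.ndarray
    start_offset_s: float
    peak_times_s: np.ndarray = field(default_factory=lambda: np.array([]))
    fs_hz: float = REGRESSOR_FS_HZ
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.peak_times_s = np.asarray(self.peak_times_s, dtype=float)
        if self.fs_hz != REGRESSOR_FS_HZ:
            raise ParameterError(f"regressor sampling rate is fixed at {REGRESSOR_FS_HZ} Hz")
        if self.peak_times_s.size > 1 and not np.all(np.diff(self.peak_times_s) > 0):
            raise ParameterError("peak times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def time_s(self) -> np.ndarray:
        return self.start_offset_s + np.arange(self.n) / self.fs_hz

    def sample(self, times_s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Interpolate at ``times_s``; also return an in-support mask."""
        times_s = np.asarray(times_s, dtype=float)
        t0 = self.start_offset_s
        t1 = self.start_offset_s + (self.n - 1) / self.fs_hz
        inside = (times_s >= t0) & (times_s <= t1)
        vals = np.interp(times_s, self.time_s, self.values)
        return vals, inside


def lowpass_co2(trace: RawCO2Trace, cutoff_hz: float = 1.0, order: int = 4) -> RawCO2Trace:
    """Zero-phase Butterworth low-pass of the raw CO2 trace (default 1 Hz, order 4)."""
    if cutoff_hz <= 0:
        raise ParameterError("cutoff must be positive")
    if cutoff_hz >= trace.fs_hz / 2:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz is at or above Nyquist ({trace.fs_hz / 2} Hz)"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=trace.fs_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, trace.values)
    return RawCO2Trace(filtered, trace.fs_hz, trace.start_offset_s)


def detect_end_tidal_peaks(
    trace: RawCO2Trace,
    min_interval_s: float = 2.0,
    prominence_mmHg: float | None = None,
    outlier_mad_k: float = 3.0,
    min_deviation_mmHg: float = 2.0,
    side: str = "low",
    window: int = 3,
) -> np.ndarray:
    """Locate end-tidal peaks and reject outliers against a moving median.

    One peak per accepted exhalation. The default prominence is 10% of the
    trace interquartile range. The outlier rule replaces the manual review
    step of a human operator: peak heights deviating more than
    ``outlier_mad_k`` robust standard deviations (1.4826 x MAD of the
    residuals, floored at ``min_deviation_mmHg``) from a ``window``-peak
    moving median are dropped. The short default window targets isolated
    erroneous breaths without flagging genuine slow envelope excursions,
    and by default only *low* outliers are rejected (``side='low'``): a
    partial exhale can only underestimate pETCO2, whereas genuinely
    elevated peaks (post-breath-hold recovery) must be kept. ``side='both'``
    gives a symmetric rule.

    Returns the retained peak sample indices (into ``trace.values``).
    """
    if min_interval_s <= 0:
        raise ParameterError("min_interval_s must be positive")
    if side not in ("low", "both"):
        raise ParameterError("side must be 'low' or 'both'")
    x = trace.values
    if prominence_mmHg is None:
        q75, q25 = np.percentile(x, [75, 25])
        prominence_mmHg = 0.1 * (q75 - q25)
    distance = max(1, int(round(min_interval_s * trace.fs_hz)))
    idx, _ = signal.find_peaks(x, distance=distance, prominence=prominence_mmHg)
    if idx.size == 0:
        raise DataError(
            "no end-tidal peaks found: check that the trace contains exhalations "
            f"(prominence threshold {prominence_mmHg:.3g} mmHg, "
            f"min interval {min_interval_s} s)"
        )
    heights = x[idx]
    moving_median = (
        pd.Series(heights).rolling(window=window, center=True, min_periods=1).median().to_numpy()
    )
    resid = heights - moving_median
    robust_sd = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    threshold = max(outlier_mad_k * robust_sd, min_deviation_mmHg)
    if side == "low":
        keep = resid >= -threshold
    else:
        keep = np.abs(resid) <= threshold
    return idx[keep]


def interpolate_petco2(
    trace: RawCO2Trace, peaks: np.ndarray, fs_out_hz: float = REGRESSOR_FS_HZ
) -> RawCO2Trace:
    """Piecewise-linear pETCO2 envelope through the peaks, resampled to 50 Hz.

    Before the first and after the last peak the envelope is held constant
    at the nearest peak value (no trend is fabricated at the run edges).
    """
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size < 2:
        raise ParameterError("at least 2 end-tidal peaks are required for interpolation")
    t = trace.time_s
    n_out = int(np.floor((t[-1] - t[0]) * fs_out_hz)) + 1
    t_out = t[0] + np.arange(n_out) / fs_out_hz
    env = np.interp(t_out, t[peaks], trace.values[peaks])
    return RawCO2Trace(env, fs_out_hz, trace.start_offset_s)


def polynomial_detrend(values: np.ndarray, order: int = 3) -> np.ndarray:
    """Residual of a least-squares polynomial fit (default cubic)."""
    values = np.asarray(values, dtype=float)
    x = np.arange(values.size, dtype=float)
    fit = np.polynomial.Polynomial.fit(x, values, deg=order)
    return values - fit(x)


def hrf_kernel(
    dt_s: float = 1.0 / REGRESSOR_FS_HZ,
    duration_s: float = 32.0,
    undershoot_ratio: float = 1.0 / 6.0,
    normalize: str = "peak",
) -> np.ndarray:
    """Canonical two-gamma HRF sampled at ``dt_s``.

    Response lobe t^6 e^-t (peak at 6 s) minus ``undershoot_ratio`` times
    the undershoot lobe t^16 e^-t (trough after ~10 s), each peak-scaled
    before combination. ``normalize='peak'`` scales the kernel maximum to 1
    (inert for correlation analysis); ``normalize='area'`` scales to unit
    integral so that slowly varying inputs keep their physical units, which
    is what the synthetic generator uses for its vascular driver.
    """
    if dt_s <= 0 or duration_s <= dt_s:
        raise ParameterError("HRF kernel needs dt > 0 and duration > dt")
    t = np.arange(0.0, duration_s, dt_s)
    response = t**6 * np.exp(-t)
    response /= response.max()
    undershoot = t**16 * np.exp(-t)
    undershoot /= undershoot.max()
    h = response - undershoot_ratio * undershoot
    if normalize == "peak":
        h = h / h.max()
    elif normalize == "area":
        h = h / (h.sum() * dt_s)
    else:
        raise ParameterError(f"unknown normalization {normalize!r}")
    return h


def build_regressor(
    envelope: RawCO2Trace,
    detrend_order: int = 3,
    hrf_duration_s: float = 32.0,
    peak_times_s: np.ndarray | None = None,
    detrend: bool = True,
) -> PetCO2Regressor:
    """Detrend the pETCO2 envelope, then convolve causally with the HRF.

    The order (detrend first, convolve second) is fixed. Output is
    truncated to the input length, so regressor sample k still sits at
    envelope time k/50 s.
    """
    if envelope.fs_hz != REGRESSOR_FS_HZ:
        raise ParameterError(
            f"envelope must be sampled at {REGRESSOR_FS_HZ} Hz; "
            "run interpolate_petco2 first"
        )
    kernel = hrf_kernel(dt_s=1.0 / envelope.fs_hz, duration_s=hrf_duration_s)
    if envelope.n < kernel.size:
        raise DataError(
            f"envelope ({envelope.n} samples) is shorter than the HRF kernel "
            f"({kernel.size} samples)"
        )
    detrended = polynomial_detrend(envelope.values, detrend_order) if detrend else envelope.values
    values = np.convolve(detrended, kernel)[: envelope.n]
    return PetCO2Regressor(
        values=values,
        start_offset_s=envelope.start_offset_s,
        peak_times_s=np.array([]) if peak_times_s is None else np.asarray(peak_times_s),
        provenance={
            "lowpass": {"cutoff_hz": 1.0, "order": 4, "phase": "zero (forward-backward)"},
            "detrend_order": detrend_order if detrend else None,
            "hrf": {
                "family": "two-gamma",
                "response": "t^6 exp(-t)",
                "undershoot": "t^16 exp(-t)",
                "undershoot_ratio": 1.0 / 6.0,
                "duration_s": hrf_duration_s,
                "normalization": "peak",
            },
            "peak_review": "automatic moving-median MAD rule (no manual review)",
        },
    )


def process_co2(
    trace: RawCO2Trace,
    lowpass_cutoff_hz: float = 1.0,
    lowpass_order: int = 4,
    min_interval_s: float = 2.0,
    prominence_mmHg: float | None = None,
    outlier_mad_k: float = 3.0,
    detrend_order: int = 3,
) -> PetCO2Regressor:
    """Full raw-trace -> regressor chain with the standard defaults."""
    filtered = lowpass_co2(trace, lowpass_cutoff_hz, lowpass_order)
    peaks = detect_end_tidal_peaks(filtered, min_interval_s, prominence_mmHg, outlier_mad_k)
    envelope = interpolate_petco2(filtered, peaks)
    reg = build_regressor(envelope, detrend_order=detrend_order,
                          peak_times_s=filtered.time_s[peaks])
    reg.provenance["lowpass"] = {
        "cutoff_hz": lowpass_cutoff_hz,
        "order": lowpass_order,
        "phase": "zero (forward-backward)",
    }
    return reg
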