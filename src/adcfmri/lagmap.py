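"""Voxelwise lagged cross-correlation against the pETCO2 regressor.

For each voxel timeseries y(t) and lag l in [-30, 0] s (0.5 s steps), the
Pearson correlation r(l) between y(t) and regressor(t - l) is computed on
the overlapping samples only (no zero padding), with the regressor linearly
interpolated from its 50 Hz grid to the shifted volume times. Negative lags
mean the fMRI signal leads the *recorded* trace, which is the physiological
situation given the ~15 s gas-analyser transport delay.

The peak over lags gives rmax and the voxel latency; peaks sitting at a lag
range extreme are not local maxima and are marked invalid. rmax is
variance-stabilised as zmax = atanh(rmax) * sqrt(N - 3), with N the overlap
count at the peak lag (overlap varies across lags).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contrast import FmriRun
from .errors import DataError, ParameterError
from .physio import PetCO2Regressor

DEFAULT_LAGS = np.arange(-30.0, 0.0 + 1e-9, 0.5)
MIN_OVERLAP = 10


@dataclass
class LagCurve:
    """Per-lag correlation for a single voxel timeseries."""

    lags_s: np.ndarray
    r: np.ndarray
    n_overlap: np.ndarray
    usable: np.ndarray


@dataclass
class XCorrMap:
    """Voxelwise peak correlation, latency, and Fisher-z maps.

    3D arrays on the run grid; NaN outside the analysis mask. ``valid`` is
    False where the peak sat at a lag extreme or the overlap was too small.
    ``per_lag_r`` (optional) stores the full r(l) curves for the in-mask
    voxels, in ``np.nonzero(mask)`` order, for correlation profiles.
    """

    rmax: np.ndarray
    latency_s: np.ndarray
    n_overlap: np.ndarray
    zmax: np.ndarray
    valid: np.ndarray
    mask: np.ndarray
    lags_s: np.ndarray
    per_lag_r: np.ndarray | None = None
    normalization_shift_s: float | None = None
    meta: dict = field(default_factory=dict)


def _masked_pearson(Y: np.ndarray, W: np.ndarray, x: np.ndarray,
                    u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rowwise Pearson r between Y rows and x over jointly valid samples.

    Y: (n_vox, n_t) with NaN allowed; W: finite-mask of Y; x: (n_t,)
    regressor values; u: (n_t,) bool usable-sample mask for this lag.
    Returns (r, n) with r = NaN where undefined.
    """
    Wu = W & u
    n = Wu.sum(axis=1).astype(float)
    Y0 = np.where(W, Y, 0.0)
    xu = np.where(u, x, 0.0)
    s_x = Wu @ x
    s_xx = Wu @ (x * x)
    s_y = Y0 @ u.astype(float)
    s_yy = (Y0 * Y0) @ u.astype(float)
    s_xy = Y0 @ xu
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * s_xy - s_x * s_y
        var_x = n * s_xx - s_x * s_x
        var_y = n * s_yy - s_y * s_y
        r = cov / np.sqrt(var_x * var_y)
    bad = (n < 2) | (var_x <= 0) | (var_y <= 0)
    r = np.where(bad, np.nan, r)
    return r, n


def _lag_matrix(
    Y: np.ndarray,
    times_s: np.ndarray,
    regressor: PetCO2Regressor,
    lags_s: np.ndarray,
    min_overlap: int,
) -> tuple[np.ndarray, np.ndarray]:
    """r and overlap count for every (voxel row, lag); NaN where unusable."""
    n_vox, n_t = Y.shape
    W = np.isfinite(Y)
    R = np.full((n_vox, lags_s.size), np.nan)
    N = np.zeros((n_vox, lags_s.size))
    for j, lag in enumerate(lags_s):
        x, inside = regressor.sample(times_s - lag)
        if inside.sum() < 2:
            continue
        r, n = _masked_pearson(Y, W, x, inside)
        r = np.where(n >= min_overlap, r, np.nan)
        R[:, j] = r
        N[:, j] = n
    return R, N


def lagged_correlation(
    voxel_ts: np.ndarray,
    times_s: np.ndarray,
    regressor: PetCO2Regressor,
    lags_s: np.ndarray | None = None,
    min_overlap: int = MIN_OVERLAP,
) -> LagCurve:
    """Correlation r(l) of one voxel timeseries against the lagged regressor."""
    voxel_ts = np.asarray(voxel_ts, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    if voxel_ts.shape != times_s.shape:
        raise ParameterError("voxel timeseries and times must have the same length")
    lags = DEFAULT_LAGS if lags_s is None else np.asarray(lags_s, dtype=float)
    R, N = _lag_matrix(voxel_ts[None, :], times_s, regressor, lags, min_overlap)
    return LagCurve(lags_s=lags, r=R[0], n_overlap=N[0], usable=np.isfinite(R[0]))


def _peak_over_lags(
    R: np.ndarray, N: np.ndarray, lags: np.ndarray, midpoint_s: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Peak r, its lag index, overlap at peak, and validity, per voxel row.

    Equal-maximum ties break toward the lag closest to the range midpoint
    (least boundary bias); a peak at either lag extreme is invalid.
    """
    if midpoint_s is None:
        midpoint_s = 0.5 * (lags[0] + lags[-1])
    usable = np.isfinite(R)
    any_usable = usable.any(axis=1)
    Rsafe = np.where(usable, R, -np.inf)
    rmax = Rsafe.max(axis=1)
    is_peak = Rsafe == rmax[:, None]
    dist = np.abs(lags - midpoint_s)
    peak_idx = np.where(is_peak, dist[None, :], np.inf).argmin(axis=1)
    rows = np.arange(R.shape[0])
    n_at_peak = N[rows, peak_idx]
    valid = any_usable & (peak_idx != 0) & (peak_idx != lags.size - 1)
    rmax = np.where(any_usable, rmax, np.nan)
    return rmax, peak_idx, n_at_peak, valid


def fisher_z(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """zmax = atanh(r) * sqrt(n - 3), clipping |r| away from 1."""
    r = np.clip(np.asarray(r, dtype=float), -1 + 1e-15, 1 - 1e-15)
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore"):
        scale = np.sqrt(np.maximum(n - 3.0, 0.0))
    return np.arctanh(r) * scale


def xcorr_map(
    run: FmriRun,
    regressor: PetCO2Regressor,
    mask: np.ndarray | None = None,
    lags_s: np.ndarray | None = None,
    min_overlap: int = MIN_OVERLAP,
    fixed_n: bool = False,
    keep_curves: bool = False,
) -> XCorrMap:
    """Voxelwise lag map for one run.

    ``fixed_n`` uses the full series length for the Fisher variance
    stabilisation instead of the per-voxel overlap at the peak lag.
    """
    if mask is None:
        mask = run.masks.get("brain")
    if mask is None:
        mask = np.ones(run.grid, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ParameterError("empty analysis mask")
    lags = DEFAULT_LAGS if lags_s is None else np.asarray(lags_s, dtype=float)
    Y = run.data[mask]
    R, N = _lag_matrix(Y, run.volume_times_s, regressor, lags, min_overlap)
    rmax, peak_idx, n_at_peak, valid = _peak_over_lags(R, N, lags)
    if fixed_n:
        n_for_z = np.full_like(n_at_peak, float(run.n_vols))
    else:
        n_for_z = n_at_peak
    zmax = fisher_z(rmax, n_for_z)

    def to3d(flat, fill=np.nan, dtype=float):
        out = np.full(run.grid, fill, dtype=dtype)
        out[mask] = flat
        return out

    return XCorrMap(
        rmax=to3d(rmax),
        latency_s=to3d(lags[peak_idx]),
        n_overlap=to3d(n_at_peak),
        zmax=to3d(zmax),
        valid=to3d(valid, fill=False, dtype=bool),
        mask=mask,
        lags_s=lags,
        per_lag_r=R if keep_curves else None,
        meta={"contrast": run.contrast, "fixed_n": fixed_n, "min_overlap": min_overlap},
    )


def normalize_latency(xmap: XCorrMap, gm_mask: np.ndarray) -> tuple[XCorrMap, float]:
    """Shift latencies by the median latency of valid grey-matter voxels."""
    gm_mask = np.asarray(gm_mask, dtype=bool)
    sel = xmap.valid & gm_mask & xmap.mask
    if not sel.any():
        raise DataError("no valid grey-matter voxels; cannot normalise latency")
    shift = float(np.median(xmap.latency_s[sel]))
    shifted = XCorrMap(
        rmax=xmap.rmax.copy(),
        latency_s=xmap.latency_s - shift,
        n_overlap=xmap.n_overlap.copy(),
        zmax=xmap.zmax.copy(),
        valid=xmap.valid.copy(),
        mask=xmap.mask.copy(),
        lags_s=xmap.lags_s.copy(),
        per_lag_r=None if xmap.per_lag_r is None else xmap.per_lag_r.copy(),
        normalization_shift_s=shift,
        meta=dict(xmap.meta),
    )
    return shifted, shift


def correlation_profile(
    run: FmriRun,
    regressor: PetCO2Regressor,
    sig_mask: np.ndarray,
    gm_mask: np.ndarray | None = None,
    lags_s: np.ndarray | None = None,
    xmap: XCorrMap | None = None,
) -> pd.DataFrame:
    """Mean r(l) over significant voxels, lag axis shifted to the GM median.

    Returns a DataFrame with columns ``lag_s`` (shifted) and ``mean_r``;
    empty (with a warning) when no voxel is significant.
    """
    import warnings

    sig_mask = np.asarray(sig_mask, dtype=bool)
    if xmap is None or xmap.per_lag_r is None:
        xmap = xcorr_map(run, regressor, mask=None, lags_s=lags_s, keep_curves=True)
    if not sig_mask.any():
        warnings.warn("no significant voxels; correlation profile is empty")
        return pd.DataFrame({"lag_s": [], "mean_r": []})
    shift = 0.0
    if gm_mask is not None:
        sel = xmap.valid & np.asarray(gm_mask, dtype=bool) & xmap.mask
        if sel.any():
            shift = float(np.median(xmap.latency_s[sel]))
    in_mask_sig = sig_mask[xmap.mask]
    curves = xmap.per_lag_r[in_mask_sig]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_r = np.nanmean(curves, axis=0)
    return pd.DataFrame({"lag_s": xmap.lags_s - shift, "mean_r": mean_r})
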