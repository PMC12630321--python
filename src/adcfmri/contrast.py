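"""Functional contrasts: BOLD, b200/b1000 dfMRI sub-series, and ADC-fMRI.

A diffusion-weighted acquisition interleaves volumes at b = 200 and
1000 s/mm2 (after two lead-in b = 0 volumes). Splitting the interleave
yields the two dfMRI sub-series; taking the log-ratio of each consecutive
(b200, b1000) pair yields the ADC timeseries

    ADC(t) = -1/(b2 - b1) * ln( S(b2, t + dt) / S(b1, t) ),

whose key property is that any multiplicative modulation common to the two
signals -- in particular T2/BOLD weighting -- cancels exactly in the ratio.

The module also carries the three-compartment CSF partial-volume estimator
used to bound how much a haemodynamically driven CSF-fraction change could
masquerade as an ADC change.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DataError, FormatError, ParameterError

B_LOW = 200.0
B_HIGH = 1000.0

#: Default compartment diffusivities, mm^2/s.
DEFAULT_DIFFUSIVITIES = {"csf": 3.0e-3, "gm": 0.8e-3, "wm": 0.75e-3}


@dataclass
class FmriRun:
    """A 4D functional run with its acquisition metadata and masks.

    ``volume_times_s`` are the per-volume sample times used everywhere
    downstream (vascular driver sampling, lagged correlation); they are
    strictly increasing with spacing ``TR_s``.
    """

    data: np.ndarray
    TR_s: float
    contrast: str
    volume_times_s: np.ndarray
    b_schedule: np.ndarray | None = None
    masks: dict = field(default_factory=dict)
    voxel_size_mm: float = 2.8

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.volume_times_s = np.asarray(self.volume_times_s, dtype=float)
        if self.data.ndim != 4:
            raise FormatError(f"run data must be 4D (x,y,z,t), got {self.data.ndim}D")
        if self.TR_s <= 0:
            raise ParameterError("TR must be positive")
        if self.volume_times_s.shape != (self.data.shape[-1],):
            raise FormatError("volume_times_s length must equal the number of volumes")
        dt = np.diff(self.volume_times_s)
        if self.volume_times_s.size > 1 and not np.allclose(dt, self.TR_s, rtol=1e-6, atol=1e-9):
            raise FormatError("volume times must be strictly increasing with spacing TR_s")
        if self.b_schedule is not None:
            self.b_schedule = np.asarray(self.b_schedule, dtype=float)
            if self.b_schedule.shape != (self.n_vols,):
                raise FormatError("b_schedule length must equal the number of volumes")
        for name, m in self.masks.items():
            if np.shape(m) != self.grid:
                raise FormatError(f"mask {name!r} does not match the data grid")

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_vols(self) -> int:
        return self.data.shape[-1]

    def replace_data(self, data: np.ndarray) -> "FmriRun":
        return FmriRun(
            data=data,
            TR_s=self.TR_s,
            contrast=self.contrast,
            volume_times_s=self.volume_times_s.copy(),
            b_schedule=None if self.b_schedule is None else self.b_schedule.copy(),
            masks=dict(self.masks),
            voxel_size_mm=self.voxel_size_mm,
        )


@dataclass
class AdcSeries:
    """ADC timeseries from interleaved b-value pairs.

    One ADC sample per (b_low at t, b_high at t+TR) pair, timestamped at the
    pair midpoint, so the effective sampling interval is 2 TR. Voxel
    time-points whose signal ratio was non-positive or non-finite are NaN in
    ``data`` and flagged in ``invalid_mask`` -- never silently clipped.
    """

    data: np.ndarray
    pair_times_s: np.ndarray
    invalid_mask: np.ndarray
    b_low: float = B_LOW
    b_high: float = B_HIGH
    TR_pair_s: float = 0.0

    def __post_init__(self) -> None:
        if self.b_high <= self.b_low:
            raise ParameterError("b_high must exceed b_low")

    def as_run(self, template: FmriRun) -> FmriRun:
        """Package the ADC series as an FmriRun (contrast 'ADC')."""
        return FmriRun(
            data=self.data,
            TR_s=self.TR_pair_s,
            contrast="ADC",
            volume_times_s=self.pair_times_s,
            masks=dict(template.masks),
            voxel_size_mm=template.voxel_size_mm,
        )


def _split_indices(b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the b_low and b_high volumes after the b = 0 lead-in."""
    n_lead = 0
    while n_lead < b.size and b[n_lead] == 0:
        n_lead += 1
    rest = b[n_lead:]
    if rest.size < 2:
        raise DataError("need at least one complete (b_low, b_high) pair")
    if np.any(rest == 0):
        raise FormatError("b = 0 volumes are only allowed as a lead-in block")
    b1, b2 = rest[0], rest[1]
    if b1 == b2:
        raise FormatError("b-schedule does not alternate between two b-values")
    expected = np.where(np.arange(rest.size) % 2 == 0, b1, b2)
    if not np.array_equal(rest, expected):
        raise FormatError("b-schedule is not strictly alternating after the b = 0 lead-in")
    idx = n_lead + np.arange(rest.size)
    low_first = b1 < b2
    idx_low = idx[0::2] if low_first else idx[1::2]
    idx_high = idx[1::2] if low_first else idx[0::2]
    # keep complete pairs only: each low volume must be followed by a high one
    n_pairs = min(idx_low.size, idx_high.size)
    idx_low, idx_high = idx_low[:n_pairs], idx_high[:n_pairs]
    if not low_first:
        # schedule started with the high b-value: the first high volume has no
        # preceding low partner, pair each low with the *next* high volume
        idx_high = idx[0::2][1 : n_pairs + 1]
        n_pairs = min(idx_low.size, idx_high.size)
        idx_low, idx_high = idx_low[:n_pairs], idx_high[:n_pairs]
    return idx_low, idx_high


def split_dfmri(run: FmriRun) -> tuple[FmriRun, FmriRun]:
    """Split an interleaved dfMRI run into its b200 and b1000 sub-series.

    b = 0 lead-in volumes are dropped; each sub-series keeps its own
    acquisition times and has effective TR = 2 x TR.
    """
    if run.b_schedule is None:
        raise ParameterError("run has no b-value schedule; not a dfMRI acquisition")
    idx_low, idx_high = _split_indices(run.b_schedule)
    out = []
    for idx, b in ((idx_low, run.b_schedule[idx_low][0]), (idx_high, run.b_schedule[idx_high][0])):
        out.append(
            FmriRun(
                data=run.data[..., idx],
                TR_s=2 * run.TR_s,
                contrast=f"b{int(b)}",
                volume_times_s=run.volume_times_s[idx],
                masks=dict(run.masks),
                voxel_size_mm=run.voxel_size_mm,
            )
        )
    return out[0], out[1]


def interleave_dfmri(low: FmriRun, high: FmriRun) -> FmriRun:
    """Re-interleave two b-value sub-series (inverse of :func:`split_dfmri`
    on the non-b0 portion); used for round-trip verification."""
    if low.n_vols != high.n_vols:
        raise FormatError("sub-series lengths differ")
    n = 2 * low.n_vols
    data = np.empty(low.data.shape[:3] + (n,), dtype=float)
    data[..., 0::2] = low.data
    data[..., 1::2] = high.data
    times = np.empty(n)
    times[0::2] = low.volume_times_s
    times[1::2] = high.volume_times_s
    b = np.empty(n)
    b[0::2] = float(low.contrast.lstrip("b"))
    b[1::2] = float(high.contrast.lstrip("b"))
    return FmriRun(
        data=data,
        TR_s=low.TR_s / 2,
        contrast="dfMRI",
        volume_times_s=times,
        b_schedule=b,
        masks=dict(low.masks),
        voxel_size_mm=low.voxel_size_mm,
    )


def compute_adc_series(run: FmriRun) -> AdcSeries:
    """ADC(t) from consecutive (b_low, b_high) pairs of an interleaved run."""
    if run.b_schedule is None:
        raise ParameterError("run has no b-value schedule; cannot compute ADC")
    idx_low, idx_high = _split_indices(run.b_schedule)
    if idx_low.size < 1:
        raise DataError("need at least one complete (b_low, b_high) pair")
    b1 = run.b_schedule[idx_low[0]]
    b2 = run.b_schedule[idx_high[0]]
    s_low = run.data[..., idx_low]
    s_high = run.data[..., idx_high]
    valid = (s_low > 0) & (s_high > 0) & np.isfinite(s_low) & np.isfinite(s_high)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc = -np.log(s_high / s_low) / (b2 - b1)
    adc = np.where(valid, adc, np.nan)
    pair_times = 0.5 * (run.volume_times_s[idx_low] + run.volume_times_s[idx_high])
    return AdcSeries(
        data=adc,
        pair_times_s=pair_times,
        invalid_mask=~valid,
        b_low=float(b1),
        b_high=float(b2),
        TR_pair_s=2 * run.TR_s,
    )


def _two_point_adc(fractions: Mapping[str, float], diffusivities: Mapping[str, float],
                   b_low: float, b_high: float) -> float:
    m_low = sum(f * np.exp(-b_low * diffusivities[k]) for k, f in fractions.items())
    m_high = sum(f * np.exp(-b_high * diffusivities[k]) for k, f in fractions.items())
    return -np.log(m_high / m_low) / (b_high - b_low)


def csf_partial_volume_effect(
    fractions: Mapping[str, float],
    diffusivities: Mapping[str, float] | None = None,
    delta_f_csf: float = 0.0,
    b_low: float = B_LOW,
    b_high: float = B_HIGH,
    relative_delta: bool = False,
    csf_key: str = "csf",
) -> float:
    """Fractional ADC change from moving CSF volume fraction into tissue.

    Evaluates the mixture signal sum_i f_i exp(-b D_i) at both b-values
    before and after shifting ``delta_f_csf`` (negative = CSF loss) from the
    CSF compartment to the tissue compartments, redistributed in proportion
    to their existing fractions. With ``relative_delta`` the shift is
    interpreted as a relative change of the current CSF fraction instead of
    absolute fraction points.

    Returns (ADC_after - ADC_before) / ADC_before.
    """
    if diffusivities is None:
        diffusivities = DEFAULT_DIFFUSIVITIES
    for k, f in fractions.items():
        if not 0.0 <= f <= 1.0:
            raise ParameterError(f"fraction {k!r} = {f} outside [0, 1]")
        if diffusivities.get(k, 0.0) <= 0:
            raise ParameterError(f"diffusivity for {k!r} must be positive")
    if not np.isclose(sum(fractions.values()), 1.0, atol=1e-8):
        raise ParameterError("fractions must sum to 1")
    f_csf = fractions.get(csf_key, 0.0)
    delta = delta_f_csf * f_csf if relative_delta else delta_f_csf
    if f_csf == 0.0 or delta == 0.0:
        return 0.0
    new_csf = f_csf + delta
    if not 0.0 <= new_csf <= 1.0:
        raise ParameterError("perturbed CSF fraction outside [0, 1]")
    tissue_total = 1.0 - f_csf
    after = {}
    for k, f in fractions.items():
        if k == csf_key:
            after[k] = new_csf
        else:
            after[k] = f - delta * (f / tissue_total) if tissue_total > 0 else f
        if not 0.0 <= after[k] <= 1.0 + 1e-12:
            raise ParameterError(f"perturbed fraction {k!r} outside [0, 1]")
    adc_before = _two_point_adc(fractions, diffusivities, b_low, b_high)
    adc_after = _two_point_adc(after, diffusivities, b_low, b_high)
    return (adc_after - adc_before) / adc_before


def csf_partial_volume_extremum(
    csf_fractions: Sequence[float],
    delta_f_csf: float,
    diffusivity_grids: Mapping[str, Sequence[float]] | None = None,
    b_low: float = B_LOW,
    b_high: float = B_HIGH,
    relative_delta: bool = False,
    tissue_key: str = "gm",
) -> tuple[float, dict]:
    """Sweep a two-compartment (CSF + tissue) grid; return the extreme
    (largest-magnitude) fractional ADC change and the parameters attaining it."""
    if diffusivity_grids is None:
        diffusivity_grids = {
            "csf": [DEFAULT_DIFFUSIVITIES["csf"]],
            tissue_key: [DEFAULT_DIFFUSIVITIES["gm"], DEFAULT_DIFFUSIVITIES["wm"]],
        }
    keys = list(diffusivity_grids)
    best: tuple[float, dict] | None = None
    for f_csf in csf_fractions:
        for combo in itertools.product(*(diffusivity_grids[k] for k in keys)):
            diff = dict(zip(keys, combo))
            frac = {"csf": f_csf, tissue_key: 1.0 - f_csf}
            change = csf_partial_volume_effect(
                frac, diff, delta_f_csf, b_low, b_high, relative_delta
            )
            if best is None or abs(change) > abs(best[0]):
                best = (change, {"f_csf": f_csf, **{f"D_{k}": v for k, v in diff.items()}})
    assert best is not None
    return best
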