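"""Phase-randomisation surrogate analysis and empirical significance thresholds.

Because the lag map takes a maximum over 61 lags, zmax is inflated under
the null and a standard-normal threshold would be anticonservative. The
empirical null is built leave-one-subject-out: surrogate copies of one
subject's pETCO2 regressor -- Fourier magnitudes preserved, phases drawn
uniformly -- are cross-correlated (full procedure, peak over lags, Fisher
z) against randomly sampled brain voxels of every *other* subject, and the
zmax values are pooled across reference subjects. The one-tailed p < 0.05
threshold is the empirical 95th percentile.

Surrogate thresholds are not built for breath-hold data: surrogates of a
task-locked regressor keep the task's spectral line and stay correlated
with it, so breath-hold analysis uses the fixed z = 3.09 instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import fft as sfft

from .contrast import FmriRun
from .errors import DataError, ParameterError
from .lagmap import DEFAULT_LAGS, MIN_OVERLAP, fisher_z
from .physio import PetCO2Regressor


@dataclass
class NullDistribution:
    """Pooled surrogate zmax samples and the derived threshold."""

    samples: np.ndarray
    contrast: str
    n_surrogates: int
    n_voxels: int
    n_subjects: int
    seed: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise DataError("null distribution contains non-finite samples")

    @property
    def threshold_p05(self) -> float:
        return significance_threshold(self, p=0.05)


def phase_randomize(series, seed: int | None = None, rng: np.random.Generator | None = None):
    """Surrogate with the same Fourier magnitudes and uniform random phases.

    The zero-frequency coefficient (and the Nyquist coefficient for even
    lengths) is kept real and untouched, so the mean is preserved exactly
    and, by Parseval, so is the variance. Accepts a plain array or a
    :class:`PetCO2Regressor` (returned as the same type).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(series, PetCO2Regressor):
        values = phase_randomize(series.values, rng=rng)
        return PetCO2Regressor(
            values=values,
            start_offset_s=series.start_offset_s,
            peak_times_s=np.array([]),
            provenance={**series.provenance, "surrogate": "phase-randomized"},
        )
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ParameterError("phase randomisation needs a 1-D series of length >= 4")
    return phase_randomize_batch(x, 1, rng)[0]


def phase_randomize_batch(x: np.ndarray, n_surrogates: int,
                          rng: np.random.Generator) -> np.ndarray:
    """(n_surrogates, len(x)) independent phase-randomised surrogates.

    One forward transform of the original series plus a batched inverse
    transform; identical null model to :func:`phase_randomize`.
    """
    x = np.asarray(x, dtype=float)
    spec = sfft.rfft(x)
    n_spec = spec.size
    hi = n_spec - 1 if x.size % 2 == 0 else n_spec  # exclude Nyquist bin when even
    mags = np.abs(spec[1:hi])
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_surrogates, hi - 1))
    specs = np.empty((n_surrogates, n_spec), dtype=complex)
    specs[:, 0] = spec[0]
    if hi < n_spec:
        specs[:, hi:] = spec[hi:]
    specs[:, 1:hi] = mags * np.cos(phases)
    specs[:, 1:hi] += 1j * (mags * np.sin(phases))
    return sfft.irfft(specs, x.size, axis=1)


def _interp_rows(S: np.ndarray, t0: float, fs: float, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation of every row of S (common time grid) at ``times``."""
    pos = (times - t0) * fs
    inside = (pos >= 0) & (pos <= S.shape[1] - 1)
    posc = np.clip(pos, 0, S.shape[1] - 1)
    i0 = np.floor(posc).astype(int)
    i1 = np.minimum(i0 + 1, S.shape[1] - 1)
    w = posc - i0
    vals = S[:, i0] * (1.0 - w) + S[:, i1] * w
    return vals, inside


def _paired_zmax(
    S: np.ndarray,
    reg_t0: float,
    reg_fs: float,
    Y: np.ndarray,
    times: np.ndarray,
    lags: np.ndarray,
    min_overlap: int,
) -> tuple[np.ndarray, np.ndarray]:
    """zmax and validity for row-paired (surrogate, voxel) series.

    Row i of ``S`` (surrogate regressor on a common 50 Hz grid) is
    correlated with row i of ``Y`` (voxel timeseries at ``times``) over all
    lags; returns the Fisher-z peak with the same boundary-exclusion rule
    as the voxelwise map.
    """
    n_pairs = Y.shape[0]
    Wy = np.isfinite(Y)
    Y0 = np.where(Wy, Y, 0.0)
    R = np.full((n_pairs, lags.size), np.nan)
    N = np.zeros((n_pairs, lags.size))
    for j, lag in enumerate(lags):
        X, inside = _interp_rows(S, reg_t0, reg_fs, times - lag)
        V = Wy & inside
        n = V.sum(axis=1).astype(float)
        X0 = np.where(V, X, 0.0)
        Yv = np.where(V, Y0, 0.0)
        s_x = X0.sum(axis=1)
        s_y = Yv.sum(axis=1)
        s_xx = (X0 * X0).sum(axis=1)
        s_yy = (Yv * Yv).sum(axis=1)
        s_xy = (X0 * Yv).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (n * s_xy - s_x * s_y) / np.sqrt(
                (n * s_xx - s_x**2) * (n * s_yy - s_y**2)
            )
        r = np.where((n >= min_overlap) & np.isfinite(r), r, np.nan)
        R[:, j] = r
        N[:, j] = n
    usable = np.isfinite(R)
    any_usable = usable.any(axis=1)
    Rsafe = np.where(usable, R, -np.inf)
    rmax = Rsafe.max(axis=1)
    mid = 0.5 * (lags[0] + lags[-1])
    dist = np.abs(lags - mid)
    idx = np.where(Rsafe == rmax[:, None], dist[None, :], np.inf).argmin(axis=1)
    rows = np.arange(n_pairs)
    valid = any_usable & (idx != 0) & (idx != lags.size - 1)
    z = fisher_z(np.where(any_usable, rmax, np.nan), N[rows, idx])
    return z, valid


def build_null(
    cohort: Sequence,
    n_surrogates: int = 5000,
    n_voxels: int = 5000,
    seed: int = 0,
    lags_s: np.ndarray | None = None,
    contrast: str | None = None,
    min_overlap: int = MIN_OVERLAP,
    mask_name: str = "brain",
) -> NullDistribution:
    """Leave-one-subject-out surrogate null of zmax.

    ``cohort`` items are ``(regressor, run)`` pairs or objects with
    ``regressor``/``run`` attributes. For each reference subject,
    ``n_surrogates`` phase-randomised copies of its regressor are paired
    with voxels drawn without replacement (``n_voxels`` per donor subject,
    seeded per reference/donor pair) from the brain masks of the other
    subjects, cycling through the pooled draw; the valid zmax values from
    every reference subject are pooled.
    """

    def unpack(item):
        if hasattr(item, "regressor") and hasattr(item, "run"):
            return item.regressor, item.run
        reg, run = item
        return reg, run

    pairs = [unpack(it) for it in cohort]
    if len(pairs) < 2:
        raise ParameterError("surrogate null needs at least 2 subjects (leave-one-out)")
    lags = DEFAULT_LAGS if lags_s is None else np.asarray(lags_s, dtype=float)
    root = np.random.default_rng(seed)
    subject_streams = root.spawn(len(pairs))
    samples: list[np.ndarray] = []
    for i, (reg_i, _) in enumerate(pairs):
        stream = subject_streams[i]
        S = phase_randomize_batch(reg_i.values, n_surrogates, stream)
        donor_Y, donor_times = [], []
        for j, (_, run_j) in enumerate(pairs):
            if j == i:
                continue
            mask = run_j.masks.get(mask_name)
            if mask is None:
                mask = np.ones(run_j.grid, dtype=bool)
            flat = run_j.data[np.asarray(mask, dtype=bool)]
            take = min(n_voxels, flat.shape[0])
            sel = stream.choice(flat.shape[0], size=take, replace=False)
            donor_Y.append(flat[sel])
            donor_times.append(run_j.volume_times_s)
        # cycle surrogate index through the pooled donor draw
        pool_sizes = [y.shape[0] for y in donor_Y]
        total = sum(pool_sizes)
        assign = np.arange(n_surrogates) % total
        offset = 0
        for Yd, td in zip(donor_Y, donor_times):
            sel = np.where((assign >= offset) & (assign < offset + Yd.shape[0]))[0]
            offset += Yd.shape[0]
            if sel.size == 0:
                continue
            z, valid = _paired_zmax(
                S[sel], reg_i.start_offset_s, reg_i.fs_hz,
                Yd[assign[sel] - (offset - Yd.shape[0])], td, lags, min_overlap,
            )
            samples.append(z[valid & np.isfinite(z)])
    pooled = np.concatenate(samples) if samples else np.array([])
    return NullDistribution(
        samples=pooled,
        contrast=contrast or "",
        n_surrogates=n_surrogates,
        n_voxels=n_voxels,
        n_subjects=len(pairs),
        seed=seed,
    )


def significance_threshold(null, p: float = 0.05) -> float:
    """Empirical one-tailed (1 - p) quantile of the pooled zmax samples."""
    samples = null.samples if isinstance(null, NullDistribution) else np.asarray(null, dtype=float)
    if samples.size < 100:
        raise DataError(
            f"need at least 100 null samples for a stable quantile, got {samples.size}"
        )
    if not 0.0 < p < 1.0:
        raise ParameterError("p must be in (0, 1)")
    return float(np.quantile(samples, 1.0 - p))
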