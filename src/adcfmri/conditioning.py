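"""Per-run signal conditioning, motion QC, noise amplification, and SNR.

Conditioning matches the study's final preprocessing: 4 mm FWHM spatial
smoothing followed by zero-phase 0.01 Hz fourth-order Butterworth high-pass
filtering. Motion quality control uses absolute displacement from the first
volume and Power-style framewise displacement (FD); a run is rejected when
the maximum absolute displacement exceeds one voxel or the mean FD exceeds
0.2 mm (strict inequalities).

The noise-amplification control re-injects volume-permuted residuals at a
chosen gain k on top of the denoised data, destroying any task-locked
structure in the residuals while keeping their spatial covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .contrast import FmriRun
from .errors import DataError, ParameterError

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...
DEFAULT_HEAD_RADIUS_MM = 50.0
DEFAULT_MEAN_FD_LIMIT_MM = 0.2


@dataclass
class RunQC:
    """Motion quality-control verdict for one run."""

    max_abs_displacement_mm: float
    mean_fd_mm: float
    voxel_size_mm: float
    accepted: bool
    reasons: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "max_abs_displacement_mm": float(self.max_abs_displacement_mm),
            "mean_fd_mm": float(self.mean_fd_mm),
            "voxel_size_mm": float(self.voxel_size_mm),
            "accepted": bool(self.accepted),
            "reasons": list(self.reasons),
        }


def smooth_spatial(run: FmriRun, fwhm_mm: float = 4.0) -> FmriRun:
    """Per-volume 3D Gaussian smoothing, sigma = FWHM / (2.3548 voxel)."""
    if fwhm_mm <= 0:
        raise ParameterError("FWHM must be positive")
    sigma_vox = fwhm_mm / FWHM_TO_SIGMA / run.voxel_size_mm
    smoothed = ndimage.gaussian_filter(
        run.data, sigma=(sigma_vox, sigma_vox, sigma_vox, 0.0), mode="nearest"
    )
    return run.replace_data(smoothed)


def highpass_temporal(
    run: FmriRun, cutoff_hz: float = 0.01, order: int = 4, keep_mean: bool = True
) -> FmriRun:
    """Per-voxel zero-phase Butterworth high-pass.

    ``keep_mean`` re-adds the voxelwise temporal mean after filtering so
    that mean-dependent quantities (tSNR) remain interpretable; the
    fluctuation content is identical either way.
    """
    fs = 1.0 / run.TR_s
    if cutoff_hz <= 0:
        raise ParameterError("cutoff must be positive")
    if cutoff_hz >= fs / 2:
        raise ParameterError(f"cutoff {cutoff_hz} Hz is at or above Nyquist ({fs / 2} Hz)")
    sos = signal.butter(order, cutoff_hz, btype="high", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, run.data, axis=-1)
    if keep_mean:
        filtered = filtered + run.data.mean(axis=-1, keepdims=True)
    return run.replace_data(filtered)


def condition_run(run: FmriRun, fwhm_mm: float = 4.0, highpass_hz: float = 0.01,
                  order: int = 4) -> FmriRun:
    """Standard conditioning chain: smooth, then high-pass."""
    return highpass_temporal(smooth_spatial(run, fwhm_mm), highpass_hz, order)


def framewise_displacement(
    motion: np.ndarray, head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM
) -> tuple[np.ndarray, np.ndarray]:
    """Power FD and absolute displacement from volume 1.

    ``motion`` is (n_volumes, 6): three translations in mm then three
    rotations in radians. Rotations contribute via arc length on a
    ``head_radius_mm`` sphere. FD of the first volume is 0 by convention.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ParameterError("motion table must have shape (n_volumes, 6)")
    if motion.shape[0] < 2:
        raise ParameterError("need at least 2 volumes for displacement metrics")
    weights = np.array([1.0, 1.0, 1.0] + [head_radius_mm] * 3)
    d = np.abs(np.diff(motion, axis=0)) * weights
    fd = np.concatenate([[0.0], d.sum(axis=1)])
    abs_disp = (np.abs(motion - motion[0]) * weights).sum(axis=1)
    return fd, abs_disp


def qc_gate(
    max_abs_displacement_mm: float,
    mean_fd_mm: float,
    voxel_size_mm: float,
    mean_fd_limit_mm: float = DEFAULT_MEAN_FD_LIMIT_MM,
) -> RunQC:
    """Accept unless max displacement > one voxel or mean FD > limit (strict)."""
    reasons = []
    if max_abs_displacement_mm > voxel_size_mm:
        reasons.append(
            f"max absolute displacement {max_abs_displacement_mm:.3g} mm exceeds "
            f"one voxel ({voxel_size_mm:.3g} mm)"
        )
    if mean_fd_mm > mean_fd_limit_mm:
        reasons.append(
            f"mean framewise displacement {mean_fd_mm:.3g} mm exceeds "
            f"{mean_fd_limit_mm:.3g} mm"
        )
    return RunQC(
        max_abs_displacement_mm=float(max_abs_displacement_mm),
        mean_fd_mm=float(mean_fd_mm),
        voxel_size_mm=float(voxel_size_mm),
        accepted=not reasons,
        reasons=reasons,
    )


def run_qc(motion: np.ndarray, voxel_size_mm: float,
           head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM,
           mean_fd_limit_mm: float = DEFAULT_MEAN_FD_LIMIT_MM) -> RunQC:
    """Motion table -> QC verdict in one call."""
    fd, abs_disp = framewise_displacement(motion, head_radius_mm)
    return qc_gate(abs_disp.max(), fd[1:].mean(), voxel_size_mm, mean_fd_limit_mm)


def _as_array(x) -> np.ndarray:
    return x.data if isinstance(x, FmriRun) else np.asarray(x, dtype=float)


def amplify_noise(
    denoised,
    residuals,
    factor: float,
    seed: int | None = None,
    per_voxel: bool = False,
    permutation: np.ndarray | None = None,
):
    """noised = denoised + factor * residuals[permuted volumes].

    By default one seeded permutation of the volume indices is shared by
    all voxels, preserving the spatial covariance of the noise;
    ``per_voxel`` draws an independent permutation per voxel instead.
    Returns the same type as ``denoised`` (FmriRun or ndarray).
    """
    den = _as_array(denoised)
    res = _as_array(residuals)
    if den.shape != res.shape:
        raise ParameterError(f"shape mismatch: denoised {den.shape} vs residuals {res.shape}")
    n_t = den.shape[-1]
    rng = np.random.default_rng(seed)
    if per_voxel:
        flat = res.reshape(-1, n_t)
        order = np.argsort(rng.random(flat.shape), axis=1)
        permuted = np.take_along_axis(flat, order, axis=1).reshape(res.shape)
    else:
        perm = rng.permutation(n_t) if permutation is None else np.asarray(permutation)
        permuted = res[..., perm]
    noised = den + factor * permuted
    if isinstance(denoised, FmriRun):
        return denoised.replace_data(noised)
    return noised


def image_snr(denoised, residuals, mask: np.ndarray | None = None) -> float:
    """Mean denoised signal divided by the residual standard deviation."""
    den = _as_array(denoised)
    res = _as_array(residuals)
    if mask is not None:
        den = den[mask]
        res = res[mask]
    sd = res.std()
    if sd == 0:
        raise DataError("residual standard deviation is zero; image SNR undefined")
    return float(den.mean() / sd)


def temporal_snr(run, baseline_window: tuple[int, int] | None = None) -> np.ndarray:
    """Per-voxel temporal mean / SD over a (start, stop) volume window.

    Voxels with zero temporal SD are flagged as NaN.
    """
    data = _as_array(run)
    n_t = data.shape[-1]
    if baseline_window is None:
        baseline_window = (0, n_t)
    start, stop = baseline_window
    if not (0 <= start < stop <= n_t):
        raise ParameterError(f"baseline window {baseline_window} outside run of {n_t} volumes")
    seg = data[..., start:stop]
    sd = seg.std(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tsnr = seg.mean(axis=-1) / sd
    return np.where(sd > 0, tsnr, np.nan)


def downsample_keep_every_other(run: FmriRun) -> FmriRun:
    """Keep even-index volumes; TR doubles, original sample times retained."""
    if run.n_vols < 4:
        raise ParameterError("need at least 4 volumes to downsample")
    return FmriRun(
        data=run.data[..., ::2],
        TR_s=2 * run.TR_s,
        contrast=run.contrast,
        volume_times_s=run.volume_times_s[::2],
        b_schedule=None if run.b_schedule is None else run.b_schedule[::2],
        masks=dict(run.masks),
        voxel_size_mm=run.voxel_size_mm,
    )
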