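"""File formats: NIfTI images, physio/regressor TSV + JSON sidecars, tables.

Conventions: images are NIfTI-1; physiological traces are two-column TSV
(``time_s``, ``co2_mmHg``) with a JSON sidecar carrying the sampling rate
and trigger alignment; run metadata (TR, contrast, b-value schedule) lives
in a JSON sidecar next to the 4D image; all tabular outputs are TSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .contrast import FmriRun
from .errors import FormatError, ParameterError
from .physio import PetCO2Regressor, RawCO2Trace
from .surrogate import NullDistribution


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def read_nifti(path, expected_ndim: tuple[int, ...] = (3, 4)):
    """Load a NIfTI image; returns (data, affine, header)."""
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several types for bad headers
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.get_fdata())
    if data.ndim not in expected_ndim:
        raise FormatError(
            f"{path}: expected {expected_ndim}-dimensional image, got {data.ndim}D"
        )
    return data, img.affine, img.header


def write_nifti(data: np.ndarray, path, affine: np.ndarray | None = None,
                voxel_size_mm: float | None = None) -> Path:
    """Write an array as NIfTI-1, preserving voxel size in the affine."""
    path = Path(path)
    if affine is None:
        affine = _affine(voxel_size_mm if voxel_size_mm else 1.0)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), path)
    return path


def save_run(run: FmriRun, base: Path | str) -> tuple[Path, Path]:
    """Write ``<base>.nii.gz`` plus ``<base>.json`` sidecar."""
    base = Path(base)
    nii = write_nifti(run.data, base.with_suffix(".nii.gz"), voxel_size_mm=run.voxel_size_mm)
    sidecar = base.with_suffix(".json")
    meta = {
        "TR_s": run.TR_s,
        "contrast": run.contrast,
        "b_schedule": None if run.b_schedule is None else run.b_schedule.tolist(),
        "volume_times_s": run.volume_times_s.tolist(),
        "voxel_size_mm": run.voxel_size_mm,
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return nii, sidecar


def load_run(base: Path | str, masks: dict | None = None) -> FmriRun:
    """Read a run written by :func:`save_run` (accepts the .nii.gz path too)."""
    base = Path(str(base).replace(".nii.gz", "").replace(".json", ""))
    data, affine, _ = read_nifti(base.with_suffix(".nii.gz"), expected_ndim=(4,))
    sidecar = base.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    return FmriRun(
        data=data,
        TR_s=meta["TR_s"],
        contrast=meta["contrast"],
        volume_times_s=np.asarray(meta["volume_times_s"]),
        b_schedule=None if meta.get("b_schedule") is None else np.asarray(meta["b_schedule"]),
        masks=masks or {},
        voxel_size_mm=meta.get("voxel_size_mm", abs(affine[0, 0])),
    )


def save_co2(trace: RawCO2Trace, base: Path | str, trigger_s: float = 0.0) -> tuple[Path, Path]:
    """Physio TSV (time_s, co2_mmHg) + JSON sidecar."""
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    tsv = base.with_suffix(".tsv")
    pd.DataFrame({"time_s": trace.time_s, "co2_mmHg": trace.values}).to_csv(
        tsv, sep="\t", index=False
    )
    sidecar = base.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {"fs_hz": trace.fs_hz, "start_offset_s": trace.start_offset_s,
             "trigger_s": trigger_s},
            indent=1,
        )
    )
    return tsv, sidecar


def load_co2(base: Path | str) -> RawCO2Trace:
    base = Path(str(base).replace(".tsv", "").replace(".json", ""))
    tsv = base.with_suffix(".tsv")
    sidecar = base.with_suffix(".json")
    if not tsv.exists() or not sidecar.exists():
        raise FormatError(f"missing physio pair {tsv} / {sidecar}")
    df = pd.read_csv(tsv, sep="\t")
    if not {"time_s", "co2_mmHg"} <= set(df.columns):
        raise FormatError(f"{tsv}: expected columns time_s, co2_mmHg")
    meta = json.loads(sidecar.read_text())
    return RawCO2Trace(
        values=df["co2_mmHg"].to_numpy(),
        fs_hz=meta["fs_hz"],
        start_offset_s=meta["start_offset_s"],
    )


def save_regressor(reg: PetCO2Regressor, base: Path | str) -> tuple[Path, Path]:
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    tsv = base.with_suffix(".tsv")
    pd.DataFrame({"time_s": reg.time_s, "value": reg.values}).to_csv(
        tsv, sep="\t", index=False
    )
    sidecar = base.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "fs_hz": reg.fs_hz,
                "start_offset_s": reg.start_offset_s,
                "peak_times_s": reg.peak_times_s.tolist(),
                "provenance": reg.provenance,
            },
            indent=1,
        )
    )
    return tsv, sidecar


def load_regressor(base: Path | str) -> PetCO2Regressor:
    base = Path(str(base).replace(".tsv", "").replace(".json", ""))
    df = pd.read_csv(base.with_suffix(".tsv"), sep="\t")
    meta = json.loads(base.with_suffix(".json").read_text())
    return PetCO2Regressor(
        values=df["value"].to_numpy(),
        start_offset_s=meta["start_offset_s"],
        peak_times_s=np.asarray(meta["peak_times_s"]),
        provenance=meta.get("provenance", {}),
    )


def save_motion(motion: np.ndarray, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ["trans_x_mm", "trans_y_mm", "trans_z_mm", "rot_x_rad", "rot_y_rad", "rot_z_rad"]
    pd.DataFrame(np.asarray(motion), columns=cols).to_csv(path, sep="\t", index=False)
    return path


def load_motion(path: Path | str) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 6:
        raise FormatError(f"{path}: motion table must have 6 columns, got {df.shape[1]}")
    return df.to_numpy(dtype=float)


def save_null(null: NullDistribution, base: Path | str) -> tuple[Path, Path]:
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    tsv = base.with_suffix(".tsv")
    pd.DataFrame({"zmax": null.samples}).to_csv(tsv, sep="\t", index=False)
    sidecar = base.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "contrast": null.contrast,
                "n_surrogates": null.n_surrogates,
                "n_voxels": null.n_voxels,
                "n_subjects": null.n_subjects,
                "seed": null.seed,
                "threshold_p05": null.threshold_p05,
            },
            indent=1,
        )
    )
    return tsv, sidecar


@dataclass
class PipelineConfig:
    """Declarative configuration with every study default pre-filled."""

    out_dir: str = "adcfmri_out"
    condition: str = "breathhold"
    contrasts: tuple = ("BOLD", "b200", "b1000", "ADC")
    seed: int = 0
    # synthetic cohort
    n_subjects: int = 8
    grid: tuple = (20, 20, 10)
    # physio
    lowpass_cutoff_hz: float = 1.0
    lowpass_order: int = 4
    detrend_order: int = 3
    peak_min_interval_s: float = 2.0
    peak_outlier_mad_k: float = 3.0
    # conditioning
    smooth_fwhm_mm: float = 4.0
    highpass_cutoff_hz: float = 0.01
    highpass_order: int = 4
    qc_mean_fd_limit_mm: float = 0.2
    qc_max_disp_voxels: float = 1.0
    motion_mean_fd_mm: float = 0.1
    # lag mapping
    lag_min_s: float = -30.0
    lag_max_s: float = 0.0
    lag_step_s: float = 0.5
    fixed_n: bool = False
    # thresholds
    breathhold_p: float = 0.001
    surrogate_n: int = 5000
    surrogate_voxels: int = 5000
    surrogate_p: float = 0.05
    # design-decision alternative flags
    residual_permutation_per_voxel: bool = False
    variance_explained_significant_only: bool = False
    csf_delta_relative: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lag_min_s >= self.lag_max_s:
            raise ParameterError("lag_min_s must be below lag_max_s")
        if self.lag_step_s <= 0:
            raise ParameterError("lag_step_s must be positive")

    @property
    def lags_s(self) -> np.ndarray:
        return np.arange(self.lag_min_s, self.lag_max_s + 1e-9, self.lag_step_s)

    def to_yaml(self, path: Path | str) -> Path:
        path = Path(path)
        d = asdict(self)
        d["contrasts"] = list(self.contrasts)
        d["grid"] = list(self.grid)
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "contrasts" in raw:
            raw["contrasts"] = tuple(raw["contrasts"])
        if "grid" in raw:
            raw["grid"] = tuple(raw["grid"])
        return cls(**raw)
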