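"""Summary metrics, map reproducibility, and between-contrast tests.

Per run: the percentage of brain voxels whose zmax exceeds the threshold,
and the variance explained (rmax^2, in %) averaged over valid voxels.
Reproducibility: similarity between two zmax maps is the Fisher
z-transformed Pearson correlation of voxelwise values within the brain,
computed within subject (run pairs), between subjects (run-averaged maps),
and across conditions (breath-hold average vs resting). Contrasts are
compared with two-tailed unpaired Mann-Whitney U tests, Bonferroni
corrected over all contrast pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, FormatError, ParameterError
from .lagmap import XCorrMap

#: One-tailed standard-normal critical value at p = 0.001, the fixed
#: breath-hold significance threshold (rounds to 3.09).
def breathhold_zthresh(p: float = 0.001) -> float:
    """Standard-normal one-tailed critical value (p = 0.001 -> 3.09)."""
    if not 0.0 < p < 1.0:
        raise ParameterError("p must be in (0, 1)")
    return float(sps.norm.isf(p))


@dataclass
class ZMap:
    """A zmax map with its validity mask (the unit of similarity analysis)."""

    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise FormatError("zmax values and validity mask shapes differ")


def _as_zmap(m) -> ZMap:
    if isinstance(m, ZMap):
        return m
    if isinstance(m, XCorrMap):
        return ZMap(m.zmax, m.valid)
    arr = np.asarray(m, dtype=float)
    return ZMap(arr, np.isfinite(arr))


@dataclass
class SummaryMetrics:
    """Per-run association summary between pETCO2 and one contrast."""

    pct_significant: float
    mean_r2_pct: float
    zthresh: float
    contrast: str
    subject: str = ""
    run: str = ""


def percent_significant(zmap, mask: np.ndarray, zthresh: float) -> float:
    """100 x |{in-mask voxels: valid and zmax > zthresh}| / |mask|."""
    zm = _as_zmap(zmap)
    mask = np.asarray(mask, dtype=bool)
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise ParameterError("empty mask")
    sig = mask & zm.valid & (np.nan_to_num(zm.values, nan=-np.inf) > zthresh)
    return 100.0 * sig.sum() / n_mask


def mean_variance_explained(xmap: XCorrMap, mask: np.ndarray | None = None) -> float:
    """Mean rmax^2 over valid in-mask voxels, as a percentage.

    Voxels excluded by the lag-boundary rule are omitted (not zero-filled).
    """
    mask = xmap.mask if mask is None else np.asarray(mask, dtype=bool)
    sel = mask & xmap.valid & np.isfinite(xmap.rmax)
    if not sel.any():
        raise DataError("no valid voxels for variance explained")
    return float(100.0 * np.mean(xmap.rmax[sel] ** 2))


def summarize_run(xmap: XCorrMap, mask: np.ndarray, zthresh: float,
                  contrast: str = "", subject: str = "", run: str = "") -> SummaryMetrics:
    return SummaryMetrics(
        pct_significant=percent_significant(xmap, mask, zthresh),
        mean_r2_pct=mean_variance_explained(xmap, mask),
        zthresh=zthresh,
        contrast=contrast or xmap.meta.get("contrast", ""),
        subject=subject,
        run=run,
    )


def average_subject_maps(maps: Sequence) -> ZMap:
    """Voxelwise mean of a subject's run maps; valid only where all are valid."""
    zmaps = [_as_zmap(m) for m in maps]
    if not zmaps:
        raise ParameterError("no maps to average")
    shape = zmaps[0].values.shape
    for zm in zmaps:
        if zm.values.shape != shape:
            raise FormatError("maps are not on a shared grid")
    valid = np.logical_and.reduce([zm.valid for zm in zmaps])
    stack = np.stack([np.nan_to_num(zm.values) for zm in zmaps])
    mean = np.where(valid, stack.mean(axis=0), np.nan)
    return ZMap(mean, valid)


def map_similarity(map_a, map_b, mask: np.ndarray | None = None,
                   min_shared: int = 10) -> float:
    """Fisher z-transformed Pearson correlation of two maps' voxel values.

    Computed over jointly valid in-mask voxels. Constant inputs raise; a
    correlation at machine |r| = 1 (e.g. duplicated maps) is clipped to a
    large finite z and flagged with a degenerate-similarity warning.
    """
    a, b = _as_zmap(map_a), _as_zmap(map_b)
    if a.values.shape != b.values.shape:
        raise FormatError("maps are not on a shared grid")
    sel = a.valid & b.valid & np.isfinite(a.values) & np.isfinite(b.values)
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool)
    if sel.sum() < min_shared:
        raise DataError(f"fewer than {min_shared} shared valid voxels")
    x, y = a.values[sel], b.values[sel]
    if x.std() == 0 or y.std() == 0:
        raise DataError("constant map: similarity undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-12:
        warnings.warn("degenerate-high similarity (|r| = 1); clipping before atanh")
    r = float(np.clip(r, -(1.0 - 1e-12), 1.0 - 1e-12))
    return float(np.arctanh(r))


@dataclass
class MapRecord:
    """One zmax map with its cohort labels."""

    subject: str
    condition: str  # 'breathhold' or 'resting'
    run: str
    zmap: ZMap


def similarity_suite(records: Sequence[MapRecord],
                     mask: np.ndarray | None = None) -> dict:
    """Intra-subject, inter-subject, and cross-condition map similarity.

    intra: per subject, mean pairwise similarity between its breath-hold
    runs. inter: per subject and condition, mean similarity from its
    (run-averaged) map to every other subject's. cross_condition: per
    subject, breath-hold average vs resting map. Subjects with missing
    runs are skipped with a warning.
    """
    subjects = sorted({r.subject for r in records})
    by_subj_cond: dict = {}
    for rec in records:
        by_subj_cond.setdefault((rec.subject, rec.condition), []).append(rec)

    intra_rows = []
    for s in subjects:
        bh = by_subj_cond.get((s, "breathhold"), [])
        if len(bh) >= 2:
            sims = [
                map_similarity(a.zmap, b.zmap, mask)
                for a, b in combinations(bh, 2)
            ]
            intra_rows.append({"subject": s, "similarity_z": float(np.mean(sims))})
        elif bh:
            warnings.warn(f"subject {s}: only one breath-hold run, intra-subject skipped")

    averaged: dict = {}
    for (s, cond), recs in by_subj_cond.items():
        averaged[(s, cond)] = average_subject_maps([r.zmap for r in recs])

    inter_rows = []
    for cond in sorted({c for (_, c) in averaged}):
        subj_maps = {s: m for (s, c), m in averaged.items() if c == cond}
        if len(subj_maps) < 2:
            continue
        for s, m in subj_maps.items():
            sims = [
                map_similarity(m, other, mask)
                for so, other in subj_maps.items()
                if so != s
            ]
            inter_rows.append(
                {"subject": s, "condition": cond, "similarity_z": float(np.mean(sims))}
            )

    cross_rows = []
    for s in subjects:
        bh = averaged.get((s, "breathhold"))
        rs = averaged.get((s, "resting"))
        if bh is None or rs is None:
            continue
        cross_rows.append(
            {"subject": s, "similarity_z": map_similarity(bh, rs, mask)}
        )

    return {
        "intra_subject": pd.DataFrame(intra_rows, columns=["subject", "similarity_z"]),
        "inter_subject": pd.DataFrame(
            inter_rows, columns=["subject", "condition", "similarity_z"]
        ),
        "cross_condition": pd.DataFrame(cross_rows, columns=["subject", "similarity_z"]),
    }


def pairwise_tests(groups: Mapping[str, Sequence[float]],
                   min_per_group: int = 3) -> pd.DataFrame:
    """Two-tailed unpaired Mann-Whitney U for every contrast pair, Bonferroni.

    The Bonferroni family is all tested pairs within this metric; corrected
    p values are capped at 1. Groups with fewer than ``min_per_group``
    values are skipped with a warning.
    """
    eligible = {}
    for name, vals in groups.items():
        vals = np.asarray(list(vals), dtype=float)
        if vals.size < min_per_group:
            warnings.warn(f"group {name!r} has fewer than {min_per_group} values; skipped")
            continue
        eligible[name] = vals
    pairs = list(combinations(sorted(eligible), 2))
    rows = []
    for a, b in pairs:
        res = sps.mannwhitneyu(eligible[a], eligible[b], alternative="two-sided")
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "U": float(res.statistic),
                "p_raw": float(res.pvalue),
                "p_bonferroni": float(min(1.0, res.pvalue * len(pairs))),
            }
        )
    return pd.DataFrame(rows, columns=["group_a", "group_b", "U", "p_raw", "p_bonferroni"])


def metrics_table(metrics: Sequence[SummaryMetrics]) -> pd.DataFrame:
    """Long-format metrics table (subject, run, contrast, metric, value)."""
    rows = []
    for m in metrics:
        for metric, value in (
            ("pct_significant", m.pct_significant),
            ("mean_r2_pct", m.mean_r2_pct),
        ):
            rows.append(
                {
                    "subject": m.subject,
                    "run": m.run,
                    "contrast": m.contrast,
                    "metric": metric,
                    "value": value,
                    "zthresh": m.zthresh,
                }
            )
    return pd.DataFrame(
        rows, columns=["subject", "run", "contrast", "metric", "value", "zthresh"]
    )
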