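"""Segmentation accuracy metrics (DSC, ICC, ASD) and method comparison.

Three complementary metrics compare a predicted mask against a reference:

* **DSC** — volumetric overlap ``2|A∩B| / (|A|+|B|)``;
* **ICC** — intra-class correlation ICC(3,1) (two-way mixed, consistency,
  single measure) of the paired voxel values inside an analysis region
  (default: the union bounding box dilated by 5 voxels — the full volume is
  background-dominated and uninformative);
* **ASD** — average surface distance in mm: the symmetric mean of the two
  directed mean nearest-surface distances, surfaces taken as foreground
  voxels with at least one 6-connected background neighbour.

Undefined values (empty masks, zero variance) are reported as NaN with a
reason code — never silently zero — and excluded from aggregates.
:func:`compare_methods` runs a one-way ANOVA per structure x metric across
segmentation methods with Benjamini-Hochberg adjustment over the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .io_prep import LabelMap

__all__ = [
    "dsc",
    "icc",
    "asd",
    "evaluate_pair",
    "aggregate_reports",
    "compare_methods",
    "MetricReport",
    "STRUCTURE_NAMES",
]

#: default label-code -> structure-name mapping
STRUCTURE_NAMES = {
    1: "left_hippocampus",
    2: "right_hippocampus",
    3: "left_amygdala",
    4: "right_amygdala",
}

METRICS = ("dsc", "icc", "asd")


def _as_bool(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    return a.astype(bool)


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient; NaN when both masks are empty."""
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return float("nan")
    return 2.0 * int((a & b).sum()) / (sa + sb)


def _default_roi(a: np.ndarray, b: np.ndarray, dilate: int = 5) -> np.ndarray:
    union = a | b
    if not union.any():
        return np.ones_like(a, dtype=bool)
    sl = ndimage.find_objects(union.astype(np.int8))[0]
    roi = np.zeros_like(a, dtype=bool)
    sl = tuple(slice(max(0, s.start - dilate), min(n, s.stop + dilate))
               for s, n in zip(sl, a.shape))
    roi[sl] = True
    return roi


def icc(a: np.ndarray, b: np.ndarray, roi: Optional[np.ndarray] = None) -> float:
    """ICC(3,1) of paired voxel values within the analysis region.

    Two-way mixed model, consistency, single measure:
    ``(MSR - MSE) / (MSR + (k-1) MSE)`` with k = 2 raters and voxels as
    targets.  NaN when the pairs carry no variance.
    """
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    if roi is None:
        roi = _default_roi(a, b)
    if not roi.any():
        raise ValueError("empty analysis region")
    x = np.stack([a[roi], b[roi]], axis=1).astype(np.float64)  # (n, k)
    n, k = x.shape
    grand = x.mean()
    row_mean = x.mean(axis=1)
    col_mean = x.mean(axis=0)
    sst = ((x - grand) ** 2).sum()
    ssr = k * ((row_mean - grand) ** 2).sum()
    ssc = n * ((col_mean - grand) ** 2).sum()
    sse = sst - ssr - ssc
    if n < 2 or sst == 0:
        return float("nan")
    msr = ssr / (n - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)


def _surface(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with >= 1 background face-neighbour (6-connectivity)."""
    st = ndimage.generate_binary_structure(mask.ndim, 1)
    eroded = ndimage.binary_erosion(mask, st, border_value=0)
    return mask & ~eroded


def asd(a: np.ndarray, b: np.ndarray, spacing: Sequence[float] = (1.0, 1.0, 1.0)) -> float:
    """Average surface distance in mm (symmetric mean of directed means)."""
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        return float("nan")
    sa, sb = _surface(a), _surface(b)
    # distance of every voxel to the nearest surface voxel of the other mask
    d_to_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    d_to_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    d_ab = d_to_b[sa].mean()
    d_ba = d_to_a[sb].mean()
    return float((d_ab + d_ba) / 2.0)


@dataclass
class MetricReport:
    """Per-structure DSC/ICC/ASD for one prediction-reference pair."""

    values: Dict[str, Dict[str, float]]
    reasons: Dict[str, Dict[str, str]] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        rows = []
        for structure, metrics in self.values.items():
            for metric, value in metrics.items():
                rows.append({"structure": structure, "metric": metric, "value": value,
                             "reason": self.reasons.get(structure, {}).get(metric, "")})
        return pd.DataFrame(rows)


def evaluate_pair(pred: LabelMap, ref: LabelMap,
                  spacing: Optional[Sequence[float]] = None,
                  names: Mapping[int, str] = STRUCTURE_NAMES) -> MetricReport:
    """All three metrics for every non-background structure code."""
    if pred.shape != ref.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {ref.shape}")
    if pred.label_set != ref.label_set:
        raise ValueError("label-set mismatch between prediction and reference")
    spacing = spacing if spacing is not None else ref.spacing
    values: Dict[str, Dict[str, float]] = {}
    reasons: Dict[str, Dict[str, str]] = {}
    for code in sorted(ref.label_set - {0}):
        name = names.get(code, f"label_{code}")
        p = pred.codes == code
        r = ref.codes == code
        vals, why = {}, {}
        vals["dsc"] = dsc(p, r)
        if np.isnan(vals["dsc"]):
            why["dsc"] = "both masks empty"
        vals["icc"] = icc(p, r)
        if np.isnan(vals["icc"]):
            why["icc"] = "zero variance in analysis region"
        vals["asd"] = asd(p, r, spacing)
        if np.isnan(vals["asd"]):
            why["asd"] = "empty mask"
        values[name] = vals
        if why:
            reasons[name] = why
    return MetricReport(values, reasons)


def aggregate_reports(reports: Sequence[MetricReport]) -> pd.DataFrame:
    """Mean (sd) per structure x metric across subjects, NaN-excluded."""
    frames = []
    for i, rep in enumerate(reports):
        f = rep.frame()
        f["subject"] = i
        frames.append(f)
    allf = pd.concat(frames, ignore_index=True)
    out = (allf.groupby(["structure", "metric"])["value"]
           .agg(mean="mean", sd="std", n_defined="count")
           .reset_index())
    return out


def compare_methods(per_method: Mapping[str, Sequence[MetricReport]],
                    alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA across methods for every structure x metric cell.

    Every method must cover the same subjects; p values are adjusted with
    Benjamini-Hochberg across all tests in the table.
    """
    methods = list(per_method)
    if len(methods) < 2:
        raise ValueError("need at least 2 methods to compare")
    counts = {m: len(v) for m, v in per_method.items()}
    if len(set(counts.values())) != 1:
        raise ValueError(f"unequal subject counts across methods: {counts}")

    long = []
    for method, reports in per_method.items():
        for i, rep in enumerate(reports):
            f = rep.frame()
            f["method"] = method
            f["subject"] = i
            long.append(f)
    table = pd.concat(long, ignore_index=True)

    rows = []
    for (structure, metric), grp in table.groupby(["structure", "metric"]):
        groups = [grp.loc[grp["method"] == m, "value"].dropna().to_numpy()
                  for m in methods]
        if any(g.size < 2 for g in groups):
            f_stat, p = float("nan"), float("nan")
        else:
            f_stat, p = stats.f_oneway(*groups)
            f_stat = max(float(f_stat), 0.0)  # guard tiny negative rounding
            if np.isnan(p):  # zero between-group variance
                dfb = len(groups) - 1
                dfw = sum(g.size for g in groups) - len(groups)
                p = float(stats.f.sf(f_stat, dfb, dfw))
        row = {"structure": structure, "metric": metric,
               "F": float(f_stat), "p": float(p)}
        for m, g in zip(methods, groups):
            row[f"mean_{m}"] = float(np.mean(g)) if g.size else float("nan")
            row[f"sd_{m}"] = float(np.std(g, ddof=1)) if g.size > 1 else float("nan")
        rows.append(row)
    out = pd.DataFrame(rows)
    mask = out["p"].notna()
    out["p_adj"] = np.nan
    if mask.any():
        out.loc[mask, "p_adj"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    out["significant"] = out["p_adj"] < alpha
    return out
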