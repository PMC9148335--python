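"""Morphometric extraction and brain-behavior partial rank correlations.

Regional volumes are measured as voxel count x voxel volume (mm^3) and
adjusted for head size as a ratio to total brain volume (TBV); a
residualization alternative is available behind a flag.  Because Spearman
correlation is invariant to strictly increasing per-variable transforms, the
two adjustments agree whenever they induce the same subject ordering.

The association test is the Spearman rank *partial* correlation: all
variables (measure, outcome, covariates) are rank-transformed (average ranks
for ties), the ranked measure and outcome are residualized on the ranked
covariates by least squares, and the correlation of the residuals is tested
against Student's t with ``df = n - 2 - k`` covariates.

:func:`brain_behavior_matrix` computes every measure x outcome cell with a
shared covariate set and flags cells at unadjusted p < alpha (the primary
screen), co-reporting Benjamini-Hochberg adjusted flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_prep import LabelMap, VolumeImage
from .evalmetrics import STRUCTURE_NAMES

__all__ = [
    "PartialCorrResult",
    "region_volumes",
    "total_brain_volume",
    "spearman_partial",
    "brain_behavior_matrix",
    "measure_cohort",
    "DEFAULT_COVARIATES",
    "DEFAULT_OUTCOMES",
]

DEFAULT_COVARIATES = ("pma_weeks", "maternal_education", "epds")
DEFAULT_OUTCOMES = ("cbcl_total", "cbcl_internalizing", "cbcl_externalizing")


@dataclass
class PartialCorrResult:
    """rho, df, p for one partial correlation."""

    rho: float
    df: int
    p: float
    n: int
    covariates: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not (-1.0 <= self.rho <= 1.0) and not np.isnan(self.rho):
            raise ValueError(f"rho {self.rho} outside [-1, 1]")
        if self.df != self.n - 2 - len(self.covariates):
            raise ValueError("df must equal n - 2 - #covariates")


def total_brain_volume(vol: VolumeImage, threshold: float = 0.25) -> float:
    """TBV in mm^3 from the above-background voxels of a skull-stripped scan.

    ``threshold`` is a fraction of the robust (99th percentile) intensity.
    """
    cut = threshold * float(np.percentile(vol.voxels, 99))
    return float((vol.voxels > cut).sum()) * vol.voxel_volume_mm3()


def region_volumes(labels: LabelMap, spacing: Optional[Sequence[float]] = None,
                   tbv: Optional[float] = None,
                   names: Mapping[int, str] = STRUCTURE_NAMES) -> pd.Series:
    """Raw (mm^3) and TBV-adjusted volume per structure.

    Returns a Series with ``vol_<name>_mm3`` entries and, when ``tbv`` is
    given, dimensionless ``adj_<name>`` ratios (raw / TBV).
    """
    spacing = spacing if spacing is not None else labels.spacing
    voxvol = float(np.prod(spacing))
    if tbv is not None and tbv <= 0:
        raise ValueError("TBV must be positive")
    out = {}
    for code in sorted(labels.label_set - {0}):
        name = names.get(code, f"label_{code}")
        raw = float((labels.codes == code).sum()) * voxvol
        out[f"vol_{name}_mm3"] = raw
        if tbv is not None:
            out[f"adj_{name}"] = raw / tbv
    return pd.Series(out)


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman_partial(x: Iterable[float], y: Iterable[float],
                     covariates: Optional[np.ndarray] = None) -> PartialCorrResult:
    """Spearman rank partial correlation of x and y given covariates.

    With no covariates this reduces exactly to the plain Spearman
    correlation.  The two-sided p value comes from the t transform with
    ``df = n - 2 - k``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        Z = np.empty((x.size, 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    n, k = x.size, Z.shape[1]
    if y.size != n or Z.shape[0] != n:
        raise ValueError("x, y, covariates must share length")
    if n < k + 4:
        raise ValueError(f"need n >= {k + 4} observations, got {n}")
    for name, arr in (("x", x), ("y", y)):
        if np.ptp(arr) == 0:
            raise ValueError(f"constant input {name}")

    rx = _rank(x)
    ry = _rank(y)
    if k:
        rz = np.column_stack([_rank(Z[:, j]) for j in range(k)])
        design = np.column_stack([np.ones(n), rz])
        bx, *_ = np.linalg.lstsq(design, rx, rcond=None)
        by, *_ = np.linalg.lstsq(design, ry, rcond=None)
        ex = rx - design @ bx
        ey = ry - design @ by
    else:
        ex = rx - rx.mean()
        ey = ry - ry.mean()
    denom = np.sqrt((ex ** 2).sum() * (ey ** 2).sum())
    total = np.sqrt(((rx - rx.mean()) ** 2).sum() * ((ry - ry.mean()) ** 2).sum())
    if denom <= 1e-12 * total:
        # the covariates explain x or y completely; nothing is left to
        # correlate, so the partial association is zero by convention
        rho, df = 0.0, n - 2 - k
        return PartialCorrResult(rho, df, 1.0, n, tuple(f"z{j}" for j in range(k)))
    rho = float(np.clip((ex * ey).sum() / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrResult(rho, df, p, n, tuple(f"z{j}" for j in range(k)))


def brain_behavior_matrix(table: pd.DataFrame,
                          measures: Optional[Sequence[str]] = None,
                          outcomes: Sequence[str] = DEFAULT_OUTCOMES,
                          covariates: Sequence[str] = DEFAULT_COVARIATES,
                          alpha: float = 0.05) -> pd.DataFrame:
    """All measure x outcome partial Spearman correlations with shared
    covariates.

    ``measures`` defaults to every ``adj_*`` column.  Returns a long-format
    frame with rho, df, p, an unadjusted significance flag at ``alpha``
    (the primary screen) and a Benjamini-Hochberg adjusted flag.
    """
    if measures is None:
        measures = [c for c in table.columns if c.startswith("adj_")]
    if not measures or not len(outcomes):
        raise ValueError("need at least one measure and one outcome")
    missing = [c for c in list(covariates) + list(outcomes) + list(measures)
               if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    sub = table[list(measures) + list(outcomes) + list(covariates)].dropna()
    Z = sub[list(covariates)].to_numpy()
    rows = []
    for m in measures:
        for oc in outcomes:
            res = spearman_partial(sub[m].to_numpy(), sub[oc].to_numpy(), Z)
            rows.append({"measure": m, "outcome": oc, "rho": res.rho,
                         "df": res.df, "p": res.p, "n": res.n})
    out = pd.DataFrame(rows)
    out["significant"] = out["p"] < alpha
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant_adj"] = out["p_adj"] < alpha
    out.attrs["covariates"] = tuple(covariates)
    out.attrs["alpha"] = alpha
    return out


def measure_cohort(cohort, table: pd.DataFrame,
                   adjust: str = "ratio") -> pd.DataFrame:
    """Measure volumes from a cohort's label maps and join the behavior table.

    ``cohort`` is any sequence of ``(VolumeImage, LabelMap)``; subjects are
    measured one at a time (lazy cohorts never hold more than one volume).
    ``adjust='ratio'`` divides by TBV; ``adjust='residual'`` residualizes the
    raw volume on TBV across subjects (rank-equivalent when the adjustment is
    monotone in the subject ordering).
    """
    if adjust not in ("ratio", "residual"):
        raise ValueError("adjust must be 'ratio' or 'residual'")
    rows = []
    for i in range(len(cohort)):
        vol, labels = cohort[i]
        tbv = total_brain_volume(vol)
        rv = region_volumes(labels, tbv=tbv if adjust == "ratio" else None)
        rv["tbv_measured_mm3"] = tbv
        rows.append(rv)
    measured = pd.DataFrame(rows)
    if adjust == "residual":
        tbv = measured["tbv_measured_mm3"].to_numpy()
        design = np.column_stack([np.ones(tbv.size), tbv])
        for col in [c for c in measured.columns if c.startswith("vol_")]:
            v = measured[col].to_numpy()
            beta, *_ = np.linalg.lstsq(design, v, rcond=None)
            measured["adj_" + col[len("vol_"):-len("_mm3")]] = v - design @ beta
    out = pd.concat([table.reset_index(drop=True), measured], axis=1)
    return out
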