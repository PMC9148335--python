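"""STAPLE consensus fusion of multiple raters' segmentations.

STAPLE (Simultaneous Truth And Performance Level Estimation) treats the
unknown true binary segmentation as a latent variable and each rater j as a
noisy channel with sensitivity ``p_j`` and specificity ``q_j``.  EM
alternates between

* **E step** — the posterior probability ``W_i`` that voxel i is foreground,
  combining the global foreground prior with each rater's vote through
  (p_j, q_j);
* **M step** — re-estimating ``p_j = sum_i W_i D_ij / sum_i W_i`` and
  ``q_j = sum_i (1-W_i)(1-D_ij) / sum_i (1-W_i)``.

Iterations stop when the largest change in any (p_j, q_j) falls below ``tol``.
The observed-data log-likelihood is recorded each iteration and is
non-decreasing (a property the tests assert).

Multi-label consensus runs the binary algorithm per structure and assigns
each voxel the label with the highest posterior among those >= 0.5.  By
default the computation is restricted to the union mask's bounding box
dilated by 5 voxels: with a global prior, the vast all-background exterior
would otherwise dominate the specificity estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_prep import LabelMap

__all__ = [
    "RaterStack",
    "StapleResult",
    "staple_binary",
    "consensus_multilabel",
    "interrater_qc",
]

_CLAMP = 1e-5


@dataclass
class RaterStack:
    """k binary masks of one structure on a common grid."""

    masks: np.ndarray  # (k, *grid) bool
    rater_ids: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks).astype(bool)
        if self.masks.ndim < 2 or self.masks.shape[0] < 2:
            raise ValueError("need at least 2 raters on a common grid")
        if not self.rater_ids:
            self.rater_ids = tuple(f"rater{j + 1}" for j in range(self.masks.shape[0]))
        if len(self.rater_ids) != self.masks.shape[0]:
            raise ValueError("rater_ids length mismatch")


@dataclass
class StapleResult:
    """Posterior field, per-rater performance, and convergence diagnostics."""

    posterior: np.ndarray
    sensitivity: np.ndarray  # p_j
    specificity: np.ndarray  # q_j
    iterations: int
    converged: bool
    log_likelihood: List[float] = field(default_factory=list)
    prior: float = 0.5

    @property
    def consensus(self) -> np.ndarray:
        """Consensus mask: posterior >= 0.5 (ties count as foreground)."""
        return self.posterior >= 0.5


def _roi_slices(union: np.ndarray, dilate: int) -> Tuple[slice, ...]:
    sl = ndimage.find_objects(union.astype(np.int8))[0]
    return tuple(slice(max(0, s.start - dilate), min(n, s.stop + dilate))
                 for s, n in zip(sl, union.shape))


def staple_binary(stack: Union[RaterStack, np.ndarray], prior="auto",
                  tol: float = 1e-6, max_iter: int = 100,
                  roi: Optional[str] = "union-dilate:5") -> StapleResult:
    """Binary STAPLE via EM.

    Parameters
    ----------
    stack : RaterStack or (k, ...) bool array
    prior : "auto" or float in (0, 1)
        Spatially constant foreground prior; "auto" uses the mean foreground
        fraction across raters (within the ROI).
    roi : "union-dilate:<n>", "full", or None
        Restrict computation to the union bounding box dilated by n voxels;
        the posterior outside is 0 and raters' performance is estimated
        inside only.

    Raises
    ------
    ValueError
        If no rater marks any voxel, or every rater marks every voxel.
    """
    if not isinstance(stack, RaterStack):
        stack = RaterStack(np.asarray(stack))
    masks = stack.masks
    k = masks.shape[0]
    grid_shape = masks.shape[1:]

    union = masks.any(axis=0)
    if not union.any():
        raise ValueError("degenerate stack: no rater marks any voxel")
    if masks.all():
        raise ValueError("degenerate stack: every rater marks every voxel")

    full_slices = tuple(slice(None) for _ in grid_shape)
    if roi and roi != "full":
        if not roi.startswith("union-dilate:"):
            raise ValueError(f"unknown roi spec {roi!r}")
        dilate = int(roi.split(":", 1)[1])
        slices = _roi_slices(union, dilate)
    else:
        slices = full_slices
    D = masks[(slice(None),) + slices].reshape(k, -1).astype(np.float64)  # (k, n)
    n = D.shape[1]

    if prior == "auto":
        gamma = float(D.mean())
    else:
        gamma = float(prior)
    if not (0.0 < gamma < 1.0):
        raise ValueError(f"degenerate prior {gamma}")

    p = np.full(k, 1.0 - _CLAMP)
    q = np.full(k, 1.0 - _CLAMP)
    w = np.empty(n)
    ll_trace: List[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step in log space for numerical safety
        log_a = np.log(gamma) + (np.log(p) @ D + np.log1p(-p) @ (1.0 - D))
        log_b = np.log1p(-gamma) + (np.log(q) @ (1.0 - D) + np.log1p(-q) @ D)
        m = np.maximum(log_a, log_b)
        a = np.exp(log_a - m)
        b = np.exp(log_b - m)
        w = a / (a + b)
        ll_trace.append(float((m + np.log(a + b)).sum()))

        sw = w.sum()
        swc = n - sw
        p_new = (D @ w) / sw if sw > 0 else p
        q_new = ((1.0 - D) @ (1.0 - w)) / swc if swc > 0 else q
        p_new = np.clip(p_new, _CLAMP, 1.0 - _CLAMP)
        q_new = np.clip(q_new, _CLAMP, 1.0 - _CLAMP)
        delta = max(np.abs(p_new - p).max(), np.abs(q_new - q).max())
        p, q = p_new, q_new
        if delta < tol:
            converged = True
            break

    posterior = np.zeros(grid_shape, dtype=np.float64)
    posterior[slices] = w.reshape(posterior[slices].shape)
    return StapleResult(posterior, p, q, it, converged, ll_trace, gamma)


def consensus_multilabel(maps: Sequence[LabelMap], **kwargs) -> LabelMap:
    """Per-structure binary STAPLE, then highest-posterior label assignment.

    Each voxel receives the label with the largest posterior among those with
    posterior >= 0.5, otherwise background.  Invariant to rater order.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 raters")
    label_set = maps[0].label_set
    shape = maps[0].shape
    for m in maps[1:]:
        if m.label_set != label_set:
            raise ValueError("inconsistent label sets across raters")
        if m.shape != shape:
            raise ValueError("raters do not share a grid")

    best_post = np.zeros(shape)
    codes = np.zeros(shape, dtype=np.int16)
    for code in sorted(label_set - {0}):
        stack = np.stack([m.codes == code for m in maps])
        if not stack.any():
            continue
        result = staple_binary(stack, **kwargs)
        take = (result.posterior >= 0.5) & (result.posterior > best_post)
        codes[take] = code
        best_post = np.maximum(best_post, np.where(result.posterior >= 0.5,
                                                   result.posterior, 0.0))
    return LabelMap(codes, label_set, maps[0].spacing)


def interrater_qc(maps: Sequence[LabelMap], threshold: float = 0.6) -> pd.DataFrame:
    """Mean pairwise Dice per structure with a pass/fail flag.

    A structure passes when its mean pairwise DSC >= threshold (inclusive).
    Structures empty in every rater are flagged undefined, not an error.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 raters")
    from .evalmetrics import dsc

    label_set = maps[0].label_set
    rows = []
    for code in sorted(label_set - {0}):
        scores = []
        for i in range(len(maps)):
            for j in range(i + 1, len(maps)):
                scores.append(dsc(maps[i].codes == code, maps[j].codes == code))
        scores = np.asarray(scores, dtype=float)
        defined = ~np.isnan(scores)
        mean = float(scores[defined].mean()) if defined.any() else float("nan")
        rows.append({
            "structure_code": code,
            "mean_pairwise_dsc": mean,
            "n_pairs": int(defined.sum()),
            "undefined": not defined.any(),
            "passed": bool(defined.any() and mean >= threshold),
        })
    out = pd.DataFrame(rows)
    out.attrs["threshold"] = threshold
    out.attrs["all_passed"] = bool(out["passed"].all() and not out["undefined"].any())
    return out
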