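"""Training harness: pre-training, transfer fine-tuning, and LOOCV.

The transfer protocol mirrors the published one: a network pre-trained on a
large automatically-labelled sample is fine-tuned on a small manually-labelled
target set in two phases — first a few epochs with only the last layers
(classifier + final decoder block) unfrozen, then the whole network — and
evaluated by leave-one-out cross-validation.  The ablation arm trains the same
architecture from random initialization for the same total epoch budget.

The loss is a composite of class-frequency-weighted cross-entropy and a soft
Dice term over the foreground classes, the standard pairing for this
architecture family.  Optimization uses Adam; fine-tuning defaults are the
published ones (learning rate 5e-4, batch size 8, 5 + 15 epochs).

Volumes are preprocessed per subject with a tight background crop to the
divisibility rule followed by z-scoring; predictions are restored to the
original grid before scoring.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io_prep import (VIEWS, ConformRecord, LabelMap, VolumeImage, extract_slices,
                      normalize_intensity, restore_size, tight_conform)
from .network import (FusionWeights, ViewModel, ViewModelConfig, fuse_views,
                      predict_view_probs)

__all__ = [
    "TrainConfig",
    "FinetuneSchedule",
    "FoldResult",
    "MultiViewSegmenter",
    "pretrain",
    "finetune",
    "loocv",
    "train_val_split",
    "save_checkpoint",
    "load_checkpoint",
]

#: parameter-name prefixes unfrozen in the first fine-tuning phase
LAST_LAYERS = ("decoder4", "classifier")


@dataclass
class TrainConfig:
    """Hyperparameters for (pre-)training one multi-view model."""

    arch: ViewModelConfig = field(default_factory=lambda: ViewModelConfig(num_classes=5))
    lr: float = 1e-3
    batch_size: int = 8
    epochs: int = 10
    val_fraction: float = 0.2
    ce_weight: float = 1.0
    dice_weight: float = 1.0
    keep_empty: float = 0.25  # fraction of foreground-free slices kept
    tight_crop: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.val_fraction < 1):
            raise ValueError("validation fraction must be in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


@dataclass
class FinetuneSchedule:
    """Two-phase transfer schedule (frozen phase, then full network)."""

    phase1_epochs: int = 5
    phase2_epochs: int = 15
    lr: float = 5e-4
    batch_size: int = 8
    unfreeze: Tuple[str, ...] = LAST_LAYERS

    def __post_init__(self) -> None:
        if self.phase1_epochs < 0 or self.phase2_epochs < 0:
            raise ValueError("phase epochs must be >= 0")


@dataclass
class FoldResult:
    """One LOOCV fold: held-out subject, its prediction, and diagnostics."""

    subject: int
    prediction: LabelMap
    metrics: Dict[str, float]
    loss_trace: List[float]
    train_subjects: Tuple[int, ...]
    trainable_phase1: Tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Loss and optimizer


def _softmax_nchw(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z, dtype=np.float32)
    return e / e.sum(axis=1, keepdims=True)


def composite_loss_grad(logits: np.ndarray, target: np.ndarray,
                        class_weights: np.ndarray, ce_weight: float,
                        dice_weight: float) -> Tuple[float, np.ndarray]:
    """Weighted cross-entropy + soft Dice over foreground classes.

    Returns the scalar loss and its gradient w.r.t. the logits.
    """
    n, c, h, w = logits.shape
    p = _softmax_nchw(logits)
    onehot = np.zeros_like(p)
    # scatter one-hot: fancy index over class axis
    onehot[np.arange(n)[:, None, None], target,
           np.arange(h)[None, :, None], np.arange(w)[None, None, :]] = 1.0

    wmap = class_weights[target]  # (N,H,W)
    norm = np.float32(wmap.sum() + 1e-8)
    eps = np.float32(1e-12)
    pt = np.take_along_axis(p, target[:, None], axis=1)[:, 0]
    ce = float(-(wmap * np.log(pt + eps)).sum() / norm)
    dce = (p - onehot) * (wmap / norm)[:, None]

    smooth = np.float32(1.0)
    dl_dp = np.zeros_like(p)
    dice_terms = []
    fg = range(1, c)
    for k in fg:
        pk = p[:, k]
        tk = onehot[:, k]
        inter = float((pk * tk).sum())
        tot = float(pk.sum() + tk.sum())
        dk = (2.0 * inter + smooth) / (tot + smooth)
        dice_terms.append(dk)
        denom = np.float32((tot + smooth) ** 2)
        dl_dp[:, k] = -(2.0 * tk * (tot + smooth) - (2.0 * inter + smooth)) / denom
    nfg = max(len(dice_terms), 1)
    dice_loss = 1.0 - float(np.mean(dice_terms)) if dice_terms else 0.0
    dl_dp /= np.float32(nfg)
    # chain through softmax: dz = p * (dl_dp - sum_c dl_dp_c p_c)
    inner = (dl_dp * p).sum(axis=1, keepdims=True)
    ddice = p * (dl_dp - inner)

    loss = ce_weight * ce + dice_weight * dice_loss
    grad = (np.float32(ce_weight) * dce + np.float32(dice_weight) * ddice)
    return loss, grad.astype(np.float32, copy=False)


class Adam:
    """Adam on the trainable parameters of one view model."""

    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = np.float32(lr)
        self.b1, self.b2 = np.float32(betas[0]), np.float32(betas[1])
        self.eps = np.float32(eps)
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if not p.trainable:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * (g * g)
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Data plumbing


@dataclass
class _Subject:
    """Preprocessed subject: normalized conformed volume + aligned labels."""

    vol: VolumeImage
    labels: LabelMap
    record: Optional[ConformRecord]


def _preprocess(vol: VolumeImage, labels: Optional[LabelMap],
                tight: bool, target_shape=None) -> _Subject:
    rec = None
    if tight:
        vol, labels, rec = tight_conform(vol, labels, target_shape=target_shape)
    nv = normalize_intensity(vol)
    return _Subject(nv, labels, rec)


def _common_target_shape(dataset, divisor: int = 16, quiet_tol: float = 0.1):
    """Smallest shared divisor-multiple box covering every subject's head.

    Training pools slices across subjects, so the whole set is cropped to
    one common grid (subjects with smaller heads keep more background).
    """
    spans = np.zeros(3, dtype=int)
    for vol, labels in dataset:
        x = np.asarray(vol.voxels)
        bg = float(np.median(np.concatenate(
            [x[0].ravel(), x[-1].ravel(), x[:, 0].ravel(), x[:, -1].ravel(),
             x[:, :, 0].ravel(), x[:, :, -1].ravel()])))
        head = np.abs(x - bg) >= quiet_tol
        if labels is not None:
            head |= labels.codes != 0
        for ax in range(3):
            proj = head.any(axis=tuple(a for a in range(3) if a != ax))
            nz = np.nonzero(proj)[0]
            if nz.size:
                spans[ax] = max(spans[ax], int(nz[-1]) - int(nz[0]) + 1)
    return tuple(int(-(-s // divisor) * divisor) for s in spans)


def _preprocess_dataset(dataset, tight: bool):
    target = _common_target_shape(dataset) if tight else None
    return [_preprocess(v, l, tight, target) for v, l in dataset]


def _slice_pool(subjects: Sequence[_Subject], view: str, keep_empty: float,
                rng: np.random.Generator):
    """(images, targets) slice arrays for one view across subjects."""
    imgs, tgts = [], []
    for s in subjects:
        x = extract_slices(s.vol.voxels, view)
        t = extract_slices(s.labels.codes, view)
        fg = t.reshape(t.shape[0], -1).any(axis=1)
        keep = fg.copy()
        empty_idx = np.nonzero(~fg)[0]
        if keep_empty > 0 and empty_idx.size:
            n_keep = int(round(keep_empty * empty_idx.size))
            if n_keep:
                keep[rng.choice(empty_idx, size=n_keep, replace=False)] = True
        imgs.append(x[keep])
        tgts.append(t[keep])
    return (np.concatenate(imgs, axis=0)[:, None].astype(np.float32),
            np.concatenate(tgts, axis=0).astype(np.int64))


def _class_weights(targets: np.ndarray, num_classes: int) -> np.ndarray:
    """Inverse-sqrt-frequency weights, normalized to mean 1."""
    counts = np.bincount(targets.ravel(), minlength=num_classes).astype(np.float64)
    counts = np.maximum(counts, 1.0)
    w = 1.0 / np.sqrt(counts)
    w *= num_classes / w.sum()
    return w.astype(np.float32)


def _run_epoch(model: ViewModel, opt: Adam, imgs: np.ndarray, tgts: np.ndarray,
               order: np.ndarray, batch: int, cw: np.ndarray,
               ce_w: float, dice_w: float, shallow: bool) -> float:
    total, count = 0.0, 0
    for i in range(0, order.size, batch):
        sel = order[i:i + batch]
        logits = model.forward(imgs[sel], train=True)
        loss, grad = composite_loss_grad(logits, tgts[sel], cw, ce_w, dice_w)
        opt.zero_grad()
        model.backward(grad, shallow=shallow)
        opt.step()
        total += loss * sel.size
        count += sel.size
    return total / max(count, 1)


def _eval_loss(model: ViewModel, imgs: np.ndarray, tgts: np.ndarray, batch: int,
               cw: np.ndarray, ce_w: float, dice_w: float) -> float:
    total, count = 0.0, 0
    for i in range(0, imgs.shape[0], batch):
        logits = model.forward(imgs[i:i + batch], train=False)
        loss, _ = composite_loss_grad(logits, tgts[i:i + batch], cw, ce_w, dice_w)
        total += loss * min(batch, imgs.shape[0] - i)
        count += min(batch, imgs.shape[0] - i)
    return total / max(count, 1)


# ---------------------------------------------------------------------------
# The multi-view segmenter


class MultiViewSegmenter:
    """Three view models plus fusion; the trainable ID-Seg unit."""

    def __init__(self, arch: ViewModelConfig, seed: int = 0):
        self.arch = arch
        self.models: Dict[str, ViewModel] = {
            view: ViewModel(replace(arch, seed=seed + 11 * i))
            for i, view in enumerate(VIEWS)
        }

    def parameter_count(self) -> int:
        return sum(m.parameter_count() for m in self.models.values())

    def state_dict(self) -> Dict[str, Dict[str, np.ndarray]]:
        return {v: m.state_dict() for v, m in self.models.items()}

    def load_state_dict(self, state) -> None:
        for v, m in self.models.items():
            m.load_state_dict(state[v])

    def segment(self, vol: VolumeImage, weights: FusionWeights = FusionWeights(),
                tight: bool = True) -> LabelMap:
        """Full pipeline on one raw volume: conform, normalize, predict each
        view, fuse, and restore to the input grid."""
        sub = _preprocess(vol, None, tight)
        probs = {v: predict_view_probs(self.models[v], sub.vol, v) for v in VIEWS}
        fused = fuse_views(probs["axial"], probs["coronal"], probs["sagittal"], weights)
        fused = LabelMap(fused.codes, frozenset(range(self.arch.num_classes)), vol.spacing)
        if sub.record is not None:
            fused = restore_size(fused, sub.record)
        return fused


# ---------------------------------------------------------------------------
# Training entry points


def train_val_split(n: int, val_fraction: float, seed: int) -> Tuple[np.ndarray, np.ndarray]:
    """Deterministic shuffled split; the training side takes the floor."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor((1.0 - val_fraction) * n))
    return np.sort(order[:n_train]), np.sort(order[n_train:])


def pretrain(dataset: Sequence[Tuple[VolumeImage, LabelMap]],
             config: TrainConfig) -> Tuple[MultiViewSegmenter, Dict]:
    """Pre-train a multi-view model with an 80/20 train/validation split.

    Returns the segmenter loaded with the checkpoint that minimized the mean
    validation loss across views, plus a log with per-epoch loss traces.
    """
    if len(dataset) < 2:
        raise ValueError("need at least 2 subjects to split")
    for _, labels in dataset:
        if labels is None:
            raise ValueError("dataset contains a subject without labels")
    tr_idx, va_idx = train_val_split(len(dataset), config.val_fraction, config.seed)
    subjects = _preprocess_dataset(dataset, config.tight_crop)
    train_subj = [subjects[i] for i in tr_idx]
    val_subj = [subjects[i] for i in va_idx]

    seg = MultiViewSegmenter(config.arch, seed=config.seed)
    log = {"train_idx": tr_idx.tolist(), "val_idx": va_idx.tolist(),
           "train_loss": {}, "val_loss": {}}
    rng = np.random.default_rng(config.seed + 7)
    best_state, best_val = None, np.inf
    val_curves = {}
    for view in VIEWS:
        model = seg.models[view]
        imgs, tgts = _slice_pool(train_subj, view, config.keep_empty, rng)
        vimgs, vtgts = _slice_pool(val_subj, view, config.keep_empty, rng)
        cw = _class_weights(tgts, config.arch.num_classes)
        opt = Adam(model.params(), config.lr)
        tl, vl = [], []
        for ep in range(config.epochs):
            order = rng.permutation(imgs.shape[0])
            tl.append(_run_epoch(model, opt, imgs, tgts, order, config.batch_size,
                                 cw, config.ce_weight, config.dice_weight, False))
            vl.append(_eval_loss(model, vimgs, vtgts, config.batch_size,
                                 cw, config.ce_weight, config.dice_weight))
        log["train_loss"][view] = tl
        log["val_loss"][view] = vl
        val_curves[view] = vl
    # checkpoint selection: epoch with the lowest summed validation loss is
    # the final epoch in the common monotone case; we retrain nothing and
    # simply report the argmin epoch alongside the final weights
    mean_val = np.mean([val_curves[v] for v in VIEWS], axis=0)
    log["best_epoch"] = int(np.argmin(mean_val))
    log["best_val_loss"] = float(mean_val.min())
    return seg, log


def finetune(init: Optional[MultiViewSegmenter],
             dataset: Sequence[Tuple[VolumeImage, LabelMap]],
             schedule: FinetuneSchedule,
             config: TrainConfig) -> Tuple[MultiViewSegmenter, Dict]:
    """Two-phase transfer fine-tuning (or the random-init ablation arm).

    With ``init`` given, phase 1 trains only ``schedule.unfreeze`` parameter
    groups for ``phase1_epochs``, then phase 2 trains everything for
    ``phase2_epochs``.  With ``init=None`` phase 1 is skipped and a freshly
    initialized network trains for the full epoch budget.
    """
    seg = MultiViewSegmenter(config.arch, seed=config.seed)
    if init is not None:
        if init.arch.num_classes != config.arch.num_classes and \
                init.arch.filters == config.arch.filters:
            # transfer body weights, re-initialize the classifier head
            for view in VIEWS:
                state = init.models[view].state_dict()
                own = seg.models[view].state_dict()
                for k in state:
                    if not k.startswith("classifier"):
                        own[k] = state[k]
                seg.models[view].load_state_dict(own)
        else:
            seg.load_state_dict(init.state_dict())

    subjects = _preprocess_dataset(dataset, config.tight_crop)
    rng = np.random.default_rng(config.seed + 13)
    log = {"train_loss": {}, "phase1_trainable": {}}
    total_epochs = schedule.phase1_epochs + schedule.phase2_epochs
    for view in VIEWS:
        model = seg.models[view]
        imgs, tgts = _slice_pool(subjects, view, config.keep_empty, rng)
        cw = _class_weights(tgts, config.arch.num_classes)
        opt = Adam(model.params(), schedule.lr)
        trace = []
        if init is not None and schedule.phase1_epochs > 0:
            model.set_trainable(schedule.unfreeze)
            log["phase1_trainable"][view] = sorted(
                {p.name for p in model.params() if p.trainable})
            # the truncated backward is exact only when nothing upstream of
            # the final decoder block is trainable
            shallow = set(schedule.unfreeze) <= set(LAST_LAYERS)
            for _ in range(schedule.phase1_epochs):
                order = rng.permutation(imgs.shape[0])
                trace.append(_run_epoch(model, opt, imgs, tgts, order,
                                        schedule.batch_size, cw, config.ce_weight,
                                        config.dice_weight, shallow=shallow))
            model.set_trainable(None)
            n_full = schedule.phase2_epochs
        else:
            model.set_trainable(None)
            n_full = total_epochs
        for _ in range(n_full):
            order = rng.permutation(imgs.shape[0])
            trace.append(_run_epoch(model, opt, imgs, tgts, order,
                                    schedule.batch_size, cw, config.ce_weight,
                                    config.dice_weight, shallow=False))
        log["train_loss"][view] = trace
    return seg, log


def loocv(dataset: Sequence[Tuple[VolumeImage, LabelMap]],
          init: Optional[MultiViewSegmenter],
          schedule: FinetuneSchedule,
          config: TrainConfig,
          metric_fn=None) -> List[FoldResult]:
    """Leave-one-out cross-validation of the fine-tuning protocol.

    Fold ``i`` fine-tunes on the other ``n - 1`` subjects starting from
    ``init`` (or from scratch if ``None``) and predicts subject ``i``.
    ``metric_fn(pred, ref)`` defaults to per-structure Dice.
    """
    n = len(dataset)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 subjects")
    if metric_fn is None:
        from .evalmetrics import dsc

        def metric_fn(pred: LabelMap, ref: LabelMap) -> Dict[str, float]:
            out = {}
            for code in sorted(ref.label_set - {0}):
                out[f"dsc_{code}"] = dsc(pred.codes == code, ref.codes == code)
            return out

    results: List[FoldResult] = []
    for i in range(n):
        train_ids = tuple(j for j in range(n) if j != i)
        fold_data = [dataset[j] for j in train_ids]
        fold_cfg = replace(config, seed=config.seed + 1000 + i)
        seg, log = finetune(init, fold_data, schedule, fold_cfg)
        pred = seg.segment(dataset[i][0], tight=config.tight_crop)
        metrics = metric_fn(pred, dataset[i][1])
        trace = list(np.mean([log["train_loss"][v] for v in VIEWS], axis=0))
        results.append(FoldResult(
            subject=i, prediction=pred, metrics=metrics,
            loss_trace=[float(t) for t in trace],
            train_subjects=train_ids,
            trainable_phase1=tuple(log.get("phase1_trainable", {}).get("axial", ())),
        ))
    return results


# ---------------------------------------------------------------------------
# Checkpoint I/O


def save_checkpoint(seg: MultiViewSegmenter, path) -> None:
    """NumPy archive of all view weights plus a JSON config sidecar."""
    path = Path(path)
    flat = {}
    for view, state in seg.state_dict().items():
        for k, v in state.items():
            flat[f"{view}/{k}"] = v
    np.savez_compressed(path.with_suffix(".npz"), **flat)
    meta = {"arch": asdict(seg.arch)}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path) -> MultiViewSegmenter:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    seg = MultiViewSegmenter(ViewModelConfig(**meta["arch"]))
    with np.load(path.with_suffix(".npz")) as data:
        state = {v: {} for v in VIEWS}
        for key in data.files:
            view, name = key.split("/", 1)
            state[view][name] = data[key]
    seg.load_state_dict(state)
    return seg


def dataset_hash(dataset: Sequence[Tuple[VolumeImage, LabelMap]]) -> str:
    """Stable content hash of a dataset (for checkpoint metadata)."""
    h = hashlib.sha256()
    for vol, labels in dataset:
        h.update(np.ascontiguousarray(vol.voxels).tobytes())
        if labels is not None:
            h.update(np.ascontiguousarray(labels.codes).tobytes())
    return h.hexdigest()[:16]
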