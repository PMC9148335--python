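"""Multi-view 2D dense-block segmentation networks and probability fusion.

One :class:`ViewModel` is a 2D encoder-decoder fully-convolutional network in
the QuickNAT family: four encoder stages of *dense blocks* (two 5x5
convolutions with input concatenation, then a 1x1 compression, each preceded
by batch norm and a shared single-parameter PReLU), 2x2 index-preserving max
pooling, a dense bottleneck, four decoder stages that unpool with the stored
indices and concatenate the encoder skip, and a 1x1 classifier.

Three identical view models (axial, coronal, sagittal) are trained on slices
along each principal axis; :func:`fuse_views` merges their per-voxel class
probabilities with weights ``(0.4, 0.4, 0.2)`` by default and takes the
argmax.

The default configuration reproduces the published pre-training network: 64
feature maps and an 88-class head (the 87 bilaterally-labelled structures of
the automated pre-training label space, plus background), which carries
exactly 3,520,871 trainable parameters per view and 10,562,613 for all three.
Fine-tuned segmentation heads use 5 classes (background + the four bilateral
limbic structures).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from ..io_prep import VIEW_AXES, LabelMap, VolumeImage, extract_slices
from .layers import BatchNorm2d, Conv2d, Dropout, MaxPool2d, MaxUnpool2d, Param, PReLU

__all__ = [
    "ViewModelConfig",
    "ViewModel",
    "ViewProbabilities",
    "FusionWeights",
    "build_view_model",
    "predict_view_probs",
    "fuse_views",
]

#: per-view fusion weights (axial, coronal, sagittal)
DEFAULT_LAMBDAS = (0.4, 0.4, 0.2)


@dataclass(frozen=True)
class ViewModelConfig:
    """Architecture hyperparameters shared by all three view models."""

    in_channels: int = 1
    filters: int = 64
    num_classes: int = 88
    kernel: int = 5
    dropout: float = 0.0
    stages: int = 4  # fixed: 4 pools <=> input divisible by 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.in_channels < 1 or self.filters < 1:
            raise ValueError("channel counts must be >= 1")
        if self.stages != 4:
            raise ValueError("architecture is defined with 4 down-sampling stages")

    @property
    def divisor(self) -> int:
        return 2 ** self.stages


class DenseBlock:
    """BN -> PReLU -> conv5x5, dense concats, then a 1x1 compression.

    Layout (``i`` input channels, ``f`` filters)::

        x1 = conv5(prelu(bn1(x)))            # i      -> f
        x2 = conv5(prelu(bn2([x, x1])))      # i+f    -> f
        y  = conv1(prelu(bn3([x, x1, x2])))  # i+2f   -> f

    One single-parameter PReLU is shared by the three activations.
    """

    def __init__(self, in_ch: int, f: int, kernel: int, rng: np.random.Generator,
                 name: str):
        self.in_ch, self.f = in_ch, f
        self.bn1 = BatchNorm2d(in_ch, name=f"{name}.bn1")
        self.bn2 = BatchNorm2d(in_ch + f, name=f"{name}.bn2")
        self.bn3 = BatchNorm2d(in_ch + 2 * f, name=f"{name}.bn3")
        self.prelu = PReLU(name=f"{name}.prelu")
        self.conv1 = Conv2d(in_ch, f, kernel, rng, name=f"{name}.conv1")
        self.conv2 = Conv2d(in_ch + f, f, kernel, rng, name=f"{name}.conv2")
        self.conv3 = Conv2d(in_ch + 2 * f, f, 1, rng, name=f"{name}.conv3")

    def params(self) -> List[Param]:
        out: List[Param] = []
        for layer in (self.bn1, self.bn2, self.bn3, self.prelu,
                      self.conv1, self.conv2, self.conv3):
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        x1 = self.conv1.forward(self.prelu.forward(self.bn1.forward(x, train), train), train)
        c1 = np.concatenate([x, x1], axis=1)
        x2 = self.conv2.forward(self.prelu.forward(self.bn2.forward(c1, train), train), train)
        c2 = np.concatenate([x, x1, x2], axis=1)
        return self.conv3.forward(self.prelu.forward(self.bn3.forward(c2, train), train), train)

    def backward(self, g: np.ndarray) -> np.ndarray:
        i, f = self.in_ch, self.f
        g_c2 = self.bn3.backward(self.prelu.backward(self.conv3.backward(g)))
        gx0 = g_c2[:, :i].copy()
        gx1 = g_c2[:, i:i + f].copy()
        gx2 = np.ascontiguousarray(g_c2[:, i + f:])
        g_c1 = self.bn2.backward(self.prelu.backward(self.conv2.backward(gx2)))
        gx0 += g_c1[:, :i]
        gx1 += g_c1[:, i:]
        gx0 += self.bn1.backward(self.prelu.backward(self.conv1.backward(np.ascontiguousarray(gx1))))
        return gx0


class ViewModel:
    """One 2D view network: 4 encoders, dense bottleneck, 4 decoders, classifier."""

    def __init__(self, config: ViewModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f, k = config.filters, config.kernel
        self.encoders = [
            DenseBlock(config.in_channels if i == 0 else f, f, k, rng, f"encoder{i + 1}")
            for i in range(4)
        ]
        self.bottleneck = DenseBlock(f, f, k, rng, "bottleneck")
        self.decoders = [DenseBlock(2 * f, f, k, rng, f"decoder{i + 1}") for i in range(4)]
        self.classifier = Conv2d(f, config.num_classes, 1, rng, name="classifier")
        self.pool = MaxPool2d()
        self.unpool = MaxUnpool2d()
        self._dropout_rng = np.random.default_rng(config.seed + 1)
        self.dropout = Dropout(config.dropout, self._dropout_rng)
        self._cache = None

    # -- parameters ---------------------------------------------------------
    def params(self) -> List[Param]:
        out: List[Param] = []
        for blk in self.encoders + [self.bottleneck] + self.decoders:
            out.extend(blk.params())
        out.extend(self.classifier.params())
        return out

    def parameter_count(self, trainable_only: bool = True) -> int:
        return sum(p.size for p in self.params() if p.trainable or not trainable_only)

    def set_trainable(self, prefixes: Optional[Tuple[str, ...]]) -> None:
        """Freeze all parameters except those whose name starts with a prefix.

        ``None`` unfreezes everything.
        """
        for p in self.params():
            p.trainable = prefixes is None or p.name.startswith(tuple(prefixes))

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected NCHW input with {self.config.in_channels} channel(s)")
        skips, idxs, shapes = [], [], []
        h = np.ascontiguousarray(x, dtype=np.float32)
        drop = [Dropout(self.config.dropout, self._dropout_rng) for _ in range(9)]
        for i, enc in enumerate(self.encoders):
            s = drop[i].forward(enc.forward(h, train), train)
            skips.append(s)
            shapes.append(s.shape)
            h, idx = self.pool.forward(s, train)
            idxs.append(idx)
        h = drop[4].forward(self.bottleneck.forward(h, train), train)
        for i, dec in enumerate(self.decoders):
            skip = skips[3 - i]
            up = MaxUnpool2d.scatter(h, idxs[3 - i], shapes[3 - i])
            h = drop[5 + i].forward(dec.forward(np.concatenate([up, skip], axis=1), train), train)
        logits = self.classifier.forward(h, train)
        if train:
            self._cache = (shapes, idxs, drop)
        return logits

    def backward(self, g: np.ndarray, shallow: bool = False) -> None:
        """Backpropagate; with ``shallow=True`` stop after the last decoder
        block (sufficient when only the classifier and final decoder are
        trainable, as in the frozen fine-tuning phase)."""
        shapes, idxs, drop = self._cache
        f = self.config.filters
        g = self.classifier.backward(g)
        gskip = [None] * 4
        for i in reversed(range(4)):
            gcat = self.decoders[i].backward(drop[5 + i].backward(g))
            if shallow and i == 3:
                self._clear_caches()
                return
            gup = np.ascontiguousarray(gcat[:, :f])
            gskip[3 - i] = gcat[:, f:]
            g = MaxUnpool2d.gather(gup, idxs[3 - i])  # unpool backward
        g = self.bottleneck.backward(drop[4].backward(g))
        for i in reversed(range(4)):
            g = MaxUnpool2d.scatter(g, idxs[i], shapes[i])  # pool backward
            g = g + gskip[i]
            g = self.encoders[i].backward(drop[i].backward(g))
        self._cache = None

    def _clear_caches(self) -> None:
        """Drop stale forward caches after a truncated backward pass."""
        for blk in self.encoders + [self.bottleneck] + self.decoders:
            blk.prelu._stack.clear()
            for layer in (blk.bn1, blk.bn2, blk.bn3):
                layer._cache = None
            for layer in (blk.conv1, blk.conv2, blk.conv3):
                layer._xp = None
        self.classifier._xp = None
        self._cache = None

    # -- serialization ------------------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        state: Dict[str, np.ndarray] = {}
        blocks = {f"encoder{i + 1}": b for i, b in enumerate(self.encoders)}
        blocks["bottleneck"] = self.bottleneck
        blocks.update({f"decoder{i + 1}": b for i, b in enumerate(self.decoders)})
        for p in self.params():
            state[p.name] = p.value.copy()
        for name, blk in blocks.items():
            for bn_name, bn in (("bn1", blk.bn1), ("bn2", blk.bn2), ("bn3", blk.bn3)):
                state[f"{name}.{bn_name}.running_mean"] = bn.running_mean.copy()
                state[f"{name}.{bn_name}.running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for p in self.params():
            if p.name not in state:
                raise KeyError(f"missing parameter {p.name} in state dict")
            if state[p.name].shape != p.value.shape:
                raise ValueError(f"shape mismatch for {p.name}")
            p.value[...] = state[p.name]
        blocks = {f"encoder{i + 1}": b for i, b in enumerate(self.encoders)}
        blocks["bottleneck"] = self.bottleneck
        blocks.update({f"decoder{i + 1}": b for i, b in enumerate(self.decoders)})
        for name, blk in blocks.items():
            for bn_name, bn in (("bn1", blk.bn1), ("bn2", blk.bn2), ("bn3", blk.bn3)):
                bn.running_mean[...] = state[f"{name}.{bn_name}.running_mean"]
                bn.running_var[...] = state[f"{name}.{bn_name}.running_var"]


def build_view_model(config: ViewModelConfig) -> Tuple[ViewModel, int]:
    """Instantiate one view network and return it with its trainable
    parameter count."""
    model = ViewModel(config)
    return model, model.parameter_count()


# ---------------------------------------------------------------------------
# Inference and fusion


@dataclass
class ViewProbabilities:
    """Per-class probability volume ``(X, Y, Z, C)`` from one view's model."""

    probs: np.ndarray
    view: str

    def __post_init__(self) -> None:
        if self.probs.ndim != 4:
            raise ValueError("expected a 4D (X, Y, Z, C) probability grid")
        if self.view not in VIEW_AXES:
            raise ValueError(f"unknown view {self.view!r}")


@dataclass(frozen=True)
class FusionWeights:
    """Fusion weights (lambda_axial, lambda_coronal, lambda_sagittal)."""

    axial: float = DEFAULT_LAMBDAS[0]
    coronal: float = DEFAULT_LAMBDAS[1]
    sagittal: float = DEFAULT_LAMBDAS[2]

    def __post_init__(self) -> None:
        vals = (self.axial, self.coronal, self.sagittal)
        if any(v < 0 for v in vals):
            raise ValueError("fusion weights must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-6:
            raise ValueError(f"fusion weights must sum to 1, got {sum(vals)}")


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z, dtype=np.float32)
    return e / e.sum(axis=-1, keepdims=True)


def predict_view_probs(model: ViewModel, vol: VolumeImage, view: str,
                       batch_size: int = 16) -> ViewProbabilities:
    """Slice the volume along ``view``, run the model, and reassemble to 3D.

    The volume must be conformed (axes divisible by 16) and normalized the
    same way as the training data.  Deterministic for fixed weights.
    """
    div = model.config.divisor
    if any(n % div for n in vol.shape):
        raise ValueError(f"volume shape {vol.shape} is not conformed (divisible by {div})")
    stack = extract_slices(vol.voxels, view)[:, None].astype(np.float32)  # (S,1,H,W)
    chunks = []
    for i in range(0, stack.shape[0], batch_size):
        logits = model.forward(stack[i:i + batch_size], train=False)
        chunks.append(_softmax(np.moveaxis(logits, 1, -1)))
    probs = np.concatenate(chunks, axis=0)  # (S, H, W, C)
    probs = np.moveaxis(probs, 0, VIEW_AXES[view])
    return ViewProbabilities(np.ascontiguousarray(probs), view)


def fuse_views(pa: ViewProbabilities, pc: ViewProbabilities, ps: ViewProbabilities,
               w: FusionWeights = FusionWeights()) -> LabelMap:
    """Weighted-argmax fusion of the three view probability grids.

    The final label is ``argmax(l1*p_ax + l2*p_cor + l3*p_sag)`` per voxel;
    exact ties go to the lowest class index.
    """
    if not (pa.view, pc.view, ps.view) == ("axial", "coronal", "sagittal"):
        raise ValueError("expected probabilities in (axial, coronal, sagittal) order")
    if pa.probs.shape != pc.probs.shape or pa.probs.shape != ps.probs.shape:
        raise ValueError("view probability grids do not share a shape")
    merged = (w.axial * pa.probs + w.coronal * pc.probs + w.sagittal * ps.probs)
    codes = merged.argmax(axis=-1).astype(np.int16)
    n_classes = pa.probs.shape[-1]
    return LabelMap(codes, frozenset(range(n_classes)))
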