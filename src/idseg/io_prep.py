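"""Volume/label I/O, intensity normalization, and grid conforming.

The segmentation network downsamples four times by a factor of two, so every
input axis must be divisible by 16.  :func:`conform_size` enforces that rule by
symmetric background cropping (preferred, geometry-exact) or symmetric zero
padding, and records the edit in a :class:`ConformRecord` so label maps
predicted on the conformed grid can be mapped back to the original grid with
:func:`restore_size`.

Volumes are resolved to a canonical RAS-like axis order at load time: grid
axis 0 runs left->right (sagittal slicing), axis 1 posterior->anterior
(coronal slicing), axis 2 inferior->superior (axial slicing).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeImage",
    "LabelMap",
    "ConformRecord",
    "load_volume",
    "load_labels",
    "save_volume",
    "save_labels",
    "normalize_intensity",
    "conform_size",
    "tight_conform",
    "restore_size",
    "extract_slices",
    "restack_slices",
    "VIEWS",
    "VIEW_AXES",
]

#: Anatomical view -> grid axis whose index enumerates the 2D slices.
VIEW_AXES = {"sagittal": 0, "coronal": 1, "axial": 2}
VIEWS = tuple(VIEW_AXES)


@dataclass
class VolumeImage:
    """A 3D intensity grid with physical spacing.

    Parameters
    ----------
    voxels : ndarray, shape (X, Y, Z)
        Finite real-valued intensities.
    spacing : tuple of float
        Voxel edge lengths in mm, all positive.
    orientation : str
        Axis-order tag; ``"RAS"`` after canonical loading.
    """

    voxels: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation: str = "RAS"
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.voxels.ndim}D")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains NaN/Inf voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(self.voxels.shape)

    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass
class LabelMap:
    """Integer-coded structure mask aligned to a :class:`VolumeImage`.

    Code 0 is background; the default label set 0..4 encodes
    left/right hippocampus (1, 2) and left/right amygdala (3, 4).
    """

    codes: np.ndarray
    label_set: frozenset = frozenset({0, 1, 2, 3, 4})
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 3:
            raise ValueError(f"expected 3D label map, got {self.codes.ndim}D")
        if not np.issubdtype(self.codes.dtype, np.integer):
            if not np.allclose(self.codes, np.round(self.codes)):
                raise ValueError("label map voxels are not integers")
            self.codes = self.codes.astype(np.int16)
        self.label_set = frozenset(int(v) for v in self.label_set)
        present = set(np.unique(self.codes).tolist())
        if not present <= self.label_set:
            raise ValueError(f"label codes {sorted(present - self.label_set)} outside label set")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(self.codes.shape)

    def mask(self, code: int) -> np.ndarray:
        """Binary mask of one structure code."""
        return self.codes == code


@dataclass
class ConformRecord:
    """Invertible record of the crop/pad applied by :func:`conform_size`."""

    crop_low: Tuple[int, int, int]
    crop_high: Tuple[int, int, int]
    pad_low: Tuple[int, int, int]
    pad_high: Tuple[int, int, int]
    original_shape: Tuple[int, int, int]
    conformed_shape: Tuple[int, int, int]
    divisor: int = 16

    def __post_init__(self) -> None:
        for ax in range(3):
            n = (self.original_shape[ax] - self.crop_low[ax] - self.crop_high[ax]
                 + self.pad_low[ax] + self.pad_high[ax])
            if n != self.conformed_shape[ax]:
                raise ValueError("record is inconsistent: crop/pad do not map "
                                 f"{self.original_shape} to {self.conformed_shape}")
        if any(n % self.divisor for n in self.conformed_shape):
            raise ValueError(f"conformed shape {self.conformed_shape} not divisible by {self.divisor}")

    def to_json(self) -> str:
        return json.dumps({k: list(v) if isinstance(v, tuple) else v
                           for k, v in self.__dict__.items()})

    @classmethod
    def from_json(cls, text: str) -> "ConformRecord":
        d = json.loads(text)
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})


# ---------------------------------------------------------------------------
# NIfTI I/O


def load_volume(path) -> VolumeImage:
    """Load a 3D NIfTI volume, reoriented to canonical (RAS) axis order."""
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D data in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive voxel spacing {spacing} in {path}")
    data = np.asarray(data, dtype=np.float32)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"volume {path} contains NaN/Inf voxels")
    return VolumeImage(data, spacing, "RAS", affine=np.asarray(img.affine))


def load_labels(path, label_set: Optional[Iterable[int]] = None) -> LabelMap:
    """Load an integer label map; ``label_set`` defaults to the codes present."""
    vol = load_volume(path)
    codes = np.round(vol.voxels).astype(np.int16)
    if label_set is None:
        label_set = frozenset(int(v) for v in np.unique(codes))
    return LabelMap(codes, frozenset(label_set), vol.spacing)


def _affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def save_volume(vol: VolumeImage, path) -> None:
    aff = vol.affine if vol.affine is not None else _affine(vol.spacing)
    nib.save(nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float32), aff), str(path))


def save_labels(labels: LabelMap, path) -> None:
    aff = _affine(labels.spacing)
    nib.save(nib.Nifti1Image(np.asarray(labels.codes, dtype=np.int16), aff), str(path))


# ---------------------------------------------------------------------------
# Normalization


def normalize_intensity(vol: VolumeImage, mask: Optional[LabelMap] = None) -> VolumeImage:
    """Z-score the volume over the mask's nonzero region (or everywhere).

    Raises
    ------
    ValueError
        If the normalization region has zero intensity variance.
    """
    x = np.asarray(vol.voxels, dtype=np.float64)
    if mask is not None:
        if mask.shape != vol.shape:
            raise ValueError(f"mask shape {mask.shape} != volume shape {vol.shape}")
        region = mask.codes != 0
        if not region.any():
            raise ValueError("normalization mask is empty")
        vals = x[region]
    else:
        vals = x.ravel()
    mu = vals.mean()
    sd = vals.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant image (sd = 0)")
    out = ((x - mu) / sd).astype(np.float32)
    return VolumeImage(out, vol.spacing, vol.orientation, affine=vol.affine)


# ---------------------------------------------------------------------------
# Conform / restore


def _axis_plan(n: int, divisor: int) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    """Candidate (crop_low, crop_high) and (pad_low, pad_high) for one axis.

    The symmetric split puts the extra voxel on the high-index side when the
    total is odd.
    """
    if n % divisor == 0:
        return (0, 0), (0, 0)
    m = (n // divisor) * divisor
    crop = (0, 0)
    if m >= divisor:
        total = n - m
        crop = (total // 2, total - total // 2)
    total_pad = ((n + divisor - 1) // divisor) * divisor - n
    pad = (total_pad // 2, total_pad - total_pad // 2)
    return crop, pad


def _background_level(x: np.ndarray) -> float:
    """Median intensity of the six border faces.

    Skull-stripped images have a constant background (0 raw, a negative
    constant after z-scoring); the crop-quietness test is taken relative to
    this level so it works on either scale.
    """
    faces = [x[0], x[-1], x[:, 0], x[:, -1], x[:, :, 0], x[:, :, -1]]
    return float(np.median(np.concatenate([f.ravel() for f in faces])))


def _slab_clean(vol: np.ndarray, fg: Optional[np.ndarray], axis: int,
                low: int, high: int, quiet_tol: float, bg_level: float) -> bool:
    """True if the candidate crop slabs hold no label and no bright voxels."""
    n = vol.shape[axis]
    idx_lo = [slice(None)] * 3
    idx_hi = [slice(None)] * 3
    idx_lo[axis] = slice(0, low)
    idx_hi[axis] = slice(n - high, n)
    for idx in (tuple(idx_lo), tuple(idx_hi)):
        if fg is not None and fg[idx].any():
            return False
        slab = vol[idx]
        if slab.size and np.abs(slab - bg_level).max() >= quiet_tol:
            return False
    return True


def conform_size(
    vol: VolumeImage,
    labels: Optional[LabelMap] = None,
    divisor: int = 16,
    quiet_tol: float = 0.1,
    background: Optional[float] = None,
    upsample: bool = False,
):
    """Make every axis length divisible by ``divisor``.

    Per axis: crop symmetrically to the largest smaller multiple when the
    removed slabs contain no foreground label and no intensity deviating by
    ``quiet_tol`` or more from the border background level; otherwise pad
    symmetrically with ``background`` (default: that level) up to the next
    multiple.  With
    ``upsample=True``, padding is replaced by trilinear (nearest for labels)
    resampling to the next multiple; the round trip then resamples back and
    is not voxel-exact.

    Returns
    -------
    (VolumeImage, LabelMap or None, ConformRecord)
    """
    if divisor < 1:
        raise ValueError("divisor must be >= 1")
    if labels is not None and labels.shape != vol.shape:
        raise ValueError(f"labels shape {labels.shape} != volume shape {vol.shape}")

    x = np.asarray(vol.voxels)
    fg = labels.codes != 0 if labels is not None else None
    bg_level = _background_level(x)
    if background is None:
        background = bg_level

    crop_lo, crop_hi, pad_lo, pad_hi = [], [], [], []
    for ax in range(3):
        crop, pad = _axis_plan(x.shape[ax], divisor)
        if crop != (0, 0) and _slab_clean(x, fg, ax, crop[0], crop[1], quiet_tol, bg_level):
            crop_lo.append(crop[0]); crop_hi.append(crop[1])
            pad_lo.append(0); pad_hi.append(0)
        else:
            crop_lo.append(0); crop_hi.append(0)
            pad_lo.append(pad[0]); pad_hi.append(pad[1])

    sl = tuple(slice(lo, x.shape[ax] - hi) for ax, (lo, hi) in enumerate(zip(crop_lo, crop_hi)))
    xc = x[sl]
    lc = labels.codes[sl] if labels is not None else None

    if upsample and any(p for p in pad_lo + pad_hi):
        from scipy.ndimage import zoom

        target = tuple(xc.shape[ax] + pad_lo[ax] + pad_hi[ax] for ax in range(3))
        factors = tuple(t / s for t, s in zip(target, xc.shape))
        xc = zoom(xc.astype(np.float32), factors, order=1)
        if lc is not None:
            lc = zoom(lc, factors, order=0)
        # record keeps the pad fields so the shape arithmetic stays valid
    else:
        pads = tuple((pad_lo[ax], pad_hi[ax]) for ax in range(3))
        if any(p != (0, 0) for p in pads):
            xc = np.pad(xc, pads, mode="constant", constant_values=background)
            if lc is not None:
                lc = np.pad(lc, pads, mode="constant", constant_values=0)

    record = ConformRecord(
        crop_low=tuple(crop_lo), crop_high=tuple(crop_hi),
        pad_low=tuple(pad_lo), pad_high=tuple(pad_hi),
        original_shape=vol.shape, conformed_shape=tuple(xc.shape), divisor=divisor,
    )
    out_vol = VolumeImage(np.ascontiguousarray(xc), vol.spacing, vol.orientation)
    out_lab = None
    if labels is not None:
        out_lab = LabelMap(np.ascontiguousarray(lc), labels.label_set, labels.spacing)
    return out_vol, out_lab, record


def tight_conform(
    vol: VolumeImage,
    labels: Optional[LabelMap] = None,
    divisor: int = 16,
    quiet_tol: float = 0.1,
    margin: int = 0,
    target_shape: Optional[Tuple[int, int, int]] = None,
):
    """Crop to the smallest divisor-multiple box containing the head.

    Standard segmentation-pipeline preprocessing: find the bounding box of
    voxels deviating from the border background level (or carrying a label),
    expand it by ``margin``, grow it to the next multiple of ``divisor`` per
    axis (recentred, clamped to the grid; padded only if the grid itself is
    too small), and crop.  ``target_shape`` overrides the per-axis box size
    so a whole dataset can share one grid (each axis must still be a
    multiple of ``divisor`` and at least the head span).  The returned
    :class:`ConformRecord` restores predictions to the original grid via
    :func:`restore_size`.
    """
    x = np.asarray(vol.voxels)
    bg_level = _background_level(x)
    head = np.abs(x - bg_level) >= quiet_tol
    if labels is not None:
        head |= labels.codes != 0
    if not head.any():
        raise ValueError("no above-background voxels to crop to")

    crop_lo, crop_hi, pad_lo, pad_hi = [], [], [], []
    for ax in range(3):
        proj = head.any(axis=tuple(a for a in range(3) if a != ax))
        nz = np.nonzero(proj)[0]
        lo = max(0, int(nz[0]) - margin)
        hi = min(x.shape[ax], int(nz[-1]) + 1 + margin)
        span = hi - lo
        target = ((span + divisor - 1) // divisor) * divisor
        if target_shape is not None:
            if target_shape[ax] % divisor:
                raise ValueError(f"target shape {target_shape} not divisible by {divisor}")
            if target_shape[ax] < target:
                raise ValueError(f"target shape {target_shape} smaller than head span {span}")
            target = target_shape[ax]
        extra = target - span
        lo = max(0, lo - extra // 2)
        hi = min(x.shape[ax], lo + target)
        lo = max(0, hi - target)
        if hi - lo < target:  # grid itself too small: pad the remainder
            deficit = target - (hi - lo)
            pad_lo.append(deficit // 2)
            pad_hi.append(deficit - deficit // 2)
        else:
            pad_lo.append(0)
            pad_hi.append(0)
        crop_lo.append(lo)
        crop_hi.append(x.shape[ax] - hi)

    sl = tuple(slice(lo, x.shape[ax] - hi) for ax, (lo, hi) in enumerate(zip(crop_lo, crop_hi)))
    xc = x[sl]
    lc = labels.codes[sl] if labels is not None else None
    pads = tuple((pad_lo[ax], pad_hi[ax]) for ax in range(3))
    if any(p != (0, 0) for p in pads):
        xc = np.pad(xc, pads, mode="constant", constant_values=bg_level)
        if lc is not None:
            lc = np.pad(lc, pads, mode="constant", constant_values=0)
    record = ConformRecord(
        crop_low=tuple(crop_lo), crop_high=tuple(crop_hi),
        pad_low=tuple(pad_lo), pad_high=tuple(pad_hi),
        original_shape=vol.shape, conformed_shape=tuple(xc.shape), divisor=divisor,
    )
    out_vol = VolumeImage(np.ascontiguousarray(xc), vol.spacing, vol.orientation)
    out_lab = None
    if labels is not None:
        out_lab = LabelMap(np.ascontiguousarray(lc), labels.label_set, labels.spacing)
    return out_vol, out_lab, record


def restore_size(labels: LabelMap, record: ConformRecord) -> LabelMap:
    """Invert :func:`conform_size` on a label map (pads removed, crops re-padded)."""
    if labels.shape != record.conformed_shape:
        raise ValueError(f"label shape {labels.shape} != record conformed shape "
                         f"{record.conformed_shape}")
    x = labels.codes
    sl = tuple(
        slice(record.pad_low[ax], x.shape[ax] - record.pad_high[ax]) for ax in range(3)
    )
    x = x[sl]
    pads = tuple((record.crop_low[ax], record.crop_high[ax]) for ax in range(3))
    if any(p != (0, 0) for p in pads):
        x = np.pad(x, pads, mode="constant", constant_values=0)
    if tuple(x.shape) != record.original_shape:
        raise ValueError("record does not restore to the original shape")
    return LabelMap(np.ascontiguousarray(x), labels.label_set, labels.spacing)


# ---------------------------------------------------------------------------
# View slicing


def extract_slices(voxels: np.ndarray, view: str) -> np.ndarray:
    """Stack of 2D slices along the given anatomical view axis.

    Returns an array of shape ``(n_slices, H, W)``; ``restack_slices``
    inverts it exactly.
    """
    if view not in VIEW_AXES:
        raise ValueError(f"unknown view {view!r}; expected one of {sorted(VIEW_AXES)}")
    arr = np.asarray(voxels)
    if arr.ndim != 3:
        raise ValueError("expected a 3D array")
    return np.ascontiguousarray(np.moveaxis(arr, VIEW_AXES[view], 0))


def restack_slices(stack: np.ndarray, view: str) -> np.ndarray:
    """Inverse of :func:`extract_slices`."""
    if view not in VIEW_AXES:
        raise ValueError(f"unknown view {view!r}; expected one of {sorted(VIEW_AXES)}")
    return np.ascontiguousarray(np.moveaxis(np.asarray(stack), 0, VIEW_AXES[view]))
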