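"""Synthetic infant-brain phantoms, simulated raters, and behavior cohorts.

The phantom is a deliberately minimal stand-in for a skull-stripped infant T2w
scan that still exhibits the two anatomical difficulties the segmentation
problem is about: each hippocampus is a *curved* tube (a torus segment,
banana-like), and each amygdala is an ellipsoid *abutting* the anterior end of
its hippocampus with deliberately *low intensity contrast* against it.  The
background is exactly zero, as after skull stripping; Gaussian noise is added
inside the brain only.

Label codes: 0 background, 1 left hippocampus, 2 right hippocampus,
3 left amygdala, 4 right amygdala.

Three generators live here:

* :func:`generate_phantom` — one volume + ground-truth label map;
* :func:`simulate_raters` — noisy manual tracings (smooth boundary
  perturbation field + surface flips), calibrated by default so that three
  raters agree at a mean pairwise Dice of about 0.76;
* :func:`generate_cohort` — a cohort of subjects with per-subject anatomy and
  a CBCL-like behavior table whose partial rank correlations with adjusted
  structure volumes, given the covariates, are embedded via a Gaussian copula.

Everything is deterministic given the seed in the spec objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_prep import LabelMap, VolumeImage

__all__ = [
    "STRUCTURES",
    "OUTCOMES",
    "PhantomSpec",
    "RaterNoiseSpec",
    "CohortTable",
    "PhantomCohort",
    "generate_phantom",
    "simulate_raters",
    "generate_cohort",
    "brain_mask",
]

#: structure name -> label code
STRUCTURES = {
    "left_hippocampus": 1,
    "right_hippocampus": 2,
    "left_amygdala": 3,
    "right_amygdala": 4,
}

#: behavior outcome short names -> CBCL T-score column
OUTCOMES = {
    "total": "cbcl_total",
    "internalizing": "cbcl_internalizing",
    "externalizing": "cbcl_externalizing",
}

# CBCL T-score means/sds used for the synthetic cohort (population values of
# the emulated proof-of-concept sample).
_CBCL_MOMENTS = {
    "total": (48.3, 10.6),
    "internalizing": (47.6, 9.12),
    "externalizing": (48.2, 10.9),
}


@dataclass
class PhantomSpec:
    """Geometry, contrast, and noise parameters of one phantom.

    Geometry is expressed in reference units of a 64-voxel grid and scaled by
    ``min(shape)/64``.  ``structure_volumes`` optionally overrides the target
    volume (in voxels) of each structure; linear dimensions are rescaled to
    match.
    """

    shape: Tuple[int, int, int] = (64, 64, 64)
    spacing: Tuple[float, float, float] = (0.9, 0.9, 0.9)
    # brain ellipsoid semi-axes (reference units)
    brain_radii: Tuple[float, float, float] = (15.5, 16.0, 15.5)
    # hippocampus torus: centreline radius, tube radius, arc span (degrees)
    hippo_major_radius: float = 5.5
    hippo_tube_radius: float = 2.2
    hippo_arc_deg: float = 200.0
    # lateral offset of each hemisphere's structures from the midline
    hemisphere_offset: float = 8.0
    # amygdala ellipsoid semi-axes
    amygdala_radii: Tuple[float, float, float] = (3.5, 3.6, 3.3)
    # tissue mean intensities; the amygdala-hippocampus gap is deliberately
    # smaller than either structure's gap to surrounding brain tissue
    brain_mean: float = 1.0
    hippo_mean: float = 1.5
    amygdala_mean: float = 1.38
    noise_sd: float = 0.08
    structure_volumes: Optional[Dict[str, float]] = None
    brain_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n % 16 for n in self.shape):
            raise ValueError(f"phantom shape {self.shape} must be divisible by 16")
        gap_inter = abs(self.amygdala_mean - self.hippo_mean)
        gap_brain = min(abs(self.hippo_mean - self.brain_mean),
                        abs(self.amygdala_mean - self.brain_mean))
        if gap_inter >= gap_brain:
            raise ValueError("amygdala-hippocampus contrast must be lower than "
                             "structure-brain contrast")

    # --- reference (unscaled) analytic volumes, in voxels -------------------
    def hippo_reference_volume(self) -> float:
        # torus segment plus the two hemispherical end caps
        frac = self.hippo_arc_deg / 360.0
        tube = frac * 2.0 * math.pi ** 2 * self.hippo_major_radius * self.hippo_tube_radius ** 2
        caps = 4.0 / 3.0 * math.pi * self.hippo_tube_radius ** 3
        return tube + caps

    def amygdala_reference_volume(self) -> float:
        a, b, c = self.amygdala_radii
        return 4.0 / 3.0 * math.pi * a * b * c


@dataclass
class RaterNoiseSpec:
    """Noise model for one team of simulated raters.

    ``boundary_sd`` is the standard deviation (in voxels) of a smooth random
    field added to the signed distance of the true boundary; ``flip_rate`` is
    the probability of flipping a voxel on the perturbed surface.  The default
    ``boundary_sd`` is calibrated so that three raters reach a mean pairwise
    Dice agreement of about 0.76 on default phantoms.
    """

    boundary_sd: float = 0.96
    flip_rate: float = 0.05
    corr_len: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boundary_sd < 0:
            raise ValueError("boundary_sd must be >= 0")
        if not (0 <= self.flip_rate < 1):
            raise ValueError("flip_rate must be in [0, 1)")


# ---------------------------------------------------------------------------
# Phantom generation


def _hemisphere_fields(spec: PhantomSpec, side: str, g: float,
                       hippo_scale: float, amyg_scale: float,
                       X: np.ndarray, Y: np.ndarray, Z: np.ndarray):
    """Implicit field values (< 0 inside) for one hemisphere's hippocampus
    and amygdala, plus their analytic bounding boxes."""
    cx = (spec.shape[0] - 1) / 2.0
    cy = (spec.shape[1] - 1) / 2.0
    cz = (spec.shape[2] - 1) / 2.0
    sign = -1.0 if side == "left" else 1.0
    tx = cx + sign * spec.hemisphere_offset * g
    ty = cy - 1.0 * g
    tz = cz + 0.5 * g

    R = spec.hippo_major_radius * g
    r = spec.hippo_tube_radius * g * hippo_scale
    half_arc = math.radians(spec.hippo_arc_deg) / 2.0

    rho = np.sqrt((Y - ty) ** 2 + (Z - tz) ** 2)
    theta = np.arctan2(Z - tz, Y - ty)  # 0 along +y
    in_arc = np.abs(_wrap(theta - math.radians(90.0))) <= half_arc
    torus = np.sqrt((rho - R) ** 2 + (X - tx) ** 2) - r
    # cap the tube ends with spheres so the field is smooth at the arc limits
    th_lo = math.radians(90.0) - half_arc
    th_hi = math.radians(90.0) + half_arc
    ends = []
    for th in (th_lo, th_hi):
        ey = ty + R * math.cos(th)
        ez = tz + R * math.sin(th)
        ends.append(np.sqrt((X - tx) ** 2 + (Y - ey) ** 2 + (Z - ez) ** 2) - r)
    hippo = np.where(in_arc, torus, np.minimum(ends[0], ends[1]))

    # amygdala abuts the anterior (low-angle) end of the arc
    th = th_lo
    end = np.array([tx, ty + R * math.cos(th), tz + R * math.sin(th)])
    tangent = np.array([0.0, math.sin(th), -math.cos(th)])  # points beyond the arc
    ar = np.array(spec.amygdala_radii) * g * amyg_scale
    centre = end + (r + 0.7 * ar[1]) * tangent
    amyg = (np.sqrt(((X - centre[0]) / ar[0]) ** 2
                    + ((Y - centre[1]) / ar[1]) ** 2
                    + ((Z - centre[2]) / ar[2]) ** 2) - 1.0)

    hippo_bbox = (tx - r, tx + r,
                  ty - R - r, ty + R + r,
                  tz - R - r, tz + R + r)
    amyg_bbox = (centre[0] - ar[0], centre[0] + ar[0],
                 centre[1] - ar[1], centre[1] + ar[1],
                 centre[2] - ar[2], centre[2] + ar[2])
    return hippo, amyg, hippo_bbox, amyg_bbox


def _wrap(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2 * np.pi) - np.pi


def generate_phantom(spec: PhantomSpec) -> Tuple[VolumeImage, LabelMap]:
    """Generate one phantom volume and its ground-truth label map.

    Raises
    ------
    ValueError
        If any structure's analytic bounding box exceeds the grid.
    """
    g = min(spec.shape) / 64.0
    rng = np.random.default_rng(spec.seed)

    x = np.arange(spec.shape[0], dtype=np.float32)[:, None, None]
    y = np.arange(spec.shape[1], dtype=np.float32)[None, :, None]
    z = np.arange(spec.shape[2], dtype=np.float32)[None, None, :]
    cx = (spec.shape[0] - 1) / 2.0
    cy = (spec.shape[1] - 1) / 2.0
    cz = (spec.shape[2] - 1) / 2.0

    br = np.array(spec.brain_radii) * g * spec.brain_scale
    brain = (((x - cx) / br[0]) ** 2 + ((y - cy) / br[1]) ** 2
             + ((z - cz) / br[2]) ** 2) <= 1.0

    # per-structure linear scale factors from target volumes
    sv = spec.structure_volumes or {}
    h_ref = spec.hippo_reference_volume() * g ** 3
    a_ref = spec.amygdala_reference_volume() * g ** 3

    X, Y, Z = np.broadcast_arrays(x, y, z)
    codes = np.zeros(spec.shape, dtype=np.int16)
    best = np.full(spec.shape, np.inf, dtype=np.float32)
    for side in ("left", "right"):
        h_name = f"{side}_hippocampus"
        a_name = f"{side}_amygdala"
        # torus volume scales with tube radius squared (centreline fixed)
        h_scale = math.sqrt(sv[h_name] / h_ref) if h_name in sv else 1.0
        a_scale = (sv[a_name] / a_ref) ** (1.0 / 3.0) if a_name in sv else 1.0
        hippo, amyg, h_bbox, a_bbox = _hemisphere_fields(
            spec, side, g, h_scale, a_scale, X, Y, Z)
        for bbox, name in ((h_bbox, h_name), (a_bbox, a_name)):
            lo = (bbox[0], bbox[2], bbox[4])
            hi = (bbox[1], bbox[3], bbox[5])
            if any(l < 0 for l in lo) or any(h > n - 1 for h, n in zip(hi, spec.shape)):
                raise ValueError(f"structure {name} does not fit in grid {spec.shape}")
        for fieldv, code in ((hippo, STRUCTURES[h_name]), (amyg, STRUCTURES[a_name])):
            inside = (fieldv < 0) & (fieldv < best)
            codes[inside] = code
            best = np.minimum(best, np.where(fieldv < 0, fieldv, np.inf)).astype(np.float32)

    means = np.zeros(spec.shape, dtype=np.float32)
    means[brain] = spec.brain_mean
    means[(codes == 1) | (codes == 2)] = spec.hippo_mean
    means[(codes == 3) | (codes == 4)] = spec.amygdala_mean
    voxels = means.copy()
    noise = rng.normal(0.0, spec.noise_sd, size=spec.shape).astype(np.float32)
    voxels[brain] += noise[brain]

    vol = VolumeImage(voxels, spec.spacing)
    labels = LabelMap(codes, frozenset({0, 1, 2, 3, 4}), spec.spacing)
    return vol, labels


def brain_mask(vol: VolumeImage, threshold: float = 0.5) -> np.ndarray:
    """Binary brain mask of a phantom (background is exactly zero)."""
    return vol.voxels > threshold * float(np.max(vol.voxels)) * 0.5


# ---------------------------------------------------------------------------
# Simulated raters


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return (outside - inside).astype(np.float32)


def _surface(mask: np.ndarray) -> np.ndarray:
    """Inner + outer one-voxel shell of a mask (6-connectivity)."""
    st = ndimage.generate_binary_structure(3, 1)
    inner = mask & ~ndimage.binary_erosion(mask, st)
    outer = ndimage.binary_dilation(mask, st) & ~mask
    return inner | outer


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def simulate_raters(truth: LabelMap, k: int, noise: RaterNoiseSpec) -> List[LabelMap]:
    """Simulate ``k`` raters tracing the structures in ``truth``.

    Each rater's mask per structure is ``{d(x) + g(x) < 0}`` where ``d`` is the
    signed distance to the true boundary (negative inside) and ``g`` is a
    smooth Gaussian random field with standard deviation ``boundary_sd``;
    voxels on the perturbed surface are then flipped with ``flip_rate`` and
    the largest connected component is kept.  Expected pairwise Dice decreases
    monotonically with ``boundary_sd``.
    """
    if k < 2:
        raise ValueError("need at least 2 raters")
    codes_present = [c for c in sorted(truth.label_set) if c != 0]
    rng_parent = np.random.default_rng(noise.seed)
    child_seeds = rng_parent.integers(0, 2 ** 31 - 1, size=(k, len(codes_present), 2))

    pad = int(math.ceil(4 + 3 * noise.boundary_sd + noise.corr_len * 3))
    out: List[LabelMap] = []
    for j in range(k):
        codes = np.zeros(truth.shape, dtype=np.int16)
        best = np.full(truth.shape, np.inf, dtype=np.float32)
        for si, code in enumerate(codes_present):
            mask = truth.codes == code
            if not mask.any():
                continue
            sl = ndimage.find_objects(mask.astype(np.int8))[0]
            sl = tuple(slice(max(0, s.start - pad), min(n, s.stop + pad))
                       for s, n in zip(sl, truth.shape))
            sub = mask[sl]
            d = _signed_distance(sub)
            rng = np.random.default_rng(int(child_seeds[j, si, 0]))
            if noise.boundary_sd > 0:
                white = rng.standard_normal(sub.shape).astype(np.float32)
                gfield = ndimage.gaussian_filter(white, noise.corr_len)
                gsd = gfield.std()
                gfield = gfield * (noise.boundary_sd / gsd) if gsd > 0 else gfield
            else:
                gfield = np.zeros(sub.shape, dtype=np.float32)
            fieldv = d + gfield
            pert = fieldv < 0
            if noise.flip_rate > 0 and pert.any():
                rng2 = np.random.default_rng(int(child_seeds[j, si, 1]))
                surf = _surface(pert)
                flips = surf & (rng2.random(sub.shape) < noise.flip_rate)
                pert = pert ^ flips
            if pert.any():
                pert = _largest_component(pert)
            region = codes[sl]
            bsub = best[sl]
            take = pert & (fieldv < bsub)
            region[take] = code
            bsub[take] = fieldv[take]
            codes[sl] = region
            best[sl] = bsub
        out.append(LabelMap(codes, truth.label_set, truth.spacing))
    return out


# ---------------------------------------------------------------------------
# Behavior cohort


@dataclass
class CohortTable:
    """Per-subject covariates, outcomes, and true structure volumes."""

    frame: pd.DataFrame
    seed: int

    def __post_init__(self) -> None:
        if self.frame["subject_id"].duplicated().any():
            raise ValueError("duplicated subject ids")
        for name in OUTCOMES.values():
            t = self.frame[name]
            if (t < 20).any() or (t > 100).any():
                raise ValueError("T scores outside [20, 100]")


class PhantomCohort(Sequence):
    """Lazy sequence of per-subject phantoms.

    Subject ``i`` is regenerated deterministically on each access, so large
    cohorts never hold more than one volume in memory.
    """

    def __init__(self, specs: List[PhantomSpec]):
        self._specs = specs

    def __len__(self) -> int:
        return len(self._specs)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(len(self)))]
        return generate_phantom(self._specs[i])

    def spec(self, i: int) -> PhantomSpec:
        return self._specs[i]


def _default_target_rho() -> Dict[Tuple[str, str], float]:
    # the embedded right-amygdala associations (volume vs CBCL T scores)
    return {
        ("right_amygdala", "total"): -0.62,
        ("right_amygdala", "internalizing"): -0.43,
        ("right_amygdala", "externalizing"): -0.59,
    }


def _normalize_targets(target_rho) -> Dict[Tuple[str, str], float]:
    if target_rho is None:
        return _default_target_rho()
    out: Dict[Tuple[str, str], float] = {}
    for key, val in target_rho.items():
        if isinstance(key, tuple):
            out[key] = float(val)
        else:  # structure name alone -> all three outcomes
            for oc in OUTCOMES:
                out[(key, oc)] = float(val)
    for (s, oc), val in out.items():
        if s not in STRUCTURES or oc not in OUTCOMES:
            raise ValueError(f"unknown target pair {(s, oc)}")
        if not abs(val) < 1:
            raise ValueError(f"|target rho| must be < 1, got {val}")
    return out


def generate_cohort(
    n: int,
    target_rho: Optional[Mapping] = None,
    seed: int = 0,
    base_spec: Optional[PhantomSpec] = None,
    structure_corr: float = 0.3,
    outcome_corr: float = 0.5,
    pma_volume_loading: float = 0.45,
    volume_log_sd: float = 0.15,
) -> Tuple[PhantomCohort, CohortTable]:
    """Generate ``n`` subjects with embedded volume-behavior associations.

    A Gaussian copula drives everything: per-subject adjusted structure
    volumes and CBCL T scores share latent residual correlations chosen so
    that the *partial Spearman* correlation between the named adjusted volume
    and score, given the covariates (PMA at scan, maternal education, EPDS),
    equals the target in expectation.  The Pearson latent correlation is
    ``2*sin(pi*rho/6)``, the inverse of the Gaussian rank-correlation map.
    Covariates confound both sides: higher PMA raises volumes and lowers
    problem scores.

    ``target_rho`` maps ``(structure, outcome)`` (or a structure name, meaning
    all three outcomes) to the desired partial Spearman rho.  The default
    embeds the right-amygdala associations (-0.62 / -0.43 / -0.59).

    Raises
    ------
    ValueError
        If the implied latent correlation matrix is not positive definite.
    """
    if n < 10:
        raise ValueError("need n >= 10 subjects")
    targets = _normalize_targets(target_rho)
    spec0 = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)

    snames = list(STRUCTURES)
    onames = list(OUTCOMES)
    ns, no = len(snames), len(onames)

    # residual correlation matrix over (4 structure latents, 3 outcome latents)
    C = np.eye(ns + no)
    C[:ns, :ns] = structure_corr
    C[ns:, ns:] = outcome_corr
    np.fill_diagonal(C, 1.0)
    for (s, oc), rho_t in targets.items():
        latent = 2.0 * math.sin(math.pi * rho_t / 6.0)
        i, jj = snames.index(s), ns + onames.index(oc)
        C[i, jj] = C[jj, i] = latent
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("infeasible correlation matrix (not positive definite)") from exc

    z_pma = rng.standard_normal(n)
    z_edu = rng.standard_normal(n)
    z_epds = rng.standard_normal(n)
    resid = rng.standard_normal((n, ns + no)) @ L.T
    U, W = resid[:, :ns], resid[:, ns:]

    pma = 44.0 + 3.0 * z_pma  # weeks, scan between ~1 and ~4 months after term
    edu = np.digitize(z_edu, [-1.0, -0.2, 0.6, 1.3])  # ordinal 0..4
    epds = np.clip(np.round(6.0 + 4.0 * z_epds), 0, 30).astype(int)

    alpha = pma_volume_loading
    voxvol = float(np.prod(spec0.spacing))
    tbv_ref_vox = 4.0 / 3.0 * math.pi * float(np.prod(spec0.brain_radii)) * (min(spec0.shape) / 64.0) ** 3
    tbv = tbv_ref_vox * voxvol * np.exp(0.05 * z_pma + 0.02 * rng.standard_normal(n))

    ref_vox = {
        "left_hippocampus": spec0.hippo_reference_volume(),
        "right_hippocampus": spec0.hippo_reference_volume(),
        "left_amygdala": spec0.amygdala_reference_volume(),
        "right_amygdala": spec0.amygdala_reference_volume(),
    }
    g3 = (min(spec0.shape) / 64.0) ** 3
    ratio0 = {s: ref_vox[s] * g3 * voxvol / (tbv_ref_vox * voxvol) for s in snames}

    adj = {}
    vol_mm3 = {}
    for i, s in enumerate(snames):
        latent = alpha * z_pma + math.sqrt(1.0 - alpha ** 2) * U[:, i]
        adj[s] = ratio0[s] * np.exp(volume_log_sd * latent)
        vol_mm3[s] = adj[s] * tbv

    # outcomes: covariate loadings give genuine confounding
    beta = {"pma": -0.20, "edu": -0.25, "epds": 0.35}
    gam = math.sqrt(1.0 - sum(b * b for b in beta.values()))
    scores = {}
    for jj, oc in enumerate(onames):
        y = (beta["pma"] * z_pma + beta["edu"] * z_edu + beta["epds"] * z_epds
             + gam * W[:, jj])
        mean, sd = _CBCL_MOMENTS[oc]
        scores[oc] = np.round(np.clip(mean + sd * y, 20.0, 100.0), 1)

    seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    specs = []
    for i in range(n):
        sv = {s: vol_mm3[s][i] / voxvol for s in snames}
        specs.append(replace(
            spec0,
            structure_volumes=sv,
            brain_scale=float((tbv[i] / (tbv_ref_vox * voxvol)) ** (1.0 / 3.0)),
            seed=int(seeds[i]),
        ))

    frame = pd.DataFrame({
        "subject_id": [f"sub-{i:04d}" for i in range(n)],
        "pma_weeks": np.round(pma, 2),
        "maternal_education": edu,
        "epds": epds,
        **{OUTCOMES[oc]: scores[oc] for oc in onames},
        **{f"true_vol_{s}_mm3": np.round(vol_mm3[s], 3) for s in snames},
        "true_tbv_mm3": np.round(tbv, 3),
    })
    return PhantomCohort(specs), CohortTable(frame, seed)
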