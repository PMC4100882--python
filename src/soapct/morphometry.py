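"""Cavity morphometry: volume, area profile, deflection angle, max sphere.

All descriptors operate on a binary cavity mask (and, for the deflection
angle, the block mask) on the native voxel grid:

* volume: voxel count times voxel volume, in mL;
* cross-sectional area profile: in-plane area per slice along the block
  long axis (z);
* deflection angle: the angle between the principal axes (largest-variance
  PCA eigenvectors) of cavity and block, folded into [0, 90] degrees —
  how far the wound channel deviates from the line of shooting;
* maximal inscribed sphere: from the spacing-aware Euclidean distance
  transform inside the cavity; the z-position of its center is the depth
  of maximal damage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from soapct.volume_io import BinaryMask

__all__ = ["CavityMetrics", "mask_volume", "area_profile", "principal_axis",
           "deflection_angle", "max_inscribed_sphere", "compute_cavity_metrics"]


class DegenerateAxisWarning(UserWarning):
    """The mask is nearly isotropic; its principal axis is ill-defined."""


def mask_volume(mask: BinaryMask) -> float:
    """Mask volume in mL (voxel count times voxel volume)."""
    return float(mask.bits.astype(bool).sum()) * mask.voxel_volume_mm3 / 1000.0


def area_profile(mask: BinaryMask) -> pd.DataFrame:
    """Cross-sectional area (mm²) per slice along the block long axis.

    Returns one row per slice in the contiguous span covered by the mask,
    with ``depth_mm`` the physical z of the slice (voxel centers) relative
    to the first mask slice.
    """
    bits = mask.bits.astype(bool)
    per_slice = bits.sum(axis=(0, 1))
    zs = np.where(per_slice > 0)[0]
    if zs.size == 0:
        return pd.DataFrame({"depth_mm": [], "area_mm2": []})
    span = np.arange(zs[0], zs[-1] + 1)
    in_plane = float(mask.spacing_mm[0] * mask.spacing_mm[1])
    return pd.DataFrame({
        "depth_mm": (span - zs[0]) * float(mask.spacing_mm[2]),
        "area_mm2": per_slice[span] * in_plane,
    })


def principal_axis(mask: BinaryMask, degeneracy_ratio: float = 1.2) -> np.ndarray:
    """Unit principal axis of a binary mask by PCA of its voxel coordinates.

    Coordinates are physical (spacing-scaled, unweighted).  The sign is
    fixed so the z-component is nonnegative (ties broken on y, then x).
    If the top two eigenvalues differ by less than ``degeneracy_ratio``
    the axis is ill-defined and a :class:`DegenerateAxisWarning` is
    emitted (the eigenvector is still returned).
    """
    coords = np.argwhere(mask.bits.astype(bool)).astype(float)
    if coords.shape[0] < 3:
        raise ValueError("mask too small for a principal axis (need >= 3 voxels)")
    coords *= mask.spacing_mm
    coords -= coords.mean(axis=0)
    cov = coords.T @ coords / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] > 0 and evals[2] / evals[1] < degeneracy_ratio:
        warnings.warn(
            f"principal axis ill-defined: eigenvalue ratio "
            f"{evals[2] / evals[1]:.3f} < {degeneracy_ratio}",
            DegenerateAxisWarning, stacklevel=2)
    axis = evecs[:, 2]
    for comp in (2, 1, 0):
        if abs(axis[comp]) > 1e-12:
            if axis[comp] < 0:
                axis = -axis
            break
    return axis


def deflection_angle(cavity_mask: BinaryMask, block_mask: BinaryMask) -> float:
    """Angle (degrees, in [0, 90]) between cavity and block principal axes.

    Uses the absolute dot product, so antiparallel eigenvectors give 0°.
    """
    cavity_mask.check_same_grid(block_mask)
    a = principal_axis(cavity_mask)
    b = principal_axis(block_mask)
    c = np.clip(abs(float(np.dot(a, b))), 0.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def max_inscribed_sphere(cavity_mask: BinaryMask,
                         refine: int = 3) -> tuple[float, np.ndarray, float]:
    """Maximal sphere inscribed in the cavity, via the distance transform.

    The Euclidean distance transform (spacing-aware) inside the mask holds
    each voxel's distance to the nearest non-cavity voxel; its maximum is
    the inscribed-sphere radius and location.  Distances between voxel
    centers track the smooth cavity surface well (the half-voxel
    digitization errors of the jagged voxel boundary cancel in the
    minimum over directions), but the sphere center itself is quantized
    to the grid.  The maximum is therefore refined on a ``refine``-fold
    subsampled window around the coarse argmax, measuring from subvoxel
    candidate centers to the same coarse background-voxel centers (an odd
    factor keeps the coarse centers among the candidates, so refinement
    never loses to the coarse pass).  The reported radius subtracts half
    a voxel — the boundary surface lies between the last cavity and first
    background voxel center — so a single-voxel cavity reports half a
    voxel.  Ties are broken toward the smallest z, then y, then x.

    Returns ``(radius_mm, center_mm, depth_mm)`` with ``depth_mm`` the z
    of the sphere center relative to the first mask slice (the entry face
    of a wound cavity).
    """
    if refine < 1 or refine % 2 == 0:
        raise ValueError("refine must be an odd positive integer")
    bits = cavity_mask.bits.astype(bool)
    if not bits.any():
        raise ValueError("empty cavity mask")
    sp = cavity_mask.spacing_mm
    # the transform is local to the mask: cropping to the bounding box plus
    # a one-voxel border leaves every inside-distance unchanged
    nz = np.nonzero(bits)
    lo = np.maximum(0, [int(w.min()) - 1 for w in nz])
    hi = np.minimum(np.array(bits.shape) - 1, [int(w.max()) + 1 for w in nz])
    crop = bits[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
    dist = ndimage.distance_transform_edt(crop, sampling=sp)
    dmax = float(dist.max())
    cand = np.argwhere(dist == dmax) + lo
    # lexicographic tie-break: smallest z, then y, then x
    i = np.lexsort((cand[:, 0], cand[:, 1], cand[:, 2]))[0]
    idx = cand[i].astype(float)
    half_voxel = 0.5 * float(np.mean(sp))
    radius = dmax - half_voxel

    if refine > 1:
        margin = int(np.ceil(dmax / float(sp.min()))) + 3
        wlo = np.maximum(0, cand[i] - margin)
        whi = np.minimum(np.array(bits.shape) - 1, cand[i] + margin)
        win = bits[wlo[0]:whi[0] + 1, wlo[1]:whi[1] + 1, wlo[2]:whi[2] + 1]
        mid = refine // 2
        # feature points: the coarse centers of background voxels only
        feat = np.ones(np.array(win.shape) * refine, dtype=bool)
        feat[mid::refine, mid::refine, mid::refine] = win
        fine = ndimage.distance_transform_edt(feat, sampling=sp / refine)
        # candidate centers: fine samples within cavity voxels
        inside = win
        for ax in range(3):
            inside = np.repeat(inside, refine, axis=ax)
        fine[~inside] = -1.0
        fmax = float(fine.max())
        fc = np.argwhere(fine == fmax)
        j = np.lexsort((fc[:, 0], fc[:, 1], fc[:, 2]))[0]
        # fine sample k within coarse voxel maps to offset (k+1/2)/refine-1/2
        idx = wlo + (fc[j] + 0.5) / refine - 0.5
        radius = fmax - half_voxel

    center = cavity_mask.origin_mm + idx * sp
    z0 = int(np.where(bits.any(axis=(0, 1)))[0][0])
    depth = float((idx[2] - z0) * sp[2])
    return radius, center, depth


@dataclass
class CavityMetrics:
    """Per-shot cavity descriptors."""

    volume_ml: float
    deflection_deg: float
    max_sphere_radius_mm: float
    max_sphere_center_mm: tuple
    max_damage_depth_mm: float

    def to_dict(self) -> dict:
        return asdict(self)


def compute_cavity_metrics(cavity_mask: BinaryMask,
                           block_mask: BinaryMask) -> tuple[CavityMetrics, pd.DataFrame]:
    """All cavity descriptors plus the area profile for one shot."""
    vol = mask_volume(cavity_mask)
    ang = deflection_angle(cavity_mask, block_mask)
    radius, center, depth = max_inscribed_sphere(cavity_mask)
    profile = area_profile(cavity_mask)
    metrics = CavityMetrics(
        volume_ml=vol,
        deflection_deg=ang,
        max_sphere_radius_mm=radius,
        max_sphere_center_mm=tuple(float(v) for v in center),
        max_damage_depth_mm=depth,
    )
    return metrics, profile
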