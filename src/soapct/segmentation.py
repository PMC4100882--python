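"""Threshold-based region-growing segmentation of soap-block CT volumes.

Three regions are extracted, mirroring the workflow used on clinical
scans of shot blocks:

* the **soap block**: voxels at or above half the (estimated) soap
  intensity, region-grown to the largest connected component;
* the **cavity**: air-intensity voxels inside the block between a first
  and a last slice along the shot axis, region-grown from seeds in the
  cavity opening;
* the **metal fragments**: connected components above a fixed 2000 HU
  threshold, counted automatically, with small components near large ones
  discounted as probable streak artifacts.

Block and cavity use 6-connectivity; fragments (small, possibly diagonal
specks) use 26-connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import convex_hull_image

from soapct.volume_io import VoxelVolume, BinaryMask

__all__ = ["FragmentSet", "estimate_soap_intensity", "segment_block",
           "segment_cavity", "segment_fragments", "apply_streak_exclusion",
           "FRAGMENT_THRESHOLD_HU"]

FRAGMENT_THRESHOLD_HU = 2000.0

_CONN6 = ndimage.generate_binary_structure(3, 1)
_CONN26 = ndimage.generate_binary_structure(3, 3)


class SegmentationError(RuntimeError):
    """A segmentation stage found nothing to segment."""


def estimate_soap_intensity(volume: VoxelVolume) -> float:
    """Robust estimate of the soap intensity (HU).

    Splits the histogram into two classes (air vs material) with Otsu's
    threshold and returns the median of the upper class.  Metal voxels are
    rare enough not to move the median.  If the two classes are not
    clearly separated (less than 200 HU apart — Otsu bisects even a
    unimodal histogram) the volume is taken to be all soap and its median
    is returned.
    """
    vals = np.asarray(volume.intensities).ravel()
    if vals.size == 0:
        raise ValueError("empty volume")
    if np.ptp(vals) == 0:
        raise ValueError("constant volume: cannot separate air from soap")
    # histogram-based Otsu keeps this O(n) in one pass
    thr = threshold_otsu(vals, nbins=512)
    upper = vals[vals > thr]
    lower = vals[vals <= thr]
    if upper.size == 0:
        raise ValueError("no voxels above the air/soap split")
    if lower.size == 0 or np.median(upper) - np.median(lower) < 200.0:
        return float(np.median(vals))
    return float(np.median(upper))


def segment_block(volume: VoxelVolume,
                  soap_intensity_hu: float | None = None) -> BinaryMask:
    """Segment the soap block by thresholding at half the soap intensity.

    Region growing with a global intensity criterion is equivalent to
    keeping the seed's connected component of the thresholded image; the
    largest component is returned.  Cavity voxels are air and fall below
    the threshold, so they are not part of the block mask.
    """
    if soap_intensity_hu is None:
        soap_intensity_hu = estimate_soap_intensity(volume)
    thr = 0.5 * soap_intensity_hu
    fg = volume.intensities >= thr
    if not fg.any():
        raise SegmentationError("no block found: no voxel above half the soap intensity")
    labels, n = ndimage.label(fg, structure=_CONN6)
    sizes = np.bincount(labels.ravel())[1:]
    largest = int(np.argmax(sizes)) + 1
    return BinaryMask.like(volume, labels == largest)


def _cavity_seeds(air: np.ndarray, block: np.ndarray, first_slice: int) -> np.ndarray:
    """Seed voxels: sub-threshold voxels in the first slice that lie inside
    the block's 2D convex hull there (the cavity opening)."""
    blk2d = block[:, :, first_slice]
    if not blk2d.any():
        # block may start a slice later (rounding at the face); use the
        # nearest non-empty block slice for the hull
        zs = np.where(block.any(axis=(0, 1)))[0]
        if zs.size == 0:
            raise SegmentationError("block mask is empty")
        blk2d = block[:, :, zs[np.argmin(np.abs(zs - first_slice))]]
    hull = convex_hull_image(blk2d)
    return air[:, :, first_slice] & hull


def segment_cavity(volume: VoxelVolume, block_mask: BinaryMask,
                   first_slice: int | None = None,
                   last_slice: int | None = None,
                   soap_intensity_hu: float | None = None) -> BinaryMask:
    """Segment the wound cavity by region growing between two slices.

    The cavity is air (below half the soap intensity) enclosed by the
    block, restricted to slices ``[first_slice, last_slice]`` along the
    shot axis and grown from seeds inside the cavity opening on the first
    slice.  Exterior air is excluded; if several seeded components exist
    the largest is kept.

    When both slice indices are omitted the segmentation is fully
    automatic: the largest air component inside the block's bounding box
    that does not touch the lateral volume boundary is taken.
    """
    block_mask.check_same_grid(volume)
    if soap_intensity_hu is None:
        soap_intensity_hu = estimate_soap_intensity(volume)
    thr = 0.5 * soap_intensity_hu
    air = volume.intensities < thr
    nz = volume.shape[2]
    block = block_mask.bits.astype(bool)

    auto = first_slice is None and last_slice is None
    if auto:
        zs = np.where(block.any(axis=(0, 1)))[0]
        first_slice, last_slice = int(zs[0]), int(zs[-1])
    if not 0 <= first_slice <= last_slice < nz:
        raise ValueError("need 0 <= first_slice <= last_slice < n_slices")

    sub = np.zeros_like(air)
    sub[:, :, first_slice:last_slice + 1] = air[:, :, first_slice:last_slice + 1]

    # restrict laterally to the block's bounding box interior so exterior
    # air cannot be picked up
    xs = np.where(block.any(axis=(1, 2)))[0]
    ys = np.where(block.any(axis=(0, 2)))[0]
    if xs.size == 0:
        raise SegmentationError("block mask is empty")
    box = np.zeros_like(sub)
    box[xs[0]:xs[-1] + 1, ys[0]:ys[-1] + 1, :] = True
    sub &= box

    if not sub.any():
        raise SegmentationError("no cavity found: no air voxels in the slice range")

    labels, n = ndimage.label(sub, structure=_CONN6)
    if auto:
        sizes = np.bincount(labels.ravel())[1:]
        order = np.argsort(sizes)[::-1]
        for k in order:
            comp = labels == k + 1
            edge = (comp[0].any() or comp[-1].any()
                    or comp[:, 0].any() or comp[:, -1].any())
            if not edge:
                return BinaryMask.like(volume, comp)
        raise SegmentationError("no cavity found: all air components touch the boundary")

    seeds = _cavity_seeds(air, block, first_slice)
    if not seeds.any():
        raise SegmentationError("no cavity found: no seed voxels in the first slice")
    seed_labels = np.unique(labels[:, :, first_slice][seeds])
    seed_labels = seed_labels[seed_labels > 0]
    if seed_labels.size == 0:
        raise SegmentationError("no cavity found: seeds fall outside air components")
    all_sizes = np.bincount(labels.ravel())
    best = int(seed_labels[np.argmax(all_sizes[seed_labels])])
    return BinaryMask.like(volume, labels == best)


@dataclass
class FragmentSet:
    """Labeled metal fragments with per-fragment statistics.

    ``table`` has one row per fragment: ``label``, ``n_voxels``,
    ``volume_mm3``, ``centroid_x_mm``/``y``/``z``, ``max_intensity_hu``
    and the ``counted`` flag (False for fragments discounted as streak
    artifacts).  ``labels`` is the label map on the volume grid.
    """

    labels: BinaryMask
    table: pd.DataFrame

    @property
    def n_counted(self) -> int:
        return int(self.table["counted"].sum())

    @property
    def n_total(self) -> int:
        return int(len(self.table))

    def counted_table(self) -> pd.DataFrame:
        return self.table[self.table["counted"]].reset_index(drop=True)


def segment_fragments(volume: VoxelVolume,
                      threshold_hu: float = FRAGMENT_THRESHOLD_HU) -> FragmentSet:
    """Segment and count metal fragments above a fixed HU threshold.

    Connected components (26-connectivity) of voxels strictly above
    ``threshold_hu``; labels are deterministic, sorted by centroid z, then
    y, then x.  An empty fragment set is a valid result.
    """
    fg = volume.intensities > threshold_hu
    labels, n = ndimage.label(fg, structure=_CONN26)
    vox_mm3 = volume.voxel_volume_mm3
    if n == 0:
        table = pd.DataFrame(columns=["label", "n_voxels", "volume_mm3",
                                      "centroid_x_mm", "centroid_y_mm",
                                      "centroid_z_mm", "max_intensity_hu",
                                      "counted"])
        return FragmentSet(BinaryMask.like(volume, labels.astype(np.uint16)), table)

    idx = np.arange(1, n + 1)
    counts = np.bincount(labels.ravel())[1:]
    cent = np.array(ndimage.center_of_mass(fg, labels, idx))
    cent_mm = volume.origin_mm + cent * volume.spacing_mm
    maxint = ndimage.maximum(volume.intensities, labels, idx)

    order = np.lexsort((cent_mm[:, 0], cent_mm[:, 1], cent_mm[:, 2]))
    relabel = np.zeros(n + 1, dtype=np.uint16)
    relabel[idx[order]] = np.arange(1, n + 1)
    labels = relabel[labels]

    table = pd.DataFrame({
        "label": np.arange(1, n + 1),
        "n_voxels": counts[order].astype(int),
        "volume_mm3": counts[order] * vox_mm3,
        "centroid_x_mm": cent_mm[order, 0],
        "centroid_y_mm": cent_mm[order, 1],
        "centroid_z_mm": cent_mm[order, 2],
        "max_intensity_hu": maxint[order],
        "counted": True,
    })
    return FragmentSet(BinaryMask.like(volume, labels), table)


def apply_streak_exclusion(fragments: FragmentSet,
                           small_max_mm3: float = 8.0,
                           proximity_mm: float = 5.0) -> FragmentSet:
    """Discount small fragments close to large ones as streak artifacts.

    A fragment of volume at most ``small_max_mm3`` whose surface-to-surface
    distance to any larger fragment is at most ``proximity_mm`` gets
    ``counted=False``.  Excluded fragments are retained in the table.  At
    ``proximity_mm=0`` nothing is excluded (disjoint components are at
    least one voxel apart), and the counted number is non-increasing in
    ``proximity_mm``.
    """
    if small_max_mm3 < 0 or proximity_mm < 0:
        raise ValueError("exclusion parameters must be nonnegative")
    table = fragments.table.copy()
    if len(table) == 0:
        return FragmentSet(fragments.labels, table)
    small = table["volume_mm3"].to_numpy() <= small_max_mm3
    large_ids = table.loc[~small, "label"].to_numpy()
    if large_ids.size == 0 or not small.any():
        return FragmentSet(fragments.labels, table)
    lab = fragments.labels.bits
    # fragment voxels are sparse: crop to their bounding box before the
    # distance transform (distances between fragments are unaffected)
    nz = np.nonzero(lab > 0)
    lo = [int(w.min()) for w in nz]
    hi = [int(w.max()) for w in nz]
    lab = lab[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
    large_mask = np.isin(lab, large_ids)
    # distance from every voxel to the nearest large-fragment voxel
    dist = ndimage.distance_transform_edt(
        ~large_mask, sampling=fragments.labels.spacing_mm)
    counted = table["counted"].to_numpy().copy()
    for i, row in table.iterrows():
        if not small[i]:
            continue
        d = float(dist[lab == row["label"]].min())
        if d <= proximity_mm:
            counted[i] = False
    table["counted"] = counted
    return FragmentSet(fragments.labels, table)
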