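import numpy as np
import pytest

from soapct.phantom import cavity_profile
from soapct.segmentation import (SegmentationError, apply_streak_exclusion,
                                 estimate_soap_intensity, segment_block,
                                 segment_cavity, segment_fragments)
from soapct.volume_io import BinaryMask, VoxelVolume


def _analytic_cavity_oracle(vol, truth):
    """Independent voxel-membership check of the parametric cavity."""
    sp, org = vol.spacing_mm, vol.origin_mm
    xs = org[0] + np.arange(vol.shape[0]) * sp[0]
    ys = org[1] + np.arange(vol.shape[1]) * sp[1]
    zs = org[2] + np.arange(vol.shape[2]) * sp[2]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    e = np.array(truth.entry_point_mm)
    u = np.array(truth.true_axis_unit_vector)
    P = np.stack([X - e[0], Y - e[1], Z - e[2]], axis=-1)
    d = P @ u
    rho2 = (P**2).sum(axis=-1) - d**2
    L = truth.cavity_params["length_mm"]
    dd = np.clip(d, 0, L)
    r = cavity_profile(truth.cavity_family, truth.cavity_params, dd.ravel())
    inside = (d.ravel() >= 0) & (d.ravel() <= L) & (rho2.ravel() <= r**2)
    return inside.reshape(vol.shape)


class TestSoapIntensity:
    def test_noiseless_exact(self, cylinder_phantom):
        vol, _ = cylinder_phantom
        assert estimate_soap_intensity(vol) == 100.0

    def test_noisy_within_band(self, noisy_cylinder_phantom):
        vol, _ = noisy_cylinder_phantom
        assert 95.0 <= estimate_soap_intensity(vol) <= 105.0

    def test_all_soap_volume_is_median(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(100, 5, (20, 20, 20)).astype(np.float32)
        vol = VoxelVolume(arr, np.ones(3))
        assert estimate_soap_intensity(vol) == pytest.approx(np.median(arr), abs=1.0)

    def test_constant_volume_rejected(self):
        vol = VoxelVolume(np.full((5, 5, 5), 100.0), np.ones(3))
        with pytest.raises(ValueError, match="constant"):
            estimate_soap_intensity(vol)


class TestSegmentBlock:
    def test_block_matches_truth_rendering(self, noisy_cylinder_phantom):
        """Block mask equals soap voxels (rendered block minus cavity) with
        Dice >= 0.99."""
        vol, truth = noisy_cylinder_phantom
        mask = segment_block(vol)
        m = 6.0  # air margin used by the generator
        sp, org = vol.spacing_mm, vol.origin_mm
        xs = org[0] + np.arange(vol.shape[0]) * sp[0]
        ys = org[1] + np.arange(vol.shape[1]) * sp[1]
        zs = org[2] + np.arange(vol.shape[2]) * sp[2]
        in_block = ((xs >= m) & (xs < m + 60))[:, None, None] \
            & ((ys >= m) & (ys < m + 60))[None, :, None] \
            & ((zs >= m) & (zs < m + 90))[None, None, :]
        expected = in_block & ~_analytic_cavity_oracle(vol, truth)
        inter = (mask.bits & expected).sum()
        dice = 2 * inter / (mask.bits.sum() + expected.sum())
        assert dice >= 0.99

    def test_all_air_rejected(self):
        vol = VoxelVolume(np.full((10, 10, 10), -1000.0), np.ones(3))
        with pytest.raises(SegmentationError, match="no block found"):
            segment_block(vol, soap_intensity_hu=100.0)

    def test_cavity_voxels_not_in_block(self, cylinder_phantom):
        vol, truth = cylinder_phantom
        mask = segment_block(vol)
        cavity = _analytic_cavity_oracle(vol, truth)
        assert not (mask.bits & cavity).any()


class TestSegmentCavity:
    def test_cylinder_cavity_dice(self, noisy_cylinder_phantom):
        vol, truth = noisy_cylinder_phantom
        block = segment_block(vol)
        cav = segment_cavity(vol, block)
        expected = _analytic_cavity_oracle(vol, truth)
        inter = (cav.bits & expected).sum()
        dice = 2 * inter / (cav.bits.sum() + expected.sum())
        assert dice >= 0.98

    def test_explicit_slice_range(self, noisy_cylinder_phantom):
        vol, truth = noisy_cylinder_phantom
        block = segment_block(vol)
        zs = np.where(block.bits.any(axis=(0, 1)))[0]
        cav = segment_cavity(vol, block, int(zs[0]), int(zs[-1]))
        assert cav.bits.sum() == pytest.approx(truth.n_cavity_voxels, rel=0.02)

    def test_zero_thickness_range_gives_one_slice_disc(self, cylinder_phantom):
        vol, truth = cylinder_phantom
        block = segment_block(vol)
        zs = np.where(block.bits.any(axis=(0, 1)))[0]
        s = int(zs[0]) + 20  # 20 mm into the 60 mm cavity
        cav = segment_cavity(vol, block, s, s)
        area = cav.bits.sum() * vol.spacing_mm[0] * vol.spacing_mm[1]
        assert cav.bits[:, :, :s].sum() == 0
        assert cav.bits[:, :, s + 1:].sum() == 0
        assert area == pytest.approx(np.pi * 100, rel=0.05)

    def test_intact_block_has_no_cavity(self, soap_box_volume):
        block = segment_block(soap_box_volume, soap_intensity_hu=100.0)
        with pytest.raises(SegmentationError, match="no cavity found"):
            segment_cavity(soap_box_volume, block, soap_intensity_hu=100.0)

    def test_block_and_cavity_disjoint(self, noisy_cylinder_phantom):
        vol, _ = noisy_cylinder_phantom
        block = segment_block(vol)
        cav = segment_cavity(vol, block)
        assert not (block.bits & cav.bits).any()

    def test_bad_slice_range_rejected(self, noisy_cylinder_phantom):
        vol, _ = noisy_cylinder_phantom
        block = segment_block(vol)
        with pytest.raises(ValueError):
            segment_cavity(vol, block, 50, 10)


class TestSegmentFragments:
    def test_well_separated_fragment_recovery(self, spindle_phantom):
        vol, truth = spindle_phantom
        frags = segment_fragments(vol)
        counted = frags.table[frags.table["volume_mm3"] > 8.0]
        assert len(counted) == len(truth.fragment_radii_mm)
        got = counted[["centroid_x_mm", "centroid_y_mm", "centroid_z_mm"]].to_numpy()
        for c in truth.fragment_centers_mm:
            assert np.min(np.linalg.norm(got - np.array(c), axis=1)) <= 1.0

    def test_no_metal_gives_empty_set(self, soap_box_volume):
        frags = segment_fragments(soap_box_volume)
        assert frags.n_total == 0
        assert frags.n_counted == 0

    def test_face_sharing_voxels_merge(self):
        arr = np.full((10, 10, 10), 100.0, dtype=np.float32)
        arr[3, 3, 3] = 3000.0
        arr[3, 3, 4] = 3000.0  # shares a face
        arr[7, 7, 7] = 3000.0
        arr[8, 8, 8] = 3000.0  # shares only a corner: merged under 26-conn
        vol = VoxelVolume(arr, np.ones(3))
        assert segment_fragments(vol).n_total == 2

    def test_deterministic_label_order(self, spindle_phantom):
        vol, _ = spindle_phantom
        t = segment_fragments(vol).table
        z = t["centroid_z_mm"].to_numpy()
        assert np.all(np.diff(z) >= 0)


class TestStreakExclusion:
    def _two_fragment_volume(self):
        arr = np.full((30, 30, 30), 100.0, dtype=np.float32)
        arr[5:10, 5:10, 5:10] = 3000.0   # 125 mm^3 large fragment
        arr[12, 7, 7] = 3000.0           # 1 voxel, 2 mm from its surface
        arr[25, 25, 25] = 3000.0         # lone speck far away
        return VoxelVolume(arr, np.ones(3))

    def test_small_near_large_excluded_lone_kept(self):
        frags = segment_fragments(self._two_fragment_volume())
        out = apply_streak_exclusion(frags, small_max_mm3=8.0, proximity_mm=5.0)
        assert out.n_total == 3
        assert out.n_counted == 2
        excluded = out.table[~out.table["counted"]]
        assert len(excluded) == 1
        assert excluded["n_voxels"].iloc[0] == 1
        assert excluded["centroid_x_mm"].iloc[0] == pytest.approx(12.0)

    def test_zero_proximity_keeps_raw_count(self):
        frags = segment_fragments(self._two_fragment_volume())
        out = apply_streak_exclusion(frags, proximity_mm=0.0)
        assert out.n_counted == out.n_total == 3

    def test_count_monotone_in_proximity(self):
        frags = segment_fragments(self._two_fragment_volume())
        counts = [apply_streak_exclusion(frags, proximity_mm=p).n_counted
                  for p in (0.0, 1.0, 3.0, 5.0, 30.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_phantom_specks_excluded_true_fragments_kept(self, spindle_phantom):
        vol, truth = spindle_phantom
        out = apply_streak_exclusion(segment_fragments(vol))
        assert out.n_counted == len(truth.fragment_radii_mm)
        assert out.n_total == out.n_counted + len(truth.streak_speck_centers_mm)

    def test_negative_parameters_rejected(self, spindle_phantom):
        vol, _ = spindle_phantom
        frags = segment_fragments(vol)
        with pytest.raises(ValueError):
            apply_streak_exclusion(frags, proximity_mm=-1.0)
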