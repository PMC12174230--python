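"""Unit tests for the SUV quantification chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lutedr import quant
from lutedr.quant import (
    SpectVolume, SphereVOI, background_stats, place_background_sphere,
    segment_above_threshold, to_suv, total_uptake,
)

from conftest import brute_force_sphere, random_blob_mask


def make_volume(values, spacing=(2.0, 2.0, 2.0), units="SUV"):
    return SpectVolume(values=np.asarray(values, dtype=float),
                       voxel_spacing_mm=spacing, units=units)


# ---------------------------------------------------------------------------
# SUV conversion
# ---------------------------------------------------------------------------

class TestToSUV:
    def test_zero_volume_stays_zero(self):
        vol = make_volume(np.zeros((4, 4, 4)), units="Bq/mL")
        out = to_suv(vol, injected_activity_MBq=7400, body_weight_kg=70)
        assert out.units == "SUV"
        assert np.all(out.values == 0)

    def test_hand_arithmetic(self):
        # 1000 Bq/mL * 70000 g / 7.4e9 Bq = 9.459e-3
        vol = make_volume(np.full((2, 2, 2), 1000.0), units="Bq/mL")
        out = to_suv(vol, injected_activity_MBq=7400, body_weight_kg=70,
                     decay_interval_h=0.0)
        assert out.values.flat[0] == pytest.approx(1000 * 70000 / 7.4e9, rel=1e-12)

    def test_one_half_life_doubles_suv(self):
        vol = make_volume(np.full((2, 2, 2), 500.0), units="Bq/mL")
        base = to_suv(vol, 7400, 70, decay_interval_h=0.0)
        decayed = to_suv(vol, 7400, 70, decay_interval_h=quant.LU177_HALF_LIFE_H)
        assert np.allclose(decayed.values, 2.0 * base.values, rtol=1e-12)

    @pytest.mark.parametrize("activity,weight", [(0, 70), (-1, 70), (7400, 0)])
    def test_nonpositive_inputs_rejected(self, activity, weight):
        vol = make_volume(np.ones((2, 2, 2)), units="Bq/mL")
        with pytest.raises(ValueError):
            to_suv(vol, activity, weight)

    def test_requires_concentration_units(self):
        vol = make_volume(np.ones((2, 2, 2)), units="SUV")
        with pytest.raises(ValueError, match="Bq/mL"):
            to_suv(vol, 7400, 70)


# ---------------------------------------------------------------------------
# sphere placement
# ---------------------------------------------------------------------------

class TestSpherePlacement:
    def test_radius_cap_on_large_cube(self):
        # 80 mm cube: inscribed distance 40 mm >> cap of 25 mm
        mask = np.zeros((50, 50, 50), dtype=bool)
        mask[5:45, 5:45, 5:45] = True  # 80 mm at 2 mm spacing
        sphere = place_background_sphere(mask, (2.0, 2.0, 2.0))
        assert sphere.radius_mm == 25.0

    def test_small_cube_inscribed_radius(self):
        # 20 mm cube at 1 mm spacing: center voxel is 10 mm from exterior
        mask = np.zeros((30, 30, 30), dtype=bool)
        mask[5:25, 5:25, 5:25] = True
        sphere = place_background_sphere(mask, (1.0, 1.0, 1.0))
        assert sphere.radius_mm == pytest.approx(10.0)
        for c in sphere.center_mm:
            assert 13.0 <= c <= 16.0  # central voxel of the cube

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            place_background_sphere(np.zeros((5, 5, 5), dtype=bool), (1, 1, 1))

    @pytest.mark.parametrize("shape,seed,spacing", [
        ((12, 12, 12), 0, (1.0, 1.0, 1.0)),
        ((16, 16, 16), 1, (2.0, 2.0, 2.0)),
        ((20, 20, 20), 2, (1.5, 1.5, 3.0)),
        ((32, 32, 32), 3, (2.36, 2.36, 3.0)),
    ])
    def test_matches_exhaustive_oracle(self, shape, seed, spacing):
        """Placement equals brute-force search over all voxel centers."""
        mask = random_blob_mask(shape, seed)
        sphere = place_background_sphere(mask, spacing)
        oracle_idx, oracle_r = brute_force_sphere(mask, spacing)
        assert sphere.radius_mm == pytest.approx(oracle_r, rel=1e-9)
        oracle_center = tuple(oracle_idx[a] * spacing[a] for a in range(3))
        assert sphere.center_mm == pytest.approx(oracle_center)


# ---------------------------------------------------------------------------
# background statistics
# ---------------------------------------------------------------------------

class TestBackgroundStats:
    def test_constant_field(self):
        vol = make_volume(np.full((11, 11, 11), 0.5), spacing=(1, 1, 1))
        sphere = SphereVOI(center_mm=(5, 5, 5), radius_mm=3.0)
        stats = background_stats(vol, sphere)
        assert stats.suv_mean == pytest.approx(0.5)
        assert stats.suv_sd == 0.0
        assert stats.threshold == pytest.approx(0.5)

    def test_published_worked_example(self):
        """Reference-region mean 0.088 with SD 0.059 must give the
        mean + 2 SD threshold 0.206."""
        vol_values = np.zeros((9, 9, 9))
        vol = make_volume(vol_values, spacing=(1, 1, 1))
        sphere = SphereVOI(center_mm=(4, 4, 4), radius_mm=2.2)
        inside = quant._sphere_member_mask(vol, sphere)
        n = int(inside.sum())
        assert n >= 4 and n % 2 == 1
        # symmetric values around 0.088 engineered to an exact sample SD
        k = (n - 1) // 2
        delta = 0.059 * np.sqrt((n - 1) / (2 * k))
        vals = np.full(n, 0.088)
        vals[:k] += delta
        vals[k:2 * k] -= delta
        vol_values[inside] = vals
        vol = make_volume(vol_values, spacing=(1, 1, 1))
        stats = background_stats(vol, sphere)
        assert stats.suv_mean == pytest.approx(0.088, abs=1e-12)
        assert stats.suv_sd == pytest.approx(0.059, abs=1e-12)
        assert stats.threshold == pytest.approx(0.206, abs=1e-9)

    def test_recovers_phantom_noise_sd(self, default_phantom):
        """Sphere SD in the muscle/background region estimates the
        generating noise SD within Monte-Carlo error."""
        spec, (vol, bg_mask, body, truth) = default_phantom
        sphere = place_background_sphere(bg_mask, vol.voxel_spacing_mm)
        stats = background_stats(vol, sphere)
        se = spec.background_suv_sd / np.sqrt(2 * (stats.n_voxels - 1))
        assert abs(stats.suv_sd - spec.background_suv_sd) < 3 * se + 1e-3

    def test_too_few_voxels_rejected(self):
        vol = make_volume(np.ones((9, 9, 9)), spacing=(5, 5, 5))
        sphere = SphereVOI(center_mm=(20, 20, 20), radius_mm=1.0)
        with pytest.raises(ValueError, match="voxel center"):
            background_stats(vol, sphere)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

class TestSegmentation:
    def test_zero_threshold_selects_body(self):
        vol = make_volume(np.full((6, 6, 6), 0.2))
        body = np.zeros((6, 6, 6), dtype=bool)
        body[1:5, 1:5, 1:5] = True
        seg = segment_above_threshold(vol, 0.0, body_mask=body)
        assert np.array_equal(seg, body)

    def test_threshold_above_max_is_empty(self):
        vol = make_volume(np.full((6, 6, 6), 0.2))
        assert not segment_above_threshold(vol, 0.3).any()

    def test_threshold_is_inclusive(self):
        vol = make_volume(np.full((4, 4, 4), 0.206))
        assert segment_above_threshold(vol, 0.206).all()

    def test_noiseless_phantom_matches_compartment_union(self, noiseless_phantom):
        """With the threshold between background and lesion SUV, the
        segmentation is exactly the union of compartment rasterizations."""
        spec, (vol, bg_mask, body, truth) = noiseless_phantom
        threshold = 0.5 * min(c.suv_value for c in spec.compartments)
        assert threshold > spec.background_suv_mean
        seg = segment_above_threshold(vol, threshold, body_mask=body)
        compartment_union = body & ~truth.background_mask
        assert np.array_equal(seg, compartment_union)


# ---------------------------------------------------------------------------
# total uptake
# ---------------------------------------------------------------------------

class TestTotalUptake:
    def test_empty_mask_zeros(self):
        vol = make_volume(np.ones((4, 4, 4)))
        m = total_uptake(vol, np.zeros((4, 4, 4), dtype=bool))
        assert (m.segmented_volume_mL, m.segmented_suv_mean, m.total_uptake) \
            == (0.0, 0.0, 0.0)

    def test_hand_arithmetic(self):
        # 10 voxels of SUV 2.0 at 8 mm^3/voxel: 0.08 mL, mean 2.0, total 0.16
        values = np.zeros((5, 5, 5))
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask.flat[:10] = True
        values[mask] = 2.0
        vol = make_volume(values, spacing=(2.0, 2.0, 2.0))
        m = total_uptake(vol, mask)
        assert m.segmented_volume_mL == pytest.approx(0.08)
        assert m.segmented_suv_mean == pytest.approx(2.0)
        assert m.total_uptake == pytest.approx(0.16)

    def test_published_identity_mean_times_volume(self):
        """The published example (segmented SUVmean 3.60, total 31,062)
        implies a volume of 8628.3 mL; mean x volume must reproduce the
        total."""
        implied_volume = 31062 / 3.60
        assert implied_volume == pytest.approx(8628.3, abs=0.05)
        m = quant.UptakeMetrics(segmented_volume_mL=implied_volume,
                                segmented_suv_mean=3.60,
                                total_uptake=3.60 * implied_volume)
        assert m.total_uptake == pytest.approx(31062, rel=1e-12)

    def test_additive_under_disjoint_union(self):
        rng = np.random.default_rng(4)
        vol = make_volume(rng.uniform(0, 5, size=(8, 8, 8)))
        mask_a = rng.uniform(size=(8, 8, 8)) < 0.3
        mask_b = (rng.uniform(size=(8, 8, 8)) < 0.3) & ~mask_a
        tot_union = total_uptake(vol, mask_a | mask_b).total_uptake
        tot_parts = (total_uptake(vol, mask_a).total_uptake
                     + total_uptake(vol, mask_b).total_uptake)
        assert tot_union == pytest.approx(tot_parts, rel=1e-9)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           seed=st.integers(min_value=0, max_value=2**16))
    def test_scaling_suv_scales_outputs(self, scale, seed):
        """Scaling all SUVs by k scales mean and total by k for a fixed
        mask (volume is unchanged)."""
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 3, size=(6, 6, 6))
        mask = rng.uniform(size=(6, 6, 6)) < 0.4
        mask.flat[0] = True
        base = total_uptake(make_volume(values), mask)
        scaled = total_uptake(make_volume(values * scale), mask)
        assert scaled.segmented_volume_mL == base.segmented_volume_mL
        assert scaled.segmented_suv_mean == pytest.approx(
            base.segmented_suv_mean * scale, rel=1e-9)
        assert scaled.total_uptake == pytest.approx(
            base.total_uptake * scale, rel=1e-9)

    def test_noiseless_phantom_total_equals_truth(self, noiseless_phantom):
        spec, (vol, bg_mask, body, truth) = noiseless_phantom
        metrics, stats, sphere, seg = quant.quantify_volume(
            vol, bg_mask, body_mask=body)
        assert stats.suv_sd == pytest.approx(0.0, abs=1e-12)
        assert metrics.total_uptake == pytest.approx(truth.total_uptake,
                                                     rel=1e-12)


# ---------------------------------------------------------------------------
# NIfTI round trip
# ---------------------------------------------------------------------------

def test_nifti_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    vol = SpectVolume(values=rng.uniform(0, 4, size=(7, 6, 5)),
                      voxel_spacing_mm=(2.36, 2.36, 3.0),
                      origin_mm=(1.0, -2.0, 3.0), units="SUV")
    path = tmp_path / "vol.nii.gz"
    quant.write_volume(vol, path)
    back = quant.read_volume(path, units="SUV")
    assert np.allclose(back.values, vol.values)
    assert back.voxel_spacing_mm == pytest.approx(vol.voxel_spacing_mm)
    assert back.origin_mm == pytest.approx(vol.origin_mm)

    mask = rng.uniform(size=(7, 6, 5)) < 0.5
    quant.write_mask(mask, vol.voxel_spacing_mm, tmp_path / "mask.nii.gz")
    assert np.array_equal(quant.read_mask(tmp_path / "mask.nii.gz"), mask)
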