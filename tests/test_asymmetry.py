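import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asymvbm.asymmetry import (
    AI_DENOM_EPS,
    build_symmetric_template,
    compute_ai,
    flip_lr,
    fwhm_to_sigma,
    gaussian_smooth,
    make_right_mask,
)
from asymvbm.volume import GMVolume, centered_affine


def make_vol(data, voxel_size=3.0):
    data = np.asarray(data, dtype=float)
    return GMVolume(data, centered_affine(data.shape, voxel_size))


class TestFlip:
    def test_involution_bit_exact(self, random_volume):
        flipped_twice = flip_lr(flip_lr(random_volume))
        assert np.array_equal(flipped_twice.data, random_volume.data)

    def test_symmetric_volume_unchanged(self, random_volume):
        sym = random_volume.like(
            0.5 * (random_volume.data + random_volume.data[::-1])
        )
        assert np.array_equal(flip_lr(sym).data, sym.data)

    def test_sum_preserved_exactly(self, random_volume):
        assert flip_lr(random_volume).data.sum() == random_volume.data.sum()

    def test_impulse_maps_to_mirror_index(self):
        # index-map oracle: on an 8-wide 3 mm centered grid the column
        # centers are -10.5..+10.5 mm; world +7.5 mm is column 6 and its
        # mirror (-7.5 mm) is column 1
        vol = make_vol(np.zeros((8, 6, 6)))
        xs = vol.affine[0, 0] * np.arange(8) + vol.affine[0, 3]
        src = int(np.flatnonzero(xs == 7.5)[0])
        dst = int(np.flatnonzero(xs == -7.5)[0])
        assert (src, dst) == (6, 1)
        vol.data[src, 3, 3] = 1.0
        out = flip_lr(vol)
        assert out.data[dst, 3, 3] == 1.0
        assert out.data.sum() == 1.0

    def test_odd_grid_rejected(self):
        vol = GMVolume(np.zeros((7, 6, 6)), centered_affine((7, 6, 6), 3.0))
        with pytest.raises(ValueError, match="even"):
            flip_lr(vol)

    def test_uncentered_grid_rejected(self):
        aff = centered_affine((8, 6, 6), 3.0)
        aff[0, 3] += 1.0
        with pytest.raises(ValueError, match="centered"):
            flip_lr(GMVolume(np.zeros((8, 6, 6)), aff))


class TestSymmetricTemplate:
    def test_single_symmetric_volume_is_fixed_point(self, random_volume):
        sym = random_volume.like(
            0.5 * (random_volume.data + random_volume.data[::-1])
        )
        out = build_symmetric_template([sym])
        assert np.allclose(out.data, sym.data)

    def test_output_equals_own_flip(self, rng):
        vols = [make_vol(rng.random((10, 12, 10))) for _ in range(5)]
        template = build_symmetric_template(vols)
        assert np.array_equal(flip_lr(template).data, template.data)

    def test_mirrored_blobs_half_amplitude(self):
        # arithmetic oracle: blob only in volume A at (i,j,k), its mirror
        # only in volume B; template = mean over {A, flip(A), B, flip(B)}
        a = np.zeros((8, 8, 8))
        b = np.zeros((8, 8, 8))
        a[5, 4, 4] = 1.0
        b[2, 4, 4] = 1.0  # mirror column of 5 on an 8-wide grid
        template = build_symmetric_template([make_vol(a), make_vol(b)])
        assert template.data[5, 4, 4] == pytest.approx(0.5)
        assert template.data[2, 4, 4] == pytest.approx(0.5)
        assert template.data.sum() == pytest.approx(1.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            build_symmetric_template([])

    def test_geometry_mismatch_rejected(self, random_volume):
        other = make_vol(np.zeros((8, 6, 6)))
        with pytest.raises(ValueError):
            build_symmetric_template([random_volume, other])


class TestRightMask:
    def test_all_mask_voxels_right_of_midline(self, random_volume):
        mask = make_right_mask(random_volume, 0.2)
        xs = random_volume.affine[0, 0] * np.arange(10) + random_volume.affine[0, 3]
        assert mask.data[xs <= 0].sum() == 0

    def test_zero_threshold_full_right_support(self, random_volume):
        mask = make_right_mask(random_volume, 0.0)
        xs = random_volume.affine[0, 0] * np.arange(10) + random_volume.affine[0, 3]
        expected = (random_volume.data > 0) & (xs > 0)[:, None, None]
        assert np.array_equal(mask.data, expected)

    def test_count_matches_exhaustive_scan(self, random_volume):
        thr = 0.6
        mask = make_right_mask(random_volume, thr)
        count = 0
        for i in range(10):
            for j in range(12):
                for k in range(10):
                    world = random_volume.index_to_world([i, j, k])[0]
                    if world[0] > 0 and random_volume.data[i, j, k] >= thr:
                        count += 1
        assert mask.n_voxels == count

    def test_bad_threshold_rejected(self, random_volume):
        with pytest.raises(ValueError):
            make_right_mask(random_volume, 1.5)


class TestComputeAI:
    def _pair(self, i1, i2, shape=(4, 4, 4)):
        orig = make_vol(np.full(shape, i1))
        flip = make_vol(np.full(shape, i2))
        mask = make_right_mask(make_vol(np.ones(shape)), 0.0)
        return orig, flip, mask

    def test_equal_inputs_give_zero(self):
        orig, flip, mask = self._pair(0.5, 0.5)
        ai = compute_ai(orig, flip, mask)
        assert np.all(ai.values == 0.0)

    def test_direct_substitution(self):
        orig, flip, mask = self._pair(0.6, 0.4)
        ai = compute_ai(orig, flip, mask)
        assert ai.values == pytest.approx(0.4, abs=1e-12)

    def test_range_boundary(self):
        orig, flip, mask = self._pair(0.3, 0.0)
        ai = compute_ai(orig, flip, mask)
        assert ai.values == pytest.approx(2.0, abs=1e-12)

    def test_zero_denominator_epsilon(self):
        orig, flip, mask = self._pair(AI_DENOM_EPS / 4, AI_DENOM_EPS / 4)
        ai = compute_ai(orig, flip, mask)
        assert np.all(ai.values == 0.0)

    def test_antisymmetry_under_swap(self, random_volume):
        flipped = flip_lr(random_volume)
        mask = make_right_mask(make_vol(np.ones(random_volume.shape)), 0.0)
        a = compute_ai(random_volume, flipped, mask)
        b = compute_ai(flipped, random_volume, mask)
        assert np.allclose(a.values, -b.values, atol=1e-12)

    @given(
        i1=st.floats(0.0, 1.0, allow_nan=False),
        i2=st.floats(0.0, 1.0, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_range_property(self, i1, i2):
        orig, flip, mask = self._pair(i1, i2, shape=(2, 2, 2))
        ai = compute_ai(orig, flip, mask)
        assert np.all(ai.values >= -2.0 - 1e-12)
        assert np.all(ai.values <= 2.0 + 1e-12)

    def test_zero_outside_mask(self, random_volume):
        flipped = flip_lr(random_volume)
        mask = make_right_mask(random_volume, 0.9)
        ai = compute_ai(random_volume, flipped, mask)
        assert np.all(ai.data[~mask.data] == 0.0)

    def test_check_flip_flag(self, random_volume):
        mask = make_right_mask(random_volume, 0.0)
        with pytest.raises(ValueError, match="flip"):
            compute_ai(random_volume, random_volume, mask, check_flip=True)


class TestSmoothing:
    def test_zero_fwhm_is_identity(self, random_volume):
        out = gaussian_smooth(random_volume, 0.0)
        assert np.array_equal(out.data, random_volume.data)

    def test_constant_image_unchanged(self):
        vol = make_vol(np.full((10, 10, 10), 0.37))
        out = gaussian_smooth(vol, 8.0)
        assert np.allclose(out.data, 0.37)

    def test_impulse_peak_matches_analytic_kernel(self):
        # closed-form separable oracle: the center value of a smoothed unit
        # impulse is the product of the three normalized 1-D kernel centers
        vol = make_vol(np.zeros((17, 17, 17)), voxel_size=3.0)
        vol.data[8, 8, 8] = 1.0
        fwhm = 8.0
        out = gaussian_smooth(vol, fwhm)
        sigma_vox = fwhm_to_sigma(fwhm) / 3.0
        radius = int(4.0 * sigma_vox + 0.5)  # scipy's default truncate=4.0
        taps = np.exp(-np.arange(-radius, radius + 1) ** 2 / (2 * sigma_vox**2))
        center = (taps / taps.sum())[radius]
        assert out.data[8, 8, 8] == pytest.approx(center**3, rel=1e-10)

    def test_integral_preserved_on_interior_support(self, rng):
        data = np.zeros((20, 20, 20))
        data[7:13, 7:13, 7:13] = rng.random((6, 6, 6))
        vol = make_vol(data)
        out = gaussian_smooth(vol, 6.0)
        assert out.data.sum() == pytest.approx(data.sum(), rel=1e-6)

    def test_negative_fwhm_rejected(self, random_volume):
        with pytest.raises(ValueError):
            gaussian_smooth(random_volume, -1.0)

    def test_ai_map_resmoothed_and_remasked(self, random_volume):
        flipped = flip_lr(random_volume)
        mask = make_right_mask(random_volume, 0.3)
        ai = gaussian_smooth(compute_ai(random_volume, flipped, mask), 6.0)
        assert ai.smoothed
        assert np.all(ai.data[~mask.data] == 0.0)
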