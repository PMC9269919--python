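import numpy as np
import pytest

from atriaquant import (
    ImageVolume,
    LabelMap,
    PhantomSpec,
    d_abs,
    fibrosis_threshold,
    generate_la_phantom,
    group_summary,
    iir_normalize,
    measure_fibrosis,
    percent_mf_slicewise,
    percent_mf_volumetric,
)
from atriaquant.core import NoEnhancementError, NormalizationError, ValidationError
from atriaquant.fibrosis import NormalizedWall


def make_volume(data, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(np.asarray(data, dtype=float), spacing=spacing)


def split_masks(shape, spacing=(1.0, 1.0, 1.0)):
    """Left half of the grid is blood pool, right half wall."""
    pool = np.zeros(shape, dtype=bool)
    wall = np.zeros(shape, dtype=bool)
    half = shape[0] // 2
    pool[:half] = True
    wall[half:] = True
    return (
        LabelMap(pool, "blood_pool", spacing),
        LabelMap(wall, "wall", spacing),
    )


def nw_from_values(values, shape=None, spacing=(1.0, 1.0, 1.0)):
    """NormalizedWall with given NI values laid out along a 1-voxel column."""
    values = np.asarray(values, dtype=float)
    if shape is None:
        shape = (len(values), 1, 1)
    wall = LabelMap(np.ones(shape, dtype=bool), "wall", spacing)
    sigma = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return NormalizedWall(values=values, wall=wall, mu_ni=float(values.mean()), sigma_ni=sigma)


class TestNormalize:
    def test_constant_image_gives_ni_one_and_zero_sd(self):
        vol = make_volume(np.full((6, 4, 4), 37.0))
        pool, wall = split_masks((6, 4, 4))
        bp, nw = iir_normalize(vol, pool, wall)
        assert bp.mu_bp == 37.0
        assert np.all(nw.values == 1.0)
        assert nw.sigma_ni == 0.0

    def test_global_intensity_scaling_leaves_ni_identical(self, rng):
        data = rng.random((6, 4, 4)) * 500 + 1
        pool, wall = split_masks((6, 4, 4))
        _, nw1 = iir_normalize(make_volume(data), pool, wall)
        # power-of-two scaling is exact in binary floating point → bit identity
        _, nw8 = iir_normalize(make_volume(8.0 * data), pool, wall)
        np.testing.assert_array_equal(nw1.values, nw8.values)
        # arbitrary scaling agrees to rounding error
        _, nw7 = iir_normalize(make_volume(7.0 * data), pool, wall)
        np.testing.assert_allclose(nw1.values, nw7.values, rtol=1e-15)

    def test_additive_offset_is_not_invariant(self, rng):
        data = rng.random((6, 4, 4)) * 500 + 1
        pool, wall = split_masks((6, 4, 4))
        _, nw = iir_normalize(make_volume(data), pool, wall)
        _, nw_off = iir_normalize(make_volume(data + 100.0), pool, wall)
        assert not np.allclose(nw.values, nw_off.values)

    def test_mu_ni_matches_direct_summation(self, rng):
        data = rng.random((6, 4, 4)) * 100
        pool, wall = split_masks((6, 4, 4))
        bp, nw = iir_normalize(make_volume(data), pool, wall)
        expected = sum(data[i, j, k] / bp.mu_bp for i, j, k in np.argwhere(wall.mask)) / wall.voxel_count
        assert nw.mu_ni == pytest.approx(expected, rel=1e-12)

    def test_empty_pool_rejected(self):
        vol = make_volume(np.ones((4, 4, 4)))
        empty = LabelMap(np.zeros((4, 4, 4), dtype=bool), "blood_pool")
        wall = LabelMap(np.ones((4, 4, 4), dtype=bool), "wall")
        with pytest.raises(NormalizationError):
            iir_normalize(vol, empty, wall)


class TestThreshold:
    def test_mean_plus_two_sd(self):
        nw = nw_from_values([1.0])
        nw.mu_ni, nw.sigma_ni = 1.0, 0.05
        nw.values = np.array([1.0, 1.0])  # ≥2 voxels
        assert fibrosis_threshold(nw) == pytest.approx(1.10)

    def test_top_of_observed_range(self):
        nw = nw_from_values([0.9, 0.9])
        nw.mu_ni, nw.sigma_ni = 0.9, 0.2
        assert fibrosis_threshold(nw) == pytest.approx(1.3)

    def test_zero_sd_degenerates_to_mean(self):
        nw = nw_from_values([0.8, 0.8])
        assert fibrosis_threshold(nw) == pytest.approx(0.8)

    def test_configurable_multiplier(self):
        nw = nw_from_values([0.9, 1.1])
        sigma = np.std([0.9, 1.1], ddof=1)
        assert fibrosis_threshold(nw, k_sd=3) == pytest.approx(1.0 + 3 * sigma)

    def test_single_voxel_rejected(self):
        with pytest.raises(ValidationError):
            fibrosis_threshold(nw_from_values([1.0]))


class TestVolumetric:
    def test_nothing_above_threshold_is_zero_percent(self):
        nw = nw_from_values([0.5, 0.6, 0.7])
        _, _, _, pct = percent_mf_volumetric(nw, t_fib=1.0)
        assert pct == 0.0

    def test_volume_uses_voxel_dimensions(self):
        values = np.concatenate([np.full(100, 2.0), np.full(50, 0.5)])
        nw = nw_from_values(values, spacing=(0.625, 0.625, 0.975))
        mf_voxels, mf_volume, wall_volume, _ = percent_mf_volumetric(nw, t_fib=1.0)
        assert mf_voxels == 100
        assert mf_volume == pytest.approx(38.0859375)  # 100 · 0.625² · 0.975
        assert wall_volume == pytest.approx(150 * 0.625**2 * 0.975)

    def test_threshold_is_strict(self):
        nw = nw_from_values([1.0, 1.0, 2.0])
        mf_voxels, *_ = percent_mf_volumetric(nw, t_fib=1.0)
        assert mf_voxels == 1  # values exactly at the threshold are healthy

    def test_noise_free_phantom_fraction_recovered_exactly(self, noise_free_phantom):
        img, truth = noise_free_phantom
        m = measure_fibrosis(img, truth.blood_pool_mask, truth.wall_mask)
        assert m.percent_mf_volumetric == pytest.approx(truth.true_percent_mf, abs=1e-12)
        assert m.percent_mf_volumetric == pytest.approx(10.0, abs=100.0 / truth.wall_mask.voxel_count)


class TestClosedFormBreakdown:
    """Binary wall with healthy NI a, fibrotic NI b: T_fib < b iff f < 0.2."""

    @pytest.mark.parametrize("f", [0.02, 0.05, 0.10, 0.15])
    def test_measured_equals_100f_below_breakdown(self, f):
        n = 2000
        k = round(f * n)
        values = np.concatenate([np.full(n - k, 0.6), np.full(k, 1.4)])
        nw = nw_from_values(values)
        t = fibrosis_threshold(nw)
        *_, pct = percent_mf_volumetric(nw, t)
        assert pct == pytest.approx(100.0 * k / n, abs=1e-12)

    @pytest.mark.parametrize("f", [0.25, 0.3, 0.5])
    def test_measured_is_zero_above_breakdown(self, f):
        n = 2000
        k = round(f * n)
        values = np.concatenate([np.full(n - k, 0.6), np.full(k, 1.4)])
        nw = nw_from_values(values)
        t = fibrosis_threshold(nw)
        *_, pct = percent_mf_volumetric(nw, t)
        assert pct == 0.0


def test_gaussian_null_approaches_phi_minus_two(rng):
    """Fibrosis-free Gaussian wall: %MF → 100·Φ(−2) ≈ 2.28%."""
    n = 120_000
    values = rng.normal(0.8, 0.1, n)
    nw = nw_from_values(values, shape=(n, 1, 1))
    t = fibrosis_threshold(nw)
    *_, pct = percent_mf_volumetric(nw, t)
    assert pct == pytest.approx(2.275, abs=0.5)


class TestSlicewise:
    def test_unique_argmax_slice_found(self):
        wall = np.zeros((4, 4, 8), dtype=bool)
        wall[:, :, :] = True
        values = np.full(wall.sum(), 0.5)
        nw = NormalizedWall(np.asarray(values), LabelMap(wall, "wall"), 0.5, 0.0)
        # put all fibrosis in slice 5: wall voxels are C-ordered, slice index
        # varies fastest, so voxel (i, j, 5) sits at flat position 16i+4j... use volume
        ni = np.full((4, 4, 8), 0.5)
        ni[1, 1, 5] = ni[2, 2, 5] = 2.0
        nw.values = ni[wall]
        k, pct, tie = percent_mf_slicewise(nw, t_fib=1.0)
        assert k == 5 and not tie
        assert pct == pytest.approx(100.0 * 2 / 16)

    def test_arithmetic_10_of_40(self):
        wall = np.zeros((40, 1, 2), dtype=bool)
        wall[:, :, :] = True
        ni = np.full((40, 1, 2), 0.5)
        ni[:10, 0, 1] = 2.0
        nw = NormalizedWall(ni[wall], LabelMap(wall, "wall"), 0.0, 0.0)
        k, pct, _ = percent_mf_slicewise(nw, t_fib=1.0)
        assert (k, pct) == (1, pytest.approx(25.0))

    def test_matches_exhaustive_per_slice_scan(self, rng):
        shape = (8, 8, 6)
        wall = rng.random(shape) < 0.6
        ni = rng.random(shape) * 2
        nw = NormalizedWall(ni[wall], LabelMap(wall, "wall"), 0.0, 0.0)
        t = 1.4
        fib = (ni > t) & wall
        counts = [fib[:, :, k].sum() for k in range(shape[2])]
        if sum(counts) == 0:
            pytest.skip("no fibrotic voxel in this draw")
        k_expect = int(np.argmax(counts))
        k, pct, _ = percent_mf_slicewise(nw, t)
        assert k == k_expect
        assert pct == pytest.approx(100.0 * counts[k_expect] / wall[:, :, k_expect].sum())

    def test_no_enhancement_is_a_distinct_error(self):
        nw = nw_from_values([0.5, 0.6, 0.7])
        with pytest.raises(NoEnhancementError):
            percent_mf_slicewise(nw, t_fib=1.0)


class TestDabs:
    def test_identity_and_sign(self):
        assert d_abs(1.0, 1.0) == 0.0
        assert d_abs(2.0, 1.35) == pytest.approx(-0.65)
        assert d_abs(1.0, 0.64) == pytest.approx(-0.36)

    def test_linearity_over_paired_animals(self, rng):
        vb = rng.random(9)
        vp = rng.random(9)
        mean_d = np.mean([d_abs(b, p) for b, p in zip(vb, vp)])
        assert mean_d == pytest.approx(vp.mean() - vb.mean())


class TestGroupSummary:
    def test_matches_printed_histology_group_stats(self):
        averages = [20.18, 21.23, 20.77, 23.73, 11.17]
        s = group_summary(averages)
        assert s.mean == pytest.approx(19.42, abs=0.005)
        assert s.sd == pytest.approx(4.80, abs=0.005)

    def test_single_value_has_no_sd(self):
        s = group_summary([3.5])
        assert (s.mean, s.median, s.sd) == (3.5, 3.5, None)

    def test_iqr_uses_linear_interpolation(self):
        s = group_summary([1.0, 2.0, 3.0, 4.0])
        assert s.iqr == pytest.approx(np.percentile([1, 2, 3, 4], 75) - np.percentile([1, 2, 3, 4], 25))

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            group_summary([])


class TestScaleInvariancePipeline:
    def test_percent_mf_bit_identical_under_global_scaling(self, default_phantom):
        img, truth = default_phantom
        m1 = measure_fibrosis(img, truth.blood_pool_mask, truth.wall_mask)
        scaled = ImageVolume(img.data * 3.7, img.spacing, img.origin)
        m2 = measure_fibrosis(scaled, truth.blood_pool_mask, truth.wall_mask)
        assert m1.percent_mf_volumetric == m2.percent_mf_volumetric
        assert m1.percent_mf_slicewise == m2.percent_mf_slicewise
        assert m1.mf_voxels == m2.mf_voxels


def test_in_situ_timepoint_rejected_for_iir(default_phantom):
    img, truth = default_phantom
    with pytest.raises(ValidationError, match="in-situ"):
        measure_fibrosis(
            img, truth.blood_pool_mask, truth.wall_mask, timepoint="in_situ"
        )
    m = measure_fibrosis(
        img, truth.blood_pool_mask, truth.wall_mask, timepoint="in_situ", allow_in_situ=True
    )
    assert m.timepoint == "in_situ"
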