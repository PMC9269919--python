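import numpy as np
import pytest
from itertools import combinations

from atriaquant import (
    ImageVolume,
    LabelMap,
    boundary_scores,
    dice,
    icc_intra,
    inter_rater_r,
    nema4_snr,
    pairwise_mean_dice,
    relative_volume_error,
)
from atriaquant.core import ValidationError
from atriaquant.metrics import _reliability, boundary_voxels
from conftest import random_mask


def box(shape, lo, hi, spacing=(1.0, 1.0, 1.0)) -> LabelMap:
    m = np.zeros(shape, dtype=bool)
    m[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    return LabelMap(m, "generic", spacing)


class TestSnr:
    def make_inputs(self, shape=(20, 20, 6)):
        signal = box(shape, (8, 8, 0), (12, 12, 6))
        rois = [
            box(shape, (0, 0, 0), (3, 3, 3)),
            box(shape, (0, 17, 0), (3, 20, 3)),
            box(shape, (17, 0, 0), (20, 3, 3)),
            box(shape, (17, 17, 0), (20, 20, 3)),
        ]
        return signal, rois

    def test_forced_arithmetic(self, rng):
        signal, rois = self.make_inputs()
        data = np.zeros((20, 20, 6))
        data[signal.mask] = 100.0
        # background alternating ±1 around 0 → SD exactly 1 per ROI (ddof=1 on ±1 of even count)
        for roi in rois:
            n = roi.voxel_count
            vals = np.tile([1.0, -1.0], n // 2 + 1)[:n]
            data[roi.mask] = vals - vals.mean()
        vol = ImageVolume(data)
        res = nema4_snr(vol, signal, rois)
        sd = np.std(data[rois[0].mask], ddof=1)
        assert res.snr == pytest.approx(0.66 * 100.0 / sd)

    def test_scale_invariance(self, rng):
        signal, rois = self.make_inputs()
        data = rng.random((20, 20, 6)) * 50 + 10
        v1 = nema4_snr(ImageVolume(data), signal, rois).snr
        v2 = nema4_snr(ImageVolume(2 * data), signal, rois).snr
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_rayleigh_background_closed_form(self, rng):
        from atriaquant.phantom import rician_noise

        shape = (30, 30, 10)
        signal = box(shape, (12, 12, 2), (18, 18, 8))
        rois = [
            box(shape, (0, 0, 0), (6, 6, 6)),
            box(shape, (0, 24, 0), (6, 30, 6)),
            box(shape, (24, 0, 0), (30, 6, 6)),
            box(shape, (24, 24, 0), (30, 30, 6)),
        ]
        mu, sigma = 500.0, 12.0
        base = np.zeros(shape)
        base[signal.mask] = mu
        data = rician_noise(base, sigma, rng)
        res = nema4_snr(ImageVolume(data), signal, rois)
        expect = 0.66 * mu / (sigma * np.sqrt(2 - np.pi / 2))
        # 3 SE over the 4 pooled background ROIs (n ≈ 864)
        assert res.snr == pytest.approx(expect, rel=0.05)

    def test_wrong_roi_count_rejected(self, rng):
        signal, rois = self.make_inputs()
        data = rng.random((20, 20, 6))
        with pytest.raises(ValidationError):
            nema4_snr(ImageVolume(data), signal, rois[:3])


class TestDice:
    def test_identity_disjoint_and_conventions(self, rng):
        a = random_mask(rng, p=0.3)
        assert dice(a, a) == 100.0
        b = LabelMap(~a.mask)
        assert dice(a, b) == 0.0
        empty = LabelMap(np.zeros(a.shape, dtype=bool))
        assert dice(empty, empty) == 100.0
        assert dice(a, empty) == 0.0

    def test_forced_arithmetic(self):
        shape = (20, 10, 1)
        a = box(shape, (0, 0, 0), (10, 10, 1))  # 100 voxels
        b = box(shape, (5, 0, 0), (15, 10, 1))  # 100 voxels, overlap 50
        assert dice(a, b) == pytest.approx(50.0)

    def test_symmetry(self, rng):
        a, b = random_mask(rng), random_mask(rng)
        assert dice(a, b) == dice(b, a)

    def test_erosion_decreases_dice_on_convex_mask(self):
        shape = (20, 20, 5)
        full = box(shape, (4, 4, 1), (16, 16, 4))
        d_prev = 100.0
        for shrink in (1, 2, 3):
            eroded = box(shape, (4 + shrink, 4 + shrink, 1), (16 - shrink, 16 - shrink, 4))
            d = dice(full, eroded)
            assert d < d_prev
            d_prev = d


class TestPairwiseDice:
    def test_three_identical(self, rng):
        m = random_mask(rng, p=0.3)
        mean, sd = pairwise_mean_dice([m, m, m])
        assert (mean, sd) == (100.0, 0.0)

    def test_matches_explicit_pair_enumeration(self, rng):
        masks = [random_mask(rng, p=0.3) for _ in range(4)]
        mean, sd = pairwise_mean_dice(masks)
        scores = [dice(a, b) for a, b in combinations(masks, 2)]
        assert mean == pytest.approx(np.mean(scores))
        assert sd == pytest.approx(np.std(scores, ddof=1))

    def test_fewer_than_two_rejected(self, rng):
        with pytest.raises(ValidationError):
            pairwise_mean_dice([random_mask(rng)])


class TestBoundaryScores:
    def test_identical_masks_score_100(self, rng):
        m = random_mask(rng, p=0.3)
        assert boundary_scores(m, m, tolerance=0)[0] == 100.0

    def test_one_voxel_offset_within_tolerance_two(self):
        shape = (20, 20, 5)
        ref = box(shape, (5, 5, 1), (12, 12, 4))
        cand = box(shape, (4, 4, 1), (13, 13, 4))  # boundary 1 voxel outside
        f1, precision, recall = boundary_scores(cand, ref, tolerance=2)
        assert f1 == pytest.approx(100.0)

    def test_matches_all_pairs_distance_oracle(self, rng):
        cand = random_mask(rng, shape=(7, 7, 4), p=0.3)
        ref = random_mask(rng, shape=(7, 7, 4), p=0.3)
        tol = 1.5
        cb = np.argwhere(boundary_voxels(cand))
        rb = np.argwhere(boundary_voxels(ref))
        if len(cb) == 0 or len(rb) == 0:
            pytest.skip("empty boundary draw")
        def frac_within(src, dst):
            hits = 0
            for p in src:
                dmin = min(np.sqrt(((p - q) ** 2).sum()) for q in dst)
                hits += dmin <= tol
            return 100.0 * hits / len(src)
        f1, precision, recall = boundary_scores(cand, ref, tolerance=tol)
        p_expect = frac_within(cb, rb)
        r_expect = frac_within(rb, cb)
        assert precision == pytest.approx(p_expect)
        assert recall == pytest.approx(r_expect)
        assert f1 == pytest.approx(2 * p_expect * r_expect / (p_expect + r_expect))

    def test_infinite_tolerance_gives_100_for_nonempty_masks(self, rng):
        a, b = random_mask(rng, p=0.2), random_mask(rng, p=0.2)
        f1, *_ = boundary_scores(a, b, tolerance=np.inf)
        assert f1 == 100.0

    def test_empty_conventions(self):
        shape = (6, 6, 3)
        empty = LabelMap(np.zeros(shape, dtype=bool))
        full = box(shape, (1, 1, 1), (4, 4, 2))
        assert boundary_scores(empty, empty)[0] == 100.0
        assert boundary_scores(empty, full)[0] == 0.0


class TestRelativeVolumeError:
    def test_cases(self, rng):
        shape = (20, 10, 1)
        ref = box(shape, (0, 0, 0), (10, 10, 1))  # 100
        assert relative_volume_error(ref, ref) == 0.0
        cand = box(shape, (0, 0, 0), (11, 10, 1))  # 110
        assert relative_volume_error(cand, ref) == pytest.approx(0.10)
        empty = LabelMap(np.zeros(shape, dtype=bool))
        assert relative_volume_error(empty, ref) == -1.0
        with pytest.raises(ValidationError):
            relative_volume_error(ref, empty)


class TestReliability:
    def test_zero_within_variance_gives_perfect_icc(self):
        icc, *_ = icc_intra([[2.0, 2.0, 2.0], [5.0, 5.0, 5.0]])
        assert icc == pytest.approx(1.0)

    def test_equal_components_give_half(self):
        # two conditions built so that sigma2_w == sigma2_b exactly
        data = [[0.0, 2.0], [2.0, 4.0]]  # within var 2, means 1 & 3 → between var 2
        icc, s2w, s2b = icc_intra(data)
        assert s2w == pytest.approx(s2b)
        assert icc == pytest.approx(0.5)

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(77)
        s2w, s2b, n_cond, reps = 1.0, 4.0, 200, 3
        mu = rng.normal(0, np.sqrt(s2b), n_cond)
        data = mu[:, None] + rng.normal(0, np.sqrt(s2w), (n_cond, reps))
        icc, *_ = icc_intra(data)
        assert icc == pytest.approx(1 / (1 + s2w / s2b), abs=0.05)

    def test_degenerate_between_variance_rejected(self):
        with pytest.raises(ValidationError):
            icc_intra([[1.0, 2.0], [1.0, 2.0]])

    def test_inter_rater_forced_arithmetic(self):
        # per condition, two operators with within var 2 each; condition means 1 and 3
        cond1 = [[0.0, 2.0], [0.0, 2.0]]
        cond2 = [[2.0, 4.0], [2.0, 4.0]]
        r, k = inter_rater_r([cond1, cond2])
        assert k == 2
        assert r == pytest.approx(2.0 / 3.0)  # (1 + 2/(2·2))⁻¹ with s2w = s2b = 2

    def test_zero_within_variance_gives_perfect_r(self):
        cond1 = [[1.0, 1.0], [1.0, 1.0]]
        cond2 = [[4.0, 4.0], [4.0, 4.0]]
        r, _ = inter_rater_r([cond1, cond2])
        assert r == pytest.approx(1.0)

    def test_k_equal_one_formula_collapses_to_icc(self):
        assert _reliability(1.5, 2.5, 1) == pytest.approx(1 / (1 + 1.5 / 2.5))

    def test_r_at_least_icc_for_same_components(self):
        for s2w, s2b in ((1.0, 1.0), (0.5, 2.0), (3.0, 0.7)):
            assert _reliability(s2w, s2b, 2) >= _reliability(s2w, s2b, 1)

    def test_single_operator_rejected(self):
        with pytest.raises(ValidationError):
            inter_rater_r([[[1.0, 2.0]], [[3.0, 4.0]]])
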