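import numpy as np
import pytest

from oarseg.losses import (LossSpec, combined_loss, hd_penalty, soft_dice_grad,
                           soft_dice_loss)
from oarseg.metrics import (UndefinedMetricError, confusion_counts,
                            contour_complexity, hausdorff_3d, sdc, weighted_sdc)


def masks_with_counts(tp: int, fp: int, fn: int):
    """Line up voxels so that pred/ref realize exactly the requested counts."""
    n = tp + fp + fn
    pred = np.zeros((n, 1, 1), dtype=np.uint8)
    ref = np.zeros((n, 1, 1), dtype=np.uint8)
    pred[:tp + fp] = 1
    ref[:tp] = 1
    ref[tp + fp:] = 1
    return pred, ref


def brute_force_hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    pa = np.argwhere(a > 0).astype(float)
    pb = np.argwhere(b > 0).astype(float)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    return max(d.min(axis=1).max(), d.min(axis=0).max())


class TestSDC:
    def test_hand_values(self):
        pred, ref = masks_with_counts(tp=3, fp=1, fn=2)
        c = confusion_counts(pred, ref)
        assert (c.tp, c.fp, c.fn) == (3, 1, 2)
        assert sdc(pred, ref) == pytest.approx(6 / 9)
        assert weighted_sdc(pred, ref, 0.5) == pytest.approx(0.5)
        assert weighted_sdc(pred, ref, 0.05) == pytest.approx(0.3 / 3.3)

    def test_identical_and_disjoint(self):
        a = np.zeros((4, 4, 4), dtype=np.uint8)
        a[:2] = 1
        assert sdc(a, a) == 1.0
        b = np.zeros_like(a)
        b[3:] = 1
        assert sdc(a, b) == 0.0

    def test_both_empty_defined_as_one_with_warning(self):
        e = np.zeros((3, 3, 3), dtype=np.uint8)
        with pytest.warns(UserWarning, match="empty"):
            assert sdc(e, e) == 1.0

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        a = (rng.random((6, 6, 6)) < 0.3).astype(np.uint8)
        b = (rng.random((6, 6, 6)) < 0.3).astype(np.uint8)
        assert sdc(a, b) == pytest.approx(sdc(b, a))

    def test_weighted_monotone_in_w(self):
        pred, ref = masks_with_counts(tp=5, fp=3, fn=2)
        vals = [weighted_sdc(pred, ref, w) for w in (0.05, 0.5, 1.0, 2.0)]
        assert vals == sorted(vals)

    def test_soft_equals_hard_on_binary_map(self):
        pred, ref = masks_with_counts(tp=4, fp=2, fn=1)
        assert sdc(pred.astype(float), ref) == pytest.approx(sdc(pred, ref))


class TestHausdorff:
    def test_identical_masks_zero(self):
        a = np.zeros((5, 5, 5), dtype=np.uint8)
        a[2, 2, 2] = 1
        assert hausdorff_3d(a, a) == 0.0

    def test_pythagorean_pair(self):
        a = np.zeros((6, 6, 6), dtype=np.uint8)
        b = np.zeros_like(a)
        a[0, 0, 0] = 1
        b[3, 4, 0] = 1
        assert hausdorff_3d(a, b) == pytest.approx(5.0)

    def test_directed_asymmetry_resolved_by_max(self):
        a = np.zeros((1, 1, 12), dtype=np.uint8)
        b = np.zeros_like(a)
        a[0, 0, 0] = 1
        b[0, 0, 0] = 1
        b[0, 0, 10] = 1
        # directed a->b is 0, b->a is 10
        assert hausdorff_3d(a, b) == pytest.approx(10.0)

    def test_empty_mask_raises_with_side(self):
        a = np.zeros((3, 3, 3), dtype=np.uint8)
        b = a.copy()
        b[0, 0, 0] = 1
        with pytest.raises(UndefinedMetricError) as exc:
            hausdorff_3d(a, b)
        assert exc.value.empty_side == "a"

    def test_matches_brute_force_and_is_metric(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            a = (rng.random((7, 7, 7)) < 0.2).astype(np.uint8)
            b = (rng.random((7, 7, 7)) < 0.2).astype(np.uint8)
            if not (a.any() and b.any()):
                continue
            d = hausdorff_3d(a, b)
            assert d == pytest.approx(brute_force_hausdorff(a, b))
            assert hausdorff_3d(b, a) == pytest.approx(d)
            assert hausdorff_3d(a, a) == 0.0

    def test_spacing_scales_distances(self):
        a = np.zeros((1, 1, 5), dtype=np.uint8)
        b = np.zeros_like(a)
        a[0, 0, 0] = 1
        b[0, 0, 2] = 1
        assert hausdorff_3d(a, b, spacing=(1, 1, 2.5)) == pytest.approx(5.0)


class TestContourComplexity:
    def test_disk_approaches_continuum_limit(self):
        r = 20
        x, y = np.ogrid[0:64, 0:64]
        disk = (((x - 32) ** 2 + (y - 32) ** 2) < r ** 2).astype(np.uint8)
        score = contour_complexity(disk[:, :, None])
        assert score == pytest.approx(2.0 / r, rel=0.10)

    def test_in_plane_scaling_halves_score(self):
        x, y = np.ogrid[0:64, 0:64]
        small = (((x - 32) ** 2 + (y - 32) ** 2) < 10 ** 2).astype(np.uint8)
        big = (((x - 32) ** 2 + (y - 32) ** 2) < 20 ** 2).astype(np.uint8)
        s1 = contour_complexity(small[:, :, None])
        s2 = contour_complexity(big[:, :, None])
        assert s2 == pytest.approx(s1 / 2, rel=0.10)

    def test_empty_mask_raises(self):
        with pytest.raises(UndefinedMetricError):
            contour_complexity(np.zeros((4, 4, 4), dtype=np.uint8))


class TestLosses:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            LossSpec(kind="sdc_plus_hd")  # roi_diagonal missing
        with pytest.raises(ValueError):
            LossSpec(tp_weight=0.0)
        with pytest.raises(ValueError):
            LossSpec(kind="focal")

    def test_smg_roi_diagonal_and_normalizer(self):
        from oarseg.core import default_roi_spec
        spec = default_roi_spec("SMG")
        assert spec.roi_diagonal == pytest.approx(96.0)  # sqrt(64^2+64^2+32^2)
        ls = LossSpec(kind="sdc_plus_hd", roi_diagonal=spec.roi_diagonal)
        assert ls.hd_normalizer == pytest.approx(31.68)

    def test_maximal_hd_term(self):
        ls = LossSpec(kind="sdc_plus_hd", roi_diagonal=96.0)
        assert 96.0 / ls.hd_normalizer == pytest.approx(3.0303, abs=1e-3)

    def test_perfect_prediction_minimises_both_terms(self):
        ref = np.zeros((8, 8, 8), dtype=np.uint8)
        ref[3:5, 3:5, 3:5] = 1
        ls = LossSpec(kind="sdc_plus_hd", roi_diagonal=96.0)
        assert combined_loss(ref.astype(float), ref, ls) == pytest.approx(0.0)

    def test_empty_prediction_gets_max_hd_penalty(self):
        ref = np.zeros((8, 8, 8), dtype=np.uint8)
        ref[3, 3, 3] = 1
        ls = LossSpec(kind="sdc_plus_hd", roi_diagonal=96.0)
        assert hd_penalty(np.zeros((8, 8, 8)), ref, ls) == pytest.approx(1 / 0.33, rel=1e-6)

    @pytest.mark.parametrize("w", [1.0, 0.5, 0.05])
    def test_analytic_gradient_matches_finite_differences(self, w):
        rng = np.random.default_rng(3)
        prob = rng.uniform(0.05, 0.95, (4, 4, 4))
        ref = (rng.random((4, 4, 4)) < 0.3).astype(np.uint8)
        g = soft_dice_grad(prob, ref, w=w)
        eps = 1e-6
        for idx in [(0, 0, 0), (1, 2, 3), (3, 3, 3)]:
            p2 = prob.copy()
            p2[idx] += eps
            num = (soft_dice_loss(p2, ref, w=w) - soft_dice_loss(prob, ref, w=w)) / eps
            assert g[idx] == pytest.approx(num, rel=1e-4, abs=1e-8)
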