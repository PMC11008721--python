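"""Reference network blocks and losses."""

import math

import numpy as np
import pytest

from rownav import netblocks as nb
from rownav.netblocks import BoxCWH
from oracles import maxpool_naive, nearest_odd_kernel


class TestEcaKernelSize:
    @pytest.mark.parametrize("c,k", [(2, 1), (64, 3), (256, 5), (128, 5), (1, 1)])
    def test_worked_values(self, c, k):
        assert nb.eca_kernel_size(c) == k

    def test_exhaustive_nearest_odd(self):
        for c in range(1, 4097):
            assert nb.eca_kernel_size(c) == nearest_odd_kernel(c)

    def test_invalid_channels(self):
        with pytest.raises(ValueError):
            nb.eca_kernel_size(0)


class TestEcaForward:
    def test_k1_closed_form(self, rng):
        t = rng.normal(size=(4, 5, 5))
        out = nb.eca_forward(t, np.array([1.0]))
        means = t.mean(axis=(1, 2))
        expect = t * (1 / (1 + np.exp(-means)))[:, None, None]
        assert np.allclose(out, expect)

    def test_zero_input_zero_output(self):
        assert np.all(nb.eca_forward(np.zeros((6, 3, 3))) == 0.0)

    def test_shape_preserved_and_scales_bounded(self, rng):
        t = rng.normal(size=(8, 4, 6))
        out = nb.eca_forward(t)
        assert out.shape == t.shape
        scale = out[np.abs(t) > 1e-12] / t[np.abs(t) > 1e-12]
        assert np.all(scale > 0) and np.all(scale < 1)

    def test_monotone_in_channel_values(self, rng):
        t = rng.normal(size=(5, 4, 4))
        k = nb.eca_kernel_size(5)
        kernel = np.abs(rng.normal(size=k))
        base = nb.eca_forward(t, kernel)
        bumped = t.copy()
        bumped[2] += 1.0
        out = nb.eca_forward(bumped, kernel)

        def scale(o, x, c):
            mask = np.abs(x[c]) > 1e-9
            return np.median(o[c][mask] / x[c][mask])

        assert scale(out, bumped, 2) >= scale(base, t, 2)

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError):
            nb.eca_forward(rng.normal(size=(4, 3, 3)), np.ones(2))


class TestCaForward:
    def test_zero_params_quarter_scaling(self, rng):
        t = rng.normal(size=(8, 5, 7))
        params = nb.make_ca_params(8, reduction=4, zero=True)
        assert np.allclose(nb.ca_forward(t, params), 0.25 * t)

    def test_constant_input_constant_attention(self):
        t = np.full((4, 6, 6), 0.7)
        params = nb.make_ca_params(4, reduction=2, seed=3)
        out = nb.ca_forward(t, params)
        # attention constant over space => output constant per channel
        assert np.allclose(out, out[:, :1, :1])

    def test_attenuation_for_nonnegative_input(self, rng):
        t = np.abs(rng.normal(size=(6, 8, 8)))
        out = nb.ca_forward(t, nb.make_ca_params(6, reduction=3, seed=1))
        assert np.all(out <= t + 1e-12) and np.all(out >= 0)
        assert out.shape == t.shape

    def test_factorised_structure_matches_naive_loop(self, rng):
        t = rng.normal(size=(3, 4, 5))
        params = nb.make_ca_params(3, reduction=1, seed=9)
        out = nb.ca_forward(t, params)
        pool_h = t.mean(axis=2)
        pool_w = t.mean(axis=1)
        mixed = np.maximum(params.w_mix @ np.concatenate([pool_h, pool_w], axis=1), 0)
        for c in range(3):
            for y in range(4):
                for x in range(5):
                    a_h = 1 / (1 + math.exp(-(params.w_h @ mixed[:, y])[c]))
                    a_w = 1 / (1 + math.exp(-(params.w_w @ mixed[:, 4 + x])[c]))
                    assert out[c, y, x] == pytest.approx(t[c, y, x] * a_h * a_w, rel=1e-12)

    def test_excessive_reduction_rejected(self):
        with pytest.raises(ValueError):
            nb.make_ca_params(4, reduction=8)


class TestSppf:
    def test_sequential_pool_equivalence(self, rng):
        for _ in range(10):
            t = rng.normal(size=(3, 12, 9))
            cat = nb.sppf_forward(t)
            assert np.array_equal(cat[3:6], nb._maxpool_same(t, 5))
            assert np.array_equal(cat[6:9], nb._maxpool_same(t, 9))
            assert np.array_equal(cat[9:12], nb._maxpool_same(t, 13))

    def test_matches_naive_maxpool(self, rng):
        t = rng.normal(size=(2, 7, 6))
        assert np.array_equal(nb._maxpool_same(t, 5), maxpool_naive(t, 5))

    def test_monotone_pyramid(self, rng):
        t = rng.normal(size=(2, 10, 10))
        cat = nb.sppf_forward(t)
        c = 2
        assert np.all(cat[c:2 * c] >= t)
        assert np.all(cat[2 * c:3 * c] >= cat[c:2 * c])
        assert np.all(cat[3 * c:] >= cat[2 * c:3 * c])

    def test_constant_tensor_fixed_point(self):
        t = np.full((2, 6, 6), 1.3)
        cat = nb.sppf_forward(t)
        assert np.all(cat == 1.3)

    def test_projection_shape(self, rng):
        t = rng.normal(size=(4, 6, 6))
        proj = rng.normal(size=(4, 16))
        assert nb.sppf_forward(t, proj).shape == t.shape
        with pytest.raises(ValueError):
            nb.sppf_forward(t, rng.normal(size=(4, 8)))


class TestFocus:
    def test_2x2_enumeration(self):
        t = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        out = nb.focus_slice(t)
        assert out.shape == (4, 1, 1)
        assert out.ravel().tolist() == [1.0, 2.0, 3.0, 4.0]  # TL, TR, BL, BR

    def test_multiset_preserved(self, rng):
        t = rng.normal(size=(3, 8, 10))
        out = nb.focus_slice(t)
        assert out.shape == (12, 4, 5)
        assert sorted(out.ravel()) == sorted(t.ravel())

    def test_full_resolution_shape(self):
        assert nb.focus_slice(np.zeros((3, 640, 640))).shape == (12, 320, 320)

    def test_odd_dims_rejected(self):
        with pytest.raises(ValueError):
            nb.focus_slice(np.zeros((1, 3, 4)))


class TestCiou:
    def test_identical_boxes_zero(self):
        t = nb.ciou_loss(BoxCWH(3, 4, 2, 5), BoxCWH(3, 4, 2, 5))
        assert t.loss == pytest.approx(0.0, abs=1e-12)
        assert t.iou == 1.0 and t.v == 0.0 and t.alpha == 0.0

    def test_concentric_squares(self):
        t = nb.ciou_loss(BoxCWH(0, 0, 2, 2), BoxCWH(0, 0, 4, 4))
        assert t.iou == pytest.approx(0.25)
        assert t.loss == pytest.approx(0.75)

    def test_disjoint_unit_squares(self):
        t = nb.ciou_loss(BoxCWH(0, 0, 1, 1), BoxCWH(10, 0, 1, 1))
        assert t.iou == 0.0 and t.rho == 10.0
        assert t.c_diag == pytest.approx(math.hypot(11, 1))
        assert t.loss == pytest.approx(1 + 100 / 122)

    def test_lower_bound_one_minus_iou(self, rng):
        for _ in range(200):
            a = BoxCWH(*rng.uniform(1, 9, 2), *rng.uniform(0.5, 4, 2))
            b = BoxCWH(*rng.uniform(1, 9, 2), *rng.uniform(0.5, 4, 2))
            t = nb.ciou_loss(a, b)
            assert t.loss >= 1 - t.iou - 1e-12
            assert t.c_diag >= t.rho - 1e-12
            assert 0 <= t.loss < 3

    def test_translation_and_scale_invariance(self, rng):
        for _ in range(100):
            a = BoxCWH(*rng.uniform(0, 10, 2), *rng.uniform(0.5, 5, 2))
            b = BoxCWH(*rng.uniform(0, 10, 2), *rng.uniform(0.5, 5, 2))
            base = nb.ciou_loss(a, b).loss
            dx, dy = rng.uniform(-30, 30, 2)
            s = rng.uniform(0.1, 10)
            shifted = nb.ciou_loss(
                BoxCWH(a.cx + dx, a.cy + dy, a.w, a.h),
                BoxCWH(b.cx + dx, b.cy + dy, b.w, b.h)).loss
            scaled = nb.ciou_loss(
                BoxCWH(s * a.cx, s * a.cy, s * a.w, s * a.h),
                BoxCWH(s * b.cx, s * b.cy, s * b.w, s * b.h)).loss
            assert shifted == pytest.approx(base, rel=1e-9, abs=1e-12)
            assert scaled == pytest.approx(base, rel=1e-9, abs=1e-12)

    def test_nonpositive_extent_rejected(self):
        with pytest.raises(ValueError):
            BoxCWH(0, 0, -1, 2)


def make_batch(n=4, n_pos=2, perfect=True, rng=None):
    rng = rng or np.random.default_rng(0)
    pos = np.zeros(n, dtype=bool)
    pos[:n_pos] = True
    cls_true = np.ones((n, 1))
    obj_true = pos.astype(float)
    if perfect:
        cls_pred = cls_true.copy()
        obj_pred = obj_true.copy()
        boxes = [BoxCWH(1, 1, 2, 2)] * n_pos
        return nb.LossBatch(cls_pred, cls_true, obj_pred, obj_true,
                            boxes, list(boxes), np.zeros((n, 4)), np.zeros((n, 4)), pos)
    cls_pred = rng.uniform(0.2, 0.9, (n, 1))
    obj_pred = rng.uniform(0.1, 0.9, n)
    bp = [BoxCWH(*rng.uniform(2, 8, 2), *rng.uniform(1, 3, 2)) for _ in range(n_pos)]
    bt = [BoxCWH(*rng.uniform(2, 8, 2), *rng.uniform(1, 3, 2)) for _ in range(n_pos)]
    return nb.LossBatch(cls_pred, cls_true, obj_pred, obj_true,
                        bp, bt, rng.normal(size=(n, 4)), rng.normal(size=(n, 4)), pos)


class TestCompositeLoss:
    def test_perfect_predictions_zero(self):
        total, parts = nb.composite_loss(make_batch(perfect=True), l1_enabled=True)
        assert total == pytest.approx(0.0, abs=1e-9)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in parts.values())

    def test_single_positive_linearity(self):
        batch = make_batch(n=1, n_pos=1, perfect=True)
        batch.cls_pred = np.array([[math.exp(-0.3)]])
        total, parts = nb.composite_loss(batch)
        assert total == pytest.approx(0.3)
        assert parts["cls"] == pytest.approx(0.3)

    def test_duplicated_batch_leaves_loss_unchanged(self):
        # doubling N_pos by duplicating identical samples: every summed term
        # doubles along with the 1/N_pos normaliser, so L is invariant
        rng = np.random.default_rng(4)
        b1 = make_batch(n=6, n_pos=2, perfect=False, rng=rng)
        dup = nb.LossBatch(
            np.concatenate([b1.cls_pred, b1.cls_pred]),
            np.concatenate([b1.cls_true, b1.cls_true]),
            np.concatenate([b1.obj_pred, b1.obj_pred]),
            np.concatenate([b1.obj_true, b1.obj_true]),
            b1.boxes_pred + b1.boxes_pred, b1.boxes_true + b1.boxes_true,
            np.concatenate([b1.reg_pred, b1.reg_pred]),
            np.concatenate([b1.reg_true, b1.reg_true]),
            np.concatenate([b1.pos_mask, b1.pos_mask]))
        t1, _ = nb.composite_loss(b1, l1_enabled=True)
        t2, _ = nb.composite_loss(dup, l1_enabled=True)
        assert t2 == pytest.approx(t1, rel=1e-12)

    def test_normalisation_by_n_pos(self):
        b = make_batch(n=2, n_pos=2, perfect=True)
        b.cls_pred = np.full((2, 1), math.exp(-0.5))
        total, parts = nb.composite_loss(b)
        assert parts["cls"] == pytest.approx(0.5)  # (0.5 + 0.5) / 2

    def test_linear_in_lambdas_and_breakdown_sums(self):
        b = make_batch(n=5, n_pos=2, perfect=False)
        t1, parts = nb.composite_loss(b, lambda1=1, lambda2=5, lambda3=1, l1_enabled=True)
        assert t1 == pytest.approx(sum(parts.values()))
        t2, parts2 = nb.composite_loss(b, lambda1=2, lambda2=5, lambda3=1, l1_enabled=True)
        assert parts2["obj"] == pytest.approx(2 * parts["obj"])
        assert t2 - t1 == pytest.approx(parts["obj"])

    def test_l1_gate(self):
        b = make_batch(n=5, n_pos=2, perfect=False)
        off, parts_off = nb.composite_loss(b, l1_enabled=False)
        on, parts_on = nb.composite_loss(b, l1_enabled=True)
        assert parts_off["reg"] == 0.0 and parts_on["reg"] > 0
        assert on > off

    def test_no_positives_rejected(self):
        b = make_batch(n=3, n_pos=1, perfect=True)
        b.pos_mask[:] = False
        b.boxes_pred, b.boxes_true = [], []
        with pytest.raises(ValueError):
            nb.composite_loss(b)
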