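"""Heat-flow codec: diffusion, source placement, encode/decode, discretization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maskflow import flow_codec as fc
from maskflow import metrics

from conftest import disc_mask


class TestHeatDiffuse:
    def test_single_pixel_accumulates_deposits(self):
        support = np.ones((1, 1), dtype=bool)
        for n in (1, 5, 40):
            assert fc.heat_diffuse(support, (0, 0), n)[0, 0] == pytest.approx(n)

    def test_bar_maximum_at_source(self):
        heat = fc.heat_diffuse(np.ones((1, 3), bool), (0, 1), 1)
        assert heat[0, 1] == heat.max()

    def test_bar_strictly_decreasing_from_source(self):
        heat = fc.heat_diffuse(np.ones((1, 5), bool), (0, 2), 50)[0]
        assert heat[0] < heat[1] < heat[2]
        assert heat[4] < heat[3] < heat[2]

    def test_heat_positive_everywhere_reachable(self):
        support = disc_mask((32, 32), [(16, 16, 10)]) > 0
        heat = fc.heat_diffuse(support, (16, 16), 2 * 32)
        assert (heat[support] > 0).all()
        assert (heat[~support] == 0).all()

    def test_source_outside_support_errors(self):
        with pytest.raises(ValueError, match="outside"):
            fc.heat_diffuse(np.ones((3, 3), bool), (5, 0), 1)


class TestSourcePixel:
    def test_odd_square_exact_center(self):
        assert fc.source_pixel(np.ones((5, 5), bool)) == (2, 2)

    def test_even_square_row_major_first_central(self):
        assert fc.source_pixel(np.ones((4, 4), bool)) == (1, 1)

    def test_disc_center(self, single_disc):
        assert fc.source_pixel(single_disc > 0) == (32, 32)

    def test_c_shape_projects_to_nearest_support_pixel(self):
        # C-shaped region whose centroid falls in the gap
        support = np.ones((9, 9), dtype=bool)
        support[2:7, 3:] = False
        rows, cols = np.nonzero(support)
        cy, cx = rows.mean(), cols.mean()
        assert not support[int(round(cy)), int(round(cx))]
        # brute-force nearest (Euclidean), ties by row-major order
        d2 = (rows - cy) ** 2 + (cols - cx) ** 2
        winners = np.flatnonzero(d2 <= d2.min() + 1e-12)
        flat = rows[winners] * 9 + cols[winners]
        expected = (int(rows[winners][np.argmin(flat)]), int(cols[winners][np.argmin(flat)]))
        assert fc.source_pixel(support) == expected

    def test_empty_support_errors(self):
        with pytest.raises(ValueError, match="empty"):
            fc.source_pixel(np.zeros((4, 4), bool))


class TestEncode:
    def test_all_background_gives_zero_flow(self):
        flow = fc.encode_mask(np.zeros((16, 16), dtype=np.int32))
        assert not flow.prob.any()
        assert not flow.grad_y.any()
        assert not flow.grad_x.any()

    def test_disc_gradients_point_toward_source(self, single_disc):
        flow = fc.encode_mask(single_disc)
        rows, cols = np.nonzero(single_disc)
        ty, tx = 32.0 - rows, 32.0 - cols
        norm = np.hypot(ty, tx)
        off_source = norm > 0
        dot = (
            flow.grad_y[rows, cols][off_source] * ty[off_source]
            + flow.grad_x[rows, cols][off_source] * tx[off_source]
        ) / norm[off_source]
        assert (dot > 0).all()
        angles = np.degrees(np.arccos(np.clip(dot, -1, 1)))
        assert angles.mean() < 15.0

    def test_prob_channel_is_foreground_indicator(self, touching_discs):
        flow = fc.encode_mask(touching_discs)
        np.testing.assert_array_equal(flow.prob, (touching_discs > 0).astype(float))

    def test_touching_discs_gradients_split_at_boundary(self, touching_discs):
        flow = fc.encode_mask(touching_discs)
        sources = {1: (32, 21), 2: (32, 41)}
        for obj_id, (sy, sx) in sources.items():
            rows, cols = np.nonzero(touching_discs == obj_id)
            ty, tx = sy - rows.astype(float), sx - cols.astype(float)
            norm = np.hypot(ty, tx)
            off = norm > 0
            dot = (
                flow.grad_y[rows, cols][off] * ty[off] + flow.grad_x[rows, cols][off] * tx[off]
            ) / norm[off]
            assert (dot > 0).all()

    def test_multi_object_encoding_is_per_object_local(self, touching_discs):
        """Encoding a multi-object mask equals encoding each object alone on
        its own support: heat never crosses the background or other objects."""
        combined = fc.encode_mask(touching_discs)
        for obj_id in (1, 2):
            alone = fc.encode_mask((touching_discs == obj_id).astype(np.int32))
            sel = touching_discs == obj_id
            np.testing.assert_allclose(combined.grad_y[sel], alone.grad_y[sel], atol=1e-12)
            np.testing.assert_allclose(combined.grad_x[sel], alone.grad_x[sel], atol=1e-12)

    def test_unit_norm_inside_objects(self, touching_discs):
        flow = fc.encode_mask(touching_discs)
        norm = np.hypot(flow.grad_y, flow.grad_x)
        inside = touching_discs > 0
        nonzero = inside & (norm > 0)
        np.testing.assert_allclose(norm[nonzero], 1.0, atol=1e-6)
        # zero-gradient in-object pixels are heat sources only
        zero_px = np.argwhere(inside & (norm == 0))
        sources = {fc.source_pixel(touching_discs == i) for i in (1, 2)}
        assert {tuple(p) for p in zero_px} <= sources
        assert not norm[~inside].any()


class TestDecode:
    def test_all_zero_flow_decodes_to_background(self):
        zero = np.zeros((32, 32))
        mask = fc.decode_flow(fc.FlowField(zero, zero, zero))
        assert not mask.any()

    def test_roundtrip_single_disc(self, single_disc):
        decoded = fc.decode_flow(fc.encode_mask(single_disc))
        assert decoded.max() == 1
        _, _, _, pairs = metrics.match_objects(decoded, single_disc, 0.5)
        assert len(pairs) == 1 and pairs[0][2] >= 0.95

    def test_roundtrip_separates_touching_discs(self, touching_discs):
        decoded = fc.decode_flow(fc.encode_mask(touching_discs))
        assert decoded.max() == 2
        _, _, _, pairs = metrics.match_objects(decoded, touching_discs, 0.5)
        assert len(pairs) == 2
        assert all(iou >= 0.9 for _, _, iou in pairs)

    def test_label_geometry_independent_of_id_permutation(self, touching_discs):
        """Decoded label geometry is canonical: permuting input ids (hence
        internal visit order) yields the identical output mask."""
        flow = fc.encode_mask(touching_discs)
        permuted = np.where(touching_discs == 1, 2, np.where(touching_discs == 2, 1, 0))
        flow_p = fc.encode_mask(permuted)
        np.testing.assert_array_equal(fc.decode_flow(flow), fc.decode_flow(flow_p))

    def test_min_object_area_erases_speckle(self, single_disc):
        flow = fc.encode_mask(single_disc)
        # an isolated 2-px foreground blip with no coherent gradient
        flow.prob[2, 2] = flow.prob[2, 3] = 1.0
        decoded = fc.decode_flow(flow, fc.DecodeParams(min_object_area=9))
        assert decoded.max() == 1

    def test_nan_rejected(self):
        zero = np.zeros((8, 8))
        bad = zero.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            fc.decode_flow(fc.FlowField(zero, bad, zero))

    def test_channel_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            fc.FlowField(np.zeros((8, 8)), np.zeros((8, 9)), np.zeros((8, 8)))


class TestDiscretization:
    def test_interval_endpoints_and_midpoint(self):
        ones = np.ones((1, 1))
        flow = fc.FlowField(prob=ones, grad_y=-ones, grad_x=ones)
        img = fc.discretize_flow(flow)
        assert img.prob[0, 0] == 255
        assert img.grad_y[0, 0] == 0
        assert img.grad_x[0, 0] == 255
        zero = fc.discretize_flow(fc.FlowField(np.zeros((1, 1)), np.zeros((1, 1)), np.zeros((1, 1))))
        assert zero.prob[0, 0] == 0
        assert zero.grad_y[0, 0] == 128  # round(127.5) half away from zero

    def test_out_of_range_rejected(self):
        ones = np.ones((1, 1))
        with pytest.raises(ValueError, match="probability"):
            fc.discretize_flow(fc.FlowField(1.5 * ones, ones, ones))
        with pytest.raises(ValueError, match="grad"):
            fc.discretize_flow(fc.FlowField(ones, 1.5 * ones, ones))

    def test_byte_roundtrip_is_identity(self):
        grid = np.arange(256, dtype=np.uint8).reshape(16, 16)
        img = fc.FlowImage(prob=grid, grad_y=grid, grad_x=grid)
        back = fc.discretize_flow(fc.dediscretize_flow(img))
        np.testing.assert_array_equal(back.prob, grid)
        np.testing.assert_array_equal(back.grad_y, grid)
        np.testing.assert_array_equal(back.grad_x, grid)

    def test_gradient_endpoint_inverses(self):
        img = fc.FlowImage(
            prob=np.zeros((1, 2), np.uint8),
            grad_y=np.array([[0, 255]], np.uint8),
            grad_x=np.array([[0, 255]], np.uint8),
        )
        flow = fc.dediscretize_flow(img)
        assert flow.grad_y[0, 0] == -1.0 and flow.grad_y[0, 1] == 1.0

    def test_continuous_roundtrip_within_one_level(self):
        values = np.linspace(-1.0, 1.0, 10001).reshape(73, 137)
        flow = fc.FlowField(prob=(values + 1) / 2, grad_y=values, grad_x=values)
        back = fc.dediscretize_flow(fc.discretize_flow(flow))
        assert np.abs(back.grad_y - values).max() <= 1.0 / 255.0
        assert np.abs(back.grad_x - values).max() <= 1.0 / 255.0
        assert np.abs(back.prob - (values + 1) / 2).max() <= 0.5 / 255.0

    @given(st.floats(min_value=-1.0, max_value=1.0, allow_nan=False))
    @settings(deadline=None, derandomize=True)
    def test_roundtrip_error_bound_holds_pointwise(self, v):
        arr = np.full((1, 1), v)
        flow = fc.FlowField(prob=np.zeros((1, 1)), grad_y=arr, grad_x=arr)
        back = fc.dediscretize_flow(fc.discretize_flow(flow))
        assert abs(back.grad_y[0, 0] - v) <= 1.0 / 255.0


class TestCanonicalize:
    def test_idempotent_on_canonical_mask(self, touching_discs):
        once = fc.canonicalize_mask(touching_discs)
        np.testing.assert_array_equal(once, fc.canonicalize_mask(once))

    def test_splits_disconnected_id_into_two(self):
        mask = np.zeros((8, 8), dtype=np.int32)
        mask[1:3, 1:3] = 5
        mask[5:7, 5:7] = 5
        out = fc.canonicalize_mask(mask)
        assert sorted(np.unique(out[out > 0])) == [1, 2]
        # row-major order of first pixel: upper-left blob gets id 1
        assert out[1, 1] == 1 and out[5, 5] == 2

    def test_diagonal_touch_is_not_connected(self):
        mask = np.zeros((4, 4), dtype=np.int32)
        mask[0, 0] = mask[1, 1] = 7
        assert fc.canonicalize_mask(mask).max() == 2

    def test_empty_mask_unchanged(self):
        out = fc.canonicalize_mask(np.zeros((4, 4), dtype=np.int32))
        assert not out.any()

    def test_negative_ids_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            fc.canonicalize_mask(np.full((2, 2), -1))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_idempotence_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.integers(0, 4, size=(12, 12)).astype(np.int32)
        once = fc.canonicalize_mask(mask)
        np.testing.assert_array_equal(once, fc.canonicalize_mask(once))
        ids = np.unique(once[once > 0])
        np.testing.assert_array_equal(ids, np.arange(1, ids.size + 1))
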