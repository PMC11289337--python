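import numpy as np
import pytest

import valvedet as vd
from valvedet.annotations_io import BBox
from valvedet.model_graph import (Detection, build_model, decode_predictions,
                                  letterbox, nms)


def small_cfg(**overrides):
    from dataclasses import replace

    cfg = vd.get_preset("avd").with_input_size(96)
    return replace(cfg, **overrides)


class TestBuildModel:
    def test_parameters_equal_bruteforce_array_enumeration(self):
        for name in ("avd", "two-scale-s", "baseline-s", "dsconv-s"):
            m = build_model(vd.get_preset(name), seed=0)
            assert m.parameter_count() == m.param_count()

    def test_dropping_a_scale_strictly_shrinks_the_model(self):
        full = build_model(small_cfg(active_scales=("P3", "P4", "P5")), seed=0)
        pruned = build_model(small_cfg(), seed=0)
        assert pruned.layer_count() < full.layer_count()
        assert pruned.parameter_count() < full.parameter_count()
        assert pruned.flop_count(96) < full.flop_count(96)

    def test_separable_mode_strictly_shrinks_at_fixed_topology(self):
        std = build_model(small_cfg(conv_mode="standard"), seed=0)
        sep = build_model(small_cfg(conv_mode="ds"), seed=0)
        assert sep.parameter_count() < std.parameter_count()
        assert sep.flop_count(96) < std.flop_count(96)
        assert sep.layer_count() == std.layer_count()


class TestForward:
    def test_grid_shapes_batch_and_scales(self):
        m = build_model(small_cfg(), seed=0)
        m.set_training(False)
        x = np.zeros((2, 3, 96, 96), np.float32)
        grids = m.forward(x)
        assert [g.shape for g in grids] == [(2, 18, 12, 12), (2, 18, 6, 6)]

    def test_three_scale_grid_resolutions(self):
        m = build_model(small_cfg(active_scales=("P3", "P4", "P5")), seed=0)
        m.set_training(False)
        grids = m.forward(np.zeros((1, 3, 96, 96), np.float32))
        assert [g.shape[2] for g in grids] == [12, 6, 3]

    def test_misaligned_input_rejected(self):
        m = build_model(small_cfg(), seed=0)
        with pytest.raises(Exception):
            m.forward(np.zeros((1, 3, 100, 100), np.float32))


class TestDecode:
    def test_zero_logits_decode_to_cell_center_anchor_size(self):
        grid = np.zeros((1, 18, 4, 4), np.float32)
        dets = decode_predictions([grid], {"P5": ((91, 88),) * 3}, [32], 0.2)[0]
        d = next(x for x in dets
                 if abs(x.bbox.x1 + x.bbox.x2) / 2 < 17 and abs(x.bbox.y1 + x.bbox.y2) / 2 < 17)
        assert (d.bbox.x1 + d.bbox.x2) / 2 == pytest.approx(16.0)
        assert (d.bbox.y1 + d.bbox.y2) / 2 == pytest.approx(16.0)
        assert d.bbox.width == pytest.approx(91.0)
        assert d.bbox.height == pytest.approx(88.0)
        assert d.confidence == pytest.approx(0.25)

    def test_size_saturates_at_four_anchors(self):
        grid = np.zeros((1, 18, 2, 2), np.float32)
        grid.reshape(1, 3, 6, 2, 2)[:, :, 2:4] = 50.0  # sigma -> 1
        dets = decode_predictions([grid], {"P5": ((10, 10),) * 3}, [32], 0.2)[0]
        assert dets[0].bbox.width == pytest.approx(40.0, rel=1e-4)

    def test_threshold_one_yields_nothing(self):
        grid = np.zeros((1, 18, 4, 4), np.float32)
        assert decode_predictions([grid], {"P5": ((91, 88),) * 3}, [32], 1.0)[0] == []

    def test_encode_decode_round_trip_through_target_space(self):
        """A ground-truth box converted to head offsets and decoded back
        reproduces itself (the training target transform is invertible)."""
        rng = np.random.default_rng(0)
        stride, anchor = 16, (40.0, 52.0)
        for _ in range(25):
            cx, cy = rng.uniform(8, 56, 2)
            w = rng.uniform(anchor[0] / 3.9, anchor[0] * 3.9)
            h = rng.uniform(anchor[1] / 3.9, anchor[1] * 3.9)
            gx, gy = cx / stride, cy / stride
            ci_, cj = int(gy), int(gx)

            def logit(s):
                s = np.clip(s, 1e-9, 1 - 1e-9)
                return np.log(s / (1 - s))

            grid = np.full((1, 18, 4, 4), -99.0, np.float32)
            g5 = grid.reshape(1, 3, 6, 4, 4)
            g5[0, 0, 0, ci_, cj] = logit((gx - cj + 0.5) / 2)
            g5[0, 0, 1, ci_, cj] = logit((gy - ci_ + 0.5) / 2)
            g5[0, 0, 2, ci_, cj] = logit(np.sqrt(w / anchor[0]) / 2)
            g5[0, 0, 3, ci_, cj] = logit(np.sqrt(h / anchor[1]) / 2)
            g5[0, 0, 4, ci_, cj] = 10.0
            g5[0, 0, 5, ci_, cj] = 10.0
            d = decode_predictions([grid], {"P4": (anchor,) * 3}, [stride], 0.5)[0][0]
            assert (d.bbox.x1 + d.bbox.x2) / 2 == pytest.approx(cx, rel=1e-4, abs=1e-3)
            assert d.bbox.width == pytest.approx(w, rel=1e-4)
            assert d.bbox.height == pytest.approx(h, rel=1e-4)


class TestNms:
    def box(self, y0, h=10.0):
        return BBox(0, y0, 10, y0 + h)

    def test_duplicate_suppressed_keeps_higher_score(self):
        a = Detection(self.box(0), 0.9)
        b = Detection(self.box(0), 0.8)
        assert nms([b, a], 0.5) == [a]

    def test_disjoint_boxes_all_kept(self):
        a = Detection(self.box(0), 0.9)
        b = Detection(self.box(50), 0.8)
        assert set(nms([a, b], 0.5)) == {a, b}

    def test_suppression_is_not_transitive_along_a_chain(self):
        """A suppresses B (IoU 0.6) but not C (IoU 1/3), even though B
        would have suppressed C — greedy keeps A and C."""
        a = Detection(self.box(0.0), 0.9)
        b = Detection(self.box(2.5), 0.8)
        c = Detection(self.box(5.0), 0.7)
        assert nms([a, b, c], 0.5) == [a, c]

    def test_empty_input(self):
        assert nms([], 0.5) == []


def test_letterbox_preserves_aspect_and_centers():
    img = np.full((100, 200), 50, np.uint8)
    canvas, scale, (dx, dy) = letterbox(img, 96)
    assert canvas.shape == (96, 96)
    assert scale == pytest.approx(96 / 200)
    assert dx == 0 and dy == (96 - 48) // 2
    assert canvas[0, 0] == 114 and canvas[48, 48] == 50
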