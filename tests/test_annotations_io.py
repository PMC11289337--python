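import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from valvedet.annotations_io import (AnnotationError, BBox, NormalizedBox,
                                     decode_yolo_box, encode_yolo_box, iou,
                                     read_label_file, split_dataset,
                                     voc_to_yolo, write_label_file, yolo_to_voc)


@st.composite
def boxes_in_image(draw, img_w=640.0, img_h=480.0):
    x1 = draw(st.floats(0, img_w - 2))
    y1 = draw(st.floats(0, img_h - 2))
    x2 = draw(st.floats(min_value=x1 + 1, max_value=img_w))
    y2 = draw(st.floats(min_value=y1 + 1, max_value=img_h))
    return BBox(x1, y1, x2, y2)


class TestEncodeDecode:
    @pytest.mark.parametrize("box,w,h,expected", [
        (BBox(0, 0, 100, 200), 100, 200, (0.5, 0.5, 1.0, 1.0)),
        (BBox(10, 20, 50, 60), 100, 200, (0.30, 0.20, 0.40, 0.20)),
        (BBox(25, 50, 75, 150), 100, 200, (0.50, 0.50, 0.50, 0.50)),
    ])
    def test_normalization_examples(self, box, w, h, expected):
        n = encode_yolo_box(box, w, h)
        assert (n.cx, n.cy, n.w, n.h) == pytest.approx(expected)

    @pytest.mark.parametrize("n,w,h,expected", [
        (NormalizedBox(0, 0.5, 0.5, 1, 1), 768, 768, (0, 0, 768, 768)),
        (NormalizedBox(0, 0.3, 0.2, 0.4, 0.2), 100, 200, (10, 20, 50, 60)),
    ])
    def test_denormalization_examples(self, n, w, h, expected):
        b = decode_yolo_box(n, w, h)
        assert (b.x1, b.y1, b.x2, b.y2) == pytest.approx(expected)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(box=boxes_in_image())
    def test_round_trip_identity(self, box):
        n = encode_yolo_box(box, 640, 480)
        b = decode_yolo_box(n, 640, 480)
        for attr in ("x1", "y1", "x2", "y2"):
            assert getattr(b, attr) == pytest.approx(getattr(box, attr), abs=1e-9)

    def test_box_outside_image_rejected(self):
        with pytest.raises(AnnotationError):
            encode_yolo_box(BBox(-1, 0, 10, 10), 100, 100)
        with pytest.raises(AnnotationError):
            BBox(10, 10, 10, 20)  # degenerate


class TestLabelFiles:
    def test_single_record_and_round_trip(self, tmp_path):
        f = tmp_path / "a.txt"
        f.write_text("0 0.5 0.5 0.25 0.25\n")
        boxes = read_label_file(f)
        assert boxes == [NormalizedBox(0, 0.5, 0.5, 0.25, 0.25)]
        write_label_file(f, boxes)
        assert read_label_file(f) == boxes

    def test_empty_file_means_no_objects(self, tmp_path):
        f = tmp_path / "empty.txt"
        f.write_text("")
        assert read_label_file(f) == []

    def test_malformed_line_names_its_number(self, tmp_path):
        f = tmp_path / "bad.txt"
        f.write_text("0 0.5 0.5 0.25 0.25\n0 0.5 0.5 0.25\n")
        with pytest.raises(AnnotationError, match=":2"):
            read_label_file(f)

    def test_six_decimal_serialization_is_lossless_enough(self, tmp_path):
        rng = np.random.default_rng(0)
        boxes = []
        for _ in range(50):
            cx, cy = rng.uniform(0.3, 0.7, 2)
            w, h = rng.uniform(0.05, 0.4, 2)
            boxes.append(NormalizedBox(0, cx, cy, w, h))
        f = tmp_path / "r.txt"
        write_label_file(f, boxes)
        back = read_label_file(f)
        for a, b in zip(boxes, back):
            assert b.cx == pytest.approx(a.cx, abs=5e-7)
            assert b.h == pytest.approx(a.h, abs=5e-7)


class TestVoc:
    XML = """<annotation><size><width>100</width><height>200</height><depth>1</depth></size>
    <object><name>aortic_valve</name>
    <bndbox><xmin>10</xmin><ymin>20</ymin><xmax>50</xmax><ymax>60</ymax></bndbox>
    </object></annotation>"""

    def test_object_converts_like_direct_encoding(self):
        out = voc_to_yolo(self.XML)
        assert len(out) == 1
        n = out[0]
        assert (n.cx, n.cy, n.w, n.h) == pytest.approx((0.30, 0.20, 0.40, 0.20))

    def test_empty_annotation(self):
        assert voc_to_yolo("<annotation><size><width>10</width><height>10</height>"
                           "</size></annotation>") == []

    def test_unknown_class_rejected(self):
        bad = self.XML.replace("aortic_valve", "mitral_valve")
        with pytest.raises(AnnotationError):
            voc_to_yolo(bad)

    def test_yolo_voc_yolo_round_trip(self):
        boxes = [NormalizedBox(0, 0.4, 0.3, 0.2, 0.1)]
        doc = yolo_to_voc(boxes, 640, 480)
        back = voc_to_yolo(doc)
        assert back[0].cx == pytest.approx(0.4, abs=1e-9)
        assert back[0].h == pytest.approx(0.1, abs=1e-9)


class TestIoU:
    def test_identity_disjoint_and_partial(self):
        a = BBox(0, 0, 2, 2)
        assert iou(a, a) == 1.0
        assert iou(a, BBox(5, 5, 7, 7)) == 0.0
        assert iou(a, BBox(1, 1, 3, 3)) == pytest.approx(1 / 7)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=boxes_in_image(), b=boxes_in_image())
    def test_symmetric_and_bounded(self, a, b):
        v = iou(a, b)
        assert v == iou(b, a)
        assert 0.0 <= v <= 1.0 + 1e-12


class TestSplit:
    def test_published_dataset_size_splits_208_13_39(self):
        tr, va, te = split_dataset(list(range(260)), (0.80, 0.05, 0.15), seed=0)
        assert (len(tr), len(va), len(te)) == (208, 13, 39)

    def test_single_item_goes_to_train(self):
        assert tuple(map(len, split_dataset([0], seed=1))) == (1, 0, 0)

    def test_same_seed_identical_partition(self):
        a = split_dataset(list(range(50)), seed=9)
        b = split_dataset(list(range(50)), seed=9)
        assert a == b

    def test_bad_ratios_rejected(self):
        with pytest.raises(AnnotationError):
            split_dataset([1, 2], (0.5, 0.4, 0.2))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(n=st.integers(1, 300), seed=st.integers(0, 10_000))
    def test_is_a_partition(self, n, seed):
        items = list(range(n))
        tr, va, te = split_dataset(items, seed=seed)
        combined = tr + va + te
        assert sorted(combined) == items
        assert len(set(combined)) == n
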