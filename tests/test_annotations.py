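"""Label I/O round trips, VOC coordinate conventions, splitting, frame
sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wildasm.annotations import (DatasetManifest, FrameSamplerConfig, NormBox,
                                 build_manifest, extract_frames,
                                 read_voc_xml, read_yolo_labels,
                                 split_dataset, write_yolo_labels)


def norm_boxes(draw):
    cid = draw(st.integers(0, 9))
    w = draw(st.floats(0.01, 1.0))
    h = draw(st.floats(0.01, 1.0))
    cx = draw(st.floats(w / 2, 1 - w / 2))
    cy = draw(st.floats(h / 2, 1 - h / 2))
    return NormBox(cid, cx, cy, w, h)


class TestYoloText:
    def test_parse_single_line(self):
        (box,) = read_yolo_labels("0 0.5 0.5 0.2 0.1", nc=10)
        assert box == NormBox(0, 0.5, 0.5, 0.2, 0.1)

    def test_empty_file_is_valid_negative(self):
        assert read_yolo_labels("", nc=10) == []
        assert write_yolo_labels([]) == ""

    @pytest.mark.parametrize("text,msg", [
        ("3 1.2 0.5 0.1 0.1", "line 1"),     # out-of-range coordinate
        ("0 0.5 0.5 0.2", "5 fields"),
        ("7 0.5 0.5 0.2 0.1", "class id"),   # nc=5 below
        ("a 0.5 0.5 0.2 0.1", "unparsable"),
    ])
    def test_malformed_lines_rejected_with_location(self, text, msg):
        with pytest.raises(ValueError, match=msg):
            read_yolo_labels(text, nc=5)

    @given(st.builds(lambda d: d, st.integers(0, 2 ** 31)))
    @settings(max_examples=25, deadline=None)
    def test_write_read_identity(self, seed):
        rng = np.random.default_rng(seed)
        boxes = []
        for _ in range(3):
            w, h = rng.uniform(0.05, 0.9, 2)
            boxes.append(NormBox(int(rng.integers(10)),
                                 rng.uniform(w / 2, 1 - w / 2),
                                 rng.uniform(h / 2, 1 - h / 2), w, h))
        back = read_yolo_labels(write_yolo_labels(boxes), nc=10)
        for a, b in zip(boxes, back):
            assert a.class_id == b.class_id
            for f in ("cx", "cy", "w", "h"):
                assert getattr(a, f) == pytest.approx(getattr(b, f), abs=1e-6)

    def test_full_width_box_round_trips(self):
        (box,) = read_yolo_labels(write_yolo_labels(
            [NormBox(1, 0.5, 0.5, 1.0, 0.4)]), nc=2)
        assert box.w == pytest.approx(1.0)


VOC = """<annotation><size><width>200</width><height>200</height><depth>3</depth></size>
<object><name>wolf</name><bndbox><xmin>1</xmin><ymin>1</ymin><xmax>100</xmax><ymax>100</ymax></bndbox></object>
</annotation>"""


class TestVocXml:
    def test_one_based_inclusive_conversion(self):
        (box,) = read_voc_xml(VOC, {"wolf": 3})
        assert (box.cx, box.cy, box.w, box.h) == pytest.approx((0.25, 0.25, 0.5, 0.5))
        assert box.class_id == 3

    def test_full_image_box(self):
        xml = VOC.replace("100</xmax>", "200</xmax>").replace("100</ymax>", "200</ymax>")
        (box,) = read_voc_xml(xml, {"wolf": 0})
        assert (box.w, box.h) == pytest.approx((1.0, 1.0))

    def test_unknown_class_listed(self):
        with pytest.raises(ValueError, match="wolf"):
            read_voc_xml(VOC, {"otter": 0})

    def test_degenerate_box_rejected(self):
        xml = VOC.replace("<xmax>100</xmax>", "<xmax>1</xmax>")
        with pytest.raises(ValueError, match="degenerate"):
            read_voc_xml(xml, {"wolf": 0})


class TestSplit:
    def test_published_dataset_size(self):
        tr, va, te = split_dataset(range(8174), (0.6, 0.2, 0.2), seed=0)
        assert (len(tr), len(va), len(te)) == (4906, 1634, 1634)

    @pytest.mark.parametrize("n,expect", [(10, (6, 2, 2)), (5, (3, 1, 1))])
    def test_floor_remainder_convention(self, n, expect):
        parts = split_dataset(range(n), (0.6, 0.2, 0.2), seed=1)
        assert tuple(len(p) for p in parts) == expect

    def test_reproducible_disjoint_exhaustive(self):
        a = split_dataset(range(100), seed=42)
        b = split_dataset(range(100), seed=42)
        assert a == b
        union = set(a[0]) | set(a[1]) | set(a[2])
        assert union == set(range(100))
        assert len(a[0]) + len(a[1]) + len(a[2]) == 100

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([1, 2], seed=0)


class TestFrameSampler:
    def test_static_video_hits_min_rate_clamp(self):
        frames = [np.zeros((8, 8))] * 301
        times = [i / 30 for i in range(301)]   # 10 s inclusive
        assert extract_frames(frames, times) == [0, 150, 300]

    def test_noise_video_hits_max_rate_clamp(self):
        rng = np.random.default_rng(0)
        frames = [rng.uniform(0, 255, (8, 8)) for _ in range(301)]
        times = [i / 30 for i in range(301)]
        picked = extract_frames(frames, times)
        assert len(picked) == 31
        gaps = np.diff([times[i] for i in picked])
        assert (gaps >= 1 / 3 - 1e-9).all()

    def test_scripted_jumps_match_simulation(self):
        """A bright square jumping every 2 s triggers captures at each jump."""
        times = [i / 10 for i in range(101)]   # 10 s at 10 fps
        frames = []
        for t in times:
            f = np.zeros((20, 20))
            pos = int(t // 2) % 3
            f[pos * 5:pos * 5 + 5, pos * 5:pos * 5 + 5] = 255.0
            frames.append(f)
        cfg = FrameSamplerConfig(min_rate=0.2, max_rate=3, diff_threshold=10)
        picked = extract_frames(frames, times, cfg)
        jump_times = {2.0, 4.0, 6.0, 8.0}
        assert jump_times <= {times[i] for i in picked}
        gaps = np.diff([times[i] for i in picked])
        assert (gaps <= 5 + 1e-9).all() and (gaps >= 1 / 3 - 1e-9).all()

    def test_empty_sequence(self):
        assert extract_frames([], []) == []

    def test_rate_config_validated(self):
        with pytest.raises(ValueError):
            FrameSamplerConfig(min_rate=5, max_rate=3)


class TestManifest:
    def _tree(self, root, stems, with_labels=True):
        (root / "images" / "all").mkdir(parents=True)
        for s in stems:
            (root / "images" / "all" / f"{s}.png").write_bytes(b"")
            if with_labels:
                lbl = root / "labels" / "all"
                lbl.mkdir(parents=True, exist_ok=True)
                (lbl / f"{s}.txt").write_text("")

    def test_pairs_images_with_labels(self, tmp_path):
        self._tree(tmp_path, ["a", "b", "c", "d"])
        m = build_manifest(tmp_path, {"all": ["a", "b", "c", "d"]})
        assert m.counts == {"all": 4}

    def test_missing_label_gets_empty_file(self, tmp_path):
        self._tree(tmp_path, ["a", "b", "c", "d"], with_labels=False)
        m = build_manifest(tmp_path, {"all": ["a", "b", "c", "d"]})
        for _, lbl in m.splits["all"]:
            assert lbl.exists() and lbl.read_text() == ""

    def test_duplicate_stem_rejected(self, tmp_path):
        for split in ("s1", "s2"):
            (tmp_path / "images" / split).mkdir(parents=True)
            (tmp_path / "images" / split / "a.png").write_bytes(b"")
        (tmp_path / "images" / "s1" / "b.png").write_bytes(b"")
        with pytest.raises(ValueError, match="duplicate"):
            build_manifest(tmp_path, {"s1": ["a", "b"], "s2": ["a"]})

    def test_yaml_round_trip(self, tmp_path):
        self._tree(tmp_path, ["a", "b", "c"])
        m = build_manifest(tmp_path, {"all": ["a", "b", "c"]}, ["wolf"])
        m.to_yaml(tmp_path / "m.yaml")
        back = DatasetManifest.from_yaml(tmp_path / "m.yaml")
        assert back.class_names == ["wolf"]
        assert back.counts == m.counts
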