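"""Annotation I/O, dataset splitting, and adaptive video frame sampling.

Supported label formats are the two the LabelImg annotation tool emits:

* YOLO text — one ``class cx cy w h`` line per box, coordinates normalized
  to image size (center/size convention);
* Pascal VOC XML (LabelImg dialect) — pixel ``bndbox`` corners, 1-based
  inclusive, converted here to continuous 0-based half-open coordinates
  before normalization.

Internally all pixel boxes are xyxy, 0-based, half-open; normalized boxes
are center/size in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from lxml import etree

__all__ = [
    "NormBox", "DatasetManifest", "FrameSamplerConfig",
    "read_yolo_labels", "write_yolo_labels", "read_voc_xml",
    "split_dataset", "extract_frames", "build_manifest",
]

_EDGE_TOL = 1e-6


@dataclass(frozen=True)
class NormBox:
    """Normalized ground-truth box: class id plus center/size in (0, 1]."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if self.class_id < 0:
            raise ValueError(f"negative class id {self.class_id}")
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box size must be positive, got w={self.w}, h={self.h}")
        for lo, hi in ((self.cx - self.w / 2, self.cx + self.w / 2),
                       (self.cy - self.h / 2, self.cy + self.h / 2)):
            if lo < -_EDGE_TOL or hi > 1 + _EDGE_TOL:
                raise ValueError(f"box extends outside the unit square: [{lo}, {hi}]")

    def to_xyxy(self, width: int, height: int) -> tuple:
        """Pixel corners (0-based, half-open) at the given image size."""
        return ((self.cx - self.w / 2) * width, (self.cy - self.h / 2) * height,
                (self.cx + self.w / 2) * width, (self.cy + self.h / 2) * height)

    @classmethod
    def from_xyxy(cls, class_id: int, x1, y1, x2, y2, width: int, height: int) -> "NormBox":
        x1, y1 = max(x1, 0.0), max(y1, 0.0)
        x2, y2 = min(x2, float(width)), min(y2, float(height))
        return cls(class_id, (x1 + x2) / 2 / width, (y1 + y2) / 2 / height,
                   (x2 - x1) / width, (y2 - y1) / height)


def read_yolo_labels(text: str, nc: int) -> list:
    """Parse YOLO label text; an empty file is a valid negative image."""
    boxes = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"line {lineno}: expected 5 fields, got {len(parts)}")
        try:
            cid = int(parts[0])
            cx, cy, w, h = (float(v) for v in parts[1:])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: unparsable value ({exc})") from None
        if cid >= nc:
            raise ValueError(f"line {lineno}: class id {cid} >= nc={nc}")
        try:
            boxes.append(NormBox(cid, cx, cy, w, h))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
    return boxes


def write_yolo_labels(boxes) -> str:
    lines = [f"{b.class_id} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}"
             for b in boxes]
    return "\n".join(lines) + ("\n" if lines else "")


def read_voc_xml(xml_content: str | bytes, class_table,
                 image_size: tuple | None = None) -> list:
    """Parse a LabelImg Pascal VOC file into normalized boxes.

    ``class_table`` maps class name -> id.  Pixel corners are 1-based
    inclusive; a bndbox (1, 1, W, H) covers the whole image.
    """
    if isinstance(xml_content, str):
        xml_content = xml_content.encode()
    root = etree.fromstring(xml_content)
    size = root.find("size")
    if size is not None:
        width = int(size.findtext("width"))
        height = int(size.findtext("height"))
    elif image_size is not None:
        width, height = image_size
    else:
        raise ValueError("image size absent from XML and not supplied")
    unknown = sorted({obj.findtext("name") for obj in root.iter("object")}
                     - set(class_table))
    if unknown:
        raise ValueError(f"unknown class names: {unknown}")
    boxes = []
    for obj in root.iter("object"):
        bnd = obj.find("bndbox")
        if bnd is None:
            raise ValueError(f"object {obj.findtext('name')!r} lacks a bndbox")
        try:
            xmin, ymin, xmax, ymax = (float(bnd.findtext(k))
                                      for k in ("xmin", "ymin", "xmax", "ymax"))
        except TypeError:
            raise ValueError("bndbox missing xmin/ymin/xmax/ymax") from None
        if xmax <= xmin or ymax <= ymin:
            raise ValueError(f"degenerate bndbox ({xmin},{ymin},{xmax},{ymax})")
        # 1-based inclusive -> 0-based half-open
        boxes.append(NormBox.from_xyxy(class_table[obj.findtext("name")],
                                       xmin - 1, ymin - 1, xmax, ymax,
                                       width, height))
    return boxes


def split_dataset(ids, ratios=(0.6, 0.2, 0.2), seed: int = 0):
    """Deterministic shuffled split.  Validation and test sizes are floored,
    the remainder goes to training — the convention that maps 8174 items at
    6:2:2 onto (4906, 1634, 1634)."""
    ids = list(ids)
    n = len(ids)
    if n < 3:
        raise ValueError(f"need at least 3 items to split, got {n}")
    r_train, r_val, r_test = ratios
    if min(ratios) <= 0 or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must be positive and sum to 1, got {ratios}")
    order = np.random.default_rng(seed).permutation(n)
    n_val = int(n * r_val)
    n_test = int(n * r_test)
    n_train = n - n_val - n_test
    shuffled = [ids[i] for i in order]
    return (shuffled[:n_train],
            shuffled[n_train:n_train + n_val],
            shuffled[n_train + n_val:])


@dataclass
class FrameSamplerConfig:
    """Adaptive keyframe sampling: capture on large inter-frame change,
    clamped between ``min_rate`` (forced capture) and ``max_rate``."""

    min_rate: float = 0.2    # frames/s; 1 per 5 s
    max_rate: float = 3.0    # frames/s
    diff_threshold: float = 15.0  # mean |intensity change| in [0, 255]

    def __post_init__(self):
        if not 0 < self.min_rate <= self.max_rate:
            raise ValueError("need 0 < min_rate <= max_rate")


def _to_gray(frame: np.ndarray) -> np.ndarray:
    f = np.asarray(frame, dtype=np.float64)
    return f.mean(axis=2) if f.ndim == 3 else f


def extract_frames(frames, timestamps, cfg: FrameSamplerConfig | None = None) -> list:
    """Select keyframe indices from a decoded, time-ordered frame sequence.

    The trigger statistic is the mean absolute grayscale difference against
    the last captured frame; captures are rate-clamped so the output rate
    stays within [min_rate, max_rate] over any sufficiently long window.
    The first frame is always captured.
    """
    cfg = cfg or FrameSamplerConfig()
    frames = list(frames)
    timestamps = np.asarray(list(timestamps), dtype=np.float64)
    if len(frames) != len(timestamps):
        raise ValueError("frames and timestamps must have equal length")
    if len(frames) == 0:
        return []
    if np.any(np.diff(timestamps) < 0):
        raise ValueError("timestamps must be nondecreasing")
    selected = [0]
    last_t = timestamps[0]
    last_gray = _to_gray(frames[0])
    tol = 1e-9
    min_gap = 1.0 / cfg.max_rate
    max_gap = 1.0 / cfg.min_rate
    for i in range(1, len(frames)):
        t = timestamps[i]
        gap = t - last_t
        if gap < min_gap - tol:
            continue
        gray = _to_gray(frames[i])
        diff = float(np.abs(gray - last_gray).mean())
        if diff > cfg.diff_threshold or gap >= max_gap - tol:
            selected.append(i)
            last_t, last_gray = t, gray
    return selected


@dataclass
class DatasetManifest:
    """Split name -> list of (image path, label path) pairs, plus class names."""

    splits: dict
    class_names: list = field(default_factory=list)

    @property
    def counts(self) -> dict:
        return {k: len(v) for k, v in self.splits.items()}

    def to_yaml(self, path):
        data = {
            "class_names": list(self.class_names),
            "splits": {k: [[str(a), str(b)] for a, b in v]
                       for k, v in self.splits.items()},
        }
        with open(path, "w") as f:
            yaml.safe_dump(data, f, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "DatasetManifest":
        with open(path) as f:
            data = yaml.safe_load(f)
        return cls(splits={k: [tuple(p) for p in v]
                           for k, v in data["splits"].items()},
                   class_names=data.get("class_names", []))


IMAGE_SUFFIXES = (".jpg", ".jpeg", ".png", ".bmp")


def build_manifest(root, split_lists: dict, class_names=None) -> DatasetManifest:
    """Pair images with label files sharing the stem under ``root``.

    Layout: ``images/<split>/<stem>.<ext>`` and ``labels/<split>/<stem>.txt``.
    Images lacking a label get an empty label file (flagged as a negative).
    """
    root = Path(root)
    splits = {}
    seen_stems: dict = {}
    for split, stems in split_lists.items():
        img_dir = root / "images" / split
        lbl_dir = root / "labels" / split
        lbl_dir.mkdir(parents=True, exist_ok=True)
        pairs = []
        for stem in stems:
            if stem in seen_stems:
                raise ValueError(f"duplicate stem {stem!r} (also in split "
                                 f"{seen_stems[stem]!r})")
            seen_stems[stem] = split
            matches = [img_dir / f"{stem}{ext}" for ext in IMAGE_SUFFIXES
                       if (img_dir / f"{stem}{ext}").exists()]
            if not matches:
                raise FileNotFoundError(f"no image for stem {stem!r} in {img_dir}")
            label = lbl_dir / f"{stem}.txt"
            if not label.exists():
                label.write_text("")
            pairs.append((matches[0], label))
        splits[split] = pairs
    return DatasetManifest(splits=splits, class_names=list(class_names or []))
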