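"""In-memory detection datasets, letterboxing, and light augmentation."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .annotations import DatasetManifest, NormBox, read_yolo_labels

__all__ = ["DetectionSample", "DetectionDataset", "letterbox", "load_split"]

PAD_VALUE = 114  # gray padding, the standard letterbox convention


@dataclass
class DetectionSample:
    """One image (H x W x 3 uint8) with its normalized boxes."""

    image: np.ndarray
    boxes: list


def letterbox(image: np.ndarray, size: int):
    """Aspect-preserving resize padded with gray to ``size`` x ``size``.

    Returns (canvas, scale, (pad_x, pad_y)); a pixel (x, y) of the source
    maps to (x * scale + pad_x, y * scale + pad_y).
    """
    h, w = image.shape[:2]
    scale = min(size / h, size / w)
    nw, nh = max(round(w * scale), 1), max(round(h * scale), 1)
    resized = np.asarray(Image.fromarray(image).resize((nw, nh), Image.BILINEAR))
    canvas = np.full((size, size, 3), PAD_VALUE, dtype=np.uint8)
    pad_x = (size - nw) // 2
    pad_y = (size - nh) // 2
    canvas[pad_y:pad_y + nh, pad_x:pad_x + nw] = resized
    return canvas, scale, (pad_x, pad_y)


class DetectionDataset:
    """A list of samples plus the tensor/target conversions training needs."""

    def __init__(self, samples, input_size: int, nc: int):
        self.samples = list(samples)
        self.input_size = input_size
        self.nc = nc

    def __len__(self):
        return len(self.samples)

    def batch(self, indices, flip_mask=None):
        """Assemble (images (B,3,S,S) float32 in [0,1], targets) for a batch.

        ``flip_mask`` optionally mirrors selected samples horizontally
        (boxes follow).  Targets are per-image (class_ids, xyxy pixel boxes).
        """
        size = self.input_size
        imgs, targets = [], []
        for pos, i in enumerate(indices):
            s = self.samples[i]
            img = s.image
            boxes = s.boxes
            if img.shape[0] != size or img.shape[1] != size:
                img, scale, (px, py) = letterbox(img, size)
                h0, w0 = s.image.shape[:2]
                pix = [(b.class_id,
                        b.to_xyxy(w0, h0)) for b in boxes]
                cls = np.array([c for c, _ in pix], int)
                xyxy = np.array([[x1 * scale + px, y1 * scale + py,
                                  x2 * scale + px, y2 * scale + py]
                                 for _, (x1, y1, x2, y2) in pix]).reshape(-1, 4)
            else:
                cls = np.array([b.class_id for b in boxes], int)
                xyxy = np.array([b.to_xyxy(size, size) for b in boxes]).reshape(-1, 4)
            if flip_mask is not None and flip_mask[pos]:
                img = img[:, ::-1]
                if len(xyxy):
                    xyxy = np.stack([size - xyxy[:, 2], xyxy[:, 1],
                                     size - xyxy[:, 0], xyxy[:, 3]], axis=1)
            imgs.append(np.ascontiguousarray(img[:, :, :3].transpose(2, 0, 1),
                                             dtype=np.float32) / 255.0)
            targets.append((cls, xyxy))
        return np.stack(imgs), targets

    def ground_truths(self):
        """Per-image (class_id, xyxy) lists at the network input size."""
        out = []
        for i in range(len(self)):
            _, t = self.batch([i])
            cls, xyxy = t[0]
            out.append([(int(c), tuple(b)) for c, b in zip(cls, xyxy)])
        return out


def load_split(manifest: DatasetManifest, split: str, input_size: int,
               nc: int) -> DetectionDataset:
    """Materialize one manifest split into memory."""
    samples = []
    for img_path, lbl_path in manifest.splits[split]:
        img = np.asarray(Image.open(img_path).convert("RGB"))
        boxes = read_yolo_labels(Path(lbl_path).read_text(), nc)
        samples.append(DetectionSample(img, boxes))
    return DetectionDataset(samples, input_size, nc)
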