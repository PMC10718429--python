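"""PNG image/mask I/O, BUSI-style directory scanning, and the dataset split.

Images are 2-D ``uint8`` arrays ("ImageGrid"); masks are 2-D ``uint8`` arrays
with values in {0, 1} ("MaskGrid"), always aligned pixel-for-pixel with their
image. The on-disk dialect is the BUSI one::

    root/
      normal/    <stem>.png, <stem>_mask.png
      benign/    ...
      malignant/ ...

An image may have several mask files (``x_mask.png``, ``x_mask_1.png`` ...);
they are merged by pixel-wise OR, since the union of the outlined regions is
the natural ground truth for a lesion split across annotations.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

LABELS = ("normal", "benign", "malignant")


def read_image(path) -> np.ndarray:
    """Read a PNG as a 2-D uint8 grid; multi-channel inputs become luminance."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.uint8)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    return arr


def write_image(path, pixels: np.ndarray) -> None:
    pixels = np.asarray(pixels)
    if pixels.ndim != 2:
        raise ValueError("expected a 2-D grid")
    Image.fromarray(pixels.astype(np.uint8), mode="L").save(Path(path), format="PNG")


def read_mask(path) -> np.ndarray:
    """Read a mask PNG and binarize at > 0 (BUSI masks are 0/255)."""
    return (read_image(path) > 0).astype(np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    write_image(path, (mask > 0).astype(np.uint8) * 255)


@dataclass(frozen=True)
class DatasetRecord:
    image_path: Path
    mask_paths: tuple  # one or more mask files, merged on load
    label: str

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    def load(self) -> tuple:
        """Return ``(image, mask)``; multiple masks are OR-merged."""
        image = read_image(self.image_path)
        mask = np.zeros_like(image, dtype=np.uint8)
        for mp in self.mask_paths:
            m = read_mask(mp)
            if m.shape != image.shape:
                raise ValueError(f"{mp}: mask shape {m.shape} != image {image.shape}")
            mask |= m
        return image, mask


_MASK_RE = re.compile(r"^(?P<stem>.+?)_mask(?:_\d+)?\.png$", re.IGNORECASE)


def scan_busi_layout(root) -> list:
    """Collect one :class:`DatasetRecord` per image under a BUSI-style tree."""
    root = Path(root)
    records = []
    for label in LABELS:
        class_dir = root / label
        if not class_dir.is_dir():
            continue
        masks: dict[str, list] = {}
        images: dict[str, Path] = {}
        for p in sorted(class_dir.glob("*.png")):
            m = _MASK_RE.match(p.name)
            if m:
                masks.setdefault(m.group("stem"), []).append(p)
            else:
                images[p.stem] = p
        missing = sorted(set(images) - set(masks))
        if missing:
            raise ValueError(f"images without mask files under {class_dir}: {missing}")
        for stem in sorted(images):
            records.append(DatasetRecord(
                image_path=images[stem],
                mask_paths=tuple(sorted(masks[stem])),
                label=label,
            ))
    return records


@dataclass(frozen=True)
class DatasetSplit:
    train: list
    validation: list
    test: list
    seed: int

    def __iter__(self):
        yield from ((r, "train") for r in self.train)
        yield from ((r, "validation") for r in self.validation)
        yield from ((r, "test") for r in self.test)


def split_dataset(records: list, ratios=(0.8, 0.1, 0.1), seed: int = 0) -> DatasetSplit:
    """Single seeded shuffle, then floor-based cuts at the cumulative ratios.

    With n=780 and ratios (0.8, 0.1, 0.1) this yields the 624/78/78 partition.
    Unstratified by class; deterministic given ``seed``.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    n = len(records)
    if n < 3:
        raise ValueError("need at least 3 records to populate all three splits")
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [records[i] for i in order]
    c1 = int(np.floor(n * ratios[0]))
    c2 = int(np.floor(n * (ratios[0] + ratios[1])))
    return DatasetSplit(train=shuffled[:c1], validation=shuffled[c1:c2],
                        test=shuffled[c2:], seed=seed)


def write_split_manifest(split: DatasetSplit, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["path", "mask_path", "label", "split"])
        for rec, part in split:
            w.writerow([rec.image_path, ";".join(str(p) for p in rec.mask_paths),
                        rec.label, part])


def resize_pair(image: np.ndarray, mask: np.ndarray, side: int) -> tuple:
    """Resize to ``side x side``: bilinear for the image, nearest for the mask."""
    if side <= 0:
        raise ValueError("side must be positive")
    if image.shape != mask.shape:
        raise ValueError("image and mask must be aligned")
    img = _sk_resize(image.astype(float), (side, side), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    msk = _sk_resize(mask.astype(float), (side, side), order=0, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return (np.clip(np.rint(img), 0, 255).astype(np.uint8),
            (msk > 0.5).astype(np.uint8))
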