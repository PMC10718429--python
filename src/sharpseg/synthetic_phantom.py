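"""Synthetic breast-ultrasound phantoms with exact ground-truth masks.

The generator emulates the structure of a BUSI-style dataset — grayscale
speckle images of varying sizes with per-image binary lesion masks and three
class labels — so the whole pipeline is testable without any download.

Image model
-----------
* Background: multiplicative speckle. A complex circular-Gaussian field is
  low-pass filtered (Gaussian smoothing of the quadrature components) and its
  squared magnitude, normalized to unit mean, multiplies ``background_mean``.
  This gives the Rayleigh-like envelope statistics characteristic of
  ultrasound rather than additive Gaussian noise.
* Lesion (benign/malignant): an ellipse with a seeded centre and axes; its
  boundary radius is perturbed by a low-order Fourier series (3-8 harmonics)
  scaled by ``boundary_irregularity`` — zero for benign (smooth), positive
  for malignant (spiculated-like). Inside the lesion the intensity is
  multiplied by ``lesion_contrast`` < 1 (hypoechoic).
* Optional posterior shadow: a vertical band below the lesion attenuated by
  ``shadow_strength``.

The mask is the analytic lesion support itself, never re-segmented from the
rendered image.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io_dataset import DatasetRecord, write_image, write_mask

LABELS = ("normal", "benign", "malignant")

#: default image sides, drawn per phantom to exercise the resize path
DEFAULT_SIDES = (96, 128, 160)


@dataclass(frozen=True)
class PhantomConfig:
    side: int = 128
    label: str = "benign"
    background_mean: float = 120.0
    speckle_scale: float = 2.0          # smoothing sigma of the speckle field
    lesion_radius_frac: tuple = (0.12, 0.28)
    lesion_contrast: float = 0.45       # hypoechoic: < 1
    boundary_irregularity: float = 0.0  # 0 for benign, > 0 for malignant
    shadow_strength: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if not 0.0 < self.lesion_contrast < 1.0:
            raise ValueError("lesion_contrast must lie in (0, 1)")
        if self.boundary_irregularity < 0:
            raise ValueError("boundary_irregularity must be >= 0")
        if not 0.0 <= self.shadow_strength <= 1.0:
            raise ValueError("shadow_strength must lie in [0, 1]")
        if self.lesion_radius_frac[1] > 0.5:
            raise ValueError("lesion cannot exceed the image")


def _speckle_field(shape, sigma: float, rng: np.random.Generator,
                   looks: int = 4) -> np.ndarray:
    """Unit-mean multiplicative speckle: multi-look complex-Gaussian envelope.

    Each look is the squared magnitude of a smoothed circular complex
    Gaussian field (fully developed speckle, exponential intensity
    statistics); averaging ``looks`` independent looks gives the
    Gamma-distributed intensity of display-level B-mode texture. A single
    look would leave pervasive near-zero patches that no real scan-converted
    image shows.
    """
    env = np.zeros(shape)
    for _ in range(looks):
        re = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
        im = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
        env += re * re + im * im
    return env / env.mean()


def _lesion_mask(side: int, cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    r_frac = rng.uniform(*cfg.lesion_radius_frac)
    r0 = r_frac * side
    margin = r0 * (1.5 + cfg.boundary_irregularity)
    lo, hi = margin, side - margin
    if hi <= lo:
        lo = hi = side / 2.0
    cy, cx = rng.uniform(lo, hi, size=2)
    aspect = rng.uniform(0.6, 1.0)
    phi = rng.uniform(0, np.pi)

    yy, xx = np.mgrid[0:side, 0:side]
    dy, dx = yy - cy, xx - cx
    # rotate into the ellipse frame
    u = np.cos(phi) * dx + np.sin(phi) * dy
    v = -np.sin(phi) * dx + np.cos(phi) * dy
    theta = np.arctan2(v / aspect, u)
    rad = np.sqrt(u * u + (v / aspect) ** 2)

    # smooth periodic radial perturbation: low-order Fourier harmonics
    perturb = np.zeros_like(theta)
    if cfg.boundary_irregularity > 0:
        for k in range(3, 9):  # low-order harmonics only: smooth spiculation
            amp = rng.uniform(0.3, 1.0) / np.sqrt(k)
            phase = rng.uniform(0, 2 * np.pi)
            perturb += amp * np.cos(k * theta + phase)
        perturb *= cfg.boundary_irregularity
    boundary = r0 * np.clip(1.0 + perturb, 0.3, 2.5)
    return (rad <= boundary).astype(np.uint8)


def generate_phantom(cfg: PhantomConfig) -> tuple:
    """Render one phantom; returns ``(image, mask, label)``."""
    rng = np.random.default_rng(cfg.seed)
    side = cfg.side
    field = cfg.background_mean * _speckle_field((side, side), cfg.speckle_scale, rng)
    if cfg.label == "normal":
        mask = np.zeros((side, side), dtype=np.uint8)
    else:
        mask = _lesion_mask(side, cfg, rng)
        attenuation = np.where(mask == 1, cfg.lesion_contrast, 1.0)
        if cfg.shadow_strength > 0 and mask.any():
            cols = mask.any(axis=0)
            bottom = np.where(mask == 1, np.arange(side)[:, None], -1).max(axis=0)
            shadow = np.ones((side, side))
            for j in np.flatnonzero(cols):
                shadow[bottom[j] + 1:, j] = 1.0 - cfg.shadow_strength
            attenuation = attenuation * shadow
        field = field * attenuation
    image = np.clip(np.rint(field), 0, 255).astype(np.uint8)
    return image, mask, cfg.label


def _class_config(label: str, side: int, seed: int) -> PhantomConfig:
    irregular = 0.25 if label == "malignant" else 0.0
    return PhantomConfig(side=side, label=label, seed=seed,
                         boundary_irregularity=irregular)


def generate_dataset(n_per_class, out_root, base_seed: int = 0,
                     sides=DEFAULT_SIDES) -> list:
    """Write a BUSI-layout phantom dataset and return its records.

    ``n_per_class`` is ``(n_normal, n_benign, n_malignant)``. Per-item seeds
    derive deterministically from ``base_seed``, so reruns are byte-identical.
    """
    out_root = Path(out_root)
    records = []
    master = np.random.default_rng(base_seed)
    for label, n in zip(LABELS, n_per_class):
        class_dir = out_root / label
        class_dir.mkdir(parents=True, exist_ok=True)
        for i in range(n):
            item_seed = int(master.integers(0, 2**31 - 1))
            side = sides[item_seed % len(sides)]
            cfg = _class_config(label, side, item_seed)
            image, mask, _ = generate_phantom(cfg)
            img_path = class_dir / f"{label} ({i + 1}).png"
            mask_path = class_dir / f"{label} ({i + 1})_mask.png"
            write_image(img_path, image)
            write_mask(mask_path, mask)
            records.append(DatasetRecord(image_path=img_path,
                                         mask_paths=(mask_path,), label=label))
    return records
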