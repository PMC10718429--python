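"""Training-time augmentation applied consistently to an image/mask pair.

One affine warp — rotation ∘ shear ∘ zoom ∘ shift about the image centre,
then an optional horizontal flip — is sampled per example and applied
identically to the image and its mask; a multiplicative brightness factor
is applied to the image only. Parameter ranges default to:

* rotation uniform in [-45, 45] degrees
* zoom in [-0.08, 0.08], interpreted as a scale factor 1 + z
* horizontal flip with probability 1/2
* width/height shift up to 0.15 of the image extent
* shear in [-0.03, 0.03] radians along x
* brightness factor in [0.99, 1.07]

Out-of-bounds samples replicate the nearest edge for images and are zero
for masks, so warps never invent lesion pixels. Masks come back strictly
binary (re-thresholded at 0.5 after interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class AugmentationConfig:
    rotation_deg: tuple = (-45.0, 45.0)
    zoom: tuple = (-0.08, 0.08)
    horizontal_flip: bool = True
    width_shift_frac: float = 0.15
    height_shift_frac: float = 0.15
    shear: tuple = (-0.03, 0.03)
    brightness: tuple = (0.99, 1.07)

    def __post_init__(self):
        for name in ("rotation_deg", "zoom", "shear", "brightness"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lower bound exceeds upper bound")
        for name in ("width_shift_frac", "height_shift_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def identity(cls) -> "AugmentationConfig":
        """Degenerate config whose samples are always the identity transform."""
        z = (0.0, 0.0)
        return cls(rotation_deg=z, zoom=z, horizontal_flip=False,
                   width_shift_frac=0.0, height_shift_frac=0.0,
                   shear=z, brightness=(1.0, 1.0))


@dataclass(frozen=True)
class TransformParams:
    angle: float = 0.0            # degrees
    zoom_factor: float = 0.0      # scale applied as 1 + zoom_factor
    flip: bool = False
    dx: float = 0.0               # fraction of width
    dy: float = 0.0               # fraction of height
    shear_amount: float = 0.0     # radians, x-shear
    brightness_factor: float = 1.0


def sample_transform(config: AugmentationConfig, rng: np.random.Generator) -> TransformParams:
    """Draw each parameter uniformly from its interval; flip is a fair coin."""
    u = rng.uniform
    return TransformParams(
        angle=u(*config.rotation_deg),
        zoom_factor=u(*config.zoom),
        flip=bool(rng.integers(0, 2)) if config.horizontal_flip else False,
        dx=u(-config.width_shift_frac, config.width_shift_frac),
        dy=u(-config.height_shift_frac, config.height_shift_frac),
        shear_amount=u(*config.shear),
        brightness_factor=u(*config.brightness),
    )


def _affine_matrix(params: TransformParams, shape) -> tuple:
    """Output->input mapping (matrix, offset) for scipy.ndimage.affine_transform.

    The forward warp is rotation @ shear @ zoom @ shift about the centre; the
    returned pair is its inverse in (row, col) coordinates.
    """
    h, w = shape
    theta = np.deg2rad(params.angle)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    shear = np.array([[1.0, params.shear_amount], [0.0, 1.0]])
    scale = 1.0 + params.zoom_factor
    zoom = np.array([[scale, 0.0], [0.0, scale]])
    forward = rot @ shear @ zoom
    shift = np.array([params.dy * h, params.dx * w])  # (row, col)
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    inv = np.linalg.inv(forward)
    # forward: y = F (x - centre) + centre + shift  =>  x = F^-1 (y - centre - shift) + centre
    offset = centre - inv @ (centre + shift)
    return inv, offset


def apply_transform(image: np.ndarray, mask: np.ndarray,
                    params: TransformParams) -> tuple:
    """Warp an image/mask pair with the same geometry; brightness on image only."""
    if image.shape != mask.shape:
        raise ValueError("image and mask must be aligned")
    identity_warp = (params.angle == 0 and params.zoom_factor == 0
                     and params.dx == 0 and params.dy == 0
                     and params.shear_amount == 0)
    img = image.astype(float)
    msk = mask.astype(float)
    if not identity_warp:
        matrix, offset = _affine_matrix(params, image.shape)
        img = ndimage.affine_transform(img, matrix, offset=offset, order=1,
                                       mode="nearest")
        msk = ndimage.affine_transform(msk, matrix, offset=offset, order=1,
                                       mode="constant", cval=0.0)
    if params.flip:
        img = img[:, ::-1]
        msk = msk[:, ::-1]
    img = img * params.brightness_factor
    out_img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    out_msk = (msk > 0.5).astype(np.uint8)
    return out_img, out_msk
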