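"""Sample and apply training-time augmentations to an image/mask pair.

One affine warp (rotation, shear, zoom, shift about the centre, optional
horizontal flip) is applied identically to image and mask; brightness only
touches the image, and the mask stays strictly binary.
"""

import numpy as np

from sharpseg import AugmentationConfig, apply_transform, sample_transform
from sharpseg.synthetic_phantom import PhantomConfig, generate_phantom

image, mask, _ = generate_phantom(PhantomConfig(label="benign", seed=8, side=96))
cfg = AugmentationConfig()  # rotation +-45 deg, zoom +-8%, shift 15%, ...
rng = np.random.default_rng(0)

print(f"original lesion area: {int(mask.sum())} px")
for i in range(4):
    params = sample_transform(cfg, rng)
    img2, msk2 = apply_transform(image, mask, params)
    print(f"draw {i}: angle {params.angle:+6.1f} deg, zoom "
          f"{1 + params.zoom_factor:.3f}, flip {params.flip!s:5s}, "
          f"brightness {params.brightness_factor:.3f} "
          f"-> lesion area {int(msk2.sum())} px, mask values "
          f"{sorted(np.unique(msk2))}")
# the lesion area changes with zoom/rotation resampling but the mask remains
# binary, and identical geometry is applied to image and mask.
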