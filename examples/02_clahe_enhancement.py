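"""CLAHE contrast enhancement of a phantom image.

The clip limit follows beta = (M/N) * (1 + alpha/100 * (S_max - 1)); with
alpha = 0 the histogram is clipped to the uniform level M/N and the mapping
stays flat, while larger alpha and S_max allow stronger local contrast.
"""

import numpy as np

from sharpseg import ClaheConfig, apply_clahe, clip_limit
from sharpseg.synthetic_phantom import PhantomConfig, generate_phantom

for alpha, smax in ((0, 4), (50, 3), (100, 4)):
    beta = clip_limit(M=64, N=256, alpha=alpha, s_max=smax)
    print(f"tile of 64 px, 256 levels, alpha={alpha:5.1f}%, S_max={smax}: "
          f"clip limit beta = {beta:.4f}")

image, mask, _ = generate_phantom(PhantomConfig(label="benign", seed=5))
enhanced = apply_clahe(image, ClaheConfig(tile_rows=8, tile_cols=8))
print(f"\nbefore: intensity range {image.min()}..{image.max()}, "
      f"std {image.std():.1f}")
print(f"after : intensity range {enhanced.min()}..{enhanced.max()}, "
      f"std {enhanced.std():.1f}")
print("lesion/background contrast before:",
      round(float(image[mask == 1].mean() / image[mask == 0].mean()), 3))
print("lesion/background contrast after :",
      round(float(enhanced[mask == 1].mean() / enhanced[mask == 0].mean()), 3))
# CLAHE widens the used intensity range and raises local contrast while the
# lesion stays darker than its surroundings.
assert enhanced.shape == image.shape
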