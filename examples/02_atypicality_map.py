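"""Gamma atypicality maps: highlighting pixels no tissue law explains.

Generates a cyst phantom, fits the normal-tissue mixture (background +
parenchyma laws), and computes the atypicality map 1 - max_i f_i(y)/f_i(mode_i).
Lesion pixels fall between the tissue laws and score high; this map is the
extra input channel the segmentation network receives.
"""

import numpy as np

from renalswin.gamma import GammaMixture, gamma_feature_map
from renalswin.phantom import PhantomSpec, generate_phantom, tiered_laws

for tier in ("clear", "mild"):
    img, mask, _ = generate_phantom(
        PhantomSpec(class_label="cyst", contrast_level=tier, seed=5))
    laws = tiered_laws(tier)
    w_bg = float(np.mean(mask.labels == 0))
    mix = GammaMixture([laws["background"], laws["parenchyma"]],
                       np.array([w_bg, 1 - w_bg]))
    amap = gamma_feature_map(img, mix).pixels
    print(f"{tier:>5} tier: mean atypicality inside lesion = "
          f"{amap[mask.labels == 2].mean():.3f}, parenchyma = "
          f"{amap[mask.labels == 1].mean():.3f}")
# The lesion should score well above the parenchyma: ~0.99 vs ~0.31 on the
# clear tier, narrowing as the lesion law approaches the parenchyma law.
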