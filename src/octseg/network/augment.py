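"""Seeded geometric augmentation applied identically to a patch and its mask.

Transforms are the usual segmentation set — horizontal flips, small rotations
and integer translations — drawn from a caller-supplied generator so training
runs are reproducible.  The image is interpolated bilinearly; the mask uses
order-0 resampling so labels stay categorical, and the output is restored to
the patch size by the transforms themselves (reflect padding at the borders).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def augment_pair(image: np.ndarray, mask: np.ndarray,
                 rng: np.random.Generator,
                 max_rotation_deg: float = 5.0,
                 max_shift_px: int = 5) -> tuple[np.ndarray, np.ndarray]:
    img, lab = image, mask
    if rng.random() < 0.5:
        img, lab = img[:, ::-1], lab[:, ::-1]
    angle = float(rng.uniform(-max_rotation_deg, max_rotation_deg))
    if angle != 0.0:
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="reflect")
        lab = ndimage.rotate(lab, angle, reshape=False, order=0, mode="reflect")
    dy = int(rng.integers(-max_shift_px, max_shift_px + 1))
    dx = int(rng.integers(-max_shift_px, max_shift_px + 1))
    if dy or dx:
        img = ndimage.shift(img, (dy, dx), order=1, mode="reflect")
        lab = ndimage.shift(lab, (dy, dx), order=0, mode="reflect")
    return np.ascontiguousarray(img), np.ascontiguousarray(lab)
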