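import numpy as np
import pytest

from octseg import PhantomSpec, generate_phantom


def small_spec(**kw) -> PhantomSpec:
    """A compact phantom geometry used throughout the unit tests."""
    base = dict(height_px=96, width_px=96, axial_pixel_um=2.2,
                surface_depth_px=20.0, epidermis_thickness_px=15.0,
                n_follicles=1, follicle_depth_px=20.0,
                follicle_halfwidth_px=8.0, speckle_level=0.1,
                attenuation_per_px=0.004, surface_waviness_amp_px=2.0, seed=0)
    base.update(kw)
    return PhantomSpec(**base)


def wide_flat_spec(**kw) -> PhantomSpec:
    """Noise-free, flat-surface phantom wide enough for the 449-sample filter."""
    base = dict(height_px=160, width_px=512, axial_pixel_um=2.2,
                surface_depth_px=40.0, epidermis_thickness_px=30.0,
                n_follicles=0, follicle_depth_px=40.0,
                follicle_halfwidth_px=15.0, speckle_level=0.0,
                attenuation_per_px=0.0, surface_waviness_amp_px=0.0, seed=0)
    base.update(kw)
    return PhantomSpec(**base)


@pytest.fixture
def flat_band_mask():
    """Mask with a flat epidermis band occupying rows 50..80 of 120x512."""
    lab = np.full((120, 512), 2, dtype=np.uint8)
    lab[:50] = 0
    lab[50:81] = 1
    from octseg import LabelMask
    return LabelMask(labels=lab)


@pytest.fixture
def one_follicle_phantom():
    img, mask, profile = generate_phantom(wide_flat_spec(n_follicles=1, seed=5))
    return img, mask, profile
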