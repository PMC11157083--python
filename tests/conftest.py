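import numpy as np
import pytest

from quapos import lm, synth


def make_grating(size: int, director_deg: float, wavelength: float, phase: float = 0.3):
    """Plain cos grating whose true director is ``director_deg`` (degrees)."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    a = np.radians(director_deg)
    k = 2 * np.pi / wavelength
    return np.cos(k * (xx * np.sin(a) - yy * np.cos(a)) + phase)


@pytest.fixture(scope="session")
def phantom_small():
    """A compact, well-separated phantom shared by classifier-level tests."""
    spec = synth.PosPhantomSpec(
        shape=(16, 72, 72),
        n_objects=6,
        semi_axes_um=(0.9, 2.0, 0.9),
        gaussian_noise_sd=8.0,
        seed=7,
    )
    return spec, *synth.make_pos_phantom(spec)


@pytest.fixture(scope="session")
def trained_model(phantom_small):
    """Forest trained on the shared phantom (preprocessed, default bank)."""
    spec, stack, mask, truth = phantom_small
    pre = lm.preprocess.preprocess(stack)
    ann = synth.sample_annotations(mask, n_per_class=100, seed=11, image_id="phantom")
    model = lm.train([ann], [pre], seed=0)
    return model, pre, mask
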