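import numpy as np
import pytest

import ivimhsi as hs
from ivimhsi import phantom as ph


@pytest.fixture(scope="session")
def bvals() -> np.ndarray:
    return np.asarray(hs.DEFAULT_BVALUES, float)


@pytest.fixture(scope="session")
def clean_phantom() -> ph.PhantomOutput:
    """Noise-free mass phantom: exact bi-exponential signals, no artifacts."""
    return hs.generate_phantom(hs.PhantomSpec(noise_sigma=0.0, seed=0))


@pytest.fixture(scope="session")
def noisy_phantom() -> ph.PhantomOutput:
    """Mass phantom at 2% (of lesion S0) Rician noise, no bias or shifts."""
    return hs.generate_phantom(hs.PhantomSpec(noise_sigma=2.0, seed=0))


@pytest.fixture(scope="session")
def acceptance_spec() -> hs.PhantomSpec:
    """The full-artifact study phantom: mass preset, 2% noise, 0.3 bias,
    per-band shifts within +/-3 px."""
    return hs.PhantomSpec(
        noise_sigma=2.0,
        bias_amplitude=0.3,
        shifts=ph.default_shifts(13, max_shift=3, seed=5),
        seed=0,
    )


@pytest.fixture(scope="session")
def acceptance_phantom(acceptance_spec) -> ph.PhantomOutput:
    return hs.generate_phantom(acceptance_spec)


@pytest.fixture(scope="session")
def breast_pixels(noisy_phantom):
    """Preprocessed cube, breast mask and flattened spectra of the noisy
    mass phantom (shared across detector tests)."""
    cube, mask, _ = hs.preprocess(noisy_phantom.cube)
    X, idx = cube.pixels(mask.mask)
    return cube, mask.mask, X, idx
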