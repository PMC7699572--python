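import numpy as np
import pytest

from aircine.phantom import PhantomSpec, make_phantom_sequence
from aircine.segmentation import SeedPoint


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free, blur-free, non-breathing circle phantom."""
    return PhantomSpec(
        ap_semiaxis=5.0, tx_semiaxis=5.0, modulation_fraction=0.0,
        noise_sd=0.0, psf_sigma=0.0, n_frames=8,
    )


@pytest.fixture(scope="session")
def breathing_spec():
    """Moderately noisy breathing phantom (default study conditions)."""
    return PhantomSpec(
        ap_semiaxis=5.0, tx_semiaxis=4.0, modulation_fraction=0.2,
        noise_sd=12.0, psf_sigma=0.8, seed=42,
    )


@pytest.fixture(scope="session")
def breathing_sequence(breathing_spec):
    return make_phantom_sequence(breathing_spec)


@pytest.fixture()
def center_seed():
    return SeedPoint(64, 64)


# random phantoms for oracle tests come from the validation envelope
from aircine.validation import draw_validation_spec as random_phantom_spec  # noqa: E402
from aircine.validation import seed_of as seed_for  # noqa: E402
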