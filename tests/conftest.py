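import numpy as np
import pytest

from racetube.pipeline import analyze_image
from racetube.synthetic import SyntheticSpec, generate_pack


@pytest.fixture(scope="session")
def noiseless_pack():
    """Six-tube pack at the canonical free-running period, no pixel noise."""
    spec = SyntheticSpec(noise_sd=0.0, mark_jitter_px=0.0, seed=0)
    return generate_pack(spec)


@pytest.fixture(scope="session")
def noiseless_records(noiseless_pack):
    img, _ = noiseless_pack
    return analyze_image(img, pack_name="clean", mark_interval_h=24.0)


@pytest.fixture(scope="session")
def noisy_pack():
    """Same geometry with realistic scanner noise."""
    spec = SyntheticSpec(noise_sd=8.0, seed=3)
    return generate_pack(spec)


@pytest.fixture(scope="session")
def noisy_records(noisy_pack):
    img, _ = noisy_pack
    return analyze_image(img, pack_name="noisy", mark_interval_h=24.0)
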