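import numpy as np
import pytest

from sran.phantom import generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def phantom_dataset(tmp_path):
    """5 identities x 3 images at 48 px, written as PNG + metadata CSV."""
    out = tmp_path / "cohort"
    metadata, phantoms = generate_dataset(5, 3, size=48, seed=99, out_dir=out)
    return out, metadata, phantoms
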