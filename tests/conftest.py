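import numpy as np
import pytest

from mixqmri import build_knee_phantom, load_sequence_presets
from mixqmri.phantom import PhantomConfig


@pytest.fixture(scope="session")
def phantom():
    """Default 160 x 160 x 7 knee phantom."""
    return build_knee_phantom()


@pytest.fixture(scope="session")
def small_phantom():
    """A reduced phantom for fast pipeline tests."""
    return build_knee_phantom(PhantomConfig(shape=(64, 64, 3)))


@pytest.fixture(scope="session")
def presets():
    return load_sequence_presets()


@pytest.fixture(scope="session")
def water_mask(phantom):
    """Voxels with signal, zero fat fraction (where ratio isolation holds)."""
    m = np.zeros(phantom.shape, dtype=bool)
    for tid, p in phantom.tissue_table.items():
        if p.proton_density > 0 and p.fat_fraction == 0:
            m |= phantom.labels == tid
    return m
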