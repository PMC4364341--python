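import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/_oracles.py importable

from myotex.synthetic_data import MuscleSpec, PhantomSpec, generate_phantom
from myotex.t2_mapping import MultiEchoVolume


TWO_MUSCLES = (
    MuscleSpec(1, "muscle_a", 0.18, 43.0),
    MuscleSpec(2, "muscle_b", 0.18, 39.0),
)


@pytest.fixture
def clean_phantom():
    """Noiseless, lesion-free two-muscle phantom."""
    spec = PhantomSpec(grid_shape=(24, 24, 24), muscles=TWO_MUSCLES, seed=7)
    vol, lmap = generate_phantom(spec)
    return spec, vol, lmap


@pytest.fixture
def noiseless_voxel():
    """Single voxel decaying exactly with S0=1000, T2=50 ms, TEs 10..100 ms."""
    te = np.arange(10.0, 101.0, 10.0)
    sig = 1000.0 * np.exp(-te / 50.0)
    return MultiEchoVolume(sig.reshape(1, 1, 1, te.size), te)
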