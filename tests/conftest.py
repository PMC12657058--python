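from pathlib import Path

import numpy as np
import pytest

from seqfrust.couplings import CouplingMatrix
from seqfrust.potentials import AA_ALPHABET, miyazawa_jernigan_1996

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def mj():
    return miyazawa_jernigan_1996()


@pytest.fixture(scope="session")
def data_dir():
    return DATA_DIR


def random_instance(seed: int, n: int, density: float = 0.2):
    """A random (CouplingMatrix, sequence) pair for oracle tests."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(AA_ALPHABET), size=n))
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(iu.size) < density
    scores = np.zeros((n, n))
    vals = rng.normal(0.0, 1.0, size=int(keep.sum()))
    scores[iu[keep], ju[keep]] = vals
    scores[ju[keep], iu[keep]] = vals
    return CouplingMatrix(scores=scores), seq


@pytest.fixture
def instance_factory():
    return random_instance
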