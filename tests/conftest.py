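import numpy as np
import pytest

from agsam.foundation import build_surrogate
from agsam.phantom import PhantomSpec, generate_phantom
from agsam.profiles import MINI


@pytest.fixture(scope="session")
def cardiac_spec():
    return PhantomSpec(style="cardiac", image_side=64, seed=7)


@pytest.fixture(scope="session")
def fundus_spec():
    return PhantomSpec(style="fundus", image_side=64, seed=7)


@pytest.fixture(scope="session")
def phantom_batch(cardiac_spec):
    """Four cardiac phantoms as (images [N,3,S,S], masks [N,S,S])."""
    samples = [generate_phantom(cardiac_spec, i) for i in range(4)]
    return (np.stack([s.image for s in samples]),
            np.stack([s.mask for s in samples]))


@pytest.fixture(scope="session")
def frozen_pair():
    """A frozen surrogate without pre-training (fast; shapes/gradients)."""
    return build_surrogate(MINI, seed=3, pretrain_steps=0)


@pytest.fixture(scope="session")
def pretrained_pair():
    """A 200-step pre-trained frozen surrogate, shared across tests."""
    return build_surrogate(MINI, seed=3, pretrain_steps=200)
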