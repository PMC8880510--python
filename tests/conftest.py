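import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from radenrich.volumes import LabeledVolume


@pytest.fixture
def random_volume():
    """Factory for small random labelled volumes."""

    def make(seed=0, shape=(4, 4, 4), spacing=(1.0, 1.0, 1.0), mask_p=0.7):
        rng = np.random.default_rng(seed)
        img = rng.normal(40, 20, shape)
        mask = rng.uniform(size=shape) < mask_p
        if mask.sum() < 2:
            mask[tuple(np.array(shape) // 2)] = True
            mask[0, 0, 0] = True
        return LabeledVolume(img, mask, spacing)

    return make


@pytest.fixture
def survival_sample():
    """Factory for right-censored survival data with optional effect."""

    def make(seed=0, n=120, beta=0.0, p_cov=1, censor=(15.0, 40.0)):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p_cov))
        eta = beta * X[:, 0]
        T = 24.0 * (-np.log(rng.uniform(size=n)) * np.exp(-eta)) ** (1 / 1.2)
        C = rng.uniform(*censor, size=n)
        return X, np.minimum(T, C), (T <= C).astype(int)

    return make
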