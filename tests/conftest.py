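import numpy as np
import pytest

from taloco.fea import StressField
from taloco.synthetic import SynthConfig, make_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180520)


@pytest.fixture(scope="session")
def small_bundle():
    """Reduced synthetic dataset for fast structural tests."""
    return make_dataset(SynthConfig(n_elements=300, seed=7))


def random_field(rng, n_max=8, vol_max=5, specimen_id="t"):
    """Small random stress field with integer volumes, so a
    volume-expansion brute force is exact."""
    n = int(rng.integers(1, n_max + 1))
    sigma = rng.uniform(0.0, 10.0, size=n)
    vol = rng.integers(1, vol_max + 1, size=n).astype(float)
    return StressField(sigma=sigma, vol=vol, specimen_id=specimen_id)


def expanded_percentile(field: StressField, q: float) -> float:
    """Brute-force oracle: expand each element into volume-proportional
    unit copies, then take the step-definition percentile by counting."""
    reps = field.vol.astype(int)
    assert np.allclose(reps, field.vol), "oracle needs integer volumes"
    expanded = np.sort(np.repeat(field.sigma, reps))
    cum = np.arange(1, expanded.size + 1)
    i = np.searchsorted(cum, q * expanded.size, side="left")
    return float(expanded[min(i, expanded.size - 1)])
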