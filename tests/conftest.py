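import numpy as np
import pandas as pd
import pytest

from mycostarve import godag, synthetic


@pytest.fixture
def chain_dag():
    """C is_a B is_a A."""
    return godag.GoDag({"A": "a", "B": "b", "C": "c"}, {"B": {"A"}, "C": {"B"}})


@pytest.fixture
def diamond_dag():
    """C is_a {B1, B2}, both is_a A."""
    return godag.GoDag(
        {"A": "a", "B1": "b1", "B2": "b2", "C": "c"},
        {"B1": {"A"}, "B2": {"A"}, "C": {"B1", "B2"}},
    )


@pytest.fixture(scope="session")
def five_sample_groups():
    """Sample→group labels for a 3-vs-2 exp/day1 design."""
    return pd.Series(
        {"exp_1": "exp", "exp_2": "exp", "exp_3": "exp",
         "day1_1": "day1", "day1_2": "day1"}
    )


def straight_ribbon(width: int, length: int = 60, pad: int = 10) -> np.ndarray:
    """Boolean mask of a horizontal ribbon of exactly `width` rows."""
    mask = np.zeros((width + 2 * pad, length + 2 * pad), dtype=bool)
    mask[pad : pad + width, pad : pad + length] = True
    return mask


@pytest.fixture(scope="session")
def mixture_samples():
    """Pooled diameter samples from three bimodal synthetic micrographs.

    Session-scoped because the measurement chain is the expensive part of the
    suite; tests must not mutate the returned list.
    """
    from mycostarve import morphometry as mm

    samples = []
    for seed in range(3):
        bundle = synthetic.generate_mycelium_image(
            30, seed=200 + seed, shape=(640, 640), noise_sd=0.05
        )
        m = mm.Micrograph(bundle.image, bundle.pixel_size, f"mix{seed}")
        samples.extend(mm.measure_micrograph(m))
    return samples
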