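import numpy as np
import pandas as pd
import pytest

from rareaml import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    """A desk-sized study design: fast but structurally faithful."""
    return SimConfig(
        seed=7,
        n_genes=200,
        n_samples_reference=60,
        n_samples_group=7,
        n_up_spiked=20,
        n_down_spiked=10,
        n_drugs=30,
        n_selective_drugs=2,
        n_rewired=8,
        n_bound_genes=40,
        n_bound_and_de=5,
        n_screen_case=4,
        n_screen_reference=20,
        n_background_peaks=30,
    )


@pytest.fixture
def tiny_de_frame():
    """10 samples, 4 genes: one clean up, one clean down, two null."""
    rng = np.random.default_rng(0)
    samples = [f"s{i}" for i in range(10)]
    groups = pd.Series(["reference"] * 7 + ["case"] * 3, index=samples)
    base = rng.normal(6.0, 0.3, size=(4, 10))
    base[0, 7:] += 3.0
    base[1, 7:] -= 3.0
    values = pd.DataFrame(base, index=["up1", "down1", "null1", "null2"], columns=samples)
    return values, groups
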