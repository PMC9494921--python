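import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_lfq():
    """A tiny hand-checkable LFQ matrix factory."""
    from neuroscreen.proteome_prep import LfqMatrix

    def make(log2_values: np.ndarray, runs=None, categories=None,
             stage="normalized"):
        n_p, n_i = log2_values.shape
        individuals = [f"I{j + 1}" for j in range(n_i)]
        proteins = [f"P{i + 1}" for i in range(n_p)]
        values = pd.DataFrame(log2_values, index=proteins, columns=individuals)
        if runs is None:
            runs = ["run1"] * n_i
        runs = pd.Series(runs, index=individuals)
        if categories is not None:
            categories = pd.Series(categories, index=individuals)
        return LfqMatrix(values=values, runs=runs, categories=categories,
                         stage=stage)

    return make
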