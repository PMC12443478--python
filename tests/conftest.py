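import numpy as np
import pytest

from burdenkit import BurdenScenario, Construct


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_scenario():
    """A scenario small enough for fast unit tests."""
    return BurdenScenario(
        seed=7,
        constructs=(Construct("Vector", 0.0), Construct("moxYG", 0.44)),
        n_genes=600,
        n_categories=10,
        category_size=20,
        n_proteins=200,
        t_max_min=1200.0,
    )
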