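import numpy as np
import pandas as pd
import pytest

from quadchain import preprocess as pp
from quadchain import synthdata as sd


@pytest.fixture(scope="session")
def prior():
    return sd.generate_prior_network(5, 5, 10, 5, 50, edge_density=0.2, seed=7)


@pytest.fixture(scope="session")
def truth(prior):
    return sd.generate_truth(prior, 3, effect_log2fc=2.0, active_map="cycle",
                             seed=3)


@pytest.fixture(scope="session")
def sim(prior, truth):
    design = sd.default_design(n_cells=60)
    return sd.simulate_counts(prior, truth, design, seed=42)


@pytest.fixture(scope="session")
def counts(sim):
    return sim[0]


@pytest.fixture(scope="session")
def cells(sim):
    return sim[1]


@pytest.fixture(scope="session")
def normed(sim):
    return pp.normalize_log1p(sim[0])
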