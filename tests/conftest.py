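import numpy as np
import pytest

from curlquant import CaSimConfig, CountSimConfig, simulate_calcium_traces, simulate_counts


@pytest.fixture(scope="session")
def small_experiment():
    """A 12-sample dual-allele experiment with 5 planted down-regulated genes."""
    config = CountSimConfig(n_genes=400, n_shared_down=5, n_shared_up=3, seed=42)
    return simulate_counts(config)


@pytest.fixture(scope="session")
def small_traceset():
    config = CaSimConfig(n_cells=8, seed=3, rate_scaling_by_group={"mutant": 0.5})
    groups = ["wt"] * 4 + ["mutant"] * 4
    return simulate_calcium_traces(config, groups)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
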