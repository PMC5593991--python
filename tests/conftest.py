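import numpy as np
import pandas as pd
import pytest

from dimorph import synthgen


@pytest.fixture(scope="session")
def small_expression():
    """20k-probe factorial experiment with 100 stress spike-ins at |log2FC|=1."""
    n_probes, n_spiked = 20_000, 100
    rng = np.random.default_rng(42)
    spiked = [f"P{i:06d}" for i in rng.choice(n_probes, n_spiked, replace=False)]
    effects = [
        synthgen.EffectSpec([p], "Stress", 1.0 if i % 2 else -1.0)
        for i, p in enumerate(spiked)
    ]
    exp = synthgen.simulate_expression(
        synthgen.SimDesign(n_probes=n_probes, seed=7), effects
    )
    return exp, pd.Index(spiked)


@pytest.fixture(scope="session")
def methylation_table():
    table, truth = synthgen.simulate_methylation(seed=0)
    return table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
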