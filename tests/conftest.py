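import numpy as np
import pytest

from awarescreen import (
    AnalysisConfig,
    ResponseMatrix,
    ScaleSpec,
    SimulationScenario,
    simulate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_scale():
    return ScaleSpec(
        scale_name="demo",
        items=[("i1", 2), ("i2", 10), ("i3", 25), ("i4", 40)],
    )


@pytest.fixture
def small_matrix(rng, small_scale):
    """60 subjects x 5 items (the 4 demo-scale items plus one extra)."""
    values = rng.integers(0, 4, size=(60, 5)).astype(float)
    return ResponseMatrix(
        subject_ids=[f"s{i}" for i in range(60)],
        item_labels=["i1", "i2", "i3", "i4", "extra"],
        values=values,
    )


@pytest.fixture
def sim_values():
    """One simulated scale draw with rising error (a < b)."""
    scen = SimulationScenario(a=0.5, b=2.0, q=4, n=200, replicates=1, seed=99)
    return simulate_dataset(scen, seed=99)


@pytest.fixture
def fast_config():
    return AnalysisConfig(seed=7, bootstrap_replicates=50)
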