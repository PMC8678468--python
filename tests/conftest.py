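import numpy as np
import pytest

from asinherit.simulate import SimConfig, simulate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(20211203)


@pytest.fixture(scope="session")
def small_sim_dir(tmp_path_factory):
    """A small single-tissue simulated dataset on disk (80 events)."""
    out = tmp_path_factory.mktemp("simdata")
    config = SimConfig(n_events=80, seed=4207, tissues=("brain",))
    simulate_dataset(config, out)
    return out


@pytest.fixture(scope="session")
def reference_design_sim_dir(tmp_path_factory):
    """Reference-design dataset (23 samples/tissue, CL females = 2), 60 events."""
    from asinherit.simulate import make_reference_design

    out = tmp_path_factory.mktemp("refdesign")
    config = make_reference_design(
        n_events=60, seed=915, tissues=("brain", "liver"), drop_liver_hybrid_females=True
    )
    simulate_dataset(config, out)
    return out
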