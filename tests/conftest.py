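import pytest

from nlrevo import pipeline, simulate


@pytest.fixture(scope="session")
def sim_config():
    return simulate.SimConfig(seed=11, n_families=25)


@pytest.fixture(scope="session")
def sim_dataset(sim_config, tmp_path_factory):
    """A small emitted synthetic dataset, loaded back through core IO."""
    out = tmp_path_factory.mktemp("simdata")
    sims = simulate.simulate_dataset(sim_config)
    simulate.emit_dataset(sims, sim_config, out, force=True)
    return pipeline.load_dataset(out), sims, out
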