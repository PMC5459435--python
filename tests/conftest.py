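from pathlib import Path

import pytest

from hmedip.simulate import (
    SimulationConfig,
    build_toy_genome,
    plant_dhmr_signals,
    simulate_reads,
    write_fixtures,
)


@pytest.fixture(scope="session")
def desk_config() -> SimulationConfig:
    """Desk-scale benchmark conditions: 1 Mb genome, depth 20, mild overdispersion."""
    return SimulationConfig(
        seed=11, depth_per_window=20.0, dispersion=0.05, n_hyper=50, n_hypo=10
    )


@pytest.fixture(scope="session")
def toy_genome(desk_config):
    return build_toy_genome(desk_config)


@pytest.fixture(scope="session")
def planted(toy_genome, desk_config):
    return plant_dhmr_signals(toy_genome, desk_config)


@pytest.fixture(scope="session")
def read_pair(toy_genome, planted, desk_config):
    return {
        cond: simulate_reads(toy_genome, planted, desk_config, cond)
        for cond in ("control", "exposed")
    }


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory, toy_genome, planted, read_pair) -> Path:
    d = tmp_path_factory.mktemp("fixtures") / "bundle"
    write_fixtures(toy_genome, planted, read_pair, d)
    return d
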