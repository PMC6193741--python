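import numpy as np
import pytest

from oncoflow import (SimulationConfig, build_tissue_mesh, default_parameters,
                      embed_network, generate_network)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def small_mesh():
    return build_tissue_mesh(0.0119, 8, 0.0005)


@pytest.fixture(scope="session")
def desk_mesh():
    return build_tissue_mesh(0.0119, 12, 0.0005)


@pytest.fixture(scope="session")
def desk_network(desk_mesh):
    return generate_network(1, 420, desk_mesh)


@pytest.fixture(scope="session")
def desk_coupling(desk_mesh, desk_network):
    return embed_network(desk_mesh, desk_network)


def _run(config, params=None):
    from oncoflow.orchestrator import run_simulation

    return run_simulation(config, params=params)


@pytest.fixture(scope="session")
def control_low_pore():
    """40-day untreated control, matured/low-permeability vessels."""
    return _run(SimulationConfig(end_day=40.0, seed=1, pore_radius=1.0e-8))


@pytest.fixture(scope="session")
def control_high_pore():
    """40-day untreated control, hyperpermeable vessels."""
    return _run(SimulationConfig(end_day=40.0, seed=1, pore_radius=1.5e-7))


@pytest.fixture(scope="session")
def treated_pair():
    """Matched day-10 injections at low/high binding affinity (r_p=10 nm)."""
    low = _run(SimulationConfig(end_day=16.0, seed=1, pore_radius=1.0e-8,
                                k_on=0.005, inject_day=10.0))
    high = _run(SimulationConfig(end_day=16.0, seed=1, pore_radius=1.0e-8,
                                 k_on=5.0, inject_day=10.0))
    return low, high


@pytest.fixture(scope="session")
def sweep_table():
    """Reduced-scale poresize × affinity × injection-day matrix + controls."""
    from oncoflow.orchestrator import experiment_matrix, run_sweep

    return run_sweep(experiment_matrix(seed=1, profile="coarse"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
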