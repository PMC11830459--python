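import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nitronet.chem import Environment, nitrogen_thermo_table
from nitronet.dynamics import solve_steady_state
from nitronet.networks import enzyme_network, transitive_closure
from nitronet.pipeline import build_nitrogen_reaction_set

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table():
    return nitrogen_thermo_table()


@pytest.fixture(scope="session")
def reaction_set(table):
    return build_nitrogen_reaction_set(table)


@pytest.fixture(scope="session")
def enz_net():
    return enzyme_network()


@pytest.fixture(scope="session")
def com_net(enz_net):
    return transitive_closure(enz_net)


@pytest.fixture(scope="session")
def worked_example_env():
    """The reference single-condition graph example: [O2] = 1e-5 M, pH 8,
    p = 0.3, I = 1e-5, D = 1e-3, k_def = 1."""
    return Environment(o2=1e-5, ph=8.0, p=0.3, influx=1e-5, efflux=1e-3, k_def=1.0)


@pytest.fixture(scope="session")
def worked_example_ss(reaction_set, worked_example_env, table):
    ss = solve_steady_state(reaction_set, worked_example_env, table)
    assert ss.converged
    return ss


@pytest.fixture(scope="session")
def n_atoms(table):
    return np.array([table[s].count("N") for s in table.state_ids], dtype=float)
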