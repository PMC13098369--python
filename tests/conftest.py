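import numpy as np
import pytest

from pcgrn import (GRNModel, SimulationDesign, generate_grn_topology,
                   simulate_expression)


@pytest.fixture(scope="session")
def benchmark_net():
    """Default benchmark topology: 1 root, 5/8/20 genes per layer."""
    return generate_grn_topology(5, 8, 20, seed=42)


@pytest.fixture(scope="session")
def benchmark_design():
    return SimulationDesign(seed=42)


@pytest.fixture(scope="session")
def benchmark_expr(benchmark_net, benchmark_design):
    return simulate_expression(benchmark_net, benchmark_design)


@pytest.fixture(scope="session")
def benchmark_fit(benchmark_net, benchmark_design):
    model = GRNModel.from_simulation(benchmark_net, benchmark_design)
    return model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
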