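import numpy as np
import pytest

import coversad as cs


@pytest.fixture(scope="session")
def standard_layout():
    return cs.generate_plot_layout()


@pytest.fixture(scope="session")
def small_layout():
    """4 transects x 11 points = 44 points; fast."""
    return cs.generate_plot_layout(4, 10, 1)


@pytest.fixture(scope="session")
def simulated_plot(standard_layout):
    """A realistic plot: 12-species Pareto community on the full layout."""
    community = cs.simulate_community(12, 1.0, 60.0, seed=42)
    records = cs.simulate_point_intercepts(community, standard_layout, seed=43)
    return community, records


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
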