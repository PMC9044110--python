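import numpy as np
import pytest

from adosdif.grm import GRMItemParams, QuadratureGrid
from adosdif.synthetic import SimulationDesign, make_clinic_design, simulate_dataset


@pytest.fixture(scope="session")
def grid():
    return QuadratureGrid.normal()


@pytest.fixture(scope="session")
def small_design():
    """Moderate-size module-3-like two-group design with no planted DIF."""
    return make_clinic_design(
        "race", "3", seed=17, n_reference=300, n_focal=300, a_range=(1.0, 2.5)
    )


@pytest.fixture(scope="session")
def small_dataset(small_design):
    ds, thetas, group = simulate_dataset(small_design)
    return ds, thetas, group


def fixed_param_design(a=2.0, b=(-1.0, 1.0), **kwargs) -> SimulationDesign:
    """Design in which every polytomous item has identical known parameters."""
    from adosdif.data_model import algorithm_spec

    spec = algorithm_spec(kwargs.pop("algorithm_id", "3"))
    params = {}
    for item in spec.item_names:
        nb = spec.n_categories[item] - 1
        params[item] = GRMItemParams(a=a, b=tuple(b[:nb]))
    defaults = dict(n_reference=100, n_focal=100, seed=0)
    defaults.update(kwargs)
    return SimulationDesign(
        spec=spec, ref_params=params, focal_params=dict(params), **defaults
    )
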