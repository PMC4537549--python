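import numpy as np
import pytest

from sphingoflux import (
    build_ad_model,
    build_homeostasis_model,
    forward_sensitivities,
    make_birth_death,
    make_linear_chain,
    make_random_network,
    make_redundant_pair,
    simulate,
)


@pytest.fixture(scope="session")
def birth_death():
    return make_birth_death(10.0, 1.0)


@pytest.fixture(scope="session")
def chain():
    return make_linear_chain(4.0, 2.0, 1.0)


@pytest.fixture(scope="session")
def redundant_pair():
    return make_redundant_pair()


@pytest.fixture(scope="session")
def random_net():
    return make_random_network(5, 8, mm_fraction=0.5, seed=1)


@pytest.fixture(scope="session")
def homeostasis():
    return build_homeostasis_model()


@pytest.fixture(scope="session")
def ad_corrected():
    return build_ad_model(corrected=True)


@pytest.fixture(scope="session")
def ad_uncorrected():
    return build_ad_model(corrected=False)


@pytest.fixture(scope="session")
def homeostasis_sensitivities(homeostasis):
    """Forward sensitivities of the full model at its operating point."""
    return forward_sensitivities(
        homeostasis,
        x0=homeostasis.initial_state(),
        grid=np.linspace(0.0, 2000.0, 201),
    )


def finite_difference_sensitivities(net, x0, grid, rel_step=1e-6):
    """Central finite-difference oracle for the forward sensitivity courses."""
    params = net.parameter_names()
    base = net.parameter_values()
    n = len(x0)
    out = np.zeros((grid.size, n, len(params)))
    for i, key in enumerate(params):
        h = rel_step * base[i]
        hi = net.copy()
        hi.set_parameter(key, base[i] + h)
        lo = net.copy()
        lo.set_parameter(key, base[i] - h)
        traj_hi = simulate(hi, x0, grid[-1] if grid[-1] > 0 else 1.0, grid)
        traj_lo = simulate(lo, x0, grid[-1] if grid[-1] > 0 else 1.0, grid)
        out[:, :, i] = (traj_hi.values - traj_lo.values) / (2 * h)
    return out
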