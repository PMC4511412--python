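import numpy as np
import pytest

import qsbiofilm as qb


@pytest.fixture()
def params():
    return qb.default_parameters()


@pytest.fixture()
def small_grid(params):
    return qb.Grid(nx=16, ny=8, L=params.L, H=params.H)


@pytest.fixture()
def seeded_state(params, small_grid):
    spec = qb.InoculumSpec(n_colonies=3, seed=7)
    return qb.generate_inoculum(spec, small_grid, params)


def quick_settings(**kw):
    """Small, fast numerical settings for unit tests."""
    defaults = dict(nx=16, ny=8, dt=1e-3, t_end=0.01, output_every=0.005,
                    solver_tol=1e-10)
    defaults.update(kw)
    return qb.default_settings(**defaults)
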