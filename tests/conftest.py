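import numpy as np
import pytest

from polarmd.engine import Engine
from polarmd.fixtures import gen_random_multipole_gas, gen_water_box, \
    gen_water_dimer
from polarmd.system import MDConfig


@pytest.fixture(scope="session")
def water_dimer_engine():
    system, params = gen_water_dimer()
    cfg = MDConfig(polar_solver="pcg", polar_eps=1e-10, polar_maxiter=300)
    return Engine(system, params, cfg), system


@pytest.fixture(scope="session")
def water8():
    """Small periodic water box with tight polarization settings."""
    system, params = gen_water_box(n_waters=8, seed=2)
    cfg = MDConfig(polar_solver="pcg", polar_eps=1e-9, polar_maxiter=300,
                   ewald_cutoff=3.0, vdw_cutoff=3.0, bspline_order=6,
                   pme_grid=(30, 30, 30))
    return Engine(system, params, cfg), system, params


@pytest.fixture(scope="session")
def gas30():
    """30-site polarizable multipole gas bound to a dipole-solver model."""
    from polarmd.polarization import PolarizationModel

    system, params = gen_random_multipole_gas(30, edge=12.0, seed=3)
    cfg = MDConfig(ewald_cutoff=5.5, bspline_order=6, pme_grid=(24, 24, 24))
    eng = Engine(system, params, cfg)
    q, mu, Q, mu_loc, Q_loc, alphas = eng._lab_multipoles(system.positions)
    pairs = eng._pairs(system.positions)
    model = PolarizationModel(system.positions, system.box, alphas,
                              eng.tholes, pairs, eng.beta, recip=eng.grid)
    rng = np.random.default_rng(11)
    E = rng.normal(size=(30, 3)) * 0.05
    return model, E
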