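import numpy as np
import pytest

from lvmodes.geometry import QuadratureGrid, make_fixture_geometry
from lvmodes.kinematics import KinematicsEngine
from lvmodes.modes import standard_basis


@pytest.fixture(scope="session")
def dom_axi():
    return make_fixture_geometry("axisymmetric")


@pytest.fixture(scope="session")
def dom_asym():
    return make_fixture_geometry("asymmetric-septal")


@pytest.fixture(scope="session")
def basis8():
    return standard_basis(8)


@pytest.fixture(scope="session")
def grid_small(dom_asym):
    return QuadratureGrid.build(dom_asym, n_mu=3, n_nu=11, n_phi=12)


@pytest.fixture(scope="session")
def engine_small(dom_asym, basis8, grid_small):
    return KinematicsEngine(dom_asym, basis8, grid_small.mu0,
                            grid_small.nu0, grid_small.phi0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_admissible_q(engine, rng, scale=0.05, max_tries=50):
    """Rejection-sample a kinematic state that passes the admissibility
    checks of the engine."""
    for _ in range(max_tries):
        q = rng.uniform(-scale, scale, engine.basis.n_q)
        try:
            engine.evaluate(q)
        except Exception:
            continue
        return q
    raise RuntimeError("could not draw an admissible state")
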