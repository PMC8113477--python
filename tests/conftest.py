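import numpy as np
import pytest

from icepept.phase import classify_frameset
from icepept.synthetic import (ScriptedTrajectoryParams, build_ice_ih,
                               build_liquid_box, generate_trajectory)


@pytest.fixture(scope="session")
def ice_lattice():
    """Periodic proton-disordered ice Ih, 3x3x3 cells (216 molecules)."""
    return build_ice_ih((3, 3, 3), seed=11)


@pytest.fixture(scope="session")
def liquid_box():
    """Random liquid box at water density, 25 Å cube."""
    return build_liquid_box((25.0, 25.0, 25.0), seed=12)


@pytest.fixture(scope="session")
def short_traj():
    """Small scripted trajectory: v=0.5 Å/ns, binding at 20 ns, 35 ns span."""
    params = ScriptedTrajectoryParams(
        box=(13.5, 13.5, 50.0), n_frames=70, t_bind=20.0, seed=13)
    return generate_trajectory(params)


@pytest.fixture(scope="session")
def short_traj_labels(short_traj):
    return classify_frameset(short_traj)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
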