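import numpy as np
import pytest

import schoenersim as ss
from schoenersim.cli import example_scenario


@pytest.fixture(scope="session")
def demo_cfg():
    return example_scenario(horizon=(0.0, 100.0))


@pytest.fixture(scope="session")
def demo_model(demo_cfg):
    return demo_cfg.build_model()


@pytest.fixture(scope="session")
def demo_traj(demo_cfg, demo_model):
    history = demo_cfg.build_history()
    return ss.integrate_schoener(demo_model, history, (0.0, 100.0), step=0.02, space="log")


@pytest.fixture(scope="session")
def certified_model():
    """A weak-competition model whose permanence certificate is strict."""
    return ss.random_weak_competition_model(3, horizon=(0.0, 150.0))


@pytest.fixture(scope="session")
def certified_bounds(certified_model):
    return ss.permanence_bounds(certified_model)


def constant_model(
    a10=1.0, a20=1.0, a11=0.35, a22=0.35, a12=1e-4, a21=1e-4,
    m1=2.0, m2=2.0, c1=0.3, c2=0.3, delays=None, schedule=None,
):
    """Constant-coefficient model helper shared across test modules."""
    C = ss.QuasiPeriodicCoefficient.constant
    return ss.SchoenerModel(
        a10=C(a10), a20=C(a20), a11=C(a11), a22=C(a22), a12=C(a12), a21=C(a21),
        m1=C(m1), m2=C(m2), c1=C(c1), c2=C(c2),
        delays=delays or {},
        schedule=schedule or ss.ImpulseSchedule.empty(n_species=2),
    )


@pytest.fixture
def make_constant_model():
    return constant_model


def synthetic_trajectory(times, states, jumps=None, history=None):
    """Build a Trajectory directly from sampled values (diagnostics tests)."""
    times = np.asarray(times, dtype=float)
    states = np.atleast_2d(np.asarray(states, dtype=float))
    if states.shape[0] != times.size:
        states = states.T
    dx = np.gradient(states, times, axis=0)
    return ss.Trajectory(
        times=times,
        states=states,
        jumps=jumps or [],
        step=float(times[1] - times[0]),
        species_count=states.shape[1],
        t0=float(times[0]),
        _node_t=times.copy(),
        _node_x=states.copy(),
        _node_dx=dx,
        _history=history,
    )


@pytest.fixture
def make_synthetic_trajectory():
    return synthetic_trajectory
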