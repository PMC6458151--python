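"""Shared fixtures: the reference two-bead model and cached trajectories."""

import pytest

import eprtools as ep


@pytest.fixture(scope="session")
def ref_model():
    """Reference driven chain: k = gamma = 1, T = (250, 25)."""
    return ep.build_chain(2, 1.0, 1.0, temps=(250.0, 25.0))


@pytest.fixture(scope="session")
def ref_state(ref_model):
    return ref_model.steady_state()


@pytest.fixture(scope="session")
def eq_model():
    """Equilibrium twin: both baths at T = 100."""
    return ep.build_chain(2, 1.0, 1.0, temps=(100.0, 100.0))


@pytest.fixture(scope="session")
def driven_traj(ref_model):
    """Steady-state Langevin path, tau_obs = 1000 at dt = 1e-3."""
    x0 = ep.draw_steady_initial(ref_model, seed=7)
    return ep.euler_maruyama(ref_model, x0, 1e-3, 1_000_000, seed=7)


@pytest.fixture(scope="session")
def eq_traj(eq_model):
    """Equilibrium Langevin path, tau_obs = 1000 at dt = 1e-3."""
    x0 = ep.draw_steady_initial(eq_model, seed=8)
    return ep.euler_maruyama(eq_model, x0, 1e-3, 1_000_000, seed=8)


@pytest.fixture(scope="session")
def small_lattice():
    """Coarse two-bead lattice on a shrunken box (keeps all rates positive)."""
    return ep.two_bead_lattice(counts=(40, 40), box_scale=0.6)


def random_two_bead_params(rng):
    """One random two-bead parameter set with non-degenerate driving.

    The temperature ratio is bounded away from 1: the trace formula for
    the entropy production rate subtracts two O(T) terms to produce an
    O(DT^2/T) result, so near-equal temperatures lose relative precision
    to cancellation and cannot be verified at tight relative tolerance.
    """
    k = rng.uniform(0.2, 5.0)
    gamma = rng.uniform(0.2, 5.0)
    th = rng.uniform(5.0, 500.0)
    tc = th * rng.uniform(0.05, 0.9)
    if rng.random() < 0.5:
        th, tc = tc, th
    return k, gamma, th, tc
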