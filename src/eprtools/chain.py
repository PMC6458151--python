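"""Bead-spring chains coupled to per-bead heat baths.

A chain of ``n`` beads, each moving in one dimension, is connected by
linear springs of stiffness ``k`` to its neighbours and, at both ends, to
rigid walls (``n + 1`` springs in total).  Bead ``i`` is immersed in its own
viscous bath of temperature ``temps[i]`` exerting friction ``gamma``.  In
the overdamped limit the displacement vector obeys the Langevin equation

    dx/dt = A x + F xi(t),

with ``A`` the symmetric tridiagonal drift matrix (diagonal ``-2k/gamma``,
off-diagonal ``k/gamma``) and ``F = diag(sqrt(2 T_i / gamma))`` the noise
amplitude.  Units use ``k_B = 1`` throughout: temperatures are stored as
energies (e.g. ``k_B T = 25``).

When bath temperatures differ the steady state carries probability
currents and dissipates: this module provides the exact stationary
covariance, density, current, conjugate thermodynamic force and entropy
production rate that serve as ground truth for every estimator in the
package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_continuous_lyapunov


__all__ = [
    "BeadSpringModel",
    "SteadyState",
    "build_chain",
    "stationary_covariance",
]


@dataclass(frozen=True)
class BeadSpringModel:
    """Overdamped bead-spring chain with per-bead baths (``k_B = 1``).

    Attributes
    ----------
    n_beads : int
        Number of beads (>= 2).
    k : float
        Spring constant shared by all ``n_beads + 1`` springs (force/length).
    gamma : float
        Friction coefficient of each bath (force·time/length).
    temps : ndarray, shape (n_beads,)
        Bath temperatures in energy units (``k_B T``).
    A : ndarray, shape (n, n)
        Drift matrix (1/time); tridiagonal ``(-2, 1) * k/gamma``.
    Fnoise : ndarray, shape (n, n)
        Diagonal noise amplitude, ``sqrt(2 T_i / gamma)``.
    D : ndarray, shape (n, n)
        Diffusion tensor ``F Fᵀ / 2 = diag(T_i / gamma)`` (length²/time).
    """

    n_beads: int
    k: float
    gamma: float
    temps: np.ndarray
    A: np.ndarray = field(repr=False)
    Fnoise: np.ndarray = field(repr=False)
    D: np.ndarray = field(repr=False)

    @property
    def is_equilibrium(self) -> bool:
        """True when all baths share one temperature (no dissipation)."""
        return bool(np.allclose(self.temps, self.temps[0]))

    def steady_state(self) -> "SteadyState":
        """Solve for the stationary Gaussian state of this chain."""
        return SteadyState(self)


def build_chain(n_beads, k, gamma, temps=None, endpoints=None):
    """Construct a bead-spring chain model.

    Parameters
    ----------
    n_beads : int
        Number of beads, at least 2.
    k, gamma : float
        Spring constant and friction, both positive.
    temps : array-like of length n_beads, optional
        Bath temperature of every bead, in energy units.
    endpoints : (T_cold, T_hot), optional
        Alternative to ``temps``: bath temperatures ramp linearly from the
        first value at bead 0 to the second at bead ``n_beads - 1``,
        inclusive of both endpoints.

    Returns
    -------
    BeadSpringModel
    """
    n_beads = int(n_beads)
    if n_beads < 2:
        raise ValueError("n_beads must be at least 2")
    if k <= 0 or gamma <= 0:
        raise ValueError("spring constant k and friction gamma must be positive")
    if (temps is None) == (endpoints is None):
        raise ValueError("provide exactly one of temps or endpoints")
    if endpoints is not None:
        t0, t1 = endpoints
        temps = np.linspace(float(t0), float(t1), n_beads)
    temps = np.asarray(temps, dtype=float)
    if temps.shape != (n_beads,):
        raise ValueError(f"temps must have length {n_beads}")
    if np.any(temps <= 0):
        raise ValueError("all bath temperatures must be positive")

    off = (k / gamma) * np.ones(n_beads - 1)
    A = np.diag(-2.0 * k / gamma * np.ones(n_beads)) + np.diag(off, 1) + np.diag(off, -1)
    Fnoise = np.diag(np.sqrt(2.0 * temps / gamma))
    D = np.diag(temps / gamma)
    return BeadSpringModel(n_beads=n_beads, k=float(k), gamma=float(gamma),
                           temps=temps, A=A, Fnoise=Fnoise, D=D)


def stationary_covariance(model: BeadSpringModel) -> np.ndarray:
    """Stationary covariance C, the unique solution of ``A C + C Aᵀ = -2 D``.

    Solved by a dense direct Lyapunov method; the chain drift matrix is
    always Hurwitz so the solution exists and is positive definite.
    """
    C = solve_continuous_lyapunov(model.A, -2.0 * model.D)
    return 0.5 * (C + C.T)


class SteadyState:
    """Exact stationary state of a bead-spring chain.

    The stationary density is the zero-mean Gaussian with covariance ``C``;
    the stationary probability current is ``j_ss(x) = (A + D C⁻¹) x ρ_ss(x)``.
    The conjugate thermodynamic force ``F(x) = j_ssᵀ D⁻¹ / ρ_ss`` is linear
    in ``x``, and the local entropy production rate ``σ̇_ss = F · j_ss`` is a
    nonnegative quadratic form times the Gaussian density.
    """

    def __init__(self, model: BeadSpringModel):
        self.model = model
        self.cov = stationary_covariance(model)
        self._cov_inv = np.linalg.inv(self.cov)
        # phi = A + D C^{-1}: the current velocity field j_ss / rho_ss = phi x
        self._phi = model.A + model.D @ self._cov_inv
        self._D_inv = np.linalg.inv(model.D)
        sign, logdet = np.linalg.slogdet(2.0 * np.pi * self.cov)
        self._log_norm = -0.5 * logdet
        self.epr = self._entropy_production_rate()
        self.heat_flow = self._heat_flow() if model.n_beads == 2 else None

    # -- scalar summaries ---------------------------------------------------

    def _entropy_production_rate(self) -> float:
        m = self.model
        val = float(np.trace(m.A @ self._D_inv @ m.A @ self.cov - self._cov_inv @ m.D))
        # guard tiny negative round-off at equilibrium
        return max(val, 0.0)

    def _heat_flow(self) -> float:
        m = self.model
        return m.k * (m.temps[0] - m.temps[1]) / (4.0 * m.gamma)

    # -- fields -------------------------------------------------------------

    def density(self, x) -> np.ndarray:
        """Stationary density ρ_ss at point(s) ``x`` (shape (..., n))."""
        x = np.asarray(x, dtype=float)
        quad = np.einsum("...i,ij,...j->...", x, self._cov_inv, x)
        return np.exp(self._log_norm - 0.5 * quad)

    def current(self, x) -> np.ndarray:
        """Stationary probability current j_ss(x) (shape (..., n))."""
        x = np.asarray(x, dtype=float)
        vel = x @ self._phi.T
        return vel * self.density(x)[..., None]

    def mean_velocity(self, x) -> np.ndarray:
        """Current velocity j_ss / ρ_ss = (A + D C⁻¹) x."""
        x = np.asarray(x, dtype=float)
        return x @ self._phi.T

    def thermodynamic_force(self, x) -> np.ndarray:
        """Conjugate force F(x) = (j_ss / ρ_ss)ᵀ D⁻¹, linear in x."""
        x = np.asarray(x, dtype=float)
        return x @ self._phi.T @ self._D_inv

    def local_epr(self, x) -> np.ndarray:
        """Local entropy production rate σ̇_ss(x) = F(x) · j_ss(x) >= 0."""
        F = self.thermodynamic_force(x)
        j = self.current(x)
        return np.einsum("...i,...i->...", F, j)


def entropy_production_rate(state: SteadyState) -> float:
    """Total steady entropy production rate Ṡ_ss (units k_B / time).

    Evaluates the trace formula ``Tr{A D⁻¹ A C - C⁻¹ D}``; for two beads
    this equals the closed form ``k (T_h - T_c)² / (4 γ T_h T_c)``.
    """
    return state.epr


def heat_flow(state: SteadyState) -> float:
    """Net steady heat flow Q̇_ss = k (T_h - T_c) / (4 γ); two beads only."""
    if state.model.n_beads != 2:
        raise ValueError("heat_flow is defined only for the two-bead chain")
    return state.heat_flow


def two_bead_epr_closed_form(model: BeadSpringModel) -> float:
    """Closed-form Ṡ_ss = k (T_h - T_c)² / (4 γ T_h T_c) for two beads."""
    if model.n_beads != 2:
        raise ValueError("closed form applies to the two-bead chain only")
    th, tc = model.temps
    return model.k * (th - tc) ** 2 / (4.0 * model.gamma * th * tc)


def two_bead_covariance_closed_form(model: BeadSpringModel) -> np.ndarray:
    """Closed-form stationary covariance for the two-bead chain."""
    if model.n_beads != 2:
        raise ValueError("closed form applies to the two-bead chain only")
    th, tc = model.temps
    pref = 1.0 / (12.0 * model.k)
    return pref * np.array([[7 * th + tc, 2 * (tc + th)],
                            [2 * (tc + th), th + 7 * tc]])


__all__ += [
    "entropy_production_rate",
    "heat_flow",
    "two_bead_epr_closed_form",
    "two_bead_covariance_closed_form",
]
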