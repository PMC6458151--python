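"""Trajectory generation: Langevin paths and lattice jump processes.

Two complementary representations of the same dynamics are provided.

* **Discrete time, continuous space** — the overdamped Langevin equation is
  integrated with the stochastic Euler scheme
  ``x_{i+1} = x_i + A x_i Δt + F η``, ``η ~ N(0, Δt I)`` per component.
* **Continuous time, discrete space** — configuration space is discretized
  on a rectangular lattice and the diffusion is replaced by a
  nearest-neighbour Markov jump process whose rates

      W(x -> x ± h_i e_i) = D_ii / h_i² ± (A x)_i / (2 h_i)

  recover the Fokker-Planck generator as ``h -> 0``.  Jump trajectories
  are sampled exactly with the Gillespie algorithm.

Both samplers take explicit integer seeds and are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .chain import BeadSpringModel, stationary_covariance

try:  # optional acceleration for the inner loops
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


__all__ = [
    "Trajectory",
    "LatticeSpec",
    "JumpTrajectory",
    "euler_maruyama",
    "draw_steady_initial",
    "jump_rates",
    "gillespie",
]


@dataclass
class Trajectory:
    """Uniformly sampled discrete-time path in continuous space.

    ``positions`` has shape (n_steps + 1, n); sample ``i`` is at time
    ``t0 + i * dt``.  ``tau_obs`` is the total observation time.
    """

    dt: float
    positions: np.ndarray
    t0: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or len(self.positions) < 2:
            raise ValueError("positions must be a (>=2, n) array")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("trajectory contains non-finite entries")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_dim(self) -> int:
        return self.positions.shape[1]

    @property
    def tau_obs(self) -> float:
        return self.dt * (len(self.positions) - 1)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.positions))

    def midpoints(self) -> np.ndarray:
        """Stratonovich midpoints (x_i + x_{i-1}) / 2, shape (n_steps, n)."""
        x = self.positions
        return 0.5 * (x[1:] + x[:-1])

    def displacements(self) -> np.ndarray:
        """Per-step displacements x_i - x_{i-1}, shape (n_steps, n)."""
        x = self.positions
        return x[1:] - x[:-1]

    def central_velocities(self) -> np.ndarray:
        """Central-difference velocities (x_{i+1} - x_{i-1}) / (2 Δt).

        Defined at the interior samples ``x_1 .. x_{N-2}``.
        """
        x = self.positions
        return (x[2:] - x[:-2]) / (2.0 * self.dt)

    def reversed(self) -> "Trajectory":
        """Time-reversed copy (odd functionals flip sign)."""
        return Trajectory(dt=self.dt, positions=self.positions[::-1].copy(),
                          t0=self.t0, seed=self.seed)


@njit(cache=False)
def _euler_loop(x0, A, fdiag, noise, out):  # pragma: no cover - jitted
    n = x0.shape[0]
    x = x0.copy()
    out[0] = x
    for i in range(noise.shape[0]):
        xnew = np.empty(n)
        for a in range(n):
            drift = 0.0
            for b in range(n):
                drift += A[a, b] * x[b]
            xnew[a] = x[a] + drift + fdiag[a] * noise[i, a]
        x = xnew
        out[i + 1] = x
    return out


def euler_maruyama(model: BeadSpringModel, x0, dt: float, n_steps: int,
                   seed: int | None = None) -> Trajectory:
    """Integrate the overdamped Langevin equation with the Euler scheme.

    Each step adds ``A x dt`` plus diagonal Gaussian noise ``F η`` with
    ``η_a ~ N(0, dt)``.  A warning is issued when ``dt`` is large compared
    with the fastest relaxation rate of ``A``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(n_steps)
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (model.n_beads,):
        raise ValueError(f"x0 must have shape ({model.n_beads},)")
    lam = np.max(np.abs(np.linalg.eigvalsh(model.A)))
    if dt * lam >= 0.1:
        warnings.warn(
            f"dt * max|eig(A)| = {dt * lam:.3g} >= 0.1; the Euler scheme "
            "may be inaccurate or unstable", stacklevel=2)

    rng = np.random.default_rng(seed)
    fdiag = np.diag(model.Fnoise).copy()
    out = np.empty((n_steps + 1, model.n_beads))
    # Draw noise in chunks to bound memory for very long runs.
    chunk = min(n_steps, 2_000_000)
    Adt = model.A * dt
    sqdt = np.sqrt(dt)
    pos = 0
    x = x0
    while pos < n_steps:
        m = min(chunk, n_steps - pos)
        noise = rng.standard_normal((m, model.n_beads)) * sqdt
        _euler_loop(x, Adt, fdiag, noise, out[pos:pos + m + 1])
        x = out[pos + m]
        pos += m
    if not np.all(np.isfinite(out)):
        bad = int(np.argmax(~np.all(np.isfinite(out), axis=1)))
        raise FloatingPointError(
            f"integration blew up (non-finite state at step {bad}); reduce dt")
    return Trajectory(dt=dt, positions=out, seed=seed)


def draw_steady_initial(model: BeadSpringModel, seed: int | None = None,
                        size: int | None = None, burn_in: float | None = None,
                        dt: float = 1e-3) -> np.ndarray:
    """Draw initial condition(s) from the stationary state.

    For this linear model the stationary law is the zero-mean Gaussian with
    the Lyapunov covariance, so by default samples are drawn from it
    exactly — equivalent to, but cheaper than, a long burn-in.  Passing
    ``burn_in`` (a time) instead integrates the Langevin dynamics from the
    origin for that long and returns the final state.
    """
    rng = np.random.default_rng(seed)
    if burn_in is not None:
        n_steps = max(int(round(burn_in / dt)), 1)
        traj = euler_maruyama(model, np.zeros(model.n_beads), dt, n_steps,
                              seed=seed)
        x = traj.positions[-1]
        return np.tile(x, (size, 1)) if size is not None else x
    C = stationary_covariance(model)
    L = np.linalg.cholesky(C)
    shape = (size, model.n_beads) if size is not None else (model.n_beads,)
    z = rng.standard_normal(shape)
    return z @ L.T


# ---------------------------------------------------------------------------
# Lattice discretization


@dataclass(frozen=True)
class LatticeSpec:
    """Rectangular lattice: per-axis (lower, upper) bounds and site counts.

    Site centres along axis ``a`` are ``lower_a + (m + 1/2) h_a`` with
    ``h_a = (upper_a - lower_a) / counts_a``.
    """

    bounds: tuple
    counts: tuple

    def __post_init__(self):
        if len(self.bounds) != len(self.counts):
            raise ValueError("bounds and counts must have equal length")
        for (lo, hi), c in zip(self.bounds, self.counts):
            if c < 2:
                raise ValueError("site counts must be at least 2")
            if not hi > lo:
                raise ValueError("bounds must be ordered lower < upper")

    @property
    def n_dim(self) -> int:
        return len(self.counts)

    @property
    def n_sites(self) -> int:
        return int(np.prod(self.counts))

    @property
    def spacings(self) -> np.ndarray:
        return np.array([(hi - lo) / c for (lo, hi), c in
                         zip(self.bounds, self.counts)])

    def axis_centers(self, axis: int) -> np.ndarray:
        lo, hi = self.bounds[axis]
        h = (hi - lo) / self.counts[axis]
        return lo + h * (np.arange(self.counts[axis]) + 0.5)

    def site_positions(self) -> np.ndarray:
        """Positions of all sites, shape (n_sites, n_dim), C-order raveled."""
        axes = [self.axis_centers(a) for a in range(self.n_dim)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=1)


def two_bead_lattice(counts=(200, 200), box_scale: float = 1.0) -> LatticeSpec:
    """Default simulation lattice: x1 in [-50, 50], x2 in [-20, 20].

    ``box_scale`` shrinks the box proportionally — needed for coarse
    grids, where the full box would put drift-dominated (negative-rate)
    sites inside the lattice.
    """
    s = float(box_scale)
    return LatticeSpec(bounds=((-50.0 * s, 50.0 * s), (-20.0 * s, 20.0 * s)),
                       counts=tuple(counts))


def model_lattice(model: BeadSpringModel, counts=(200, 200),
                  n_sigma: float = 4.0) -> LatticeSpec:
    """Lattice box adapted to the model: ±n_sigma stationary std per axis.

    The standard two-bead box (±50, ±20) is about 4σ for the reference
    parameters (T = 250/25); for other temperature ratios the box must
    follow the stationary spread or reflecting walls distort the state.
    """
    C = stationary_covariance(model)
    sig = np.sqrt(np.diag(C))
    bounds = tuple((-n_sigma * s, n_sigma * s) for s in sig)
    return LatticeSpec(bounds=bounds, counts=tuple(counts))


def lattice_edges(model: BeadSpringModel, lattice: LatticeSpec):
    """Directed nearest-neighbour edges and their jump rates.

    Returns ``(src, dst, rate, axis, sign)`` arrays over all admissible
    (in-grid) directed edges.  Rate for a step of ±h_a along axis ``a``
    from a site at ``x`` is ``D_aa / h_a² ± (A x)_a / (2 h_a)``; edges that
    would leave the grid are dropped (reflecting boundary).

    Raises if any rate is negative — the grid is then too wide (drift
    overwhelms diffusion at the boundary) or too coarse.
    """
    if lattice.n_dim != model.n_beads:
        raise ValueError("lattice dimension must match the number of beads")
    pos = lattice.site_positions()
    Ax = pos @ model.A.T
    h = lattice.spacings
    Ddiag = np.diag(model.D)
    counts = lattice.counts
    n_sites = lattice.n_sites
    strides = np.ones(lattice.n_dim, dtype=np.int64)
    for a in range(lattice.n_dim - 2, -1, -1):
        strides[a] = strides[a + 1] * counts[a + 1]
    idx = np.arange(n_sites)
    multi = np.stack(np.unravel_index(idx, counts), axis=1)

    srcs, dsts, rates, axes_, signs = [], [], [], [], []
    for a in range(lattice.n_dim):
        base = Ddiag[a] / h[a] ** 2
        drift = Ax[:, a] / (2.0 * h[a])
        for sgn in (+1, -1):
            rate = base + sgn * drift
            ok = (multi[:, a] + sgn >= 0) & (multi[:, a] + sgn < counts[a])
            neg = ok & (rate < 0)
            if np.any(neg):
                bad = pos[np.argmax(neg)]
                raise ValueError(
                    "negative jump rate at site "
                    f"{bad}: grid too wide or too coarse for this model")
            srcs.append(idx[ok])
            dsts.append(idx[ok] + sgn * strides[a])
            rates.append(rate[ok])
            axes_.append(np.full(ok.sum(), a, dtype=np.int8))
            signs.append(np.full(ok.sum(), sgn, dtype=np.int8))
    return (np.concatenate(srcs), np.concatenate(dsts),
            np.concatenate(rates), np.concatenate(axes_), np.concatenate(signs))


def jump_rates(model: BeadSpringModel, lattice: LatticeSpec) -> sparse.csc_matrix:
    """Generator matrix W of the lattice jump process (columns sum to 0).

    ``W[y, x]`` is the rate of jumping from site ``x`` to neighbouring site
    ``y``; the diagonal holds minus the total exit rates.
    """
    src, dst, rate, _, _ = lattice_edges(model, lattice)
    n = lattice.n_sites
    W = sparse.coo_matrix((rate, (dst, src)), shape=(n, n)).tocsc()
    exit_rates = np.asarray(W.sum(axis=0)).ravel()
    W = W - sparse.diags(exit_rates)
    return W.tocsc()


@dataclass
class JumpTrajectory:
    """Continuous-time path on the lattice: visited sites and jump times.

    ``sites[0]`` is occupied on ``[0, times[0])``, ``sites[i]`` on
    ``[times[i-1], times[i])``; the last site is occupied until ``tau_obs``.
    """

    sites: np.ndarray
    times: np.ndarray
    tau_obs: float
    lattice: LatticeSpec | None = None
    seed: int | None = None

    def __post_init__(self):
        self.sites = np.asarray(self.sites, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.sites) - 1:
            raise ValueError("need exactly one jump time per transition")
        if len(self.times) and (np.any(np.diff(self.times) <= 0)
                                or self.times[0] < 0
                                or self.times[-1] > self.tau_obs):
            raise ValueError("jump times must be increasing within [0, tau_obs]")


@njit(cache=False)
def _gillespie_loop(start, tau_obs, nbr, rts, total, u_site, u_time,
                    sites_out, times_out):  # pragma: no cover - jitted
    site = start
    t = 0.0
    n_jumps = 0
    cap = times_out.shape[0]
    finished = False
    for i in range(u_site.shape[0]):
        r = total[site]
        if r <= 0.0:  # absorbing site: occupied until tau_obs
            finished = True
            break
        t += -np.log(u_time[i]) / r
        if t >= tau_obs:
            finished = True
            break
        u = u_site[i] * r
        acc = 0.0
        nxt = site
        for m in range(nbr.shape[0]):
            acc += rts[m, site]
            if u < acc:
                nxt = nbr[m, site]
                break
        site = nxt
        sites_out[n_jumps + 1] = site
        times_out[n_jumps] = t
        n_jumps += 1
        if n_jumps >= cap:
            break
    return n_jumps, finished


def _neighbor_table(W: sparse.spmatrix):
    """Per-site neighbour/rate table (max degree rows) from a generator."""
    W = W.tocsc()
    n = W.shape[0]
    indptr, indices, data = W.indptr, W.indices, W.data
    deg = np.zeros(n, dtype=np.int64)
    for j in range(n):
        deg[j] = np.sum(indices[indptr[j]:indptr[j + 1]] != j)
    maxdeg = int(deg.max())
    nbr = np.zeros((maxdeg, n), dtype=np.int64)
    rts = np.zeros((maxdeg, n), dtype=float)
    for j in range(n):
        m = 0
        for p in range(indptr[j], indptr[j + 1]):
            i = indices[p]
            if i != j and data[p] > 0:
                nbr[m, j] = i
                rts[m, j] = data[p]
                m += 1
    total = rts.sum(axis=0)
    return nbr, rts, total


def gillespie(rates: sparse.spmatrix, start_site: int, tau_obs: float,
              seed: int | None = None,
              lattice: LatticeSpec | None = None) -> JumpTrajectory:
    """Exact stochastic simulation of the lattice jump process.

    Waiting times are exponential with the current site's total exit rate;
    the next site is chosen with probability proportional to its rate.
    The path is truncated at ``tau_obs``.
    """
    if tau_obs <= 0:
        raise ValueError("tau_obs must be positive")
    nbr, rts, total = _neighbor_table(rates)
    rng = np.random.default_rng(seed)
    # Expected number of events plus slack; regrow if exceeded.
    sites_chunks, times_chunks = [], []
    site = int(start_site)
    t_done = 0.0
    first = True
    while True:
        mean_rate = max(total[site], float(np.mean(total)))
        est = int(mean_rate * (tau_obs - t_done) * 1.2) + 1000
        u_site = rng.random(est)
        u_time = rng.random(est)
        sites_out = np.empty(est + 1, dtype=np.int64)
        times_out = np.empty(est, dtype=float)
        sites_out[0] = site
        n, finished = _gillespie_loop(site, tau_obs - t_done, nbr, rts, total,
                                      u_site, u_time, sites_out, times_out)
        keep_sites = sites_out[:n + 1] if first else sites_out[1:n + 1]
        sites_chunks.append(keep_sites.copy())
        times_chunks.append(times_out[:n] + t_done)
        first = False
        site = int(sites_out[n])
        if finished:
            break
        # restart the clock at the last jump (memoryless waiting times)
        t_done = times_out[n - 1] + t_done
    sites = np.concatenate(sites_chunks)
    times = np.concatenate(times_chunks) if times_chunks else np.empty(0)
    return JumpTrajectory(sites=sites, times=times, tau_obs=float(tau_obs),
                          lattice=lattice, seed=seed)
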