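"""Langevin and lattice-jump samplers: arithmetic, moments, stationarity."""

import dataclasses

import numpy as np
import pytest
from scipy import sparse

import eprtools as ep
from eprtools.ldt import _max_eig
from eprtools.simulate import model_lattice


class TestEulerMaruyama:
    def test_deterministic_step_arithmetic(self, ref_model):
        noiseless = dataclasses.replace(ref_model, Fnoise=np.zeros((2, 2)))
        traj = ep.euler_maruyama(noiseless, np.array([1.0, 0.0]), 1e-3, 1,
                                 seed=0)
        np.testing.assert_allclose(traj.positions[1], [1 - 0.002, 0.001],
                                   rtol=1e-14)

    def test_seed_reproducibility(self, ref_model):
        a = ep.euler_maruyama(ref_model, np.zeros(2), 1e-3, 2000, seed=5)
        b = ep.euler_maruyama(ref_model, np.zeros(2), 1e-3, 2000, seed=5)
        c = ep.euler_maruyama(ref_model, np.zeros(2), 1e-3, 2000, seed=6)
        np.testing.assert_array_equal(a.positions, b.positions)
        assert not np.array_equal(a.positions, c.positions)

    def test_one_step_drift_and_noise_moments(self, ref_model):
        # regressing dx on x recovers A dt; residual covariance is F F^T dt
        traj = ep.euler_maruyama(ref_model, ep.draw_steady_initial(
            ref_model, 1), 1e-3, 200_000, seed=1)
        x, dx = traj.positions[:-1], np.diff(traj.positions, axis=0)
        Ahat_dt, *_ = np.linalg.lstsq(x, dx, rcond=None)
        np.testing.assert_allclose(Ahat_dt.T, ref_model.A * 1e-3,
                                   atol=1.2e-3)
        resid = dx - x @ Ahat_dt
        rc = np.cov(resid.T)
        np.testing.assert_allclose(np.diag(rc),
                                   np.diag(ref_model.Fnoise) ** 2 * 1e-3,
                                   rtol=0.05)
        assert abs(rc[0, 1]) < 3 * np.sqrt(rc[0, 0] * rc[1, 1] / len(resid))

    def test_stationary_covariance_is_preserved(self, driven_traj, ref_model):
        C = ep.stationary_covariance(ref_model)
        sample = np.cov(driven_traj.positions.T)
        # block standard errors: ~tau_obs / tau_rel independent blocks
        assert np.abs(sample - C).max() / np.abs(C).max() < 0.1

    def test_large_dt_warns(self, ref_model):
        with pytest.warns(UserWarning, match="Euler"):
            ep.euler_maruyama(ref_model, np.zeros(2), 0.05, 10, seed=0)

    def test_trajectory_helpers(self, ref_model):
        traj = ep.euler_maruyama(ref_model, np.zeros(2), 1e-3, 100, seed=2)
        assert traj.tau_obs == pytest.approx(0.1)
        np.testing.assert_allclose(
            traj.midpoints(),
            0.5 * (traj.positions[1:] + traj.positions[:-1]))
        rev = traj.reversed()
        np.testing.assert_allclose(rev.displacements(),
                                   -traj.displacements()[::-1])


class TestDrawSteadyInitial:
    def test_moments_match_stationary_gaussian(self, ref_model):
        x = ep.draw_steady_initial(ref_model, seed=3, size=20_000)
        C = ep.stationary_covariance(ref_model)
        se_mean = np.sqrt(np.diag(C) / len(x))
        assert np.all(np.abs(x.mean(axis=0)) < 3 * se_mean)
        np.testing.assert_allclose(np.cov(x.T), C, rtol=0.05)

    def test_reproducible_and_burn_in_variant(self, ref_model):
        a = ep.draw_steady_initial(ref_model, seed=4)
        b = ep.draw_steady_initial(ref_model, seed=4)
        np.testing.assert_array_equal(a, b)
        c = ep.draw_steady_initial(ref_model, seed=4, burn_in=10.0)
        assert c.shape == (2,) and np.all(np.isfinite(c))


class TestJumpRates:
    def test_rate_at_origin_is_purely_diffusive(self, ref_model):
        lat = ep.two_bead_lattice((200, 200))
        src, dst, rate, axis, sign = ep.simulate.lattice_edges(ref_model, lat)
        pos = lat.site_positions()
        h = lat.spacings
        # nearest site to the origin
        i = int(np.argmin(np.einsum("ij,ij->i", pos, pos)))
        x = pos[i]
        D = np.diag(ref_model.D)
        for a in range(2):
            for s in (+1, -1):
                m = (src == i) & (axis == a) & (sign == s)
                expected = D[a] / h[a] ** 2 + s * (ref_model.A @ x)[a] / (2 * h[a])
                assert rate[m][0] == pytest.approx(expected, rel=1e-12)

    def test_methods_grid_rate_arithmetic(self, ref_model):
        # step toward +x1 from (1, 0) on the 200x200 box: 250/0.25 - 2/1 = 998
        lat = ep.two_bead_lattice((200, 200))
        src, dst, rate, axis, sign = ep.simulate.lattice_edges(ref_model, lat)
        pos = lat.site_positions()
        i = int(np.argmin(np.einsum("ij,ij->i", pos - np.array([1.0, 0.0]),
                                    pos - np.array([1.0, 0.0]))))
        m = (src == i) & (axis == 0) & (sign == 1)
        x = pos[i]
        expected = 250.0 / 0.25 + (-2 * x[0] + x[1]) / (2 * 0.5)
        assert rate[m][0] == pytest.approx(expected, rel=1e-12)
        # at the exact printed point the rate is 998
        assert 250.0 / 0.25 + (-2 * 1.0 + 0.0) / (2 * 0.5) == 998.0

    def test_columns_sum_to_zero(self, ref_model, small_lattice):
        W = ep.jump_rates(ref_model, small_lattice)
        colsums = np.asarray(W.sum(axis=0)).ravel()
        assert np.abs(colsums).max() < 1e-10
        offdiag = W - sparse.diags(W.diagonal())
        assert offdiag.min() >= 0

    def test_coarse_wide_grid_raises(self, ref_model):
        # full box at 40x40: drift overwhelms diffusion near the corners
        with pytest.raises(ValueError, match="grid"):
            ep.jump_rates(ref_model, ep.two_bead_lattice((40, 40)))

    def test_stationary_vector_approaches_gaussian(self, ref_model):
        st = ref_model.steady_state()
        tvs = []
        for counts in ((100, 100), (200, 200)):
            lat = model_lattice(ref_model, counts)
            W = ep.jump_rates(ref_model, lat)
            _, v = _max_eig(W.tocsc(), sigma=0.5)
            pi = np.abs(v) / np.abs(v).sum()
            rho = st.density(lat.site_positions())
            rho = rho / rho.sum()
            tvs.append(0.5 * np.abs(pi - rho).sum())
        assert tvs[1] < tvs[0] < 0.05


class TestGillespie:
    def test_two_state_occupation_closed_form(self):
        a, b = 2.0, 3.0
        W = sparse.csc_matrix(np.array([[-a, b], [a, -b]]))
        jt = ep.gillespie(W, 0, tau_obs=2000.0, seed=9)
        times = np.concatenate([[0.0], jt.times, [jt.tau_obs]])
        dwell = np.diff(times)
        t0 = dwell[jt.sites == 0].sum() / jt.tau_obs
        # time fraction in site 0 is b/(a+b); SE from switching count
        se = 1.0 / np.sqrt(len(jt.times))
        assert abs(t0 - b / (a + b)) < 3 * se

    def test_reproducible_under_seed(self, ref_model, small_lattice):
        W = ep.jump_rates(ref_model, small_lattice)
        j1 = ep.gillespie(W, 820, tau_obs=5.0, seed=11)
        j2 = ep.gillespie(W, 820, tau_obs=5.0, seed=11)
        np.testing.assert_array_equal(j1.sites, j2.sites)
        np.testing.assert_array_equal(j1.times, j2.times)

    def test_jumps_connect_lattice_neighbors(self, ref_model, small_lattice):
        W = ep.jump_rates(ref_model, small_lattice)
        jt = ep.gillespie(W, 820, tau_obs=2.0, seed=12, lattice=small_lattice)
        steps = np.abs(np.diff(jt.sites))
        counts = small_lattice.counts
        assert set(np.unique(steps)).issubset({1, counts[1]})

    def test_equilibrium_occupation_matches_boltzmann(self, eq_model):
        lat = model_lattice(eq_model, (40, 40))
        W = ep.jump_rates(eq_model, lat)
        jt = ep.gillespie(W, lat.n_sites // 2, tau_obs=500.0, seed=13)
        occ = np.zeros(lat.n_sites)
        times = np.concatenate([[0.0], jt.times, [jt.tau_obs]])
        np.add.at(occ, jt.sites, np.diff(times))
        occ /= occ.sum()
        rho = eq_model.steady_state().density(lat.site_positions())
        rho /= rho.sum()
        assert 0.5 * np.abs(occ - rho).sum() < 0.15
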