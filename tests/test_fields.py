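"""Kernel/histogram estimation of density, current and force fields."""

import numpy as np
import pytest

import eprtools as ep
from eprtools.fields import (FieldOnGrid, KernelForceField, bandwidth_factor,
                             two_bead_grid)


class TestBandwidthRule:
    def test_rule_of_thumb_arithmetic(self):
        # N = 1000, d = 2, unit robust scale: (0.001)^(1/6)/0.6745
        assert bandwidth_factor(1000, 2) / 0.6745 == pytest.approx(
            0.4688, abs=5e-4)

    def test_shrinks_at_the_dimensional_rate(self):
        r = bandwidth_factor(10_000, 2) / bandwidth_factor(1000, 2)
        assert r == pytest.approx(10 ** (-1 / 6), rel=1e-12)

    @pytest.mark.parametrize("method", ["paper", "position_mad"])
    def test_scale_equivariance(self, method, driven_traj):
        short = ep.Trajectory(dt=driven_traj.dt,
                              positions=driven_traj.positions[:5000])
        doubled = ep.Trajectory(dt=short.dt, positions=2 * short.positions)
        np.testing.assert_allclose(
            ep.bandwidth_rule(doubled, method),
            2 * ep.bandwidth_rule(short, method), rtol=1e-10)

    def test_degenerate_coordinate_raises(self):
        pos = np.zeros((100, 2))
        pos[:, 0] = np.linspace(0, 1, 100)
        traj = ep.Trajectory(dt=0.1, positions=pos)
        with pytest.raises(ValueError, match="degenerate"):
            ep.bandwidth_rule(traj, "position_mad")


class TestDensity:
    def test_repeated_point_occupies_one_bin(self):
        pos = np.tile([3.3, -2.2], (50, 1))
        traj = ep.Trajectory(dt=0.1, positions=pos)
        grid = two_bead_grid()
        rho = ep.estimate_density(traj, grid)
        nz = np.nonzero(rho.values)
        assert len(nz[0]) == 1
        assert rho.values.sum() * grid.bin_volume == pytest.approx(1.0)

    def test_histogram_mass_sums_to_one(self, driven_traj):
        # on a grid wide enough to contain every sample the mass is exact
        grid = ep.GridSpec(bounds=((-500.0, 500.0), (-200.0, 200.0)),
                           counts=(100, 100))
        rho = ep.estimate_density(driven_traj, grid)
        assert rho.values.sum() * grid.bin_volume == pytest.approx(
            1.0, abs=1e-12)
        # on the standard box, mass equals the in-box fraction of samples
        grid2 = two_bead_grid()
        rho2 = ep.estimate_density(driven_traj, grid2)
        _, inside = grid2.bin_indices(driven_traj.positions)
        assert rho2.values.sum() * grid2.bin_volume == pytest.approx(
            inside.mean(), abs=1e-12)

    def test_gaussian_kernel_mass_nearly_one(self, driven_traj):
        cfg = ep.KernelConfig(density_kernel="gaussian", bandwidth=[2.0, 1.0])
        rho = ep.estimate_density(driven_traj, two_bead_grid(), cfg)
        assert rho.values.sum() * rho.grid.bin_volume == pytest.approx(
            1.0, abs=1e-2)
        assert rho.values.min() >= 0

    def test_sup_error_decreases_with_observation_time(self, eq_model):
        grid = two_bead_grid(counts=(50, 50))
        st = eq_model.steady_state()
        rho_true = st.density(grid.site_positions()).reshape(grid.counts)
        errs = []
        for n in (20_000, 400_000):
            traj = ep.euler_maruyama(eq_model,
                                     ep.draw_steady_initial(eq_model, 21),
                                     1e-2, n, seed=21)
            rho = ep.estimate_density(traj, grid)
            errs.append(np.abs(rho.values - rho_true).max())
        assert errs[1] < errs[0]

    def test_all_samples_outside_grid_raise(self):
        pos = np.tile([500.0, 500.0], (10, 1))
        traj = ep.Trajectory(dt=0.1, positions=pos)
        with pytest.raises(ValueError, match="outside"):
            ep.estimate_density(traj, two_bead_grid())


class TestCurrent:
    def test_time_reversal_flips_current(self, driven_traj):
        grid = two_bead_grid(counts=(50, 50))
        short = ep.Trajectory(dt=driven_traj.dt,
                              positions=driven_traj.positions[:200_001])
        j_fwd = ep.estimate_current(short, grid)
        j_rev = ep.estimate_current(short.reversed(), grid)
        np.testing.assert_allclose(j_rev.values, -j_fwd.values, atol=1e-12)

    def test_driven_current_aligns_with_analytic(self, driven_traj,
                                                 ref_state):
        grid = two_bead_grid()
        cfg = ep.KernelConfig(density_kernel="gaussian",
                              current_kernel="epanechnikov",
                              bandwidth=[3.0, 2.0])
        jhat = ep.estimate_current(driven_traj, grid, cfg)
        j_true = ref_state.current(grid.site_positions()).reshape(
            grid.counts + (2,))
        rho_true = ref_state.density(grid.site_positions()).reshape(grid.counts)
        hi = rho_true > 0.2 * rho_true.max()
        cos = (np.einsum("ki,ki->", jhat.values[hi], j_true[hi])
               / np.linalg.norm(jhat.values[hi])
               / np.linalg.norm(j_true[hi]))
        assert cos > 0.5

    def test_equilibrium_current_consistent_with_zero(self, eq_traj):
        # segment-replicate SEs: per-bin current means should sit within
        # noise of zero almost everywhere under detailed balance
        grid = two_bead_grid(counts=(30, 30))
        n_seg = 10
        seg_len = (len(eq_traj.positions) - 1) // n_seg
        fields = []
        for s in range(n_seg):
            seg = ep.Trajectory(dt=eq_traj.dt,
                                positions=eq_traj.positions[
                                    s * seg_len: (s + 1) * seg_len + 1])
            fields.append(ep.estimate_current(seg, grid).values)
        stack = np.stack(fields)
        mean = stack.mean(axis=0)
        se = stack.std(axis=0, ddof=1) / np.sqrt(n_seg)
        visited = se > 0
        exceed = np.abs(mean[visited]) > 3 * se[visited]
        assert exceed.mean() < 0.02


class TestForce:
    def test_plug_in_of_analytic_fields_recovers_force(self, ref_state,
                                                       ref_model):
        grid = two_bead_grid()
        pos = grid.site_positions()
        rho = FieldOnGrid(grid, ref_state.density(pos).reshape(grid.counts),
                          "density")
        cur = FieldOnGrid(grid, ref_state.current(pos).reshape(
            grid.counts + (2,)), "current")
        F = ep.estimate_force(rho, cur, ref_model)
        F_true = ref_state.thermodynamic_force(pos).reshape(grid.counts + (2,))
        sel = F.estimated
        np.testing.assert_allclose(F.values[sel], F_true[sel], rtol=1e-8)

    def test_force_scales_linearly_with_current(self, ref_state, ref_model):
        grid = two_bead_grid(counts=(20, 20))
        pos = grid.site_positions()
        rho = FieldOnGrid(grid, ref_state.density(pos).reshape(grid.counts),
                          "density")
        cur = FieldOnGrid(grid, ref_state.current(pos).reshape(
            grid.counts + (2,)), "current")
        cur3 = FieldOnGrid(grid, 3.0 * cur.values, "current")
        F1 = ep.estimate_force(rho, cur, ref_model)
        F3 = ep.estimate_force(rho, cur3, ref_model)
        np.testing.assert_allclose(F3.values, 3 * F1.values, rtol=1e-10)

    def test_sparse_bins_are_flagged_unestimated(self, driven_traj,
                                                 ref_model):
        grid = two_bead_grid()
        rho = ep.estimate_density(driven_traj, grid)
        cur = ep.estimate_current(driven_traj, grid)
        F = ep.estimate_force(rho, cur, ref_model, min_count=5)
        assert F.estimated is not None
        assert np.all(F.values[~F.estimated] == 0)
        # corner bins far outside the distribution cannot be estimated
        assert not F.estimated[0, 0]

    def test_nearest_bin_lookup_outside_returns_fill(self, driven_traj,
                                                     ref_model):
        grid = two_bead_grid()
        rho = ep.estimate_density(driven_traj, grid)
        cur = ep.estimate_current(driven_traj, grid)
        F = ep.estimate_force(rho, cur, ref_model)
        vals, ok = F.at(np.array([[0.0, 0.0], [500.0, 0.0]]))
        assert ok[0] and not ok[1]
        assert np.all(vals[1] == 0)


class TestKernelForceField:
    def test_matches_analytic_force_in_bulk(self, driven_traj, ref_model,
                                            ref_state):
        kf = KernelForceField(driven_traj, ref_model, bandwidth=[3.0, 2.0],
                              max_train=50_000)
        # probe the well-sampled core of the distribution
        pts = 0.7 * ep.draw_steady_initial(ref_model, 2, size=200)
        F_est = kf(pts)
        F_true = ref_state.thermodynamic_force(pts)
        cos = (np.einsum("ij,ij->", F_est, F_true)
               / np.linalg.norm(F_est) / np.linalg.norm(F_true))
        assert cos > 0.6

    def test_empty_neighborhood_returns_zero(self, driven_traj, ref_model):
        kf = KernelForceField(driven_traj, ref_model, bandwidth=[1.0, 1.0])
        assert np.all(kf(np.array([400.0, 400.0])) == 0)
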