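"""Tilted-operator cumulants: oracles, convexity, TUR inequality."""

import numpy as np
import pytest
from scipy import sparse

import eprtools as ep
from eprtools.ldt import (LatticeCumulants, exact_cumulants, exact_tur_ratio,
                          scgf, tilted_matrix)
from eprtools.simulate import model_lattice


@pytest.fixture(scope="module")
def two_site():
    a, b = 2.0, 3.0
    W = sparse.csc_matrix(np.array([[-a, b], [a, -b]]))
    d = sparse.csc_matrix(np.array([[0.0, 0.3], [1.0, 0.0]]))
    return a, b, W, d


@pytest.fixture(scope="module")
def three_cycle():
    # uniform driven cycle with forward rate 2, backward 0.5
    k1, k2 = 2.0, 0.5
    W = np.full((3, 3), 0.0)
    d = np.zeros((3, 3))
    for i in range(3):
        W[(i + 1) % 3, i] = k1
        W[i, (i + 1) % 3] = k2
        W[i, i] = -(k1 + k2)
        d[(i + 1) % 3, i] = 1.0
        d[i, (i + 1) % 3] = -1.0
    return k1, k2, sparse.csc_matrix(W), sparse.csc_matrix(d)


class TestTiltedMatrix:
    def test_zero_tilt_is_identity_operation(self, two_site):
        _, _, W, d = two_site
        np.testing.assert_allclose(tilted_matrix(W, d, 0.0).toarray(),
                                   W.toarray())

    def test_zero_weights_never_tilt(self, two_site):
        _, _, W, _ = two_site
        d0 = sparse.csc_matrix((2, 2))
        for lam in (-1.0, 0.3, 2.0):
            np.testing.assert_allclose(tilted_matrix(W, d0, lam).toarray(),
                                       W.toarray())

    def test_diagonal_is_untouched(self, two_site):
        _, _, W, d = two_site
        M = tilted_matrix(W, d, 0.7)
        np.testing.assert_allclose(M.diagonal(), W.diagonal())


class TestSCGF:
    def test_two_site_closed_form(self, two_site):
        a, b, W, d = two_site
        for lam in (-0.5, 0.2, 0.8):
            # char. poly: x^2 + (a+b) x + ab(1 - e^{lam (d12+d21)}) = 0
            roots = np.roots([1.0, a + b, a * b * (1 - np.exp(lam * 1.3))])
            assert scgf(W, d, lam) == pytest.approx(max(roots.real),
                                                    rel=1e-12)

    def test_vanishes_at_zero(self, ref_model, small_lattice):
        lc = LatticeCumulants(ref_model, small_lattice)
        st = ref_model.steady_state()
        w = ep.edge_weights_from_field(st, ref_model, small_lattice,
                                       edges=lc.edges)
        assert abs(lc.cumulants(w).phi0) < 1e-8

    def test_detailed_balance_symmetry_exact_reversible_chain(self):
        # phi(l) = phi(-l) for reversible dynamics with antisymmetric d:
        # build an exactly reversible chain from symmetric conductances
        rng = np.random.default_rng(5)
        n = 8
        pi = rng.uniform(0.5, 2.0, n)
        g = np.triu(rng.uniform(0.1, 1.0, (n, n)), 1)
        g = g + g.T
        W = g / pi[None, :]
        np.fill_diagonal(W, 0.0)
        np.fill_diagonal(W, -W.sum(axis=0))
        d = np.triu(rng.normal(size=(n, n)), 1)
        d = d - d.T
        Ws, ds = sparse.csc_matrix(W), sparse.csc_matrix(d)
        for lam in (0.05, 0.2):
            assert scgf(Ws, ds, lam) == pytest.approx(scgf(Ws, ds, -lam),
                                                      rel=1e-10)

    def test_equilibrium_lattice_symmetry_approximate(self, eq_model):
        # the lattice discretization is reversible only as h -> 0
        lat = model_lattice(eq_model, (40, 40))
        lc = LatticeCumulants(eq_model, lat)
        fld = ep.init_field("random", eq_model, lat, M=10, seed=0)
        w = ep.edge_weights_from_field(fld, eq_model, lat, edges=lc.edges)
        pp = lc._phi(w, 0.05)
        pm = lc._phi(w, -0.05)
        assert pp > 0  # a non-gradient weighting accumulates fluctuations
        assert pp == pytest.approx(pm, rel=0.05)

    def test_convex_on_stencil(self, three_cycle):
        _, _, W, d = three_cycle
        lams = np.array([-0.2, -0.1, 0.0, 0.1, 0.2])
        phis = np.array([scgf(W, d, l) for l in lams])
        assert np.all(np.diff(phis, 2) > -1e-12)


class TestExactCumulants:
    def test_zero_weights_give_zero_cumulants(self, three_cycle):
        _, _, W, _ = three_cycle
        d0 = sparse.csc_matrix((3, 3))
        res = exact_cumulants(W, d0)
        assert res.mean == pytest.approx(0.0, abs=1e-10)
        assert res.scaled_var == pytest.approx(0.0, abs=1e-8)

    def test_cycle_current_closed_forms(self, three_cycle):
        k1, k2, W, d = three_cycle
        res = exact_cumulants(W, d, dlam=1e-6, dlam_var=1e-3)
        assert res.mean == pytest.approx(k1 - k2, rel=1e-7)
        assert res.scaled_var == pytest.approx(k1 + k2, rel=1e-5)
        # TUR: 2(k1-k2)^2/(k1+k2) <= (k1-k2) ln(k1/k2) = cycle EPR
        ratio = exact_tur_ratio(W, d)
        assert ratio == pytest.approx(2 * (k1 - k2) ** 2 / (k1 + k2),
                                      rel=1e-3)
        assert ratio <= (k1 - k2) * np.log(k1 / k2) + 1e-9

    def test_lattice_mean_converges_to_epr_under_refinement(self, ref_model,
                                                            ref_state):
        # joint refinement: spacing h -> 0 and box -> infinity.  At fixed
        # box the error floor is set by the reflecting-wall truncation,
        # so both must be refined for phi'(0) to approach the EPR.
        errs = []
        for counts, nsig in (((100, 100), 4.0), ((200, 200), 5.0),
                             ((300, 300), 6.0)):
            lat = model_lattice(ref_model, counts, n_sigma=nsig)
            lc = LatticeCumulants(ref_model, lat)
            w = ep.edge_weights_from_field(ref_state, ref_model, lat,
                                           edges=lc.edges)
            errs.append(abs(lc.cumulants(w).mean - ref_state.epr))
        assert errs[2] < errs[1] < errs[0]
        assert errs[2] / ref_state.epr < 0.02

    def test_tur_inequality_for_random_fields(self, ref_model, ref_state,
                                              small_lattice):
        lc = LatticeCumulants(ref_model, small_lattice)
        for seed in range(3):
            fld = ep.init_field("random", ref_model, small_lattice, M=20,
                                seed=seed)
            w = ep.edge_weights_from_field(fld, ref_model, small_lattice,
                                           edges=lc.edges)
            assert lc.tur_ratio(w) <= ref_state.epr * (1 + 1e-6)


class TestEta:
    def test_restricted_to_two_beads(self):
        m = ep.build_chain(5, 1.0, 1.0, endpoints=(25.0, 250.0))
        with pytest.raises(ValueError, match="two beads"):
            ep.eta(m, ep.two_bead_lattice((20, 20), box_scale=0.5))

    def test_equilibrium_ratio_is_zero(self, eq_model):
        # mean current vanishes under detailed balance -> zero TUR ratio
        lat = model_lattice(eq_model, (40, 40))
        lc = LatticeCumulants(eq_model, lat)
        fld = ep.init_field("random", eq_model, lat, M=10, seed=1)
        w = ep.edge_weights_from_field(fld, eq_model, lat, edges=lc.edges)
        # the coarse discretization carries O(h^2) residual irreversibility
        assert lc.tur_ratio(w) == pytest.approx(0.0, abs=1e-4)
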