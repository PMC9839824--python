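import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import kmreduce as km
from kmreduce.psi import psi_quadrature

W_GRID = np.linspace(0.0, 10.0, 101)


def all_builders():
    return {
        "homogeneous": km.psi_homogeneous(1000.0),
        "discrete": km.psi_discrete(1000.0, [(0.5, 1.0, 1.0), (0.5, 0.5, 2.0)]),
        "gamma_const": km.psi_gamma(1000.0, p=2.0, c_mode="constant_one"),
        "gamma_prop": km.psi_gamma(1000.0, p=2.0, c_mode="proportional_to_trait"),
        "quadrature": psi_quadrature(1000.0, km.gamma_trait(2.0)),
    }


class TestPsiHomogeneous:
    def test_zero_at_zero(self):
        assert km.psi_homogeneous(100.0)(0.0) == 0.0

    def test_initial_slope_is_N(self):
        assert km.psi_homogeneous(1000.0).prime(0.0) == pytest.approx(1000.0)

    def test_value_at_one(self):
        # 1000 (1 - e^{-1})
        assert km.psi_homogeneous(1000.0)(1.0) == pytest.approx(
            1000.0 * (1.0 - math.exp(-1.0)), rel=1e-14)

    def test_rejects_nonpositive_N(self):
        with pytest.raises(ValueError):
            km.psi_homogeneous(0.0)


class TestPsiDiscrete:
    def test_single_atom_is_homogeneous(self):
        hom = km.psi_homogeneous(1000.0)
        one = km.psi_discrete(1000.0, [(1.0, 1.0, 1.0)])
        for w in (0.0, 0.5, 2.0):
            assert one(w) == pytest.approx(hom(w), rel=1e-14)

    def test_two_group_immunity_value(self):
        # N1 (1 - e^{-w}) + N2 eps2 (1 - e^{-eps1 w}) at w = 1
        psi = km.psi_discrete(1000.0, [(0.5, 1.0, 1.0), (0.5, 0.5, 2.0)])
        expected = 500.0 * (1.0 - math.exp(-1.0)) + 1000.0 * (1.0 - math.exp(-0.5))
        assert psi(1.0) == pytest.approx(expected, rel=1e-14)

    def test_two_group_initial_slope(self):
        # Psi'(0) = N1 + N2 eps1 eps2
        psi = km.psi_discrete(1000.0, [(0.5, 1.0, 1.0), (0.5, 0.5, 2.0)])
        assert psi.prime(0.0) == pytest.approx(500.0 + 500.0 * 0.5 * 2.0, rel=1e-14)

    def test_unnormalised_weights_rejected(self):
        with pytest.raises(ValueError):
            km.psi_discrete(1.0, [(0.6, 1.0, 1.0), (0.5, 1.0, 1.0)])


class TestPsiGamma:
    def test_p1_constant_value(self):
        # N = 1, p = 1: Psi(1) = 1 - (1 + 1)^{-1} = 0.5
        assert km.psi_gamma(1.0, 1.0, "constant_one")(1.0) == pytest.approx(0.5)

    def test_large_p_approaches_homogeneous(self):
        psi = km.psi_gamma(1.0, 1e6, "constant_one")
        hom = km.psi_homogeneous(1.0)
        for w in (0.5, 1.0, 2.0):
            assert abs(psi(w) - hom(w)) < 1e-4

    def test_saturation_is_N_in_both_modes(self):
        for mode in ("constant_one", "proportional_to_trait"):
            assert km.psi_gamma(7.0, 2.0, mode).saturation == 7.0

    def test_rejects_nonpositive_p(self):
        with pytest.raises(ValueError):
            km.psi_gamma(1.0, 0.0)


class TestGammaLaplace:
    def test_at_zero(self):
        assert km.gamma_laplace(3.0, 0.0) == 1.0

    def test_p1_lambda1(self):
        assert km.gamma_laplace(1.0, 1.0) == 0.5

    def test_matches_density_quadrature(self):
        p = 2.0
        dens = km.gamma_trait(p).density
        val, _ = quad(lambda x: math.exp(-x) * dens(x), 0, np.inf)
        assert km.gamma_laplace(p, 1.0) == pytest.approx(val, abs=1e-8)


class TestPsiQuadrature:
    def test_trivial_maps_match_homogeneous(self):
        trait = km.TraitModel(a=lambda x: 1.0, c=lambda x: 1.0, x_bar=1.0,
                              density=km.gamma_trait(2.0).density)
        psi = psi_quadrature(1000.0, trait)
        hom = km.psi_homogeneous(1000.0)
        for w in (0.1, 1.0, 3.0):
            assert psi(w) == pytest.approx(hom(w), abs=1e-10 * 1000)

    def test_constant_a_averages_c(self):
        # with a = 1, heterogeneous infectiousness reduces to its mean
        trait = km.TraitModel(a=lambda x: 1.0, c=lambda x: x, x_bar=1.0,
                              density=km.gamma_trait(3.0).density)
        psi = psi_quadrature(1.0, trait)
        for w in (0.1, 1.0, 3.0):
            assert psi(w) == pytest.approx(1.0 - math.exp(-w), abs=1e-8)

    def test_matches_gamma_closed_form(self):
        psi_q = psi_quadrature(1.0, km.gamma_trait(2.0))
        psi_cf = km.psi_gamma(1.0, 2.0, "constant_one")
        assert psi_q(1.5) == pytest.approx(psi_cf(1.5), abs=1e-8)

    def test_discrete_trait_reduces_exactly(self):
        trait = km.discrete_trait([(1.0, 0.5), (2.0, 0.5)], a=[1.0, 0.5],
                                  c=[1.0, 2.0], x_bar=1.0)
        psi_q = psi_quadrature(10.0, trait)
        psi_d = km.psi_discrete(10.0, [(0.5, 1.0, 1.0), (0.5, 0.5, 2.0)])
        for w in (0.0, 0.7, 4.0):
            assert psi_q(w) == psi_d(w)

    def test_bad_density_fails_self_check(self):
        trait = km.TraitModel(a=lambda x: x, c=lambda x: 1.0, x_bar=2.0,
                              density=lambda x: 2.0 * km.gamma_trait(1.0).density(x))
        with pytest.raises(ValueError, match="self-check"):
            psi_quadrature(1.0, trait)


class TestPsiProperties:
    @pytest.mark.parametrize("name,psi", all_builders().items())
    def test_concave_nondecreasing_bounded(self, name, psi):
        vals = np.asarray(psi(W_GRID))
        assert vals[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(vals) >= -1e-10)
        assert np.all(np.diff(vals, 2) <= 1e-10)  # concavity
        assert np.all(vals <= psi.saturation * (1 + 1e-12))

    @pytest.mark.parametrize("name,psi", all_builders().items())
    def test_derivative_matches_finite_difference(self, name, psi):
        h = 1e-6
        for w in (0.1, 1.0, 5.0):
            fd = (psi(w + h) - psi(w - h)) / (2 * h)
            assert float(psi.prime(w)) == pytest.approx(fd, rel=1e-6)

    @pytest.mark.parametrize("name,psi", [
        (k, v) for k, v in all_builders().items() if k != "discrete"
    ])
    def test_saturation_reached(self, name, psi):
        # builders here have min a >= 0.5 on the support... gamma a(x) = x
        # has small-a mass, so allow its slower approach via larger w
        w_probe = 50.0 if name == "homogeneous" else 1e6
        assert float(psi(w_probe)) == pytest.approx(
            psi.saturation, rel=1e-6 if name == "homogeneous" else 1e-2)

    @settings(max_examples=50, derandomize=True)
    @given(p=st.floats(0.3, 10.0), w=st.floats(0.0, 20.0))
    def test_gamma_laplace_in_unit_interval(self, p, w):
        val = km.gamma_laplace(p, w)
        assert 0.0 < val <= 1.0

    @settings(max_examples=30, derandomize=True)
    @given(w1=st.floats(0.0, 8.0), w2=st.floats(0.0, 8.0))
    def test_gamma_psi_monotone(self, w1, w2):
        psi = km.psi_gamma(1.0, 1.5, "constant_one")
        lo, hi = sorted((w1, w2))
        assert psi(lo) <= psi(hi) + 1e-12


def test_gamma_quadrature_agreement_grid():
    # closed form vs quadrature within 1e-8 absolute at N = 1
    for p in (0.5, 1.0, 2.0, 5.0):
        for mode in ("constant_one", "proportional_to_trait"):
            cf = km.psi_gamma(1.0, p, mode)
            q = psi_quadrature(1.0, km.gamma_trait(p, mode))
            assert np.max(np.abs(np.asarray(cf(W_GRID)) - np.asarray(q(W_GRID)))) < 1e-8
            assert np.max(np.abs(np.asarray(cf.prime(W_GRID))
                                 - np.asarray(q.prime(W_GRID)))) < 1e-8
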