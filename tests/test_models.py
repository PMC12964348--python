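"""Form-factor evaluators: closed-form limits, oracle parity, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import j1
from scipy.stats import norm

from fibersans import models as md
import _reference as ref


Q_D11 = np.geomspace(0.0013, 0.4102, 120)


class TestPowerLaw:
    def test_closed_form(self):
        assert md.eval_power_law(np.array([0.1]), 1.0, 4.0, 0.0)[0] == \
            pytest.approx(1.0e4, rel=1e-12)

    def test_zero_exponent_is_constant(self):
        out = md.eval_power_law(Q_D11, 2.5, 0.0, 0.5)
        assert np.allclose(out, 3.0)

    def test_zero_scale_is_background(self):
        out = md.eval_power_law(Q_D11, 0.0, 4.0, 0.125)
        assert np.allclose(out, 0.125)


class TestFlexibleCylinder:
    def test_forward_limit_scale_plus_background(self):
        p = md.FlexCylinderPowerlawParams(
            alpha1=2.0, radius_R=16.0, contour_L_C=5000.0, kuhn_b=318.0,
            alpha2=0.0, decay_D=4.0, background_c=0.25)
        out = md.eval_flexible_cylinder(np.array([1e-6]), p)
        assert out[0] == pytest.approx(2.25, rel=1e-4)

    def test_cross_section_first_zero(self):
        # [2 J1(x)/x]^2 first vanishes at x = 3.8317; with R = 16 A that is
        # q = 0.2395 1/A
        q = np.linspace(0.22, 0.26, 4001)
        vals = md.cross_section_factor(q, 16.0)
        q_zero = q[np.argmin(vals)]
        assert q_zero == pytest.approx(3.8317 / 16.0, abs=2e-4)

    def test_scalar_reference_parity_chitin_parameters(self):
        """Vectorized evaluator vs the independent scalar transcription,
        <=1% everywhere on the D11 window for the fiber parameter set."""
        mine = md.wormlike_chain_factor(Q_D11, 5000.0, 318.0) \
            * md.cross_section_factor(Q_D11, 16.0)
        theirs = np.array([
            ref.flexible_cylinder_reference(float(q), 16.0, 5000.0, 318.0)
            for q in Q_D11])
        assert np.max(np.abs(mine / theirs - 1.0)) < 0.01

    def test_rigid_limit_matches_rod_integral(self):
        # a chain whose Kuhn segment far exceeds its contour is a rod
        L = 1000.0
        q = np.geomspace(1e-4, 19.9 / L, 50)
        mine = md.wormlike_chain_factor(q, L, 10 * L)
        rod = np.array([ref.rod_form_factor(float(x), L) for x in q])
        assert np.max(np.abs(mine / rod - 1.0)) < 0.02

    def test_flexible_limit_matches_debye(self):
        L, b = 1e5, 100.0
        rg2 = md._alpha_sq(L / b) * md._rg2_benoit_doty(L, b)
        q = np.geomspace(1e-5, 0.5 / np.sqrt(rg2), 25)
        mine = md.wormlike_chain_factor(q, L, b)
        debye = md._debye(q * q * rg2)
        assert np.max(np.abs(mine / debye - 1.0)) < 0.01

    def test_continuous_across_internal_branches(self):
        b = 318.0
        q = np.geomspace(1e-3, 0.4, 40)
        for lo, hi in ((2.999, 3.001), (4.999, 5.001)):
            a = md.wormlike_chain_factor(q, lo * b, b)
            c = md.wormlike_chain_factor(q, hi * b, b)
            assert np.max(np.abs(a / c - 1.0)) < 0.02

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(min_value=5.0, max_value=50.0),
           st.floats(min_value=50.0, max_value=1000.0),
           st.floats(min_value=1.0, max_value=50.0))
    def test_finite_nonnegative(self, radius, kuhn, n_segments):
        p = md.FlexCylinderPowerlawParams(
            alpha1=1.0, radius_R=radius, contour_L_C=n_segments * kuhn,
            kuhn_b=kuhn, alpha2=1e-10, decay_D=4.0, background_c=0.0)
        q = np.geomspace(1e-5, 1.0, 60)
        out = md.eval_flexible_cylinder(q, p)
        assert np.all(np.isfinite(out))
        assert np.all(out >= 0.0)


class TestBeaucage:
    def test_single_level_guinier_limit(self):
        """With B=0 the unified model is exactly Guinier + background."""
        p = md.BeaucageParams(
            levels=(md.BeaucageLevel(G=100.0, Rg=50.0, B=0.0, D=2.0),),
            background_c=0.125)
        q = np.geomspace(1e-4, 0.1, 50)
        expected = 100.0 * np.exp(-(q * 50.0) ** 2 / 3.0) + 0.125
        assert np.allclose(md.eval_beaucage(q, p), expected, rtol=1e-14)
        assert md.eval_beaucage(np.array([0.0]), p)[0] == pytest.approx(
            100.125, rel=1e-14)

    def test_high_q_pure_power_law_limit(self):
        """At q Rg >> 1 the erf crossover saturates: I -> B q^-D + c."""
        p = md.BeaucageParams(
            levels=(md.BeaucageLevel(G=100.0, Rg=50.0, B=1e-4, D=2.6),),
            background_c=0.01)
        q = np.geomspace(1.0, 5.0, 20) / 5.0  # q Rg in [10, 50]
        expected = 1e-4 * q ** (-2.6) + 0.01
        assert np.allclose(md.eval_beaucage(q, p), expected, rtol=1e-12)

    def test_low_q_power_term_vanishes(self):
        p = md.BeaucageParams(
            levels=(md.BeaucageLevel(G=0.0, Rg=100.0, B=1.0, D=3.0),))
        out = md.eval_beaucage(np.geomspace(1e-6, 1e-4, 10), p)
        # erf^3D ~ q^9 beats q^-3: the term must fall to zero, not blow up
        assert np.all(np.isfinite(out))
        assert out[0] < out[-1] < 1e-6

    def test_two_level_mid_slope_matches_second_decay_exponent(self):
        """A two-level curve built from published complex-fit parameters
        shows a log-log slope of -D2 where level 2's power law rules."""
        p = md.BeaucageParams(
            levels=(md.BeaucageLevel(G=1000.0, Rg=1859.0, B=5.5e-6, D=2.64),
                    md.BeaucageLevel(G=5.0, Rg=125.2, B=3.6e-5, D=2.63)),
            background_c=0.0)
        q = np.array([0.15, 0.17])  # q Rg2 ~ 20: deep in level-2 power law
        i = md.eval_beaucage(q, p)
        slope = np.log(i[1] / i[0]) / np.log(q[1] / q[0])
        assert slope == pytest.approx(-2.63, abs=0.02)

    def test_power_term_suppressed_by_next_level_rg(self):
        q = np.geomspace(1e-3, 0.4, 60)
        lv2 = md.BeaucageLevel(G=1.0, Rg=50.0, B=1e-5, D=2.5)
        out = []
        for rg2 in (10.0, 50.0, 120.0):
            p = md.BeaucageParams(levels=(
                md.BeaucageLevel(G=100.0, Rg=500.0, B=1e-4, D=2.5),
                md.BeaucageLevel(G=1.0, Rg=rg2, B=0.0, D=2.5)))
            # level-1 power term only, with increasing cutoff Rg2
            term = md.eval_beaucage(q, p) - (
                100.0 * np.exp(-(q * 500.0) ** 2 / 3.0)
                + 1.0 * np.exp(-(q * rg2) ** 2 / 3.0))
            out.append(term)
        assert np.all(out[1] <= out[0] + 1e-15)
        assert np.all(out[2] <= out[1] + 1e-15)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.5, max_value=4.4),
           st.floats(min_value=10.0, max_value=2000.0))
    def test_finite_nonnegative(self, decay, rg):
        p = md.BeaucageParams(
            levels=(md.BeaucageLevel(G=10.0, Rg=rg, B=1e-5, D=decay),))
        out = md.eval_beaucage(np.geomspace(1e-5, 1.0, 80), p)
        assert np.all(np.isfinite(out))
        assert np.all(out >= 0.0)


class TestEllipsoidChain:
    def test_forward_intensity_is_scale_plus_background(self):
        p = md.EllipsoidChainParams.uniform(5, (30.0, 15.0, 15.0), 40.0,
                                            scale=3.0, background=0.5)
        out = md.eval_ellipsoid_chain(np.array([1e-7, 1e-5]), p)
        assert out[0] == pytest.approx(3.5, rel=1e-9)

    def test_single_subunit_is_plain_ellipsoid(self):
        p = md.EllipsoidChainParams.uniform(1, (20.0, 20.0, 20.0), 30.0)
        q = np.geomspace(1e-3, 0.4, 40)
        sphere = np.array([ref.sphere_form_amplitude(float(x), 20.0) ** 2
                           for x in q])
        assert np.allclose(md.eval_ellipsoid_chain(q, p), sphere, rtol=1e-8,
                           atol=1e-12)

    def test_two_spheres_match_interference_formula(self):
        q = np.geomspace(1e-3, 0.4, 60)
        p = md.EllipsoidChainParams.uniform(2, (15.0, 15.0, 15.0), 45.0)
        mine = md.eval_ellipsoid_chain(q, p)
        closed = np.array([ref.two_sphere_intensity(float(x), 15.0, 45.0)
                           for x in q])
        assert np.max(np.abs(mine - closed)) < 1e-3 * closed.max()

    def test_chain_reversal_symmetry(self):
        rng = np.random.default_rng(3)
        axes = tuple(tuple(rng.uniform(10, 40, size=3)) for _ in range(4))
        q = np.geomspace(1e-3, 0.4, 30)
        fwd = md.eval_ellipsoid_chain(
            q, md.EllipsoidChainParams(4, axes, 50.0))
        rev = md.eval_ellipsoid_chain(
            q, md.EllipsoidChainParams(4, axes[::-1], 50.0))
        assert np.allclose(fwd, rev, rtol=1e-12)

    def test_five_subunits_extend_low_q_mass(self):
        # more subunits -> larger apparent size -> faster low-q falloff
        q = np.array([0.02])
        one = md.eval_ellipsoid_chain(
            q, md.EllipsoidChainParams.uniform(1, (20.0, 15.0, 15.0), 35.0))
        five = md.eval_ellipsoid_chain(
            q, md.EllipsoidChainParams.uniform(5, (20.0, 15.0, 15.0), 35.0))
        assert five[0] < one[0]


class TestGaussianSmearing:
    def test_zero_width_identity(self):
        vals = md.eval_power_law(Q_D11, 1e-10, 4.0, 0.01)
        assert np.array_equal(md.smear_gaussian(vals, Q_D11, 0.0), vals)

    def test_constant_unchanged(self):
        vals = np.full_like(Q_D11, 2.5)
        out = md.smear_gaussian(vals, Q_D11, 0.09)
        assert np.allclose(out, 2.5, rtol=1e-10)

    def test_bessel_minimum_filled_in(self):
        q = np.geomspace(0.05, 0.41, 400)
        vals = md.cross_section_factor(q, 16.0)
        out = md.smear_gaussian(vals, q, 0.05)
        i_min = np.argmin(vals)
        assert out[i_min] > vals[i_min]

    def test_matches_direct_convolution(self):
        """Quadrature smearing vs brute-force Gaussian convolution."""
        q = np.geomspace(0.02, 0.41, 300)
        vals = md.cross_section_factor(q, 16.0) + 0.01
        dqq = 0.05
        out = md.smear_gaussian(vals, q, dqq)
        fine = np.geomspace(0.005, 1.2, 6000)
        fine_vals = md.cross_section_factor(fine, 16.0) + 0.01
        check_idx = [50, 150, 250]
        for i in check_idx:
            sig = dqq * q[i]
            w = norm.pdf(fine, loc=q[i], scale=sig)
            direct = np.trapezoid(w * fine_vals, fine) / np.trapezoid(w, fine)
            assert out[i] == pytest.approx(direct, rel=5e-3)
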