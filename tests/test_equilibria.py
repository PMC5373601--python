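import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ktzlog import equilibria as eq
from ktzlog.model import ModelParams, State, logistic_gain, simulate


def residual(rec, params):
    return rec.residual(params)


class TestFixedPointsCase1:
    def test_three_roots_symmetric(self):
        p = ModelParams(K=0.6, T=0.3)
        xs = sorted(r.x_star for r in eq.fixed_points_case1(p))
        assert xs == pytest.approx([-0.25, 0.0, 0.25], abs=1e-12)

    def test_only_origin_at_large_T(self):
        p = ModelParams(K=0.6, T=0.7)
        xs = [r.x_star for r in eq.fixed_points_case1(p)]
        assert xs == [0.0]

    @given(st.floats(min_value=0.05, max_value=1.9),
           st.floats(min_value=0.01, max_value=1.5))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_residuals(self, K, T):
        p = ModelParams(K=K, T=T)
        recs = eq.fixed_points_case1(p)
        xs = sorted(r.x_star for r in recs)
        assert xs == pytest.approx(sorted(-x for x in xs), abs=1e-12)
        for r in recs:
            assert residual(r, p) <= 1e-12
            assert abs(r.x_star) <= 1.0 + 1e-12

    def test_H_negation_flips_set(self):
        p = ModelParams(K=0.6, T=0.2, H=-0.01)
        a = sorted(r.x_star for r in eq.fixed_points_case1(p))
        b = sorted(-r.x_star for r in eq.fixed_points_case1(p.mirrored()))
        assert a == pytest.approx(b, abs=1e-14)

    def test_K_equal_one_linear_branch(self):
        p = ModelParams(K=1.0, T=0.3, H=0.05)
        recs = eq.fixed_points_case1(p)
        assert recs
        for r in recs:
            assert residual(r, p) <= 1e-12


class TestEigenvaluesCase1:
    def test_characteristic_polynomial_residual(self):
        p = ModelParams(K=0.6, T=0.3)
        for r in eq.fixed_points_case1(p):
            lams = eq.eigenvalues_case1(r, p)
            for lam in lams:
                res = lam ** 2 - (p.T / r.p ** 2) * lam \
                    + p.K * p.T / r.p ** 2
                assert abs(res) <= 1e-10

    def test_unit_modulus_on_ns_line(self):
        # origin at T = K (K > 0.5): Neimark-Sacker condition |L| = 1
        for K in (0.6, 0.8, 1.3):
            p = ModelParams(K=K, T=K)
            origin = [r for r in eq.fixed_points_case1(p)
                      if r.x_star == 0.0][0]
            lams = eq.eigenvalues_case1(origin, p)
            assert np.abs(lams) == pytest.approx([1.0, 1.0], abs=1e-12)

    def test_stable_above_ns_line(self):
        p = ModelParams(K=0.6, T=0.7)
        origin = eq.fixed_points_case1(p)[0]
        lams = eq.eigenvalues_case1(origin, p)
        assert np.abs(lams).max() < 1.0


class TestFixedPointsCase2:
    def test_origin_when_xR_zero(self):
        p = ModelParams(K=0.6, T=0.3, delta=0.001, lam=0.001, xR=0.0)
        assert any(r.x_star == 0.0 for r in eq.fixed_points_case2(p))

    def test_against_iteration_oracle(self):
        # alpha = 1 makes z* = x_R - x*, so x* solves x = f((x_R - Kx)/T)
        p = ModelParams(K=0.6, T=0.35, delta=0.001, lam=0.001, xR=-0.5)
        recs = eq.fixed_points_case2(p)
        assert len(recs) == 1
        x = 0.0
        for _ in range(20000):
            x = logistic_gain((p.xR - p.K * x) / p.T)
        assert recs[0].x_star == pytest.approx(x, abs=1e-10)
        assert recs[0].z_star == pytest.approx(p.xR - recs[0].x_star,
                                               abs=1e-12)

    def test_xR_negation_flips_set(self):
        p = ModelParams(K=0.6, T=0.3, delta=0.001, lam=0.001, xR=-0.4)
        a = sorted(r.x_star for r in eq.fixed_points_case2(p))
        b = sorted(-r.x_star for r in eq.fixed_points_case2(p.mirrored()))
        assert a == pytest.approx(b, abs=1e-14)

    def test_residuals(self):
        p = ModelParams(K=0.8, T=0.2, delta=0.01, lam=0.005, xR=-0.3)
        for r in eq.fixed_points_case2(p):
            assert residual(r, p) <= 1e-12

    def test_alpha_undefined_raises(self):
        p = ModelParams(K=0.6, T=0.3, delta=0.0, lam=0.001, xR=-0.3)
        with pytest.raises(ValueError):
            eq.fixed_points_case2(p)


class TestEigenvaluesCase2:
    def test_frozen_z_limit_factorizes(self):
        """delta = lambda = 0: spectrum = case-I pair plus the root 1."""
        p1 = ModelParams(K=0.6, T=0.3)
        fp = eq.fixed_points_case1(p1)[0]
        pair = eq.eigenvalues_case1(fp, p1)
        rec = eq.FixedPointRecord(fp.x_star, fp.y_star, 0.0, fp.s,
                                  fp.p0, fp.p)
        triple = eq.eigenvalues_case2(rec, p1)
        all_roots = sorted(np.concatenate([pair, [1.0]]),
                           key=lambda z: (z.real, z.imag))
        got = sorted(triple, key=lambda z: (z.real, z.imag))
        assert np.allclose(got, all_roots, atol=1e-10)

    def test_polynomial_residual_and_closed_form(self):
        p = ModelParams(K=0.6, T=0.3, delta=0.001, lam=0.001, xR=-0.4)
        for rec in eq.fixed_points_case2(p):
            lams = eq.eigenvalues_case2(rec, p)
            c = rec.detail.coefficients
            for lam in lams:
                res = ((c[0] * lam + c[1]) * lam + c[2]) * lam + c[3]
                assert abs(res) <= 1e-10 * max(1.0, abs(c[0]))
            assert rec.detail.agreement <= 1e-8


class TestStabilityClassification:
    def test_stable_origin_verified(self):
        p = ModelParams(K=0.6, T=0.7)
        rec = eq.fixed_points(p)[0]
        assert eq.classify_stability(rec, p) == "stable"

    def test_unstable_origin_in_oa_region(self):
        p = ModelParams(K=0.6, T=0.3)
        origin = [r for r in eq.fixed_points(p) if r.x_star == 0.0][0]
        assert eq.classify_stability(origin, p) == "unstable"

    def test_marginal_flag_on_ns_line(self):
        p = ModelParams(K=0.7, T=0.7)
        origin = [r for r in eq.fixed_points(p) if r.x_star == 0.0][0]
        assert origin.marginal

    def test_case2_stable_fp_verified(self):
        p = ModelParams(K=0.6, T=0.35, delta=0.001, lam=0.001, xR=-0.5)
        rec = eq.fixed_points(p)[0]
        assert eq.classify_stability(rec, p) == "stable"


class TestBoundaryCurves:
    def test_all_three_meet_at_half_half(self):
        curves = {c.kind: c for c in eq.boundary_curves_case1((0.01, 2.0))}
        assert set(curves) == {"pitchfork", "NS_super", "NS_sub"}
        for c in curves.values():
            K, T = c.points[:, 0], c.points[:, 1]
            i = np.argmin(np.abs(K - 0.5))
            assert T[i] == pytest.approx(0.5, abs=1e-9)

    def test_subcritical_curve_vanishes_at_K_one(self):
        c = [c for c in eq.boundary_curves_case1((0.01, 2.0))
             if c.kind == "NS_sub"][0]
        K, T = c.points[:, 0], c.points[:, 1]
        assert T[np.argmin(np.abs(K - 1.0))] == pytest.approx(0.0, abs=1e-9)

    def test_TH_curves_touch_zero_bias_limits(self):
        # the H(T) limit meets H = 0 exactly where the K x T limits say
        for K, Tmax in ((0.3, 0.7), (0.6, 0.6)):
            curves = eq.boundary_curves_TH(K)
            T, H = curves[0].points[:, 0], curves[0].points[:, 1]
            assert H[np.argmin(np.abs(T - Tmax))] == pytest.approx(
                0.0, abs=1e-3)

    def test_quasistatic_boundary(self):
        assert eq.quasistatic_boundary(0.6, 0.2) == pytest.approx((0.4, -0.4))
        assert eq.quasistatic_boundary(0.5, 0.5) == (0.0, 0.0)

    def test_quasistatic_predicts_spike_onset(self):
        """Simulated oscillation onset lies within O(delta) of x_R=-(K-T)."""
        from ktzlog.chaos import locate_bifurcation
        from ktzlog.phases import ClassifierConfig

        p = ModelParams(K=0.6, T=0.2, delta=1e-4, lam=1e-4, xR=-0.3)
        cfg = ClassifierConfig(window=400_000, discard=100_000)
        xc = locate_bifurcation(p, "xR", (-0.41, -0.38), "spike_onset",
                                cfg, tol=1e-5)
        assert xc == pytest.approx(-0.4, abs=5e-3)
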