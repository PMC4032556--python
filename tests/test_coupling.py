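"""Interface coupling coefficients and hybrid regime behaviour."""

import math

import numpy as np
import pytest

import md2bd
from md2bd import (alpha_3d, alpha_exact_1d, bath_parameters, beta_3d,
                   beta_exact_1d, combined_sde_coeffs_1d, run_hybrid_1d,
                   surface_quadrature_oracle, taylor_coeffs_1d)
from md2bd.coupling import _hybrid1d_step
from md2bd.errors import ParameterError

BATH = bath_parameters("A", 1e3, 10.0, 1.0, 1.0)
BATH_B = bath_parameters("B", 1e3, 10.0, 1.0, 1.0)
BATH_C = bath_parameters("C", 1e3, 10.0, 1.0, 1.0)


class TestOneSidedCoefficients1D:
    def test_alpha_at_rest(self):
        expect = -BATH.lambda_mu * BATH.sigma_mu ** 2 / (BATH.mu + 1.0)
        assert alpha_exact_1d(0.0, BATH) == pytest.approx(expect, rel=1e-14)
        assert expect == pytest.approx(-313.48, abs=0.01)

    def test_beta_at_rest_is_gamma_sqrt_d(self):
        assert beta_exact_1d(0.0, BATH) == pytest.approx(10.0, rel=1e-12)

    def test_odd_part_gives_friction(self):
        V = math.sqrt(BATH.D * BATH.gamma)
        odd = alpha_exact_1d(V, BATH) - alpha_exact_1d(-V, BATH)
        assert odd == pytest.approx(-BATH.gamma * V, rel=0.01)

    def test_taylor_agreement(self):
        a0_taylor, b_taylor = taylor_coeffs_1d(0.0, BATH)
        assert a0_taylor == pytest.approx(alpha_exact_1d(0.0, BATH), rel=1e-12)
        assert b_taylor == pytest.approx(beta_exact_1d(0.0, BATH), rel=1e-12)
        for V in np.linspace(-math.sqrt(10), math.sqrt(10), 7):
            a_t, b_t = taylor_coeffs_1d(V, BATH)
            assert a_t == pytest.approx(alpha_exact_1d(V, BATH), rel=1e-2)
            assert b_t == pytest.approx(beta_exact_1d(V, BATH), rel=1e-2)

    def test_combined_coefficients_limits(self):
        drift0, noise0 = combined_sde_coeffs_1d(0.0, BATH)
        assert drift0 == 0.0
        assert noise0 == pytest.approx(BATH.gamma * math.sqrt(2 * BATH.D),
                                       rel=1e-3)
        # numerical drift slope at 0 -> -gamma as mu -> infinity
        big = bath_parameters("A", 1e6, 10.0, 1.0)
        h = 1e-3
        dplus, _ = combined_sde_coeffs_1d(h, big)
        assert dplus / h == pytest.approx(-10.0, rel=1e-3)

    def test_requires_model_a(self):
        with pytest.raises(ParameterError):
            alpha_exact_1d(0.0, BATH_B)


class TestCoefficients3D:
    @pytest.mark.parametrize("bath", [BATH_B, BATH_C], ids=["B", "C"])
    def test_endpoint_identities_exact(self, bath):
        V = np.array([1.0, 2.0, 3.0])
        R, g, D = bath.R, bath.gamma, bath.D
        assert np.allclose(alpha_3d(R, V, bath), -g * V, rtol=1e-14)
        assert np.allclose(beta_3d(R, bath), g * math.sqrt(2 * D) * np.eye(3),
                           rtol=1e-14)
        assert np.allclose(alpha_3d(-R, V, bath), 0.0)
        assert np.allclose(beta_3d(-R, bath), 0.0)

    def test_plug_in_at_interface_centre(self):
        aB = alpha_3d(0.0, np.zeros(3), BATH_B)[0]
        aC = alpha_3d(0.0, np.zeros(3), BATH_C)[0]
        assert aB == pytest.approx(-470.2, abs=0.1)
        assert aC == pytest.approx(-500.2, abs=0.1)
        # the C/B constant-term ratio is (4/3) sqrt(2/pi)
        assert aC / aB == pytest.approx(4.0 / 3.0 * math.sqrt(2 / math.pi),
                                        rel=1e-12)
        assert beta_3d(0.0, BATH_B)[0, 0] == pytest.approx(10.0, rel=1e-12)

    @pytest.mark.parametrize("bath", [BATH_B, BATH_C], ids=["B", "C"])
    def test_continuity_in_depth(self, bath):
        xs = np.linspace(-bath.R, bath.R, 101)
        V = np.array([0.7, -0.4, 0.2])
        a = np.array([alpha_3d(x, V, bath) for x in xs])
        b = np.array([np.diag(beta_3d(x, bath)) for x in xs])
        h = xs[1] - xs[0]
        # bounded increments: |d alpha/dX1| <= ~1100; beta has a sqrt
        # behaviour at X1 = -R, so its first increment scales like sqrt(h)
        assert np.abs(np.diff(a, axis=0)).max() < 1500.0 * h
        assert np.abs(np.diff(b, axis=0)).max() < 1.5 * bath.gamma * math.sqrt(
            3.0 * bath.D * h / bath.R)

    @pytest.mark.parametrize("bath", [BATH_B, BATH_C], ids=["B", "C"])
    def test_quadrature_oracle_agreement(self, bath):
        R = bath.R
        for X1 in [-R, -R / 2, 0.0, R / 2, R]:
            for V in [np.zeros(3), np.array([0.5, -0.3, 0.2])]:
                a_cf = alpha_3d(X1, V, bath)
                a_q, b_q = surface_quadrature_oracle(X1, V, bath)
                assert np.allclose(a_q, a_cf, rtol=1e-4, atol=1e-9)
                b_cf = np.diag(beta_3d(X1, bath))
                assert np.allclose(b_q, b_cf, rtol=1e-4, atol=1e-9)

    def test_empty_cap_is_exactly_zero(self):
        a_q, b_q = surface_quadrature_oracle(-1.0, np.array([1.0, 1, 1]), BATH_B)
        assert np.all(a_q == 0.0) and np.all(b_q == 0.0)


class TestHybridRegimes1D:
    def test_bd_region_update_matches_langevin(self):
        # with no bath and X >= R, the hybrid step is exactly one
        # Euler-Maruyama Langevin update
        scaled = bath_parameters("A", 100.0, 10.0, 1.0, 1.0)
        xs = np.empty(8)
        vs = np.empty(8)
        dt = 1e-4
        rng1 = np.random.default_rng(77)
        X, V, n, status = _hybrid1d_step(rng1, xs, vs, 0, 5.0, 2.0, scaled.mu,
                                         1.0, dt, 10.0, scaled.sigma_mu,
                                         scaled.lambda_mu, 0.0, 10.0, 1.0)
        rng2 = np.random.default_rng(77)
        rng2.random(2)                    # the two (rejected) influx draws
        xi = rng2.standard_normal()
        assert status == 0
        assert X == pytest.approx(5.0 + 2.0 * dt)
        assert V == pytest.approx(2.0 - 10.0 * 2.0 * dt
                                  + 10.0 * math.sqrt(2 * dt) * xi)

    def test_md_region_update_is_pure_collision_dynamics(self):
        # far inside the MD region with a zero-velocity bath and V = 0,
        # nothing moves and no correction is applied
        scaled = bath_parameters("A", 100.0, 10.0, 1.0, 1.0)
        xs = np.linspace(-9, -4, 10).copy()
        vs = np.zeros(10)
        rng = np.random.default_rng(78)
        X, V, n, status = _hybrid1d_step(rng, xs, vs, 10, -2.5, 0.0,
                                         scaled.mu, 1.0, 1e-4, 10.0,
                                         scaled.sigma_mu, scaled.lambda_mu,
                                         0.0, 10.0, 1.0)
        assert (X, V) == (-2.5, 0.0)

    def test_public_step_wrappers_round_trip(self, rng):
        # 1-D: no bath, BD region -> free flight + Langevin velocity update
        scaled = bath_parameters("A", 100.0, 10.0, 1.0, 1.0)
        bath_state = md2bd.HeatBathState1D(np.empty(0), np.empty(0))
        heavy = md2bd.HeavyState1D(X=5.0, V=1.0, R=1.0)
        b2, h2 = md2bd.hybrid_step_1d(bath_state, heavy, scaled, 1e-4, 10.0,
                                      rng)
        assert h2.X == pytest.approx(5.0 + 1.0 * 1e-4)
        assert b2.n == 0 or b2.positions.min() >= -10.0
        # 3-D: a couple of steps keep the invariants (no interpenetration)
        bathC = bath_parameters("C", 100.0, 10.0, 1.0, 1.0)
        heavy3 = md2bd.HeavyState3D(X=[0.0, 0.0, 0.0], V=[0.0, 0.0, 0.0],
                                    R=1.0)
        b3 = md2bd.equilibrium_bath_3d(rng, bathC, [-4, -3, -3], [0, 3, 3],
                                       heavy3)
        for _ in range(5):
            b3, heavy3 = md2bd.hybrid_step_3d(b3, heavy3, bathC, 1e-4, rng)
        d = np.linalg.norm(b3.positions - heavy3.X, axis=1)
        assert d.min() >= 1.0 - 1e-9
        assert np.all(b3.positions[:, 0] <= 0.0)

    def test_hybrid_ensemble_matches_bd_statistics(self):
        ens = run_hybrid_1d(mu=100, gamma=10, D=1, L=10, R=1, dt=1e-4,
                            t_end=1.0, n_realizations=1500, seed=13,
                            save_every=1000)
        t, msd, se = md2bd.estimate_msd(ens)
        ref = md2bd.msd_langevin(t, 1.0, 10.0)
        z = (msd[1:] - ref[1:]) / se[1:]
        assert np.abs(z).max() < 3.0
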