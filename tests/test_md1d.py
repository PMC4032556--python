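"""1-D MD engine: boundary influx laws, stepping, equilibrium maintenance."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

import md2bd
from md2bd import (HeatBathState1D, HeavyState1D, bath_parameters,
                   equilibrium_bath_1d, influx_position_sample,
                   influx_probability, influx_velocity_sample, md_step_A)
from md2bd.errors import StepSizeError
from test_params import erfc_dist_cdf

BATH = bath_parameters("A", 1e3, 10.0, 1.0)
SCALED = bath_parameters("A", 100.0, 10.0, 1.0)


class TestInfluxProbability:
    def test_plug_in(self):
        assert influx_probability(10.0, 1e3, 1e-7) == pytest.approx(1.25125e-4)

    def test_zero_step(self):
        assert influx_probability(10.0, 1e3, 0.0) == 0.0

    def test_too_large_step_rejected(self):
        with pytest.raises(StepSizeError):
            influx_probability(10.0, 1e3, 1e-2)

    def test_mc_crossing_oracle(self, rng):
        # brute-force count of equilibrium particles crossing b under free
        # flight in dt vs the closed form gamma*(mu+1)*dt/8
        bath, dt, trials = SCALED, 1e-4, 200_000
        W = 9 * bath.sigma_mu * dt
        counts = rng.poisson(bath.lambda_mu * W, size=trials)
        tot = int(counts.sum())
        x = rng.uniform(-W, 0.0, size=tot)      # b = 0
        v = bath.sigma_mu * rng.standard_normal(tot)
        crossed = x + v * dt > 0
        per_trial = np.zeros(trials)
        np.add.at(per_trial, np.repeat(np.arange(trials), counts), crossed)
        expect = influx_probability(bath.gamma, bath.mu, dt)
        se = per_trial.std(ddof=1) / math.sqrt(trials)
        assert abs(per_trial.mean() - expect) < 3 * se


class TestInfluxSamples:
    def test_position_support_and_mean_depth(self, rng):
        dt, b = 1e-4, -10.0
        xs = np.array([influx_position_sample(rng, b, "left", BATH, dt)
                       for _ in range(20000)])
        assert np.all(xs > b)
        depth = xs - b
        expect = BATH.sigma_mu * dt * math.sqrt(2.0) * math.sqrt(math.pi) / 4.0
        assert depth.mean() == pytest.approx(expect, rel=0.02)

    def test_position_ks_scaled_erfc(self, rng):
        dt = 1e-4
        xs = np.array([influx_position_sample(rng, 0.0, "right", BATH, dt)
                       for _ in range(100_000)])
        z = -xs / (BATH.sigma_mu * dt * math.sqrt(2.0))
        assert stats.kstest(z, erfc_dist_cdf).pvalue > 0.01

    def test_velocity_support(self, rng):
        dt, b = 1e-4, -10.0
        for _ in range(200):
            x = influx_position_sample(rng, b, "left", BATH, dt)
            v = influx_velocity_sample(rng, x, b, "left", BATH, dt)
            assert b - x + v * dt > 0      # Heaviside constraint

    def test_velocity_limit_at_boundary(self, rng):
        # x -> b+: truncation tends to v > 0 (half-normal)
        dt, b = 1e-4, 0.0
        vs = np.array([influx_velocity_sample(rng, b + 1e-12, b, "left",
                                              BATH, dt) for _ in range(20000)])
        assert np.all(vs > 0)
        assert vs.mean() == pytest.approx(BATH.sigma_mu * math.sqrt(2 / math.pi),
                                          rel=0.03)

    def test_joint_law_chi2(self, rng):
        # binned joint (depth, v) against H(b-x+v dt) lambda f(v)
        dt = 1e-4
        n = 100_000
        d = np.empty(n)
        v = np.empty(n)
        for i in range(n):
            x = influx_position_sample(rng, 0.0, "left", BATH, dt)
            d[i] = x
            v[i] = influx_velocity_sample(rng, x, 0.0, "left", BATH, dt)
        sig = BATH.sigma_mu
        d_edges = np.array([0, 0.2, 0.5, 0.9, 1.5, 2.5, 6.0]) * sig * dt
        v_edges = np.array([-np.inf, 0.3, 0.8, 1.5, 2.5, np.inf]) * sig

        def cell_prob(d0, d1, v0, v1):
            # integral over depth of the truncated-normal mass in [v0, v1]
            f = lambda x: (stats.norm.cdf(max(v1 / sig, x / (dt * sig)))
                           - stats.norm.cdf(max(v0 / sig, x / (dt * sig))))
            val, _ = integrate.quad(f, d0, d1, limit=200)
            return val

        probs = np.array([[cell_prob(d_edges[i], d_edges[i + 1],
                                     v_edges[j], v_edges[j + 1])
                           for j in range(len(v_edges) - 1)]
                          for i in range(len(d_edges) - 1)])
        obs, _, _ = np.histogram2d(d, v, bins=(d_edges, v_edges))
        inside = obs.sum()
        exp = probs / probs.sum() * inside
        keep = exp.ravel() > 5
        res = stats.chisquare(obs.ravel()[keep],
                              exp.ravel()[keep] * inside / exp.ravel()[keep].sum(),
                              ddof=0)
        assert res.pvalue > 0.01


class TestMdStepA:
    def test_pure_free_flight_without_bath(self, rng):
        bath_state = HeatBathState1D(np.empty(0), np.empty(0))
        heavy = HeavyState1D(X=1.0, V=-2.0)
        new_bath, new_heavy, counters = md_step_A(
            bath_state, heavy, SCALED, 1e-4, 10.0, rng)
        assert new_heavy.X == pytest.approx(1.0 - 2.0 * 1e-4)
        assert new_heavy.V == -2.0
        assert counters["collisions"] == 0

    def test_zero_temperature_no_motion(self, rng):
        xs = np.linspace(-5, 5, 50)
        bath_state = HeatBathState1D(xs, np.zeros(50))
        heavy = HeavyState1D(X=0.25, V=0.0)
        for _ in range(20):
            bath_state, heavy, _ = md_step_A(bath_state, heavy, SCALED,
                                             1e-4, 10.0, rng)
        assert heavy.X == 0.25 and heavy.V == 0.0

    def test_equilibrium_density_maintained(self, rng):
        bath_state = equilibrium_bath_1d(rng, SCALED, -10.0, 10.0)
        heavy = HeavyState1D(X=0.0, V=0.0)
        pooled = []
        for step in range(400):
            bath_state, heavy, _ = md_step_A(bath_state, heavy, SCALED,
                                             1e-4, 10.0, rng)
            if step % 40 == 0:
                pooled.append(bath_state.positions.copy())
        pos = np.concatenate(pooled)
        counts, _ = np.histogram(pos, bins=10, range=(-10, 10))
        expect = SCALED.lambda_mu * 2.0 * len(pooled)
        # Poisson fluctuation band (samples are correlated; allow 5 sigma)
        assert np.all(np.abs(counts - expect) < 5 * math.sqrt(expect))


class TestRunModelA:
    def test_bath_count_stationary(self, model_a_ensemble):
        counts = model_a_ensemble.meta["bath_counts"]
        expect = 2 * 10.0 * SCALED.lambda_mu
        mean_per_real = counts.mean(axis=1)
        assert mean_per_real.mean() == pytest.approx(
            expect, abs=3 * mean_per_real.std(ddof=1) / math.sqrt(len(mean_per_real)))

    def test_flux_audit_insertions_match_removals(self, model_a_ensemble):
        meta = model_a_ensemble.meta
        ins = meta["inserted_left"] + meta["inserted_right"]
        rem = meta["removed"]
        assert abs(ins - rem) < 5 * math.sqrt(ins)

    def test_velocity_variance_equipartition(self, model_a_ensemble):
        # stationary heavy velocity variance -> sigma^2/(mu+1) = D*gamma
        late = model_a_ensemble.times > 0.2
        v = model_a_ensemble.V[:, late, 0]
        per_real = v.var(axis=1)
        se = per_real.std(ddof=1) / math.sqrt(per_real.shape[0])
        assert v.var() == pytest.approx(10.0, abs=max(4 * se, 1.0))

    def test_velocity_autocorrelation_decay(self, model_a_ensemble):
        # log-VACF slope within 15% of -gamma, fitted where the signal is
        # well above the ensemble noise floor (acf > acf(0)/3)
        times = model_a_ensemble.times
        v = model_a_ensemble.V[:, :, 0]
        dt_s = times[1] - times[0]
        i0 = np.searchsorted(times, 0.2)
        n_or = 60
        lags = np.arange(0, int(0.08 / dt_s) + 1)
        acf = np.array([np.mean(v[:, i0:i0 + n_or] * v[:, i0 + k:i0 + n_or + k])
                        for k in lags])
        tau = lags * dt_s
        keep = acf > acf[0] / 3.0
        slope = np.polyfit(tau[keep], np.log(acf[keep]), 1)[0]
        assert slope == pytest.approx(-10.0, rel=0.15)
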