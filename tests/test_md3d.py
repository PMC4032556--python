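"""3-D MD engines: boundary flux, entrant laws, windows, bath moments."""

import math

import numpy as np
import pytest
from scipy import stats

import md2bd
from md2bd import (HeatBathState3D, HeavyState3D, bath_parameters,
                   equilibrium_bath_3d, influx_count_3d, influx_sample_3d,
                   md_step_3d, run_model_3d, shift_window)
from md2bd.errors import GeometryError

BATH_B = bath_parameters("B", 100.0, 10.0, 1.0, 1.0)
BATH_C = bath_parameters("C", 100.0, 10.0, 1.0, 1.0)


class TestInfluxCount:
    def test_plug_in(self):
        val = influx_count_3d(10.0, 1e3, 1e-6, 1.0, 1.0)
        assert val == pytest.approx(5.975e-4, rel=1e-3)

    def test_linear_in_area_and_dt(self):
        base = influx_count_3d(10.0, 1e3, 1e-6, 1.0, 1.0)
        assert influx_count_3d(10.0, 1e3, 2e-6, 1.0, 3.0) == pytest.approx(
            6 * base, rel=1e-12)

    @pytest.mark.parametrize("bath", [BATH_B, BATH_C], ids=["B", "C"])
    def test_mc_crossing_oracle(self, rng, bath):
        # free-flight crossings of a half-space equilibrium field through a
        # unit patch vs 3*gamma*(mu+1)*dt/(16*pi*R^2)
        dt, trials = 1e-4, 100_000
        # strip deep enough to contain every possible crosser
        W = (1.05 if bath.model == "C" else 9.0) * bath.sigma_mu * dt
        counts = rng.poisson(bath.lambda_mu * W, size=trials)  # unit patch
        tot = int(counts.sum())
        x1 = rng.uniform(-W, 0.0, size=tot)
        if bath.model == "C":
            v1 = rng.uniform(-bath.sigma_mu, bath.sigma_mu, size=tot)
        else:
            v1 = bath.sigma_mu * rng.standard_normal(tot)
        crossed = x1 + v1 * dt > 0
        per_trial = np.zeros(trials)
        np.add.at(per_trial, np.repeat(np.arange(trials), counts), crossed)
        expect = influx_count_3d(bath.gamma, bath.mu, dt, bath.R, 1.0)
        se = per_trial.std(ddof=1) / math.sqrt(trials)
        assert abs(per_trial.mean() - expect) < 3 * se


class TestInfluxSample:
    def test_model_c_depth_support_and_mean(self, rng):
        dt = 1e-4
        depths = np.array([influx_sample_3d(rng, BATH_C, 0.0, dt)[0][0]
                           for _ in range(20000)])
        assert np.all(depths > 0)
        assert np.all(depths <= BATH_C.sigma_mu * dt + 1e-15)
        assert depths.mean() == pytest.approx(BATH_C.sigma_mu * dt / 3.0,
                                              rel=0.02)

    def test_model_b_heaviside_support(self, rng):
        dt = 1e-4
        for _ in range(500):
            pos, vel = influx_sample_3d(rng, BATH_B, 2.0, dt)
            assert 2.0 - pos[0] + vel[0] * dt > 0

    def test_model_c_speed_preserved(self, rng):
        dt = 1e-4
        for _ in range(200):
            _, vel = influx_sample_3d(rng, BATH_C, 0.0, dt)
            assert np.linalg.norm(vel) == pytest.approx(BATH_C.sigma_mu,
                                                        rel=1e-12)


class TestWindow:
    def _bath(self, rng):
        return equilibrium_bath_3d(rng, BATH_C, [-2, -2, -2], [2, 2, 2])

    def test_identity_shift(self, rng):
        b = self._bath(rng)
        b2 = shift_window(b, b.window, BATH_C, rng)
        assert b2.n == b.n
        assert np.allclose(b2.positions, b.positions)

    def test_fresh_region_density(self, rng):
        b = self._bath(rng)
        counts = []
        for _ in range(200):
            b2 = shift_window(b, ([-2, -1, -2], [2, 3, 2]), BATH_C, rng)
            fresh = b2.positions[:, 1] > 2.0
            counts.append(fresh.sum())
        lam_vol = BATH_C.lambda_mu * 4 * 4 * 1
        mean = np.mean(counts)
        assert mean == pytest.approx(lam_vol,
                                     abs=3 * math.sqrt(lam_vol / 200))

    def test_disjoint_windows_rejected(self, rng):
        b = self._bath(rng)
        with pytest.raises(GeometryError):
            shift_window(b, ([10, 10, 10], [12, 12, 12]), BATH_C, rng)

    def test_density_flat_across_seam(self, rng):
        # after a shift, stepping maintains a flat profile; snapshots are
        # spaced by ~ the window transit time so they are near-independent
        heavy = HeavyState3D(X=[0.0, 0.0, 0.0], V=[0, 0, 0], R=1.0)
        b = equilibrium_bath_3d(rng, BATH_C, [-2, -2, -2], [2, 2, 2], heavy)
        b = shift_window(b, ([-2, -1, -2], [2, 3, 2]), BATH_C, rng, heavy)
        pooled = []
        for step in range(2500):
            b, heavy, _ = md_step_3d(b, heavy, BATH_C, 1e-4, rng)
            if step % 500 == 499:
                pooled.append(b.positions[:, 1].copy())
        y = np.concatenate(pooled)
        # seam was at y = 2; sphere occupies y in [-1, 1] -- test beyond it
        counts, _ = np.histogram(y, bins=3, range=(1.5, 3))
        expect = BATH_C.lambda_mu * (0.5 * 4 * 4) * len(pooled)
        assert np.all(np.abs(counts - expect) < 5 * math.sqrt(expect))


class TestBathMoments:
    @pytest.mark.parametrize("bath", [BATH_B, BATH_C], ids=["B", "C"])
    def test_velocity_increment_variance_rate(self, rng, bath):
        """Fluctuation-dissipation oracle at rest: per-component variance
        rate of the heavy-sphere velocity increment -> 2*gamma^2*D."""
        dt = 5e-5
        reps = 4000
        dV = np.empty((reps, 3))
        for r in range(reps):
            heavy = HeavyState3D(X=np.zeros(3), V=np.zeros(3), R=1.0)
            b = equilibrium_bath_3d(rng, bath, [-2, -2, -2], [2, 2, 2], heavy)
            b, heavy, _ = md_step_3d(b, heavy, bath, dt, rng)
            dV[r] = heavy.V
        sq = (dV ** 2).ravel()                 # isotropic: pool components
        rate = sq.mean() / dt
        se = sq.std(ddof=1) / math.sqrt(sq.size) / dt
        assert abs(rate - 2 * bath.gamma ** 2 * bath.D) < 3 * se


@pytest.fixture(scope="module", params=["B", "C"])
def ens3d(request):
    return run_model_3d(model=request.param, mu=100, gamma=10, D=1, R=1,
                        window_half_width=2.5, dt=1e-4, t_end=0.4,
                        n_realizations=40, seed=21, save_every=100)


class TestRunModel3D:
    def test_stationary_velocity_variance(self, ens3d):
        late = ens3d.times > 0.2
        v = ens3d.V[:, late, :]
        per_real = v.reshape(v.shape[0], -1).var(axis=1)
        se = per_real.std(ddof=1) / math.sqrt(len(per_real))
        # sigma^2/(mu+1) = D*gamma (finite-mu correction ~ 1%)
        assert v.var() == pytest.approx(10.0, abs=max(3 * se, 0.6))

    def test_friction_from_velocity_autocorrelation(self, ens3d):
        # acf ratio at lag tau: gamma_eff = -log(acf(tau)/acf(0))/tau
        times = ens3d.times
        tau_idx = 5                            # lag 0.005... spacing 0.01
        i0 = np.searchsorted(times, 0.2)
        v = ens3d.V[:, :, :]                   # pool all components
        x = v[:, i0:-tau_idx, :].ravel()
        y = v[:, i0 + tau_idx:, :].ravel()
        ratio = (x * y).mean() / (x * x).mean()
        tau = tau_idx * (times[1] - times[0])
        gamma_eff = -math.log(ratio) / tau
        assert gamma_eff == pytest.approx(10.0, rel=0.2)

    def test_msd_matches_langevin(self, ens3d):
        # the Langevin description is the mu -> infinity limit; compare
        # beyond the collision-resolution scale (a few mean collision times)
        t, msd, se = md2bd.estimate_msd(ens3d)
        ref = 3 * md2bd.msd_langevin(t, 1.0, 10.0)
        keep = t >= 0.05
        z = (msd[keep] - ref[keep]) / se[keep]
        assert np.abs(z).max() < 3.0
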