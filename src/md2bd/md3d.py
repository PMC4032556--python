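"""Three-dimensional MD heat-bath engines (models B and C).

A heavy sphere of radius ``R`` sits in an ideal gas of point particles that
collide elastically with it (and never with each other).  The bath is
simulated only inside an axis-aligned window; each window face carries the
exact boundary influx: the expected number of entrants per face per step is
``area * 3*gamma*(mu+1)*dt / (16*pi*R^2)`` (identical for B and C), with
the joint depth/velocity law of the entrants given by the one-step
free-flight crossing construction.  Insertions are Poisson-distributed per
face, which reduces to the Bernoulli single-insertion rule when the mean is
small.

Model B draws bath velocities from an isotropic Maxwellian with scale
``sigma_mu``; model C places them on the fixed-speed shell ``|v| =
sigma_mu``.  For model B the entrant depth profile is
``erfc(d/(sigma*dt*sqrt(2)))``; for model C it is the triangular profile
``(sigma - d/dt)_+`` supported on ``(0, sigma*dt]``.

The window may be re-centred ("moving window") around the sphere; newly
exposed volume is filled from the unconditioned equilibrium field, which is
the exact law of the bath that was not being simulated there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .collisions import _collide_1d, _sphere_hit_time
from .errors import GeometryError, ParameterError, StateError, StepSizeError
from .harness import TrajectoryEnsemble
from .params import (BathParams, _erfc_sample_scalar, _truncnorm_scalar,
                     DEFAULT_ENVELOPE, bath_parameters)

__all__ = [
    "HeatBathState3D",
    "HeavyState3D",
    "influx_count_3d",
    "influx_sample_3d",
    "equilibrium_bath_3d",
    "md_step_3d",
    "shift_window",
    "run_model_3d",
]

_SQRT2 = math.sqrt(2.0)
_A1 = DEFAULT_ENVELOPE.a1
_A2 = DEFAULT_ENVELOPE.a2
_EVENT_CAP = 10000


@dataclass
class HeatBathState3D:
    """Bath particles inside the currently populated window.

    ``window`` is ``(lo, hi)`` with two length-3 arrays.
    """

    positions: np.ndarray
    velocities: np.ndarray
    window: tuple[np.ndarray, np.ndarray]

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.velocities = np.atleast_2d(np.asarray(self.velocities, dtype=float))
        lo, hi = self.window
        self.window = (np.asarray(lo, dtype=float), np.asarray(hi, dtype=float))
        if self.positions.shape != self.velocities.shape:
            raise StateError("positions and velocities must have equal shape")

    @property
    def n(self) -> int:
        return self.positions.shape[0]


@dataclass
class HeavyState3D:
    """Heavy-sphere centre, velocity and radius."""

    X: np.ndarray
    V: np.ndarray
    R: float

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.V = np.asarray(self.V, dtype=float)


def influx_count_3d(gamma: float, mu: float, dt: float, R: float,
                    area: float) -> float:
    """Expected entrants through a planar patch of the given area per step:
    ``area * 3*gamma*(mu+1)*dt / (16*pi*R^2)`` (models B and C alike)."""
    if gamma <= 0 or mu <= 0 or R <= 0 or dt < 0 or area < 0:
        raise ParameterError("arguments must be positive (dt, area >= 0)")
    return area * 3.0 * gamma * (mu + 1.0) * dt / (16.0 * math.pi * R * R)


# ---------------------------------------------------------------------------
# numba sampling helpers
# ---------------------------------------------------------------------------

@njit(cache=True)
def _shell_scalar(rng, sigma):
    """One isotropic velocity with |v| = sigma."""
    c = 2.0 * rng.random() - 1.0
    phi = 2.0 * math.pi * rng.random()
    s = math.sqrt(1.0 - c * c)
    return sigma * c, sigma * s * math.cos(phi), sigma * s * math.sin(phi)


@njit(cache=True)
def _influx_draw(rng, model_c, sigma, dt):
    """Depth and velocity of one face entrant in face-local coordinates.

    Returns (depth, w, l1, l2): w > depth/dt is the inward speed, l1/l2 the
    tangential components.
    """
    if model_c:
        u = rng.random()
        d = sigma * dt * (1.0 - math.sqrt(1.0 - u))     # triangular profile
        w = d / dt + rng.random() * (sigma - d / dt)    # uniform on (d/dt, sigma]
        lat = math.sqrt(max(sigma * sigma - w * w, 0.0))
        phi = 2.0 * math.pi * rng.random()
        return d, w, lat * math.cos(phi), lat * math.sin(phi)
    z, _ = _erfc_sample_scalar(rng, _A1, _A2)
    d = _SQRT2 * sigma * dt * z                         # erfc profile
    w = _truncnorm_scalar(rng, sigma, d / dt, True)
    return d, w, sigma * rng.standard_normal(), sigma * rng.standard_normal()


@njit(cache=True)
def _influx_face(rng, ps, vs, n, lo, hi, axis, side, model_c, sigma, dt,
                 mean_count, X, R, gate):
    """Poisson-number insertion on one window face.

    side 0 inserts at the low face (inward normal +e_axis), side 1 at the
    high face.  With ``gate`` set, entrants falling inside the heavy sphere
    are discarded (thinning).
    """
    m = rng.poisson(mean_count)
    ins = 0
    ax1 = (axis + 1) % 3
    ax2 = (axis + 2) % 3
    for _ in range(m):
        if n >= ps.shape[0]:
            break
        d, w, l1, l2 = _influx_draw(rng, model_c, sigma, dt)
        if side == 0:
            pa = lo[axis] + d
            va = w
        else:
            pa = hi[axis] - d
            va = -w
        p1 = lo[ax1] + rng.random() * (hi[ax1] - lo[ax1])
        p2 = lo[ax2] + rng.random() * (hi[ax2] - lo[ax2])
        if gate:
            da = pa - X[axis]
            d1 = p1 - X[ax1]
            d2 = p2 - X[ax2]
            if da * da + d1 * d1 + d2 * d2 < R * R:
                continue
        ps[n, axis] = pa
        ps[n, ax1] = p1
        ps[n, ax2] = p2
        vs[n, axis] = va
        vs[n, ax1] = l1
        vs[n, ax2] = l2
        n += 1
        ins += 1
    return n, ins


@njit(cache=True)
def _fill_region(rng, ps, vs, n, lo, hi, ex_lo, ex_hi, lam, sigma, model_c, X, R):
    """Equilibrium fill of the box [lo, hi] excluding [ex_lo, ex_hi] and the
    sphere (thinned Poisson sample)."""
    vol = (hi[0] - lo[0]) * (hi[1] - lo[1]) * (hi[2] - lo[2])
    m = rng.poisson(lam * vol)
    for _ in range(m):
        if n >= ps.shape[0]:
            break
        x0 = lo[0] + rng.random() * (hi[0] - lo[0])
        x1 = lo[1] + rng.random() * (hi[1] - lo[1])
        x2 = lo[2] + rng.random() * (hi[2] - lo[2])
        if (ex_lo[0] <= x0 <= ex_hi[0] and ex_lo[1] <= x1 <= ex_hi[1]
                and ex_lo[2] <= x2 <= ex_hi[2]):
            continue
        d0 = x0 - X[0]
        d1 = x1 - X[1]
        d2 = x2 - X[2]
        if d0 * d0 + d1 * d1 + d2 * d2 < R * R:
            continue
        ps[n, 0] = x0
        ps[n, 1] = x1
        ps[n, 2] = x2
        if model_c:
            v0, v1, v2 = _shell_scalar(rng, sigma)
        else:
            v0 = sigma * rng.standard_normal()
            v1 = sigma * rng.standard_normal()
            v2 = sigma * rng.standard_normal()
        vs[n, 0] = v0
        vs[n, 1] = v1
        vs[n, 2] = v2
        n += 1
    return n


# ---------------------------------------------------------------------------
# collision resolution and stepping
# ---------------------------------------------------------------------------

@njit(cache=True)
def _resolve_3d(rng, ps, vs, n, X, V, mu, R, dt, membrane, memb_pos, p_bind):
    """Advance sphere and bath to t+dt, resolving collisions in order.

    With ``membrane`` set, sphere contact with the plane x1 = memb_pos binds
    with probability ``p_bind`` (return flag) or specularly reflects V1.
    Returns (n_events, bound, t_bound, status); status -1 on cascade-cap
    overflow.  X and V are mutated in place.
    """
    t_cur = 0.0
    nev = 0
    for _ in range(_EVENT_CAP):
        s_left = dt - t_cur
        s_min = s_left
        i_min = -1
        kind = 0  # 1 bath collision, 2 membrane contact
        for i in range(n):
            t = _sphere_hit_time(ps[i, 0] - X[0], ps[i, 1] - X[1], ps[i, 2] - X[2],
                                 vs[i, 0] - V[0], vs[i, 1] - V[1], vs[i, 2] - V[2],
                                 R, s_min)
            if 0.0 <= t < s_min:
                s_min = t
                i_min = i
                kind = 1
        if membrane and V[0] < 0.0:
            s_mem = (memb_pos + R - X[0]) / V[0]
            if 0.0 <= s_mem < s_min:
                s_min = s_mem
                kind = 2
        if kind == 0:
            for i in range(n):
                ps[i, 0] += vs[i, 0] * s_left
                ps[i, 1] += vs[i, 1] * s_left
                ps[i, 2] += vs[i, 2] * s_left
            X[0] += V[0] * s_left
            X[1] += V[1] * s_left
            X[2] += V[2] * s_left
            return nev, False, 0.0, 0
        for i in range(n):
            ps[i, 0] += vs[i, 0] * s_min
            ps[i, 1] += vs[i, 1] * s_min
            ps[i, 2] += vs[i, 2] * s_min
        X[0] += V[0] * s_min
        X[1] += V[1] * s_min
        X[2] += V[2] * s_min
        t_cur += s_min
        if kind == 2:
            if rng.random() < p_bind:
                return nev, True, t_cur, 0
            V[0] = -V[0]
        else:
            n0 = (ps[i_min, 0] - X[0]) / R
            n1 = (ps[i_min, 1] - X[1]) / R
            n2 = (ps[i_min, 2] - X[2]) / R
            nrm = math.sqrt(n0 * n0 + n1 * n1 + n2 * n2)
            n0 /= nrm
            n1 /= nrm
            n2 /= nrm
            Vn = V[0] * n0 + V[1] * n1 + V[2] * n2
            vn = vs[i_min, 0] * n0 + vs[i_min, 1] * n1 + vs[i_min, 2] * n2
            Vnp, vnp = _collide_1d(Vn, vn, mu)
            V[0] += (Vnp - Vn) * n0
            V[1] += (Vnp - Vn) * n1
            V[2] += (Vnp - Vn) * n2
            vs[i_min, 0] += (vnp - vn) * n0
            vs[i_min, 1] += (vnp - vn) * n1
            vs[i_min, 2] += (vnp - vn) * n2
            nev += 1
    return nev, False, 0.0, -1


@njit(cache=True)
def _compact_3d(ps, vs, n, lo, hi, reflect_lo0):
    """Drop particles outside the window; optionally reflect at x1 = lo[0]."""
    k = 0
    for i in range(n):
        if reflect_lo0 and ps[i, 0] < lo[0]:
            ps[i, 0] = 2.0 * lo[0] - ps[i, 0]
            vs[i, 0] = -vs[i, 0]
        if (lo[0] <= ps[i, 0] <= hi[0] and lo[1] <= ps[i, 1] <= hi[1]
                and lo[2] <= ps[i, 2] <= hi[2]):
            if k != i:
                ps[k, 0] = ps[i, 0]
                ps[k, 1] = ps[i, 1]
                ps[k, 2] = ps[i, 2]
                vs[k, 0] = vs[i, 0]
                vs[k, 1] = vs[i, 1]
                vs[k, 2] = vs[i, 2]
            k += 1
    return k, n - k


@njit(cache=True)
def _influx_all_faces(rng, ps, vs, n, lo, hi, model_c, sigma, dt, rate_area,
                      X, R, skip_lo0, gate_lo0_is_hi0):
    """Influx on the six window faces.

    rate_area is the expected count per unit face area per step.  With
    ``skip_lo0`` the low-x1 face is skipped (membrane).  Sphere-overlap
    gating is applied on every face.  Returns (n, inserted).
    """
    ins_tot = 0
    for axis in range(3):
        ax1 = (axis + 1) % 3
        ax2 = (axis + 2) % 3
        area = (hi[ax1] - lo[ax1]) * (hi[ax2] - lo[ax2])
        mean = rate_area * area
        for side in range(2):
            if axis == 0 and side == 0 and skip_lo0:
                continue
            n, ins = _influx_face(rng, ps, vs, n, lo, hi, axis, side, model_c,
                                  sigma, dt, mean, X, R, True)
            ins_tot += ins
    return n, ins_tot


@njit(cache=True)
def _maybe_shift_window(rng, ps, vs, n, lo, hi, X, R, margin, lam, sigma, model_c):
    """Re-centre lateral axes (1, 2) on the sphere when it comes within
    ``R + margin`` of a lateral face; fill newly exposed volume from the
    equilibrium field.  Returns (n, shifted)."""
    need = False
    for ax in range(1, 3):
        half = 0.5 * (hi[ax] - lo[ax])
        c = 0.5 * (hi[ax] + lo[ax])
        if abs(X[ax] - c) > half - (R + margin):
            need = True
    if not need:
        return n, False
    old_lo = lo.copy()
    old_hi = hi.copy()
    for ax in range(1, 3):
        half = 0.5 * (hi[ax] - lo[ax])
        lo[ax] = X[ax] - half
        hi[ax] = X[ax] + half
    n, _ = _compact_3d(ps, vs, n, lo, hi, False)
    n = _fill_region(rng, ps, vs, n, lo, hi, old_lo, old_hi, lam, sigma,
                     model_c, X, R)
    return n, True


@njit(cache=True)
def _md3d_step(rng, ps, vs, n, X, V, mu, R, dt, lo, hi, model_c, sigma,
               rate_area, lam, reflect_lo0, skip_lo0, follow_mode,
               window_margin):
    """One full 3-D MD iteration inside the window.

    follow_mode: 0 keeps the window fixed, 1 re-centres lateral axes on the
    sphere, 2 re-centres all three axes.
    Returns (n, n_events, n_removed, n_inserted, status).
    """
    nev, _, _, status = _resolve_3d(rng, ps, vs, n, X, V, mu, R, dt,
                                    False, 0.0, 0.0)
    if status < 0:
        return n, nev, 0, 0, -1
    if follow_mode == 2:
        # translate the window so it stays centred on the sphere in x1 too
        c0 = 0.5 * (lo[0] + hi[0])
        half0 = 0.5 * (hi[0] - lo[0])
        if abs(X[0] - c0) > half0 - (R + window_margin):
            old_lo = lo.copy()
            old_hi = hi.copy()
            lo[0] = X[0] - half0
            hi[0] = X[0] + half0
            n, _ = _compact_3d(ps, vs, n, lo, hi, False)
            n = _fill_region(rng, ps, vs, n, lo, hi, old_lo, old_hi, lam,
                             sigma, model_c, X, R)
    n, nrm = _compact_3d(ps, vs, n, lo, hi, reflect_lo0)
    if follow_mode >= 1:
        n, _ = _maybe_shift_window(rng, ps, vs, n, lo, hi, X, R,
                                   window_margin, lam, sigma, model_c)
    n, nins = _influx_all_faces(rng, ps, vs, n, lo, hi, model_c, sigma, dt,
                                rate_area, X, R, skip_lo0, False)
    return n, nev, nrm, nins, 0


# ---------------------------------------------------------------------------
# public interface
# ---------------------------------------------------------------------------

def influx_sample_3d(rng: np.random.Generator, bath: BathParams, b: float,
                     dt: float) -> tuple[np.ndarray, np.ndarray]:
    """One boundary entrant through the plane ``x1 = b`` (unit patch).

    Samples the joint law of position and velocity of a particle that ended
    up at ``x1 > b`` after one free-flight step from the equilibrium bath at
    ``x1 < b``: model B uses the erfc depth profile with the matching
    truncated-Maxwellian ``v1``; model C the triangular depth profile with
    shell velocity conditioned on ``v1 > (x1-b)/dt``.  Lateral position is
    uniform on the unit patch ``(0,1)^2``.
    """
    if bath.model == "A":
        raise ParameterError("influx_sample_3d requires bath model B or C")
    d, w, l1, l2 = _influx_draw(rng, bath.model == "C", bath.sigma_mu, dt)
    pos = np.array([b + d, rng.random(), rng.random()])
    vel = np.array([w, l1, l2])
    return pos, vel


def equilibrium_bath_3d(rng: np.random.Generator, bath: BathParams,
                        lo, hi, heavy: HeavyState3D | None = None) -> HeatBathState3D:
    """Equilibrium bath field in the box ``[lo, hi]``, excluding the sphere."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    vol = float(np.prod(hi - lo))
    cap = int(bath.lambda_mu * vol + 10.0 * math.sqrt(bath.lambda_mu * vol + 1.0) + 64)
    ps = np.empty((cap, 3))
    vs = np.empty((cap, 3))
    X = heavy.X if heavy is not None else np.array([np.inf, np.inf, np.inf])
    R = heavy.R if heavy is not None else 0.0
    empty = np.array([1.0, 1.0, 1.0])
    n = _fill_region(rng, ps, vs, 0, lo, hi, empty, empty - 2.0,
                     bath.lambda_mu, bath.sigma_mu, bath.model == "C", X, R)
    return HeatBathState3D(ps[:n].copy(), vs[:n].copy(), (lo, hi))


def md_step_3d(bath_state: HeatBathState3D, heavy: HeavyState3D,
               bath: BathParams, dt: float, rng: np.random.Generator,
               follow: bool = False) -> tuple[HeatBathState3D, HeavyState3D, dict]:
    """One iteration of the 3-D MD model (B or C) inside the window.

    Free flight, chronological sphere–point collision resolution, removal
    at the window boundary, Poisson influx on all faces, and (with
    ``follow``) window re-centring around the sphere.

    Returns the updated states and a counter dict.
    """
    if bath.model == "A":
        raise ParameterError("md_step_3d requires bath model B or C")
    rate_area = influx_count_3d(bath.gamma, bath.mu, dt, bath.R, 1.0)
    lo, hi = bath_state.window
    lo = lo.copy()
    hi = hi.copy()
    cap = bath_state.n + 4 * (1 + int(rate_area * float(np.prod(hi - lo)) + 64))
    ps = np.empty((cap, 3))
    vs = np.empty((cap, 3))
    ps[:bath_state.n] = bath_state.positions
    vs[:bath_state.n] = bath_state.velocities
    X = heavy.X.copy()
    V = heavy.V.copy()
    n, nev, nrm, nins, status = _md3d_step(
        rng, ps, vs, bath_state.n, X, V, bath.mu, bath.R, dt, lo, hi,
        bath.model == "C", bath.sigma_mu, rate_area, bath.lambda_mu,
        False, False, 2 if follow else 0, 0.5)
    if status < 0:
        raise StepSizeError("collision cascade exceeded the iteration cap")
    new_bath = HeatBathState3D(ps[:n].copy(), vs[:n].copy(), (lo, hi))
    new_heavy = HeavyState3D(X=X, V=V, R=heavy.R)
    return new_bath, new_heavy, {"collisions": nev, "removed": nrm,
                                 "inserted": nins}


def shift_window(bath_state: HeatBathState3D, new_window, bath: BathParams,
                 rng: np.random.Generator,
                 heavy: HeavyState3D | None = None) -> HeatBathState3D:
    """Move the populated window: drop particles outside the new box and
    fill newly exposed volume from the equilibrium field.

    Raises
    ------
    GeometryError
        If the new window does not overlap the old one.
    """
    new_lo = np.asarray(new_window[0], dtype=float)
    new_hi = np.asarray(new_window[1], dtype=float)
    old_lo, old_hi = bath_state.window
    if np.any(np.minimum(new_hi, old_hi) <= np.maximum(new_lo, old_lo)):
        raise GeometryError("new window must overlap the old window")
    vol = float(np.prod(new_hi - new_lo))
    cap = bath_state.n + int(bath.lambda_mu * vol
                             + 10.0 * math.sqrt(bath.lambda_mu * vol + 1.0) + 64)
    ps = np.empty((cap, 3))
    vs = np.empty((cap, 3))
    ps[:bath_state.n] = bath_state.positions
    vs[:bath_state.n] = bath_state.velocities
    n, _ = _compact_3d(ps, vs, bath_state.n, new_lo, new_hi, False)
    X = heavy.X if heavy is not None else np.array([np.inf, np.inf, np.inf])
    R = heavy.R if heavy is not None else 0.0
    n = _fill_region(rng, ps, vs, n, new_lo, new_hi, old_lo, old_hi,
                     bath.lambda_mu, bath.sigma_mu, bath.model == "C", X, R)
    return HeatBathState3D(ps[:n].copy(), vs[:n].copy(), (new_lo, new_hi))


@njit(cache=True)
def _run_3d_single(rng, ps, vs, n, n_steps, save_every, mu, R, dt, lo, hi,
                   model_c, sigma, rate_area, lam):
    X = np.zeros(3)
    V = np.zeros(3)
    n_save = n_steps // save_every + 1
    Xs = np.empty((n_save, 3))
    Vs = np.empty((n_save, 3))
    Xs[0] = X
    Vs[0] = V
    counters = np.zeros(3, dtype=np.int64)
    k = 1
    for s in range(1, n_steps + 1):
        n, nev, nrm, nins, status = _md3d_step(
            rng, ps, vs, n, X, V, mu, R, dt, lo, hi, model_c, sigma,
            rate_area, lam, False, False, 2, 0.5)
        if status < 0:
            return Xs, Vs, counters, -1
        counters[0] += nev
        counters[1] += nrm
        counters[2] += nins
        if s % save_every == 0:
            Xs[k] = X
            Vs[k] = V
            k += 1
    return Xs, Vs, counters, 0


def run_model_3d(*, model: str, mu: float, gamma: float, D: float, R: float,
                 window_half_width: float, dt: float, t_end: float,
                 n_realizations: int, seed: int,
                 save_every: int | None = None) -> TrajectoryEnsemble:
    """Ensemble of heavy-sphere trajectories in a full 3-D bath.

    The sphere starts at the origin at rest inside a cubic moving window of
    the given half-width, with influx on all six faces.
    """
    bath = bath_parameters(model, mu, gamma, D, R)
    rate_area = influx_count_3d(gamma, mu, dt, R, 1.0)
    n_steps = int(round(t_end / dt))
    if save_every is None:
        save_every = max(1, n_steps // 100)
    W = window_half_width
    vol = (2.0 * W) ** 3
    mean_n = bath.lambda_mu * vol
    cap = int(mean_n + 10.0 * math.sqrt(mean_n) + 256)

    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(seed).spawn(n_realizations)]
    n_save = n_steps // save_every + 1
    Xs = np.empty((n_realizations, n_save, 3))
    Vs = np.empty((n_realizations, n_save, 3))
    totals = np.zeros(3, dtype=np.int64)
    empty_lo = np.array([1.0, 1.0, 1.0])
    empty_hi = empty_lo - 2.0
    for r, rng in enumerate(streams):
        lo = np.array([-W, -W, -W])
        hi = np.array([W, W, W])
        ps = np.empty((cap, 3))
        vs = np.empty((cap, 3))
        n0 = _fill_region(rng, ps, vs, 0, lo, hi, empty_lo, empty_hi,
                          bath.lambda_mu, bath.sigma_mu, bath.model == "C",
                          np.zeros(3), R)
        Xr, Vr, ctr, status = _run_3d_single(
            rng, ps, vs, n0, n_steps, save_every, bath.mu, R, dt, lo, hi,
            bath.model == "C", bath.sigma_mu, rate_area, bath.lambda_mu)
        if status < 0:
            raise StepSizeError("collision cascade exceeded the iteration cap")
        Xs[r] = Xr
        Vs[r] = Vr
        totals += ctr
    times = np.arange(n_save) * dt * save_every
    return TrajectoryEnsemble(
        times=times, X=Xs, V=Vs,
        meta={"model": model, "mu": mu, "gamma": gamma, "D": D, "R": R,
              "dt": dt, "seed": seed, "collisions": int(totals[0]),
              "removed": int(totals[1]), "inserted": int(totals[2])})
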