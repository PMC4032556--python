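"""One-dimensional MD heat-bath engine (model A) on the interval [-L, L].

One iteration performs: free flight of all particles, chronological exact
resolution of heavy–bath collisions, removal of bath particles that left
the domain, and a Bernoulli boundary influx at each end with per-step
probability ``gamma*(mu+1)*dt/8``.  Inserted particles have their position
drawn from the one-step penetration profile ``erfc(|x-b| / (sigma*dt*sqrt(2)))``
and their velocity from the matching one-sided truncated Maxwellian, so the
finite domain is statistically indistinguishable from an infinite
equilibrium bath.

Equal-mass bath–bath collisions exchange velocities, which is a relabeling
of free-flight paths: the unordered set of (position, velocity) pairs, the
heavy-particle dynamics and the boundary fluxes are identical whether or
not the relabeling (a sort) is carried out, so the engine omits it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .collisions import _collide_1d
from .errors import ParameterError, StateError, StepSizeError
from .harness import TrajectoryEnsemble
from .params import (BathParams, _erfc_sample_scalar, _truncnorm_scalar,
                     DEFAULT_ENVELOPE, bath_parameters)

__all__ = [
    "HeatBathState1D",
    "HeavyState1D",
    "influx_probability",
    "influx_position_sample",
    "influx_velocity_sample",
    "equilibrium_bath_1d",
    "md_step_A",
    "run_model_A",
]

_SQRT2 = math.sqrt(2.0)
_A1 = DEFAULT_ENVELOPE.a1
_A2 = DEFAULT_ENVELOPE.a2

#: iteration cap for the within-step collision cascade
_EVENT_CAP = 10000


@dataclass
class HeatBathState1D:
    """Positions and velocities of the currently simulated bath particles."""

    positions: np.ndarray
    velocities: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.positions.shape != self.velocities.shape:
            raise StateError("positions and velocities must have equal length")

    @property
    def n(self) -> int:
        return self.positions.size


@dataclass
class HeavyState1D:
    """Heavy-particle position, velocity and radius."""

    X: float
    V: float
    R: float = 0.0


def influx_probability(gamma: float, mu: float, dt: float) -> float:
    """Per-step probability ``gamma*(mu+1)*dt/8`` of one insertion per side.

    This equals the mean number of equilibrium bath particles that cross a
    fixed point during one step of length ``dt``; it must be well below 1
    for the Bernoulli single-insertion rule to be valid.

    Raises
    ------
    StepSizeError
        If the value reaches 1.
    """
    if dt < 0:
        raise ParameterError("dt must be non-negative")
    p = gamma * (mu + 1.0) * dt / 8.0
    if p >= 1.0:
        raise StepSizeError(f"influx probability {p:.3g} >= 1; reduce dt")
    return p


def influx_position_sample(rng: np.random.Generator, b: float, side: str,
                           bath: BathParams, dt: float) -> float:
    """Position of a particle inserted at boundary ``b``.

    The one-step penetration depth ``|x - b|`` is ``sigma*dt*sqrt(2)`` times
    an erfc-distributed variate; ``side='left'`` inserts into ``x > b``,
    ``side='right'`` into ``x < b``.
    """
    z, _ = _erfc_sample_scalar(rng, _A1, _A2)
    depth = _SQRT2 * bath.sigma_mu * dt * z
    return b + depth if side == "left" else b - depth


def influx_velocity_sample(rng: np.random.Generator, x: float, b: float,
                           side: str, bath: BathParams, dt: float) -> float:
    """Velocity of a particle inserted at position ``x`` near boundary ``b``.

    Maxwellian ``Normal(0, sigma^2)`` restricted to the half-line consistent
    with having crossed ``b`` during the step: ``v > (x-b)/dt`` for a left
    insertion, mirrored for a right one.
    """
    cut = (x - b) / dt
    if side == "left":
        return _truncnorm_scalar(rng, bath.sigma_mu, cut, True)
    return _truncnorm_scalar(rng, bath.sigma_mu, cut, False)


def equilibrium_bath_1d(rng: np.random.Generator, bath: BathParams,
                        lo: float, hi: float) -> HeatBathState1D:
    """Equilibrium bath field on ``[lo, hi]``: Poisson positions, Maxwellian
    velocities."""
    n = rng.poisson(bath.lambda_mu * (hi - lo))
    xs = rng.uniform(lo, hi, size=n)
    vs = bath.sigma_mu * rng.standard_normal(n)
    return HeatBathState1D(xs, vs)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _resolve_collisions_1d(xs, vs, n, X, V, mu, Reff, dt):
    """Advance everything to t+dt resolving heavy-bath collisions in order.

    The heavy particle occupies (X-Reff, X+Reff); a bath particle collides
    on the face it approaches.  Positions are advanced event by event; bath
    particles not involved fly freely.  Returns (X, V, n_events) with
    n_events = -1 on cascade-cap overflow.
    """
    t_cur = 0.0
    n_events = 0
    for _ in range(_EVENT_CAP):
        s_min = dt - t_cur
        i_min = -1
        for i in range(n):
            rel = vs[i] - V
            if xs[i] >= X + Reff:
                gap = xs[i] - (X + Reff)
            elif xs[i] <= X - Reff:
                gap = xs[i] - (X - Reff)
            else:
                # interior overlap is excluded at initialization; a particle
                # exactly on a face (post-collision) separates by construction
                continue
            # strict approach condition; gap == 0 (touching) is no event
            if rel * gap < 0.0:
                s = -gap / rel
                if s < s_min:
                    s_min = s
                    i_min = i
        if i_min < 0:
            break
        # advance to the event and collide
        for i in range(n):
            xs[i] += vs[i] * s_min
        X += V * s_min
        t_cur += s_min
        Vn, vn = _collide_1d(V, vs[i_min], mu)
        V = Vn
        vs[i_min] = vn
        n_events += 1
    else:
        return X, V, -1
    # free flight over the remainder
    rem = dt - t_cur
    for i in range(n):
        xs[i] += vs[i] * rem
    X += V * rem
    return X, V, n_events


@njit(cache=True)
def _compact_1d(xs, vs, n, lo, hi):
    """Drop particles outside [lo, hi]; returns (new_n, n_removed)."""
    k = 0
    for i in range(n):
        if lo <= xs[i] <= hi:
            xs[k] = xs[i]
            vs[k] = vs[i]
            k += 1
    return k, n - k


@njit(cache=True)
def _influx_1d(rng, xs, vs, n, b, left, sigma, dt, a1, a2):
    """Insert one boundary particle (left=True: into x>b, else into x<b)."""
    z, _ = _erfc_sample_scalar(rng, a1, a2)
    depth = _SQRT2 * sigma * dt * z
    if left:
        x = b + depth
        v = _truncnorm_scalar(rng, sigma, depth / dt, True)
    else:
        x = b - depth
        v = _truncnorm_scalar(rng, sigma, -depth / dt, False)
    xs[n] = x
    vs[n] = v
    return n + 1


@njit(cache=True)
def _md1d_step(rng, xs, vs, n, X, V, mu, Reff, dt, L, sigma, p_influx, a1, a2):
    """One full model-A iteration on [-L, L].

    Returns (X, V, n, n_events, n_removed, ins_left, ins_right).
    """
    X, V, n_events = _resolve_collisions_1d(xs, vs, n, X, V, mu, Reff, dt)
    n, n_removed = _compact_1d(xs, vs, n, -L, L)
    ins_l = 0
    ins_r = 0
    if rng.random() < p_influx and n < xs.shape[0]:
        n = _influx_1d(rng, xs, vs, n, -L, True, sigma, dt, a1, a2)
        ins_l = 1
    if rng.random() < p_influx and n < xs.shape[0]:
        n = _influx_1d(rng, xs, vs, n, L, False, sigma, dt, a1, a2)
        ins_r = 1
    return X, V, n, n_events, n_removed, ins_l, ins_r


@njit(cache=True)
def _run_model_a_single(rng, xs, vs, n, n_steps, save_every, mu, dt, L,
                        sigma, p_influx, a1, a2):
    """One model-A realization from X(0)=V(0)=0; records every save_every."""
    X = 0.0
    V = 0.0
    n_save = n_steps // save_every + 1
    Xs = np.empty(n_save)
    Vs = np.empty(n_save)
    ns = np.empty(n_save, dtype=np.int64)
    Xs[0] = X
    Vs[0] = V
    ns[0] = n
    counters = np.zeros(4, dtype=np.int64)  # events, removed, ins_l, ins_r
    k = 1
    for s in range(1, n_steps + 1):
        X, V, n, nev, nrm, il, ir = _md1d_step(
            rng, xs, vs, n, X, V, mu, 0.0, dt, L, sigma, p_influx, a1, a2)
        if nev < 0:
            return Xs, Vs, ns, counters, -1
        counters[0] += nev
        counters[1] += nrm
        counters[2] += il
        counters[3] += ir
        if s % save_every == 0:
            Xs[k] = X
            Vs[k] = V
            ns[k] = n
            k += 1
    return Xs, Vs, ns, counters, 0


# ---------------------------------------------------------------------------
# public stepping / running interface
# ---------------------------------------------------------------------------

def md_step_A(bath_state: HeatBathState1D, heavy: HeavyState1D,
              bath: BathParams, dt: float, L: float,
              rng: np.random.Generator) -> tuple[HeatBathState1D, HeavyState1D, dict]:
    """One iteration of MD model A on ``[-L, L]``.

    Returns the updated bath state, heavy state and a counter dict
    (``collisions``, ``removed``, ``inserted_left``, ``inserted_right``).

    Raises
    ------
    StepSizeError
        If the influx probability is not below 0.1, or the within-step
        collision cascade exceeds its iteration cap.
    """
    p = influx_probability(bath.gamma, bath.mu, dt)
    if p >= 0.1:
        raise StepSizeError(f"influx probability {p:.3g} >= 0.1; reduce dt")
    cap = bath_state.n + 4
    xs = np.empty(cap)
    vs = np.empty(cap)
    xs[:bath_state.n] = bath_state.positions
    vs[:bath_state.n] = bath_state.velocities
    X, V, n, nev, nrm, il, ir = _md1d_step(
        rng, xs, vs, bath_state.n, heavy.X, heavy.V, bath.mu, 0.0, dt, L,
        bath.sigma_mu, p, _A1, _A2)
    if nev < 0:
        raise StepSizeError("collision cascade exceeded the iteration cap")
    new_bath = HeatBathState1D(xs[:n].copy(), vs[:n].copy())
    new_heavy = HeavyState1D(X=X, V=V, R=heavy.R)
    counters = {"collisions": nev, "removed": nrm,
                "inserted_left": il, "inserted_right": ir}
    return new_bath, new_heavy, counters


def run_model_A(*, mu: float, gamma: float, D: float, L: float, dt: float,
                t_end: float, n_realizations: int, seed: int,
                save_every: int | None = None,
                guard_band: float = 2.0) -> TrajectoryEnsemble:
    """Ensemble of heavy-particle trajectories in the full 1-D bath.

    Every realization starts from ``X(0)=0``, ``V(0)=0`` in an independent
    equilibrium bath field on ``[-L, L]`` and uses its own spawned RNG
    stream.

    Parameters
    ----------
    mu, gamma, D : float
        Bath model A parameters.
    L : float
        Domain half-width.
    dt, t_end : float
        Time step and final time.
    n_realizations, seed : int
    save_every : int, optional
        Record every this many steps (default: ~100 samples per run).
    guard_band : float
        Warn if the heavy particle comes within this distance of a boundary.
    """
    bath = bath_parameters("A", mu, gamma, D)
    p = influx_probability(gamma, mu, dt)
    if p >= 0.1:
        raise StepSizeError(f"influx probability {p:.3g} >= 0.1; reduce dt")
    n_steps = int(round(t_end / dt))
    if save_every is None:
        save_every = max(1, n_steps // 100)
    mean_n = 2.0 * L * bath.lambda_mu
    cap = int(mean_n + 10.0 * math.sqrt(mean_n) + 64)

    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(seed).spawn(n_realizations)]
    n_save = n_steps // save_every + 1
    Xs = np.empty((n_realizations, n_save))
    Vs = np.empty((n_realizations, n_save))
    counts = np.empty((n_realizations, n_save), dtype=np.int64)
    totals = np.zeros(4, dtype=np.int64)
    for r, rng in enumerate(streams):
        xs = np.empty(cap)
        vs = np.empty(cap)
        n0 = rng.poisson(mean_n)
        if n0 > cap:
            n0 = cap
        xs[:n0] = rng.uniform(-L, L, size=n0)
        vs[:n0] = bath.sigma_mu * rng.standard_normal(n0)
        Xr, Vr, nr, ctr, status = _run_model_a_single(
            rng, xs, vs, n0, n_steps, save_every, bath.mu, dt, L,
            bath.sigma_mu, p, _A1, _A2)
        if status < 0:
            raise StepSizeError("collision cascade exceeded the iteration cap")
        Xs[r] = Xr
        Vs[r] = Vr
        counts[r] = nr
        totals += ctr
    if np.max(np.abs(Xs)) > L - guard_band:
        warnings.warn("heavy particle entered the boundary guard band; "
                      "domain statistics may be perturbed", RuntimeWarning)
    times = np.arange(n_save) * dt * save_every
    return TrajectoryEnsemble(
        times=times, X=Xs[..., None], V=Vs[..., None],
        meta={"model": "A", "mu": mu, "gamma": gamma, "D": D, "L": L,
              "dt": dt, "seed": seed, "bath_counts": counts,
              "collisions": int(totals[0]), "removed": int(totals[1]),
              "inserted_left": int(totals[2]), "inserted_right": int(totals[3])})
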