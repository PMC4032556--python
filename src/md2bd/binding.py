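"""Protein binding to a reactive membrane: three-regime hybrid simulation
and its mean-field PDE reference.

A protein sphere (radius ``R``) diffuses in a cuboid whose face ``x1 = 0``
is a membrane carrying receptors.  On contact (centre at ``x1 = R``) the
protein binds with probability ``P = K sqrt(2 pi/(D gamma))`` and is
otherwise specularly reflected.  Three descriptions are stitched along
``x1``:

* ``x1 < h``: MD model B in a moving window hugging the membrane, coupled
  across the interface at ``x1 = h`` by the cap drift/noise correction;
* ``h <= x1 <= h3``: velocity Langevin dynamics with the MD time step;
* ``x1 >= h2``: the overdamped model with a larger step ``dt_bar``.

The Langevin and overdamped regions overlap on ``[h2, h3]``; the time
variable is shifted by ``t* = 3/(2 gamma)`` at every switch between the
two BD levels (subtracted on entering the Langevin level, added back on
leaving), matching the large-time lag of the velocity model behind the
overdamped one.

The mean-field limit of the protein's ``x1``-marginal is the 1-D diffusion
equation with a Robin (partially absorbing) condition at the contact plane
and a no-flux condition at the far wall; it is solved here with
Crank–Nicolson and serves as the reference for the particle model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.linalg import solve_banded

from .bd import t_star
from .errors import GeometryError, ParameterError, StepSizeError
from .md3d import (_compact_3d, _fill_region, _influx_all_faces,
                   _maybe_shift_window, _resolve_3d, influx_count_3d)
from .coupling import _alpha_3d, _beta_3d
from .params import bath_parameters

__all__ = [
    "AppGeometry",
    "ReactiveBoundary",
    "reaction_probability",
    "pde_reference",
    "simulate_binding",
    "BindingResult",
]


@dataclass(frozen=True)
class AppGeometry:
    """Cuboid geometry of the binding problem.

    ``0 < h < h2 < h3 < L1`` are the MD interface, the inner and outer
    edges of the Langevin/overdamped overlap, and the far wall; ``h4`` is
    the lateral half-width of the moving MD window.
    """

    L1: float
    h: float
    h2: float
    h3: float
    h4: float
    R: float

    def __post_init__(self) -> None:
        if not 0 < self.h < self.h2 < self.h3 < self.L1:
            raise GeometryError("need 0 < h < h2 < h3 < L1")
        if not 0 < self.R < self.h:
            raise GeometryError("need 0 < R < h")
        if self.h4 <= self.R:
            raise GeometryError("lateral window half-width must exceed R")


@dataclass(frozen=True)
class ReactiveBoundary:
    """Per-hit binding probability and the matching Robin rate constant."""

    P: float
    K: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.P <= 1.0:
            raise ParameterError("P must lie in [0, 1]")


def reaction_probability(K: float, D: float, gamma: float) -> ReactiveBoundary:
    """Per-contact binding probability ``P = K sqrt(2 pi/(D gamma))``.

    A Maxwellian flux of proteins with velocity scale ``sqrt(D gamma)``
    hitting a surface that binds each hit with probability ``P`` absorbs
    mass at rate ``K rho``, which is the Robin condition of the mean-field
    model.

    Raises
    ------
    ParameterError
        If the resulting probability exceeds 1.
    """
    if K < 0 or D <= 0 or gamma <= 0:
        raise ParameterError("K must be >= 0 and D, gamma > 0")
    P = K * math.sqrt(2.0 * math.pi / (D * gamma))
    if P > 1.0:
        raise ParameterError(f"P = {P:.3g} > 1; reduce K or increase D*gamma")
    return ReactiveBoundary(P=P, K=K)


# ---------------------------------------------------------------------------
# PDE reference
# ---------------------------------------------------------------------------

def pde_reference(K: float, D: float, length: float, n_grid: int, T: float,
                  n_times: int = 101, cfl: float = 2.0):
    """Crank–Nicolson solution of ``rho_t = D rho_xx`` on ``[0, length]``.

    Boundary conditions: Robin ``D rho_x(0) = K rho(0)`` (partially
    absorbing membrane) and no-flux at ``x = length``; uniform initial
    condition normalised to unit mass.

    Returns
    -------
    x : grid, shape (n_grid,)
    times : shape (n_times,)
    rho : shape (n_times, n_grid)
    bound : shape (n_times,)
        Absorbed probability ``K * int rho(0, s) ds`` (trapezoidal in
        time, consistent with the scheme: interior + absorbed mass is
        conserved to solver precision).
    """
    if n_grid < 10:
        raise ParameterError("n_grid too small")
    x = np.linspace(0.0, length, n_grid)
    dx = x[1] - x[0]
    dt = cfl * dx * dx / D          # CN is unconditionally stable; dt set by accuracy
    n_steps_total = max(int(math.ceil(T / dt)), n_times - 1)
    # align steps with output times
    per = max(1, int(math.ceil(n_steps_total / (n_times - 1))))
    dt = T / ((n_times - 1) * per)

    # semi-discrete operator A (rho' = A rho) with ghost-node BCs
    main = np.full(n_grid, -2.0 * D / dx ** 2)
    off = np.full(n_grid - 1, D / dx ** 2)
    # Robin at 0: rho_-1 = rho_1 - 2 dx (K/D) rho_0
    main[0] = -2.0 * D / dx ** 2 - 2.0 * K / dx
    upper = off.copy()
    upper[0] = 2.0 * D / dx ** 2
    lower = off.copy()
    lower[-1] = 2.0 * D / dx ** 2
    # banded matrices for (I - dt/2 A) rho^{n+1} = (I + dt/2 A) rho^n
    ab = np.zeros((3, n_grid))
    ab[0, 1:] = -0.5 * dt * upper
    ab[1, :] = 1.0 - 0.5 * dt * main
    ab[2, :-1] = -0.5 * dt * lower

    rho = np.full(n_grid, 1.0 / length)
    times = np.linspace(0.0, T, n_times)
    out = np.empty((n_times, n_grid))
    out[0] = rho
    bound = np.zeros(n_times)
    absorbed = 0.0
    k = 1
    for step in range((n_times - 1) * per):
        rhs = rho.copy()
        rhs[1:-1] += 0.5 * dt * (lower[:-1] * rho[:-2] + main[1:-1] * rho[1:-1]
                                 + upper[1:] * rho[2:])
        rhs[0] += 0.5 * dt * (main[0] * rho[0] + upper[0] * rho[1])
        rhs[-1] += 0.5 * dt * (lower[-1] * rho[-2] + main[-1] * rho[-1])
        new = solve_banded((1, 1), ab, rhs)
        absorbed += K * 0.5 * dt * (rho[0] + new[0])
        rho = new
        if (step + 1) % per == 0:
            out[k] = rho
            bound[k] = absorbed
            k += 1
    return x, times, out, bound


# ---------------------------------------------------------------------------
# particle simulation
# ---------------------------------------------------------------------------

@njit(cache=True)
def _binding_single(rng, ps, vs, cps, mu, gamma, D, R, P, L1, h, h2, h3, h4,
                    h_on, h_off, dt, dt_bar, tstar, sig, lam, rate_area,
                    x1_init, use_md):
    """One protein realization; returns (X1 at checkpoints, bound time,
    status).  Unbound realizations report NaN as bound time; checkpoints
    after binding report NaN positions.  With use_md False the membrane
    layer runs pure Langevin dynamics instead of the MD bath (ablation
    mode used to check that the coupling is unbiased)."""
    ncp = cps.shape[0]
    rec = np.full(ncp, np.nan)
    X = np.zeros(3)
    V = np.zeros(3)
    lo = np.zeros(3)
    hi = np.zeros(3)
    X[0] = x1_init
    n = 0
    sd = math.sqrt(D * gamma)
    if X[0] >= h2:
        mode = 0
        t = 0.0
    else:
        mode = 1
        t = -tstar
        V[0] = sd * rng.standard_normal()
        V[1] = sd * rng.standard_normal()
        V[2] = sd * rng.standard_normal()
        if X[0] < h_on:
            mode = 2
            if use_md:
                lo[0] = 0.0
                hi[0] = h
                lo[1] = X[1] - h4
                hi[1] = X[1] + h4
                lo[2] = X[2] - h4
                hi[2] = X[2] + h4
                n = _fill_region(rng, ps, vs, 0, lo, hi, hi, lo - 1.0, lam,
                                 sig, False, X, R)
    k = 0
    while k < ncp and t < cps[ncp - 1]:
        if mode == 0:
            amp = math.sqrt(2.0 * D * dt_bar)
            X[0] += amp * rng.standard_normal()
            X[1] += amp * rng.standard_normal()
            X[2] += amp * rng.standard_normal()
            if X[0] > L1:
                X[0] = 2.0 * L1 - X[0]
            t += dt_bar
            if X[0] < h2:
                mode = 1
                t -= tstar
                V[0] = sd * rng.standard_normal()
                V[1] = sd * rng.standard_normal()
                V[2] = sd * rng.standard_normal()
        elif mode == 1:
            X[0] += V[0] * dt
            X[1] += V[1] * dt
            X[2] += V[2] * dt
            amp = gamma * math.sqrt(2.0 * D * dt)
            V[0] += -gamma * V[0] * dt + amp * rng.standard_normal()
            V[1] += -gamma * V[1] * dt + amp * rng.standard_normal()
            V[2] += -gamma * V[2] * dt + amp * rng.standard_normal()
            if X[0] > L1:
                X[0] = 2.0 * L1 - X[0]
                V[0] = -V[0]
            t += dt
            if X[0] > h3:
                mode = 0
                t += tstar
            elif X[0] < h_on:
                mode = 2
                if use_md:
                    lo[0] = 0.0
                    hi[0] = h
                    lo[1] = X[1] - h4
                    hi[1] = X[1] + h4
                    lo[2] = X[2] - h4
                    hi[2] = X[2] + h4
                    n = _fill_region(rng, ps, vs, 0, lo, hi, hi, lo - 1.0,
                                     lam, sig, False, X, R)
        elif not use_md:
            # ablation: pure Langevin with exact membrane contact handling
            V00 = V[0]
            V01 = V[1]
            V02 = V[2]
            if V[0] < 0.0 and X[0] + V[0] * dt < R:
                s_mem = (R - X[0]) / V[0]
                X[1] += V[1] * s_mem
                X[2] += V[2] * s_mem
                X[0] = R
                if rng.random() < P:
                    t += s_mem
                    return rec, t, 0
                V[0] = -V[0]
                X[0] += V[0] * (dt - s_mem)
                X[1] += V[1] * (dt - s_mem)
                X[2] += V[2] * (dt - s_mem)
            else:
                X[0] += V[0] * dt
                X[1] += V[1] * dt
                X[2] += V[2] * dt
            amp = gamma * math.sqrt(2.0 * D * dt)
            V[0] += -gamma * V00 * dt + amp * rng.standard_normal()
            V[1] += -gamma * V01 * dt + amp * rng.standard_normal()
            V[2] += -gamma * V02 * dt + amp * rng.standard_normal()
            t += dt
            if X[0] > h_off:
                mode = 1
        else:
            X0 = X[0]
            V00 = V[0]
            V01 = V[1]
            V02 = V[2]
            nev, bound, t_b, status = _resolve_3d(rng, ps, vs, n, X, V, mu, R,
                                                  dt, True, 0.0, P)
            if status < 0:
                return rec, np.nan, -1
            if bound:
                t += t_b
                return rec, t, 0
            n, _ = _compact_3d(ps, vs, n, lo, hi, True)
            n, _ = _maybe_shift_window(rng, ps, vs, n, lo, hi, X, R, 0.5,
                                       lam, sig, False)
            n, _ = _influx_all_faces(rng, ps, vs, n, lo, hi, False, sig, dt,
                                     rate_area, X, R, True, False)
            s = X0 - h
            if -R < s < R:
                a0, a1, a2 = _alpha_3d(s, V00, V01, V02, gamma, D, mu, R, False)
                b11, bl = _beta_3d(s, gamma, D, R)
                sq = math.sqrt(dt)
                V[0] += a0 * dt + b11 * sq * rng.standard_normal()
                V[1] += a1 * dt + bl * sq * rng.standard_normal()
                V[2] += a2 * dt + bl * sq * rng.standard_normal()
            elif s >= R:
                amp = gamma * math.sqrt(2.0 * D * dt)
                V[0] += -gamma * V00 * dt + amp * rng.standard_normal()
                V[1] += -gamma * V01 * dt + amp * rng.standard_normal()
                V[2] += -gamma * V02 * dt + amp * rng.standard_normal()
            t += dt
            if X[0] > h_off:
                mode = 1
                n = 0
        while k < ncp and t >= cps[k]:
            rec[k] = X[0]
            k += 1
    return rec, np.nan, 0


@dataclass
class BindingResult:
    """Output of :func:`simulate_binding`."""

    checkpoint_times: np.ndarray
    X1: np.ndarray                   # (n_real, n_checkpoints), NaN once bound
    bound_times: np.ndarray          # (n_real,), NaN when unbound
    bound_prob: np.ndarray           # fraction bound by each checkpoint
    bound_se: np.ndarray
    meta: dict = field(default_factory=dict)


def simulate_binding(*, K: float, D: float, gamma: float, mu: float,
                     R: float = 1.0, L1: float = 100.0, h: float = 4.0,
                     h2: float = 8.0, h3: float = 12.0, h4: float = 3.0,
                     dt: float, dt_bar: float, t_end: float,
                     n_realizations: int, seed: int,
                     n_checkpoints: int = 11,
                     md_layer: str = "full") -> BindingResult:
    """Three-regime hybrid simulation of protein binding to the membrane.

    Initial centre positions are uniform on ``[R, L1]`` along ``x1`` (the
    mean-field reference uses the matching contact coordinate
    ``x1 - R in [0, L1 - R]``).  Each realization runs on its own spawned
    RNG stream until bound or past the last checkpoint.

    ``md_layer='langevin'`` replaces the explicit MD bath near the
    membrane by pure Langevin dynamics (ablation mode): a consistency
    control for the MD/BD coupling, which must reproduce the same
    statistics within Monte-Carlo error.
    """
    if md_layer not in ("full", "langevin"):
        raise ParameterError("md_layer must be 'full' or 'langevin'")
    geom = AppGeometry(L1=L1, h=h, h2=h2, h3=h3, h4=h4, R=R)
    boundary = reaction_probability(K, D, gamma)
    bath = bath_parameters("B", mu, gamma, D, R)
    p_step = influx_count_3d(gamma, mu, dt, R, 1.0)
    # buffer beyond which the bath need not exist: sphere cannot touch it
    h_on = h + R + 0.5
    h_off = h_on + 0.5
    if h_off >= h3:
        raise GeometryError("buffer overlaps the outer Langevin interface")
    vol = h * (2.0 * h4) ** 2
    mean_n = bath.lambda_mu * vol
    cap = int(mean_n + 10.0 * math.sqrt(mean_n) + 256)
    cps = np.linspace(0.0, t_end, n_checkpoints)

    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(seed).spawn(n_realizations)]
    X1 = np.empty((n_realizations, n_checkpoints))
    bound_times = np.empty(n_realizations)
    for r, rng in enumerate(streams):
        ps = np.empty((cap, 3))
        vs = np.empty((cap, 3))
        x1_init = rng.uniform(R, L1)
        rec, t_b, status = _binding_single(
            rng, ps, vs, cps, bath.mu, gamma, D, R, boundary.P, L1, h, h2,
            h3, h4, h_on, h_off, dt, dt_bar, t_star(gamma), bath.sigma_mu,
            bath.lambda_mu, p_step, x1_init, md_layer == "full")
        if status < 0:
            raise StepSizeError("collision cascade exceeded the iteration cap")
        X1[r] = rec
        bound_times[r] = t_b
    is_bound = ~np.isnan(bound_times)
    bound_prob = np.array([np.mean(is_bound & (bound_times <= c)) for c in cps])
    bound_se = np.sqrt(bound_prob * (1.0 - bound_prob) / n_realizations)
    return BindingResult(
        checkpoint_times=cps, X1=X1, bound_times=bound_times,
        bound_prob=bound_prob, bound_se=bound_se,
        meta={"K": K, "D": D, "gamma": gamma, "mu": mu, "R": R, "L1": L1,
              "h": h, "h2": h2, "h3": h3, "h4": h4, "dt": dt,
              "dt_bar": dt_bar, "seed": seed, "P": boundary.P,
              "n_realizations": n_realizations})
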