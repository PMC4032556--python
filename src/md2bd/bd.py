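"""Brownian-dynamics integrators and the closed-form references.

Two BD levels are used throughout:

* velocity Langevin dynamics ``dX = V dt``, ``dV = -gamma V dt +
  gamma*sqrt(2D) dW`` integrated by Euler–Maruyama with step ``dt``;
* the overdamped (Smoluchowski) limit ``dX = sqrt(2D) dW`` integrated
  exactly with a larger step ``dt_bar``.

The per-component mean squared displacement of the Langevin model,

``MSD(t) = 2Dt - 3D/gamma + 4D e^{-gamma t}/gamma - D e^{-2 gamma t}/gamma``,

approaches ``2D(t - t*)`` with the time shift ``t* = 3/(2 gamma)``; for
``t >> 1/gamma`` the position is Gaussian with variance ``2D(t - t*)``.
The shift ``t*`` is the bookkeeping constant used when switching between
the two BD levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import ParameterError

__all__ = [
    "BDParams",
    "langevin_step",
    "overdamped_step",
    "msd_langevin",
    "msd_langevin_linear",
    "t_star",
    "shifted_gaussian_density",
    "run_langevin_ensemble",
]


@dataclass(frozen=True)
class BDParams:
    """Friction/diffusion coefficients and the two integrator steps."""

    gamma: float
    D: float
    dt: float
    dt_bar: float | None = None

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.D <= 0 or self.dt <= 0:
            raise ParameterError("gamma, D and dt must be positive")
        if self.gamma * self.dt >= 0.1:
            raise ParameterError("explicit scheme requires gamma*dt < 0.1")
        if self.dt_bar is not None and self.dt_bar < self.dt:
            raise ParameterError("dt_bar must be >= dt")


@njit(cache=True)
def _langevin_step_scalar(X, V, gamma, D, dt, xi):
    Vn = V - gamma * V * dt + gamma * math.sqrt(2.0 * D * dt) * xi
    return X + V * dt, Vn


def langevin_step(X, V, params: BDParams, rng: np.random.Generator):
    """One Euler–Maruyama step of the velocity Langevin equation.

    ``V' = V - gamma*V*dt + gamma*sqrt(2*D*dt)*xi`` per component and
    ``X' = X + V*dt`` (position advanced with the pre-step velocity).
    Works on scalars or same-shape arrays.
    """
    X = np.asarray(X, dtype=float)
    V = np.asarray(V, dtype=float)
    xi = rng.standard_normal(V.shape) if V.shape else rng.standard_normal()
    Vn = V - params.gamma * V * params.dt + params.gamma * math.sqrt(
        2.0 * params.D * params.dt) * xi
    Xn = X + V * params.dt
    if X.shape == ():
        return float(Xn), float(Vn)
    return Xn, Vn


def overdamped_step(X, D: float, dt_bar: float, rng: np.random.Generator):
    """One step of the overdamped model: Gaussian increment, variance
    ``2*D*dt_bar`` per component (exact in distribution)."""
    X = np.asarray(X, dtype=float)
    xi = rng.standard_normal(X.shape) if X.shape else rng.standard_normal()
    Xn = X + math.sqrt(2.0 * D * dt_bar) * xi
    return float(Xn) if X.shape == () else Xn


def msd_langevin(t, D: float, gamma: float):
    """Per-component mean squared displacement of the Langevin model.

    ``2Dt - 3D/g + 4D exp(-g t)/g - D exp(-2 g t)/g``; vanishes at ``t=0``.
    """
    t = np.asarray(t, dtype=float)
    out = (2.0 * D * t - 3.0 * D / gamma
           + 4.0 * D * np.exp(-gamma * t) / gamma
           - D * np.exp(-2.0 * gamma * t) / gamma)
    return float(out) if out.shape == () else out


def msd_langevin_linear(t, D: float, gamma: float):
    """Linear large-time approximation ``2D(t - 3/(2 gamma))``."""
    t = np.asarray(t, dtype=float)
    out = 2.0 * D * (t - 1.5 / gamma)
    return float(out) if out.shape == () else out


def t_star(gamma: float) -> float:
    """The Langevin-to-overdamped time shift ``t* = 3/(2 gamma)``."""
    return 1.5 / gamma


def shifted_gaussian_density(x, t: float, D: float, gamma: float):
    """Large-time position density of a Langevin particle started at rest,

    ``rho(x, t) = exp(-x^2 / (4D(t-t*))) / sqrt(4 pi D (t-t*))``,

    valid for ``t >> 1/gamma``.

    Raises
    ------
    ParameterError
        If ``t <= t* = 3/(2 gamma)`` (the variance would be non-positive).
    """
    ts = t_star(gamma)
    if t <= ts:
        raise ParameterError(f"density defined only for t > t* = {ts}")
    x = np.asarray(x, dtype=float)
    var = 2.0 * D * (t - ts)
    out = np.exp(-x * x / (2.0 * var)) / math.sqrt(2.0 * math.pi * var)
    return float(out) if out.shape == () else out


@njit(cache=True)
def _langevin_paths(rng, n_real, n_steps, save_every, gamma, D, dt):
    n_save = n_steps // save_every + 1
    Xs = np.empty((n_real, n_save))
    Vs = np.empty((n_real, n_save))
    for r in range(n_real):
        X = 0.0
        V = 0.0
        Xs[r, 0] = X
        Vs[r, 0] = V
        k = 1
        for s in range(1, n_steps + 1):
            X, V = _langevin_step_scalar(X, V, gamma, D, dt, rng.standard_normal())
            if s % save_every == 0:
                Xs[r, k] = X
                Vs[r, k] = V
                k += 1
    return Xs, Vs


def run_langevin_ensemble(rng: np.random.Generator, n_real: int, t_end: float,
                          params: BDParams, save_every: int = 1):
    """Ensemble of 1-D Langevin paths from rest; returns ``(times, X, V)``.

    Used as the BD reference in tests and the hybrid comparisons.
    """
    n_steps = int(round(t_end / params.dt))
    Xs, Vs = _langevin_paths(rng, int(n_real), n_steps, int(save_every),
                             params.gamma, params.D, params.dt)
    times = np.arange(Xs.shape[1]) * params.dt * save_every
    return times, Xs, Vs
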