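"""MD/BD interface coupling: drift and noise corrections for a heavy
particle straddling the interface, and the hybrid stepping algorithms.

When the heavy particle overlaps the interface between the MD subdomain
(bath simulated explicitly) and the BD subdomain (bath absent), the
collisions it would have received from the BD side are replaced by a
velocity correction applied once per step,

``V(t+dt) = V~(t+dt) + alpha(V(t)) dt + beta(V(t)) sqrt(dt) xi``,

where ``V~`` is the post-collision velocity from the simulated side.  In
1-D the one-sided coefficients are exact integrals over the unsimulated
equilibrium bath:

``alpha(V) = -(lam/(mu+1)) [ (sig^2+V^2) erfc(-V/(sig sqrt2))
                             + V sig sqrt(2/pi) exp(-V^2/(2 sig^2)) ]``

``beta^2(V) = (2 lam/(mu+1)^2) [ V (3 sig^2+V^2) erfc(-V/(sig sqrt2))
                                 + sqrt(2/pi) (2 sig^2+V^2) sig
                                   exp(-V^2/(2 sig^2)) ]``

with ``lam = lambda_mu`` and ``sig = sigma_mu``.  Their sum over both
sides recovers the Langevin drift ``-gamma V`` and noise ``gamma sqrt(2D)``
in the ``mu -> infinity`` limit.

In 3-D the corrections depend on how deep the sphere centre sits in the BD
half space (coordinate ``X1 in [-R, R]``, MD at ``x1 < 0``); the closed
forms are surface integrals over the spherical cap exposed to the BD side
and interpolate continuously between zero (sphere fully in MD) and the
full Langevin coefficients (sphere fully in BD).  The noise matrix is
diagonal and evaluated at ``V = 0``.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from numba import njit
from scipy import integrate

from .errors import ParameterError, StepSizeError
from .harness import TrajectoryEnsemble
from .md1d import _compact_1d, _influx_1d, _resolve_collisions_1d, influx_probability
from .md3d import (_fill_region, _influx_all_faces, _maybe_shift_window,
                   _compact_3d, _resolve_3d)
from .params import BathParams, DEFAULT_ENVELOPE, bath_parameters

__all__ = [
    "alpha_exact_1d",
    "beta_exact_1d",
    "taylor_coeffs_1d",
    "combined_sde_coeffs_1d",
    "alpha_3d",
    "beta_3d",
    "surface_quadrature_oracle",
    "hybrid_step_1d",
    "hybrid_step_3d",
    "run_hybrid_1d",
    "run_hybrid_3d",
]

_SQRT2 = math.sqrt(2.0)
_SQRT_2_PI = math.sqrt(2.0 / math.pi)
_A1 = DEFAULT_ENVELOPE.a1
_A2 = DEFAULT_ENVELOPE.a2


# ---------------------------------------------------------------------------
# one-dimensional coefficients (model A)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _alpha_1d(V, lam, sig, mu):
    e = math.erfc(-V / (sig * _SQRT2))
    g = math.exp(-V * V / (2.0 * sig * sig))
    return -lam / (mu + 1.0) * ((sig * sig + V * V) * e
                                + V * sig * _SQRT_2_PI * g)


@njit(cache=True)
def _beta2_1d(V, lam, sig, mu):
    e = math.erfc(-V / (sig * _SQRT2))
    g = math.exp(-V * V / (2.0 * sig * sig))
    return 2.0 * lam / ((mu + 1.0) ** 2) * (
        V * (3.0 * sig * sig + V * V) * e
        + _SQRT_2_PI * (2.0 * sig * sig + V * V) * sig * g)


def _require_model_a(bath: BathParams) -> None:
    if bath.model != "A":
        raise ParameterError("the 1-D coefficients require bath model A")


def alpha_exact_1d(V: float, bath: BathParams) -> float:
    """Exact one-sided drift on a heavy particle at the interface.

    Accounts for the collisions it would receive from the unsimulated
    equilibrium bath on its right; ``alpha(0) = -lambda_mu sigma_mu^2/(mu+1)``.
    """
    _require_model_a(bath)
    return _alpha_1d(float(V), bath.lambda_mu, bath.sigma_mu, bath.mu)


def beta_exact_1d(V: float, bath: BathParams) -> float:
    """Exact one-sided noise amplitude; ``beta(0) = gamma sqrt(D)``."""
    _require_model_a(bath)
    return math.sqrt(_beta2_1d(float(V), bath.lambda_mu, bath.sigma_mu, bath.mu))


def taylor_coeffs_1d(V: float, bath: BathParams) -> tuple[float, float]:
    """Leading-order expansions of the one-sided coefficients for mu >> 1:

    ``alpha ~ -(gamma/4) sqrt(pi (mu+1) D gamma / 2) - (gamma/2) V`` and
    ``beta ~ gamma sqrt(D) + (3/4) sqrt(pi gamma / (2 (mu+1))) V``
    (the remainders are O(V^2 / sqrt(mu+1)) resp. O(V^2)).  Used only as
    cross-checks, never in stepping.
    """
    _require_model_a(bath)
    g, D, mu = bath.gamma, bath.D, bath.mu
    alpha = (-(g / 4.0) * math.sqrt(math.pi * (mu + 1.0) * D * g / 2.0)
             - 0.5 * g * V)
    beta = (g * math.sqrt(D)
            + 0.75 * math.sqrt(math.pi * g / (2.0 * (mu + 1.0))) * V)
    return alpha, beta


def combined_sde_coeffs_1d(V: float, bath: BathParams) -> tuple[float, float]:
    """Two-sided drift and noise from the exact one-sided forms:
    ``drift = alpha(V) - alpha(-V)``, ``noise = sqrt(beta^2(V)+beta^2(-V))``.

    As ``mu -> infinity`` these converge to the Langevin coefficients
    ``-gamma V`` and ``gamma sqrt(2 D)``.
    """
    _require_model_a(bath)
    lam, sig, mu = bath.lambda_mu, bath.sigma_mu, bath.mu
    drift = _alpha_1d(V, lam, sig, mu) - _alpha_1d(-V, lam, sig, mu)
    noise = math.sqrt(_beta2_1d(V, lam, sig, mu) + _beta2_1d(-V, lam, sig, mu))
    return drift, noise


# ---------------------------------------------------------------------------
# three-dimensional coefficients (models B and C)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _alpha_3d(x1, V0, V1, V2, gamma, D, mu, R, model_c):
    q = x1 / R
    if model_c:
        const = -0.5 * gamma * math.sqrt((mu + 1.0) * D * gamma) * (1.0 - q * q)
    else:
        const = -(3.0 * gamma / 8.0) * math.sqrt(
            math.pi * (mu + 1.0) * D * gamma / 2.0) * (1.0 - q * q)
    a0 = const - 0.5 * gamma * V0 * (1.0 + q ** 3)
    lat = 0.25 * gamma * (2.0 + 3.0 * q - q ** 3)
    return a0, -lat * V1, -lat * V2


@njit(cache=True)
def _beta_3d(x1, gamma, D, R):
    q = x1 / R
    b11 = math.sqrt(gamma * gamma * D * (1.0 + q ** 3))
    bl = math.sqrt(gamma * gamma * D * (1.0 + 1.5 * q - 0.5 * q ** 3))
    return b11, bl


def _check_x1(X1: float, R: float) -> None:
    if not -R <= X1 <= R:
        raise ParameterError(f"X1 = {X1} outside the straddling range [-R, R]")


def alpha_3d(X1: float, V, bath: BathParams) -> np.ndarray:
    """Closed-form 3-D drift correction for a sphere with centre depth
    ``X1 in [-R, R]`` into the BD half space.

    At ``X1 = R`` this is the full Langevin drift ``-gamma V``; at
    ``X1 = -R`` it vanishes.  Models B and C differ only in the
    velocity-independent part of the first component.
    """
    if bath.model == "A":
        raise ParameterError("alpha_3d requires bath model B or C")
    _check_x1(X1, bath.R)
    V = np.asarray(V, dtype=float)
    a0, a1, a2 = _alpha_3d(float(X1), V[0], V[1], V[2], bath.gamma, bath.D,
                           bath.mu, bath.R, bath.model == "C")
    return np.array([a0, a1, a2])


def beta_3d(X1: float, bath: BathParams) -> np.ndarray:
    """Closed-form diagonal noise matrix (identical for models B and C),
    evaluated at ``V = 0``: ``gamma sqrt(2D) I`` at ``X1 = R``, zero at
    ``X1 = -R``."""
    if bath.model == "A":
        raise ParameterError("beta_3d requires bath model B or C")
    _check_x1(X1, bath.R)
    b11, bl = _beta_3d(float(X1), bath.gamma, bath.D, bath.R)
    return np.diag([b11, bl, bl])


def surface_quadrature_oracle(X1: float, V, bath: BathParams,
                              n_u: int = 400, n_phi: int = 256
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Independent numerical evaluation of the 3-D coupling coefficients.

    Integrates the per-surface-element mean velocity change over the
    spherical cap exposed to the BD side,

    ``alpha_j = -(2 lam /((mu+1) R)) Int_S (y_j - X_j) [I2 + 2 (V.n) I1] dy``

    ``beta_jj^2 = (4 lam /((mu+1)^2 R^2)) I3 Int_S (y_j - X_j)^2 dy``

    where ``I_k`` is the k-th half-line moment of the bath's normal-speed
    marginal, itself computed by quadrature.  Used only as a test oracle
    for :func:`alpha_3d` / :func:`beta_3d` (to linear order in ``V``).

    Returns ``(alpha, beta_diag)``.
    """
    if bath.model == "A":
        raise ParameterError("the oracle requires bath model B or C")
    _check_x1(X1, bath.R)
    V = np.asarray(V, dtype=float)
    R, lam, sig, mu = bath.R, bath.lambda_mu, bath.sigma_mu, bath.mu

    # half-line moments of the 1-D normal-speed marginal
    if bath.model == "C":
        # component of a fixed-speed isotropic velocity: uniform on [-sig, sig]
        f1 = lambda c: 1.0 / (2.0 * sig)
        upper = sig
    else:
        f1 = lambda c: math.exp(-c * c / (2.0 * sig * sig)) / (
            sig * math.sqrt(2.0 * math.pi))
        upper = np.inf
    I = [integrate.quad(lambda c, k=k: c ** k * f1(c), 0.0, upper)[0]
         for k in range(4)]

    # cap S(X): y = X + R*(u, s cos(phi), s sin(phi)) with y1 > 0
    c0 = -X1 / R
    if c0 >= 1.0:
        return np.zeros(3), np.zeros(3)
    u_nodes, u_w = np.polynomial.legendre.leggauss(n_u)
    u = 0.5 * (u_nodes + 1.0) * (1.0 - c0) + c0
    w_u = 0.5 * (1.0 - c0) * u_w
    phi = 2.0 * math.pi * (np.arange(n_phi) + 0.5) / n_phi
    w_phi = 2.0 * math.pi / n_phi
    s = np.sqrt(np.clip(1.0 - u ** 2, 0.0, None))
    # unit normals n = (y - X)/R on the (u, phi) grid
    n1 = u[:, None] * np.ones_like(phi)[None, :]
    n2 = s[:, None] * np.cos(phi)[None, :]
    n3 = s[:, None] * np.sin(phi)[None, :]
    w2 = (w_u[:, None] * w_phi) * R * R          # surface measure R^2 du dphi
    vdotn = V[0] * n1 + V[1] * n2 + V[2] * n3
    pref = -2.0 * lam / ((mu + 1.0) * R)
    kern = I[2] + 2.0 * vdotn * I[1]
    alpha = np.array([
        pref * np.sum(R * n1 * kern * w2),
        pref * np.sum(R * n2 * kern * w2),
        pref * np.sum(R * n3 * kern * w2),
    ])
    bpref = 4.0 * lam / ((mu + 1.0) ** 2 * R * R) * I[3]
    beta2 = np.array([
        bpref * np.sum((R * n1) ** 2 * w2),
        bpref * np.sum((R * n2) ** 2 * w2),
        bpref * np.sum((R * n3) ** 2 * w2),
    ])
    return alpha, np.sqrt(beta2)


# ---------------------------------------------------------------------------
# hybrid stepping, 1-D
# ---------------------------------------------------------------------------

@njit(cache=True)
def _hybrid1d_step(rng, xs, vs, n, X, V, mu, R, dt, L, sig, lam, p_influx,
                   gamma, D):
    """One iteration of the 1-D hybrid algorithm on Omega = (-L, L) with
    MD in (-L, 0) and BD in (0, L).

    Gating uses the state at the start of the step.  Returns
    (X, V, n, status).
    """
    X0 = X
    V0 = V
    X, V, nev = _resolve_collisions_1d(xs, vs, n, X, V, mu, R, dt)
    if nev < 0:
        return X, V, n, -1
    n, _ = _compact_1d(xs, vs, n, -L, 0.0)
    if rng.random() < p_influx and n < xs.shape[0]:
        n = _influx_1d(rng, xs, vs, n, -L, True, sig, dt, _A1, _A2)
    straddle = -R < X0 < R
    if not straddle:
        if rng.random() < p_influx and n < xs.shape[0]:
            n = _influx_1d(rng, xs, vs, n, 0.0, False, sig, dt, _A1, _A2)
    if straddle:
        a = _alpha_1d(V0, lam, sig, mu)
        b2 = _beta2_1d(V0, lam, sig, mu)
        V = V + a * dt + math.sqrt(b2 * dt) * rng.standard_normal()
    elif X0 >= R:
        V = V - gamma * V0 * dt + gamma * math.sqrt(2.0 * D * dt) * rng.standard_normal()
    return X, V, n, 0


@njit(cache=True)
def _run_hybrid1d_single(rng, xs, vs, n, n_steps, save_every, mu, R, dt, L,
                         sig, lam, p_influx, gamma, D):
    X = 0.0
    V = 0.0
    n_save = n_steps // save_every + 1
    Xs = np.empty(n_save)
    Vs = np.empty(n_save)
    Xs[0] = X
    Vs[0] = V
    k = 1
    for s in range(1, n_steps + 1):
        X, V, n, status = _hybrid1d_step(rng, xs, vs, n, X, V, mu, R, dt, L,
                                         sig, lam, p_influx, gamma, D)
        if status < 0:
            return Xs, Vs, -1
        if s % save_every == 0:
            Xs[k] = X
            Vs[k] = V
            k += 1
    return Xs, Vs, 0


def hybrid_step_1d(bath_state, heavy, bath: BathParams, dt: float, L: float,
                   rng: np.random.Generator):
    """One public iteration of the 1-D hybrid algorithm.

    MD model A runs in ``(-L, 0)``, the Langevin model in ``(0, L)``; the
    interface correction applies while the heavy particle (radius
    ``heavy.R``) straddles the origin.  Returns updated (bath, heavy)
    states; see :func:`run_hybrid_1d` for the ensemble driver.
    """
    from .md1d import HeatBathState1D, HeavyState1D
    p = influx_probability(bath.gamma, bath.mu, dt)
    if p >= 0.1:
        raise StepSizeError(f"influx probability {p:.3g} >= 0.1; reduce dt")
    cap = bath_state.n + 4
    xs = np.empty(cap)
    vs = np.empty(cap)
    xs[:bath_state.n] = bath_state.positions
    vs[:bath_state.n] = bath_state.velocities
    X, V, n, status = _hybrid1d_step(
        rng, xs, vs, bath_state.n, heavy.X, heavy.V, bath.mu, heavy.R, dt,
        L, bath.sigma_mu, bath.lambda_mu, p, bath.gamma, bath.D)
    if status < 0:
        raise StepSizeError("collision cascade exceeded the iteration cap")
    return (HeatBathState1D(xs[:n].copy(), vs[:n].copy()),
            HeavyState1D(X=X, V=V, R=heavy.R))


def hybrid_step_3d(bath_state, heavy, bath: BathParams, dt: float,
                   rng: np.random.Generator):
    """One public iteration of the 3-D hybrid algorithm.

    The MD model (B or C) occupies the bath window, whose high-``x1``
    face is the MD/BD interface; the cap correction applies while
    ``X1`` is within ``R`` of it and the Langevin update beyond.
    Returns updated (bath, heavy) states.
    """
    from .md3d import HeatBathState3D, HeavyState3D, influx_count_3d
    if bath.model == "A":
        raise ParameterError("hybrid_step_3d requires bath model B or C")
    rate_area = influx_count_3d(bath.gamma, bath.mu, dt, bath.R, 1.0)
    lo, hi = bath_state.window
    lo = lo.copy()
    hi = hi.copy()
    cap = bath_state.n + 4 * (64 + int(rate_area * float(np.prod(hi - lo))))
    ps = np.empty((cap, 3))
    vs = np.empty((cap, 3))
    ps[:bath_state.n] = bath_state.positions
    vs[:bath_state.n] = bath_state.velocities
    X = heavy.X.copy()
    V = heavy.V.copy()
    n, status = _hybrid3d_step(
        rng, ps, vs, bath_state.n, X, V, bath.mu, bath.R, dt, lo, hi,
        bath.model == "C", bath.sigma_mu, rate_area, bath.lambda_mu,
        bath.gamma, bath.D, hi[0])
    if status < 0:
        raise StepSizeError("collision cascade exceeded the iteration cap")
    return (HeatBathState3D(ps[:n].copy(), vs[:n].copy(), (lo, hi)),
            HeavyState3D(X=X, V=V, R=heavy.R))


def run_hybrid_1d(*, mu: float, gamma: float, D: float, L: float, R: float,
                  dt: float, t_end: float, n_realizations: int, seed: int,
                  save_every: int | None = None) -> TrajectoryEnsemble:
    """Ensemble of 1-D hybrid trajectories from ``X(0) = V(0) = 0``.

    MD model A runs in ``(-L, 0)``; the Langevin model in ``(0, L)``; the
    interface correction applies while ``X in (-R, R)``.  Initial bath
    fields exclude the interval covered by the heavy particle.
    """
    bath = bath_parameters("A", mu, gamma, D, R)
    p = influx_probability(gamma, mu, dt)
    if p >= 0.1:
        raise StepSizeError(f"influx probability {p:.3g} >= 0.1; reduce dt")
    if not 0 < R < L:
        raise ParameterError("need 0 < R < L")
    n_steps = int(round(t_end / dt))
    if save_every is None:
        save_every = max(1, n_steps // 100)
    mean_n = L * bath.lambda_mu
    cap = int(mean_n + 10.0 * math.sqrt(mean_n) + 64)

    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(seed).spawn(n_realizations)]
    n_save = n_steps // save_every + 1
    Xs = np.empty((n_realizations, n_save))
    Vs = np.empty((n_realizations, n_save))
    for r, rng in enumerate(streams):
        xs = np.empty(cap)
        vs = np.empty(cap)
        # equilibrium field on (-L, -R); (-R, 0) is covered by the particle
        n0 = min(rng.poisson(bath.lambda_mu * (L - R)), cap)
        xs[:n0] = rng.uniform(-L, -R, size=n0)
        vs[:n0] = bath.sigma_mu * rng.standard_normal(n0)
        Xr, Vr, status = _run_hybrid1d_single(
            rng, xs, vs, n0, n_steps, save_every, bath.mu, R, dt, L,
            bath.sigma_mu, bath.lambda_mu, p, gamma, D)
        if status < 0:
            raise StepSizeError("collision cascade exceeded the iteration cap")
        Xs[r] = Xr
        Vs[r] = Vr
    times = np.arange(n_save) * dt * save_every
    return TrajectoryEnsemble(
        times=times, X=Xs[..., None], V=Vs[..., None],
        meta={"kind": "hybrid-1d", "mu": mu, "gamma": gamma, "D": D, "L": L,
              "R": R, "dt": dt, "seed": seed})


# ---------------------------------------------------------------------------
# hybrid stepping, 3-D
# ---------------------------------------------------------------------------

@njit(cache=True)
def _hybrid3d_step(rng, ps, vs, n, X, V, mu, R, dt, lo, hi, model_c, sig,
                   rate_area, lam, gamma, D, interface):
    """One 3-D hybrid iteration: MD window at x1 < interface, BD beyond.

    The x1-high window face sits at the interface; its influx is gated by
    sphere overlap.  Gating of the velocity update uses the state at the
    start of the step.  Returns (n, status).
    """
    X0 = X[0]
    V00 = V[0]
    V01 = V[1]
    V02 = V[2]
    nev, _, _, status = _resolve_3d(rng, ps, vs, n, X, V, mu, R, dt,
                                    False, 0.0, 0.0)
    if status < 0:
        return n, -1
    n, _ = _compact_3d(ps, vs, n, lo, hi, False)
    n, _ = _maybe_shift_window(rng, ps, vs, n, lo, hi, X, R, 0.5, lam, sig,
                               model_c)
    n, _ = _influx_all_faces(rng, ps, vs, n, lo, hi, model_c, sig, dt,
                             rate_area, X, R, False, False)
    s = X0 - interface
    if -R < s < R:
        a0, a1, a2 = _alpha_3d(s, V00, V01, V02, gamma, D, mu, R, model_c)
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
    return n, 0


@njit(cache=True)
def _run_hybrid3d_single(rng, ps, vs, n, n_steps, save_every, mu, R, dt,
                         lo, hi, model_c, sig, rate_area, lam, gamma, D):
    X = np.zeros(3)
    V = np.zeros(3)
    n_save = n_steps // save_every + 1
    Xs = np.empty((n_save, 3))
    Vs = np.empty((n_save, 3))
    Xs[0] = X
    Vs[0] = V
    k = 1
    for s in range(1, n_steps + 1):
        n, status = _hybrid3d_step(rng, ps, vs, n, X, V, mu, R, dt, lo, hi,
                                   model_c, sig, rate_area, lam, gamma, D, 0.0)
        if status < 0:
            return Xs, Vs, -1
        if s % save_every == 0:
            Xs[k] = X
            Vs[k] = V
            k += 1
    return Xs, Vs, 0


def run_hybrid_3d(*, model: str, mu: float, gamma: float, D: float, R: float,
                  depth: float, lateral_half_width: float, dt: float,
                  t_end: float, n_realizations: int, seed: int,
                  save_every: int | None = None) -> TrajectoryEnsemble:
    """Ensemble of 3-D hybrid trajectories from rest at the origin.

    The MD model (B or C) occupies the half space ``x1 < 0``, simulated in
    a window ``[-depth, 0] x [+-lateral_half_width]^2`` that follows the
    sphere laterally; the Langevin model acts for ``X1 >= R`` and the cap
    correction while ``X1 in (-R, R)``.
    """
    bath = bath_parameters(model, mu, gamma, D, R)
    from .md3d import influx_count_3d
    rate_area = influx_count_3d(gamma, mu, dt, R, 1.0)
    n_steps = int(round(t_end / dt))
    if save_every is None:
        save_every = max(1, n_steps // 100)
    W = lateral_half_width
    vol = depth * (2.0 * W) ** 2
    mean_n = bath.lambda_mu * vol
    cap = int(mean_n + 10.0 * math.sqrt(mean_n) + 256)
    empty_lo = np.array([1.0, 1.0, 1.0])
    empty_hi = empty_lo - 2.0

    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(seed).spawn(n_realizations)]
    n_save = n_steps // save_every + 1
    Xs = np.empty((n_realizations, n_save, 3))
    Vs = np.empty((n_realizations, n_save, 3))
    model_c = bath.model == "C"
    for r, rng in enumerate(streams):
        lo = np.array([-depth, -W, -W])
        hi = np.array([0.0, W, W])
        ps = np.empty((cap, 3))
        vs = np.empty((cap, 3))
        n0 = _fill_region(rng, ps, vs, 0, lo, hi, empty_lo, empty_hi,
                          bath.lambda_mu, bath.sigma_mu, model_c,
                          np.zeros(3), R)
        Xr, Vr, status = _run_hybrid3d_single(
            rng, ps, vs, n0, n_steps, save_every, bath.mu, R, dt, lo, hi,
            model_c, bath.sigma_mu, rate_area, bath.lambda_mu, gamma, D)
        if status < 0:
            raise StepSizeError("collision cascade exceeded the iteration cap")
        Xs[r] = Xr
        Vs[r] = Vr
    if np.min(Xs[:, :, 0]) < -depth + R + 0.5:
        warnings.warn("heavy sphere approached the bottom of the MD window",
                      RuntimeWarning)
    times = np.arange(n_save) * dt * save_every
    return TrajectoryEnsemble(
        times=times, X=Xs, V=Vs,
        meta={"kind": "hybrid-3d", "model": bath.model, "mu": mu,
              "gamma": gamma, "D": D, "R": R, "dt": dt, "seed": seed})
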