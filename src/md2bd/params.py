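"""Heat-bath parameters and the random-variate generators used by all engines.

The heat bath is an ideal gas of light point particles (mass ``m``) that
thermalises a heavy particle (mass ``M``, mass ratio ``mu = M/m``) through
elastic collisions.  Three bath models are supported:

``A``
    one-dimensional bath; particles on the line with Maxwellian velocities.
``B``
    three-dimensional bath around a heavy sphere of radius ``R``; Maxwellian
    velocities.
``C``
    three-dimensional bath with fixed particle speed ``sigma_mu`` and
    isotropic directions.

For a prescribed friction ``gamma`` and diffusion coefficient ``D`` of the
limiting Langevin dynamics (``mu -> infinity``), the bath must be prepared
with a specific spatial Poisson density ``lambda_mu`` and velocity scale
``sigma_mu``:

=====  =====================================================  =========================
model  ``lambda_mu``                                          ``sigma_mu``
=====  =====================================================  =========================
A      ``(1/4) * sqrt(pi*(mu+1)*gamma / (2*D))``              ``sqrt((mu+1)*D*gamma)``
B      ``(3/(8 R^2)) * sqrt((mu+1)*gamma / (2*pi*D))``        ``sqrt((mu+1)*D*gamma)``
C      ``(3/(8 pi R^2)) * sqrt((mu+1)*gamma / D)``            ``2*sqrt((mu+1)*D*gamma)``
=====  =====================================================  =========================

All quantities are dimensionless.

The module also implements the exact samplers needed by the boundary-influx
construction: the complementary-error-function distribution
``sqrt(pi)*erfc(z)`` on ``[0, inf)`` (acceptance–rejection with an
exponential envelope), one-sided truncated Gaussians, spatial Poisson
fields, and the fixed-speed velocity shell of model C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from numba import njit
from scipy import optimize, special

from .errors import NumericalError, ParameterError

__all__ = [
    "BathParams",
    "EnvelopeConstants",
    "DEFAULT_ENVELOPE",
    "bath_parameters",
    "erfc_sample",
    "optimize_envelope",
    "truncated_gaussian_sample",
    "poisson_field",
    "speed_shell_sample",
]

SQRT_PI = math.sqrt(math.pi)

#: mean of the normalised distribution sqrt(pi)*erfc(z) on [0, inf)
ERFC_DIST_MEAN = SQRT_PI / 4.0


# ---------------------------------------------------------------------------
# bath parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BathParams:
    """Parameters of one heat-bath model.

    Attributes
    ----------
    model : {'A', 'B', 'C'}
        Bath model kind.
    mu : float
        Heavy-to-light mass ratio ``M/m``.
    gamma, D : float
        Friction and diffusion coefficients of the limiting Langevin
        dynamics.
    R : float
        Heavy-particle radius.  Required for models B and C; for model A it
        does not enter the bath law (it is carried for hybrid geometry only)
        and defaults to 0.
    lambda_mu : float
        Spatial Poisson density of bath particles (per length in 1-D, per
        volume in 3-D).
    sigma_mu : float
        Bath velocity scale (Maxwellian std for A/B, the fixed speed for C).
    """

    model: Literal["A", "B", "C"]
    mu: float
    gamma: float
    D: float
    R: float
    lambda_mu: float
    sigma_mu: float


def bath_parameters(model: str, mu: float, gamma: float, D: float,
                    R: float | None = None) -> BathParams:
    """Resolve the bath density and velocity scale for the requested model.

    Parameters
    ----------
    model : {'A', 'B', 'C'}
    mu, gamma, D : float
        Positive mass ratio, friction and diffusion coefficients.
    R : float, optional
        Heavy-particle radius; required (positive) for models B and C.

    Returns
    -------
    BathParams

    Raises
    ------
    ParameterError
        If an argument is non-positive or ``R`` is missing for B/C.
    """
    model = str(model).upper()
    if model not in ("A", "B", "C"):
        raise ParameterError(f"unknown bath model {model!r}")
    if mu <= 0 or gamma <= 0 or D <= 0:
        raise ParameterError("mu, gamma and D must be positive")
    if model == "A":
        R = 0.0 if R is None else float(R)
        lam = 0.25 * math.sqrt(math.pi * (mu + 1.0) * gamma / (2.0 * D))
        sig = math.sqrt((mu + 1.0) * D * gamma)
    else:
        if R is None or R <= 0:
            raise ParameterError(f"model {model} requires a positive radius R")
        if model == "B":
            lam = 3.0 / (8.0 * R * R) * math.sqrt((mu + 1.0) * gamma / (2.0 * math.pi * D))
            sig = math.sqrt((mu + 1.0) * D * gamma)
        else:  # C
            lam = 3.0 / (8.0 * math.pi * R * R) * math.sqrt((mu + 1.0) * gamma / D)
            sig = 2.0 * math.sqrt((mu + 1.0) * D * gamma)
    return BathParams(model=model, mu=float(mu), gamma=float(gamma), D=float(D),
                      R=float(R), lambda_mu=lam, sigma_mu=sig)


# ---------------------------------------------------------------------------
# erfc-distribution rejection sampler
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnvelopeConstants:
    """Envelope constants of the erfc rejection sampler.

    ``a1`` is the scale of the exponential proposal ``z = -a1*log(U)`` and
    ``a2`` the envelope amplitude.  Validity of the scheme requires
    ``a2 * erfc(z) * exp(z/a1) <= 1`` for all ``z >= 0``; the total
    acceptance probability is ``a2 / (a1 * sqrt(pi))``.
    """

    a1: float
    a2: float

    def __post_init__(self) -> None:
        if self.a1 <= 0 or self.a2 <= 0:
            raise ParameterError("envelope constants must be positive")
        if _envelope_sup(self.a1) * self.a2 > 1.0 + 1e-9:
            raise ParameterError(
                "invalid envelope: a2*erfc(z)*exp(z/a1) exceeds 1 for some z>=0")

    @property
    def acceptance(self) -> float:
        """Total acceptance probability ``a2 / (a1*sqrt(pi))``."""
        return self.a2 / (self.a1 * SQRT_PI)


def _envelope_sup(a1: float) -> float:
    """sup_{z>=0} erfc(z)*exp(z/a1), computed through erfcx for stability."""
    # log objective: log erfcx(z) - z^2 + z/a1; unimodal on [0, inf)
    def neg_log(z: float) -> float:
        return -(math.log(special.erfcx(z)) - z * z + z / a1)

    res = optimize.minimize_scalar(neg_log, bounds=(0.0, 12.0), method="bounded",
                                   options={"xatol": 1e-13})
    return max(1.0, math.exp(-res.fun))  # the sup is >= value at z=0, which is 1


#: the constants used throughout the simulations (three-decimal optimum)
DEFAULT_ENVELOPE = EnvelopeConstants(a1=0.532, a2=0.814)


@njit(cache=True)
def _erfc_sample_scalar(rng, a1, a2):
    """One variate from sqrt(pi)*erfc(z); returns (z, proposals_used)."""
    k = 0
    while True:
        k += 1
        z1 = rng.random()
        z2 = -a1 * math.log(z1)
        z3 = rng.random()
        if z1 * z3 < a2 * math.erfc(z2):
            return z2, k


@njit(cache=True)
def _erfc_sample_array(rng, n, a1, a2):
    out = np.empty(n)
    total = 0
    for i in range(n):
        z, k = _erfc_sample_scalar(rng, a1, a2)
        out[i] = z
        total += k
    return out, total


def erfc_sample(rng: np.random.Generator, size: int | None = None,
                constants: EnvelopeConstants | None = None,
                return_stats: bool = False):
    """Sample the normalised complementary-error-function distribution.

    The target density is ``sqrt(pi) * erfc(z)`` on ``[0, inf)``
    (``int_0^inf erfc = 1/sqrt(pi)``).  Proposals are exponential with scale
    ``a1``; a proposal ``z`` drawn as ``-a1*log(U)`` is accepted when
    ``U * U' < a2 * erfc(z)``.

    Parameters
    ----------
    rng : numpy.random.Generator
    size : int, optional
        Number of variates; a scalar is returned when omitted.
    constants : EnvelopeConstants, optional
        Defaults to :data:`DEFAULT_ENVELOPE`.
    return_stats : bool
        If true, also return the total number of proposals consumed, from
        which the empirical acceptance fraction is ``n / proposals``.
    """
    c = constants or DEFAULT_ENVELOPE
    if size is None:
        z, k = _erfc_sample_scalar(rng, c.a1, c.a2)
        return (z, k) if return_stats else z
    out, total = _erfc_sample_array(rng, int(size), c.a1, c.a2)
    return (out, total) if return_stats else out


def optimize_envelope() -> EnvelopeConstants:
    """Numerically maximise the total acceptance of the erfc sampler.

    For a given proposal scale ``a1`` the largest admissible amplitude is
    ``a2(a1) = 1 / sup_{z>=0} erfc(z)*exp(z/a1)`` (the envelope constraint is
    active at the optimum); the total acceptance ``a2(a1)/(a1*sqrt(pi))`` is
    then maximised over ``a1``.

    Returns
    -------
    EnvelopeConstants
        The optimum, approximately ``a1 = 0.532``, ``a2 = 0.814``.

    Raises
    ------
    NumericalError
        If the scalar optimizer fails to converge.
    """
    def neg_acceptance(a1: float) -> float:
        return -1.0 / (_envelope_sup(a1) * a1 * SQRT_PI)

    res = optimize.minimize_scalar(neg_acceptance, bounds=(0.05, 3.0),
                                   method="bounded", options={"xatol": 1e-12})
    if not res.success:
        raise NumericalError(f"envelope optimization failed: {res}")
    a1 = float(res.x)
    return EnvelopeConstants(a1=a1, a2=1.0 / _envelope_sup(a1))


# ---------------------------------------------------------------------------
# one-sided truncated Gaussian
# ---------------------------------------------------------------------------

@njit(cache=True)
def _std_norm_tail(rng, a):
    """Exact standard-normal variate conditioned on z >= a.

    Naive rejection for a <= 0.3 (acceptance >= ~0.38); Robert's (1995)
    translated-exponential rejection otherwise.  Both are exact.
    """
    if a <= 0.3:
        while True:
            z = rng.standard_normal()
            if z >= a:
                return z
    alpha = 0.5 * (a + math.sqrt(a * a + 4.0))
    while True:
        z = a + rng.exponential(1.0 / alpha)
        d = z - alpha
        if rng.random() < math.exp(-0.5 * d * d):
            return z


@njit(cache=True)
def _truncnorm_scalar(rng, sigma, cutoff, above):
    """Normal(0, sigma^2) conditioned on v >= cutoff (above) or v <= cutoff."""
    if above:
        return sigma * _std_norm_tail(rng, cutoff / sigma)
    return -sigma * _std_norm_tail(rng, -cutoff / sigma)


@njit(cache=True)
def _truncnorm_array(rng, n, sigma, cutoff, above):
    out = np.empty(n)
    for i in range(n):
        out[i] = _truncnorm_scalar(rng, sigma, cutoff, above)
    return out


def truncated_gaussian_sample(rng: np.random.Generator, sigma: float,
                              cutoff: float, side: str = "below",
                              size: int | None = None):
    """Exact one-sided truncated ``Normal(0, sigma^2)`` variates.

    Parameters
    ----------
    rng : numpy.random.Generator
    sigma : float
        Standard deviation of the untruncated Gaussian.
    cutoff : float
        Truncation point (``-inf``/``inf`` give the untruncated law).
    side : {'below', 'above'}
        ``'below'`` restricts to ``v <= cutoff``, ``'above'`` to
        ``v >= cutoff``.
    size : int, optional
    """
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    if side not in ("below", "above"):
        raise ParameterError("side must be 'below' or 'above'")
    above = side == "above"
    if not np.isfinite(cutoff):
        # no truncation (or an impossible one)
        if (above and cutoff > 0) or (not above and cutoff < 0):
            raise ParameterError("truncation removes the whole support")
        if size is None:
            return sigma * rng.standard_normal()
        return sigma * rng.standard_normal(int(size))
    if size is None:
        return _truncnorm_scalar(rng, float(sigma), float(cutoff), above)
    return _truncnorm_array(rng, int(size), float(sigma), float(cutoff), above)


# ---------------------------------------------------------------------------
# Poisson field and fixed-speed shell
# ---------------------------------------------------------------------------

def poisson_field(rng: np.random.Generator, lam: float, region) -> np.ndarray:
    """Sample a homogeneous spatial Poisson field.

    Parameters
    ----------
    rng : numpy.random.Generator
    lam : float
        Intensity (points per unit measure).
    region : tuple
        Either an interval ``(a, b)`` or a box ``((a1,b1), (a2,b2), (a3,b3))``.

    Returns
    -------
    numpy.ndarray
        Positions, shape ``(n,)`` for an interval or ``(n, 3)`` for a box.
        Count ``n ~ Poisson(lam * measure)``, positions i.i.d. uniform.
    """
    if lam <= 0:
        raise ParameterError("lam must be positive")
    region = np.asarray(region, dtype=float)
    if region.ndim == 1:
        a, b = region
        measure = max(b - a, 0.0)
        n = rng.poisson(lam * measure) if measure > 0 else 0
        return rng.uniform(a, b, size=n) if n else np.empty(0)
    lows, highs = region[:, 0], region[:, 1]
    sides = np.clip(highs - lows, 0.0, None)
    measure = float(np.prod(sides))
    n = rng.poisson(lam * measure) if measure > 0 else 0
    if n == 0:
        return np.empty((0, region.shape[0]))
    return rng.uniform(lows, highs, size=(n, region.shape[0]))


@njit(cache=True)
def _shell_sample_array(rng, n, sigma_mu):
    """Isotropic fixed-speed velocities |v| = sigma_mu (Archimedes map)."""
    out = np.empty((n, 3))
    for i in range(n):
        c = 2.0 * rng.random() - 1.0          # cos(theta), uniform on [-1, 1]
        phi = 2.0 * math.pi * rng.random()
        s = math.sqrt(1.0 - c * c)
        out[i, 0] = sigma_mu * c
        out[i, 1] = sigma_mu * s * math.cos(phi)
        out[i, 2] = sigma_mu * s * math.sin(phi)
    return out


def speed_shell_sample(rng: np.random.Generator, sigma_mu: float,
                       size: int | None = None) -> np.ndarray:
    """Velocities with uniform direction and magnitude exactly ``sigma_mu``.

    This is the velocity law of bath model C,
    ``f(v) ~ delta(|v| - sigma_mu)``.  Each Cartesian component is uniform
    on ``[-sigma_mu, sigma_mu]`` (Archimedes projection).
    """
    if sigma_mu <= 0:
        raise ParameterError("sigma_mu must be positive")
    out = _shell_sample_array(rng, 1 if size is None else int(size), float(sigma_mu))
    return out[0] if size is None else out
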