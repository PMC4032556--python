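"""Elastic-collision kernels and point–sphere collision-time detection.

A heavy particle (mass ``M``) collides frictionlessly with light point
particles (mass ``m``, mass ratio ``mu = M/m``).  Post-collision velocities
follow from conservation of momentum and kinetic energy alone.  In 3-D only
the velocity components along the contact normal (the line through the
sphere centre and the contact point) change; tangential components are
untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import GeometryError, StateError

__all__ = [
    "CollisionEvent",
    "collide_1d",
    "collide_3d",
    "collision_time_point_sphere",
]


@dataclass(frozen=True)
class CollisionEvent:
    """A heavy–bath collision within a time step.

    Attributes
    ----------
    t_c : float
        Collision time measured from the start of the step, ``0 <= t_c <= dt``.
    bath_index : int
        Index of the colliding bath particle (-1 when not applicable).
    contact_normal : numpy.ndarray or None
        Unit vector from the sphere centre to the contact point (3-D only).
    """

    t_c: float
    bath_index: int = -1
    contact_normal: np.ndarray | None = None


@njit(cache=True)
def _collide_1d(V, v, mu):
    Vp = (mu - 1.0) / (mu + 1.0) * V + 2.0 / (mu + 1.0) * v
    vp = (1.0 - mu) / (mu + 1.0) * v + 2.0 * mu / (mu + 1.0) * V
    return Vp, vp


def collide_1d(V: float, v: float, mu: float) -> tuple[float, float]:
    """1-D elastic collision of the heavy particle (velocity ``V``) with a
    bath particle (velocity ``v``).

    Returns the post-collision pair ``(V~, v~)``:

    .. code-block:: text

        V~ = (mu-1)/(mu+1) V + 2/(mu+1) v
        v~ = (1-mu)/(mu+1) v + 2 mu/(mu+1) V

    Momentum ``mu*V + v`` and energy ``mu*V^2 + v^2`` are conserved exactly
    (in units of the light mass).
    """
    return _collide_1d(float(V), float(v), float(mu))


@njit(cache=True)
def _collide_3d(V, v, normal, mu):
    # decompose on the contact normal; tangential parts are unchanged
    Vn = V[0] * normal[0] + V[1] * normal[1] + V[2] * normal[2]
    vn = v[0] * normal[0] + v[1] * normal[1] + v[2] * normal[2]
    Vnp, vnp = _collide_1d(Vn, vn, mu)
    Vp = V + (Vnp - Vn) * normal
    vp = v + (vnp - vn) * normal
    return Vp, vp


def collide_3d(V, v, normal, mu: float):
    """3-D elastic collision of a heavy sphere with a bath point particle.

    The normal components transform as in :func:`collide_1d`; tangential
    components are unchanged.  Momentum and energy are conserved exactly.

    Parameters
    ----------
    V, v : array_like, shape (3,)
        Pre-collision velocities of the heavy and bath particle.
    normal : array_like, shape (3,)
        Unit contact normal (sphere centre -> contact point).
    mu : float
        Mass ratio.

    Raises
    ------
    GeometryError
        If ``normal`` is not unit to within 1e-12.
    """
    V = np.asarray(V, dtype=float)
    v = np.asarray(v, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if abs(normal @ normal - 1.0) > 1e-12:
        raise GeometryError("contact normal must be a unit vector")
    return _collide_3d(V, v, normal, float(mu))


@njit(cache=True)
def _sphere_hit_time(dx0, dx1, dx2, rv0, rv1, rv2, R, dt):
    """Earliest t in (0, dt] with |dx + rv*t| = R and approaching velocity.

    dx is the bath-minus-centre separation, rv the relative velocity.
    Returns -1.0 when there is no such root (grazing double roots count as
    no collision).
    """
    b = dx0 * rv0 + dx1 * rv1 + dx2 * rv2
    if b >= 0.0:                      # separating or tangential
        return -1.0
    a = rv0 * rv0 + rv1 * rv1 + rv2 * rv2
    c = dx0 * dx0 + dx1 * dx1 + dx2 * dx2 - R * R
    disc = b * b - a * c
    if disc <= 0.0:                   # miss, or grazing double root
        return -1.0
    t = c / (-b + np.sqrt(disc))      # stable smallest positive root
    if t < 0.0 or t > dt:
        return -1.0
    return t


def collision_time_point_sphere(X, V, x, v, R: float, dt: float) -> CollisionEvent | None:
    """Exact collision time of a free-flying point with a free-flying sphere.

    Solves ``|x + v t - (X + V t)| = R`` for the smallest root
    ``t in [0, dt]`` with approaching relative velocity.

    Parameters
    ----------
    X, V : array_like, shape (3,)
        Sphere centre position and velocity at the start of the step.
    x, v : array_like, shape (3,)
        Point-particle position and velocity.
    R, dt : float
        Sphere radius and step length.

    Returns
    -------
    CollisionEvent or None
        The event (with contact normal at ``t_c``) or None when the
        trajectories do not meet within the step.

    Raises
    ------
    StateError
        If the point starts strictly inside the sphere.
    """
    X = np.asarray(X, dtype=float)
    V = np.asarray(V, dtype=float)
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    dx = x - X
    if dx @ dx < R * R * (1.0 - 1e-12):
        raise StateError("point particle starts inside the sphere")
    rv = v - V
    t = _sphere_hit_time(dx[0], dx[1], dx[2], rv[0], rv[1], rv[2], float(R), float(dt))
    if t < 0.0:
        return None
    normal = (dx + rv * t) / R
    normal = normal / np.linalg.norm(normal)
    return CollisionEvent(t_c=float(t), contact_normal=normal)
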