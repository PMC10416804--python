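"""Closed-form volumes and surface areas for the primitive cell shapes.

These forms supply the analytic ground truth against which voxel-based
measurements are validated: spheres, triaxial ellipsoids (exact area via
incomplete elliptic integrals, with the Knud Thomsen approximation available
as a documented fallback) and capsules (sphero-cylinders), which stand in for
elongated invasive cells.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import ellipeinc, ellipkinc

__all__ = [
    "sphere_volume",
    "sphere_surface_area",
    "ellipsoid_volume",
    "ellipsoid_surface_area",
    "knud_thomsen_surface_area",
    "capsule_volume",
    "capsule_surface_area",
    "wadell_sphericity",
]

_REL_TOL = 1e-9


def sphere_volume(r: float) -> float:
    if r <= 0:
        raise ValueError("radius must be positive")
    return 4.0 / 3.0 * math.pi * r**3


def sphere_surface_area(r: float) -> float:
    if r <= 0:
        raise ValueError("radius must be positive")
    return 4.0 * math.pi * r**2


def ellipsoid_volume(a: float, b: float, c: float) -> float:
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    return 4.0 / 3.0 * math.pi * a * b * c


def ellipsoid_surface_area(a: float, b: float, c: float) -> float:
    """Exact surface area of a triaxial ellipsoid with semi-axes a, b, c.

    Uses Legendre's incomplete elliptic integrals for the general case, with
    the standard closed forms for the degenerate prolate/oblate/spherical
    cases (where the general expression is 0/0).
    """
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    a, b, c = sorted((float(a), float(b), float(c)), reverse=True)

    if (a - c) <= _REL_TOL * a:  # sphere
        return sphere_surface_area((a + b + c) / 3.0)
    if (a - b) <= _REL_TOL * a:  # oblate spheroid: a = b > c
        e = math.sqrt(1.0 - (c / a) ** 2)
        return 2.0 * math.pi * a**2 + math.pi * c**2 / e * math.log((1.0 + e) / (1.0 - e))
    if (b - c) <= _REL_TOL * a:  # prolate spheroid: a > b = c
        e = math.sqrt(1.0 - (c / a) ** 2)
        return 2.0 * math.pi * c**2 * (1.0 + a / (c * e) * math.asin(e))

    phi = math.acos(c / a)
    m = (a**2 * (b**2 - c**2)) / (b**2 * (a**2 - c**2))
    sin_phi = math.sin(phi)
    return 2.0 * math.pi * c**2 + (2.0 * math.pi * a * b / sin_phi) * (
        float(ellipeinc(phi, m)) * sin_phi**2 + float(ellipkinc(phi, m)) * math.cos(phi) ** 2
    )


def knud_thomsen_surface_area(a: float, b: float, c: float, p: float = 1.6075) -> float:
    """Knud Thomsen approximation (max relative error ~1.1% at p = 1.6075)."""
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    ap, bp, cp = a**p, b**p, c**p
    return 4.0 * math.pi * ((ap * bp + ap * cp + bp * cp) / 3.0) ** (1.0 / p)


def capsule_volume(radius: float, cylinder_length: float) -> float:
    """Volume of a capsule: cylinder of given length capped by two hemispheres."""
    if radius <= 0 or cylinder_length < 0:
        raise ValueError("radius must be positive and cylinder_length non-negative")
    return math.pi * radius**2 * cylinder_length + sphere_volume(radius)


def capsule_surface_area(radius: float, cylinder_length: float) -> float:
    if radius <= 0 or cylinder_length < 0:
        raise ValueError("radius must be positive and cylinder_length non-negative")
    return 2.0 * math.pi * radius * cylinder_length + sphere_surface_area(radius)


def wadell_sphericity(volume: float, surface_area: float) -> float:
    """Ψ = π^(1/3) (6V)^(2/3) / A — ratio of equal-volume-sphere area to actual area."""
    if volume <= 0 or surface_area <= 0:
        raise ValueError("volume and surface area must be positive")
    return math.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / surface_area


def sample_ellipsoid_surface(a: float, b: float, c: float, n_theta: int = 180,
                             n_phi: int = 90) -> np.ndarray:
    """Points on the ellipsoid surface (parametric grid), shape (N, 3) as (z, y, x).

    Semi-axes are interpreted per axis in (z, y, x) order: a along z, b along
    y, c along x.  Used for ground-truth nearest-distance computations.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    phi = np.linspace(0.0, np.pi, n_phi)
    T, P = np.meshgrid(theta, phi, indexing="ij")
    z = a * np.cos(P)
    y = b * np.sin(P) * np.cos(T)
    x = c * np.sin(P) * np.sin(T)
    return np.column_stack([z.ravel(), y.ravel(), x.ravel()])


def sample_capsule_surface(radius: float, half_length: float, axis: int,
                           n: int = 4000) -> np.ndarray:
    """Points on a capsule surface centred at the origin, axis ∈ {0,1,2} (z,y,x)."""
    rng = np.random.default_rng(0)  # fixed grid-free sampling; deterministic
    # cylinder part
    t = rng.uniform(-half_length, half_length, n)
    ang = rng.uniform(0, 2 * np.pi, n)
    cyl_axis = t
    cyl_u = radius * np.cos(ang)
    cyl_v = radius * np.sin(ang)
    # cap part: hemispheres at ±half_length
    vec = rng.normal(size=(n, 3))
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    cap_axis = np.where(vec[:, 0] >= 0, half_length, -half_length) + radius * vec[:, 0]
    cap_u = radius * vec[:, 1]
    cap_v = radius * vec[:, 2]
    ax = np.concatenate([cyl_axis, cap_axis])
    u = np.concatenate([cyl_u, cap_u])
    v = np.concatenate([cyl_v, cap_v])
    pts = np.zeros((ax.size, 3))
    others = [i for i in range(3) if i != axis]
    pts[:, axis] = ax
    pts[:, others[0]] = u
    pts[:, others[1]] = v
    return pts
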