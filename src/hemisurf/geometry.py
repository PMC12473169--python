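"""Coordinate transforms and differential geometry of parametric surfaces.

A reconstructed lesion surface lives naturally in cylindrical
coordinates (the rotation axis of the acquisition is the z axis), so the
package carries the usual transforms plus the tangent-frame machinery
needed to query normals and tangent planes on any parametric surface
r(u, v) = (x(u,v), y(u,v), z(u,v)).

A point is *regular* when the 2x3 Jacobian [r_u; r_v] has rank 2, i.e.
the tangent vectors are linearly independent and the tangent plane is
non-degenerate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .errors import HemisurfError

__all__ = [
    "CylCoord",
    "CartPoint",
    "ParametricSurface",
    "TangentFrame",
    "TangentPlane",
    "cyl_to_cart",
    "cart_to_cyl",
    "tangent_frame",
    "regularity_rank",
    "tangent_plane_at",
    "sphere_surface",
]


@dataclass(frozen=True)
class CylCoord:
    """Cylindrical coordinates: radius r >= 0 (mm), azimuth phi in (-pi, pi], height z (mm)."""

    r: float
    phi: float
    z: float

    def __post_init__(self):
        if self.r < 0:
            raise HemisurfError("cylindrical radius must be >= 0")
        if not (-math.pi < self.phi <= math.pi + 1e-15):
            raise HemisurfError("phi must lie in (-pi, pi]")


@dataclass(frozen=True)
class CartPoint:
    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class TangentFrame:
    """Tangent vectors r_u, r_v and their cross product N = r_u x r_v."""

    ru: np.ndarray
    rv: np.ndarray
    normal: np.ndarray


@dataclass(frozen=True)
class TangentPlane:
    """Plane N . (p - p0) = 0 through the tangency point p0."""

    nx: float
    ny: float
    nz: float
    x0: float
    y0: float
    z0: float

    def residual(self, p: CartPoint) -> float:
        """Signed value of the plane equation at p (0 on the plane)."""
        return (
            self.nx * (p.x - self.x0)
            + self.ny * (p.y - self.y0)
            + self.nz * (p.z - self.z0)
        )


def cyl_to_cart(c: CylCoord) -> CartPoint:
    """(r, phi, z) -> (r cos phi, r sin phi, z)."""
    return CartPoint(c.r * math.cos(c.phi), c.r * math.sin(c.phi), c.z)


def cart_to_cyl(p: CartPoint) -> CylCoord:
    """(x, y, z) -> (sqrt(x^2+y^2), atan2(y, x), z); phi := 0 on the axis."""
    r = math.hypot(p.x, p.y)
    phi = math.atan2(p.y, p.x) if r > 0.0 else 0.0
    if phi <= -math.pi:  # atan2 returns -pi for (-r, -0.0); fold to +pi
        phi = math.pi
    return CylCoord(r=r, phi=phi, z=p.z)


@dataclass
class ParametricSurface:
    """A surface r(u, v) on a rectangular parameter domain.

    ``eval_fn(u, v)`` returns an (x, y, z) triple.  ``partials(u, v)``,
    when supplied, returns analytic (r_u, r_v); otherwise central finite
    differences with step ``step`` * (domain span) are used.
    """

    eval_fn: Callable[[float, float], tuple]
    domain: tuple  # (u_min, u_max, v_min, v_max)
    step: float = 1e-5
    partials: Optional[Callable[[float, float], tuple]] = None

    def __post_init__(self):
        if self.step <= 0:
            raise HemisurfError("finite-difference step must be > 0")
        u0, u1, v0, v1 = self.domain
        if not (u1 > u0 and v1 > v0):
            raise HemisurfError("degenerate parameter domain")

    def eval(self, u: float, v: float) -> CartPoint:
        x, y, z = self.eval_fn(u, v)
        return CartPoint(float(x), float(y), float(z))

    def contains(self, u: float, v: float, margin: float = 0.0) -> bool:
        u0, u1, v0, v1 = self.domain
        return (u0 + margin <= u <= u1 - margin) and (v0 + margin <= v <= v1 - margin)


def tangent_frame(s: ParametricSurface, u: float, v: float) -> TangentFrame:
    """Tangent vectors at (u, v) and their cross-product normal.

    Uses the surface's analytic partials when present, otherwise
    second-order central differences (point must sit strictly inside the
    domain so the stencil fits).
    """
    u0, u1, v0, v1 = s.domain
    if s.partials is not None:
        ru, rv = s.partials(u, v)
        ru = np.asarray(ru, dtype=float)
        rv = np.asarray(rv, dtype=float)
    else:
        hu = s.step * (u1 - u0)
        hv = s.step * (v1 - v0)
        if not s.contains(u, v, margin=0.0) or not (
            u - hu >= u0 and u + hu <= u1 and v - hv >= v0 and v + hv <= v1
        ):
            raise HemisurfError("(u, v) too close to the domain edge for central differences")
        pu1 = np.asarray(s.eval_fn(u + hu, v), dtype=float)
        pu0 = np.asarray(s.eval_fn(u - hu, v), dtype=float)
        pv1 = np.asarray(s.eval_fn(u, v + hv), dtype=float)
        pv0 = np.asarray(s.eval_fn(u, v - hv), dtype=float)
        ru = (pu1 - pu0) / (2.0 * hu)
        rv = (pv1 - pv0) / (2.0 * hv)
    return TangentFrame(ru=ru, rv=rv, normal=np.cross(ru, rv))


def regularity_rank(f: TangentFrame, tol: float = 1e-10) -> int:
    """Rank of the 2x3 Jacobian [r_u; r_v] via singular values.

    Singular values below ``tol`` times the largest count as zero;
    rank 2 means the point is regular (well-defined tangent plane).
    """
    jac = np.vstack([f.ru, f.rv])
    sv = np.linalg.svd(jac, compute_uv=False)
    if sv[0] == 0.0:
        return 0
    return int(np.sum(sv > tol * sv[0]))


def tangent_plane_at(s: ParametricSurface, u: float, v: float) -> TangentPlane:
    """Tangent plane at a regular point of the surface."""
    frame = tangent_frame(s, u, v)
    if regularity_rank(frame) < 2:
        raise HemisurfError(f"surface is degenerate at (u={u}, v={v}); no tangent plane")
    p0 = s.eval(u, v)
    n = frame.normal
    return TangentPlane(nx=n[0], ny=n[1], nz=n[2], x0=p0.x, y0=p0.y, z0=p0.z)


def sphere_surface(R: float) -> ParametricSurface:
    """Sphere of radius R in latitude/longitude parametrization.

    x = R cos u cos v, y = R cos u sin v, z = R sin u, so every point
    satisfies x^2 + y^2 + z^2 = R^2.  Analytic partials are attached.
    """
    if R <= 0:
        raise HemisurfError("sphere radius must be > 0")

    def ev(u, v):
        return (R * math.cos(u) * math.cos(v), R * math.cos(u) * math.sin(v), R * math.sin(u))

    def dp(u, v):
        ru = (-R * math.sin(u) * math.cos(v), -R * math.sin(u) * math.sin(v), R * math.cos(u))
        rv = (-R * math.cos(u) * math.sin(v), R * math.cos(u) * math.cos(v), 0.0)
        return ru, rv

    return ParametricSurface(
        eval_fn=ev,
        domain=(-math.pi / 2, math.pi / 2, -math.pi, math.pi),
        partials=dp,
    )
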