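"""Idealized bacterial cell surface: charts, sampling, stepping and camera projection.

The cell is modeled as a cylinder of radius ``r`` and length ``L`` (default
``L = 2r``) capped by two hemispheres of the same radius.  The axial coordinate
``x`` runs along the cell axis with ``x = 0`` at the junction between the left
cap and the cylinder; the optical axis is ``z`` so the camera records ``(x, y)``.

Charts
------
* cylinder: ``(axial, azimuth)`` with 3-D position
  ``(axial, r sin(azimuth), r cos(azimuth))`` — azimuth 0 faces the camera.
* caps: a unit direction vector from the cap center;
  left-cap directions have a non-positive x component, right-cap non-negative.

The cylinder chart is isometric under unrolling, so straight lines in
``(axial, r·azimuth)`` are geodesics.  Cap geodesics are great circles.  The two
surfaces meet tangentially at the junction circles, so a geodesic passes
smoothly from one chart to the other; the stepping code transfers the unused
arc length across the junction with the intrinsic direction preserved.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Region",
    "CellGeometry",
    "SurfacePoint",
    "CameraPoint",
    "sample_uniform_point",
    "step_on_surface",
    "geodesic_confinement_test",
    "reflect_into_disc",
    "project_to_camera",
    "chart_to_camera",
]

_ROUNDTRIP_TOL = 1e-9


class Region(str, enum.Enum):
    CYLINDER = "cylinder"
    CAP_LEFT = "cap_left"
    CAP_RIGHT = "cap_right"


class Mode(str, enum.Enum):
    """Where the walker is allowed to reside."""

    WHOLE_SURFACE = "whole_surface"
    CYLINDER_ONLY = "cylinder_only"


@dataclass(frozen=True)
class CellGeometry:
    """Cylinder + hemispherical caps; lengths in μm.

    ``cylinder_length`` defaults to twice the radius (a cell whose cylindrical
    section is as long as its diameter); total cell length is
    ``cylinder_length + 2·radius``.
    """

    radius: float = 0.5
    cylinder_length: float | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        if self.cylinder_length is None:
            object.__setattr__(self, "cylinder_length", 2.0 * self.radius)
        if self.cylinder_length < 0:
            raise ValueError("cylinder_length must be non-negative")

    @property
    def total_length(self) -> float:
        return self.cylinder_length + 2.0 * self.radius

    @property
    def cylinder_area(self) -> float:
        return 2.0 * math.pi * self.radius * self.cylinder_length

    @property
    def cap_area(self) -> float:
        """Combined area of both hemispherical caps (one full sphere)."""
        return 4.0 * math.pi * self.radius**2


@dataclass(frozen=True)
class SurfacePoint:
    """A point on the cell surface in its region's chart.

    For cylinder points ``axial``/``azimuth`` are the chart coordinates and
    ``cap_dir`` is ``None``; for cap points ``cap_dir`` is the unit direction
    from the cap center and the other two fields are derived conveniences.
    """

    region: Region
    axial: float = 0.0
    azimuth: float = 0.0
    cap_dir: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.region is Region.CYLINDER:
            if self.cap_dir is not None:
                raise ValueError("cylinder points carry no cap_dir")
        else:
            if self.cap_dir is None:
                raise ValueError("cap points require a cap_dir unit vector")
            n = math.sqrt(sum(c * c for c in self.cap_dir))
            if abs(n - 1.0) > 1e-7:
                raise ValueError(f"cap_dir must be unit length, |u| = {n}")

    def to_xyz(self, geometry: CellGeometry) -> np.ndarray:
        r = geometry.radius
        if self.region is Region.CYLINDER:
            return np.array(
                [self.axial, r * math.sin(self.azimuth), r * math.cos(self.azimuth)]
            )
        ux, uy, uz = self.cap_dir
        cx = 0.0 if self.region is Region.CAP_LEFT else geometry.cylinder_length
        return np.array([cx + r * ux, r * uy, r * uz])

    @staticmethod
    def from_xyz(xyz: np.ndarray, geometry: CellGeometry) -> "SurfacePoint":
        x, y, z = float(xyz[0]), float(xyz[1]), float(xyz[2])
        r, L = geometry.radius, geometry.cylinder_length
        if x < 0.0:
            u = (x / r, y / r, z / r)
            return SurfacePoint(Region.CAP_LEFT, axial=x, azimuth=math.atan2(y, z), cap_dir=u)
        if x > L:
            u = ((x - L) / r, y / r, z / r)
            return SurfacePoint(Region.CAP_RIGHT, axial=x, azimuth=math.atan2(y, z), cap_dir=u)
        return SurfacePoint(Region.CYLINDER, axial=x, azimuth=math.atan2(y, z))


@dataclass(frozen=True)
class CameraPoint:
    """Orthographic image-plane position: x along the cell axis, y lateral."""

    x: float
    y: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y])


# ---------------------------------------------------------------------------
# sampling


def sample_uniform_point(
    geometry: CellGeometry,
    rng: np.random.Generator,
    mode: Mode | str = Mode.WHOLE_SURFACE,
) -> SurfacePoint:
    """Draw a point uniformly by surface area over the allowed region."""
    mode = Mode(mode)
    r, L = geometry.radius, geometry.cylinder_length
    if mode is Mode.WHOLE_SURFACE:
        p_cap = geometry.cap_area / (geometry.cap_area + geometry.cylinder_area)
        if rng.random() < p_cap:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            if rng.random() < 0.5:
                u[0] = -abs(u[0])
                return SurfacePoint(Region.CAP_LEFT, axial=r * u[0],
                                    azimuth=math.atan2(u[1], u[2]), cap_dir=tuple(u))
            u[0] = abs(u[0])
            return SurfacePoint(Region.CAP_RIGHT, axial=L + r * u[0],
                                azimuth=math.atan2(u[1], u[2]), cap_dir=tuple(u))
    if L == 0:
        raise ValueError("cylinder_only sampling requires cylinder_length > 0")
    return SurfacePoint(
        Region.CYLINDER,
        axial=float(rng.uniform(0.0, L)),
        azimuth=float(rng.uniform(0.0, 2.0 * math.pi)),
    )


# ---------------------------------------------------------------------------
# stepping


def _fold(x: float, L: float) -> float:
    """Specular (triangle-wave) reflection of x into [0, L]."""
    if L == 0:
        return 0.0
    y = math.fmod(x, 2.0 * L)
    if y < 0:
        y += 2.0 * L
    return 2.0 * L - y if y > L else y


def _azimuthal_unit(phi: float) -> np.ndarray:
    """Unit tangent in the direction of increasing azimuthal arc length."""
    return np.array([0.0, math.cos(phi), -math.sin(phi)])


def _cap_basis(u0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal tangent basis (axial-ward, azimuthal) at a cap point."""
    sin2 = 1.0 - u0[0] * u0[0]
    if sin2 < 1e-24:  # pole: any orthonormal pair in the y-z plane works
        return np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 0.0])
    e_ax = np.array([1.0, 0.0, 0.0]) - u0[0] * u0
    e_ax /= math.sqrt(sin2)
    phi = math.atan2(u0[1], u0[2])
    return e_ax, _azimuthal_unit(phi)


def _step_cap(side: Region, u0: np.ndarray, t: np.ndarray, s: float,
              geometry: CellGeometry, mode: Mode, depth: int) -> SurfacePoint:
    """Advance arc length s along the great circle from u0 with unit tangent t."""
    if depth > 8:
        raise RuntimeError("geodesic junction-transfer did not terminate")
    r, L = geometry.radius, geometry.cylinder_length
    theta = s / r
    w = math.cos(theta) * u0 + math.sin(theta) * t
    crossed = w[0] < 0 if side is Region.CAP_RIGHT else w[0] > 0
    if not crossed:
        w = w / np.linalg.norm(w)
        ax = (L + r * w[0]) if side is Region.CAP_RIGHT else r * w[0]
        return SurfacePoint(side, axial=ax, azimuth=math.atan2(w[1], w[2]),
                            cap_dir=tuple(w))
    # find the equator crossing and hand the remaining arc to the cylinder
    if side is Region.CAP_RIGHT:
        theta_c = math.atan2(u0[0], -t[0])
    else:
        theta_c = math.atan2(-u0[0], t[0])
    w_c = math.cos(theta_c) * u0 + math.sin(theta_c) * t
    d_c = -math.sin(theta_c) * u0 + math.cos(theta_c) * t
    phi_c = math.atan2(w_c[1], w_c[2])
    a = d_c[0]
    b = float(d_c @ _azimuthal_unit(phi_c))
    s_rem = s - r * theta_c
    x_start = L if side is Region.CAP_RIGHT else 0.0
    start = SurfacePoint(Region.CYLINDER, axial=x_start, azimuth=phi_c)
    return _step_cylinder(start, s_rem * a, s_rem * b, geometry, mode, depth + 1)


def _step_cylinder(p: SurfacePoint, du: float, dv: float,
                   geometry: CellGeometry, mode: Mode, depth: int) -> SurfacePoint:
    if depth > 8:
        raise RuntimeError("geodesic junction-transfer did not terminate")
    r, L = geometry.radius, geometry.cylinder_length
    ax = p.axial + du
    if mode is Mode.CYLINDER_ONLY:
        return SurfacePoint(Region.CYLINDER, axial=_fold(ax, L),
                            azimuth=p.azimuth + dv / r)
    if 0.0 <= ax <= L:
        return SurfacePoint(Region.CYLINDER, axial=ax, azimuth=p.azimuth + dv / r)
    # straight line in the unrolled chart up to the junction, then a great circle
    if ax > L:
        f = (L - p.axial) / du
        side = Region.CAP_RIGHT
    else:
        f = p.axial / (-du)
        side = Region.CAP_LEFT
    s_tot = math.hypot(du, dv)
    phi_c = p.azimuth + f * dv / r
    u_c = np.array([0.0, math.sin(phi_c), math.cos(phi_c)])
    t = (du / s_tot) * np.array([1.0, 0.0, 0.0]) + (dv / s_tot) * _azimuthal_unit(phi_c)
    return _step_cap(side, u_c, t, (1.0 - f) * s_tot, geometry, mode, depth + 1)


def step_on_surface(
    p: SurfacePoint,
    displacement: np.ndarray,
    geometry: CellGeometry,
    mode: Mode | str = Mode.WHOLE_SURFACE,
) -> SurfacePoint:
    """Move by a tangent-chart displacement ``(along-axis, circumferential)``.

    The step is taken along the surface geodesic whose initial direction matches
    the chart displacement and whose length equals its Euclidean norm.  Steps
    must stay well below the curvature scale: ``|displacement| < radius / 2``.
    In ``cylinder_only`` mode a walker reflects specularly off the cylinder
    ends; in ``whole_surface`` mode it passes smoothly onto the caps.
    """
    mode = Mode(mode)
    du, dv = float(displacement[0]), float(displacement[1])
    s = math.hypot(du, dv)
    if s >= geometry.radius / 2.0:
        raise ValueError(
            f"step length {s:.4g} μm exceeds the curvature limit radius/2 = "
            f"{geometry.radius / 2.0:.4g} μm; reduce the time step"
        )
    if s == 0.0:
        return p
    if p.region is Region.CYLINDER:
        return _step_cylinder(p, du, dv, geometry, mode, 0)
    if mode is Mode.CYLINDER_ONLY:
        raise ValueError("cylinder_only mode cannot step a cap point")
    u0 = np.asarray(p.cap_dir, dtype=float)
    e_ax, e_az = _cap_basis(u0)
    t = (du * e_ax + dv * e_az) / s
    return _step_cap(p.region, u0, t, s, geometry, mode, 0)


def chart_to_surface(
    origin: SurfacePoint,
    uv: np.ndarray,
    geometry: CellGeometry,
    mode: Mode | str = Mode.WHOLE_SURFACE,
) -> SurfacePoint:
    """Exponential map: chart displacement about ``origin`` → surface point.

    Unlike :func:`step_on_surface` this accepts displacements up to the
    confinement scale (no curvature-limit check); it is the scalar counterpart
    of the vectorized camera mapping used by the simulator.
    """
    mode = Mode(mode)
    du, dv = float(uv[0]), float(uv[1])
    if du == 0.0 and dv == 0.0:
        return origin
    if origin.region is Region.CYLINDER:
        return _step_cylinder(origin, du, dv, geometry, mode, 0)
    if mode is Mode.CYLINDER_ONLY:
        raise ValueError("cylinder_only mode requires cylinder origins")
    u0 = np.asarray(origin.cap_dir, dtype=float)
    e_ax, e_az = _cap_basis(u0)
    s = math.hypot(du, dv)
    t = (du * e_ax + dv * e_az) / s
    return _step_cap(origin.region, u0, t, s, geometry, mode, 0)


# ---------------------------------------------------------------------------
# confinement


def reflect_into_disc(displacement: np.ndarray, R_conf: float) -> np.ndarray:
    """Specular (radial mirror) reflection of a chart displacement into |d| ≤ R."""
    d = np.array(displacement, dtype=float)
    norm = math.hypot(d[0], d[1])
    while norm > R_conf:
        d *= (2.0 * R_conf - norm) / norm
        norm = abs(2.0 * R_conf - norm)
    return d


def geodesic_confinement_test(
    origin: SurfacePoint,
    candidate_displacement_from_origin: np.ndarray,
    R_conf: float,
) -> tuple[bool, np.ndarray]:
    """Reflective circular confinement in the origin-centered chart.

    Returns ``(inside, reflected_displacement)``: ``inside`` is True when the
    candidate already lies within the confinement radius, in which case it is
    returned unchanged; otherwise the displacement is mirrored about the circle
    (repeatedly, if one reflection is not enough).  The test is purely
    chart-level — exact on the unrolled cylinder, an exponential-map
    approximation on the caps — so ``origin`` only fixes the chart.
    """
    if R_conf <= 0:
        raise ValueError("R_conf must be positive")
    d = np.asarray(candidate_displacement_from_origin, dtype=float)
    inside = math.hypot(d[0], d[1]) <= R_conf
    return inside, (d.copy() if inside else reflect_into_disc(d, R_conf))


# ---------------------------------------------------------------------------
# projection


def project_to_camera(p: SurfacePoint, geometry: CellGeometry) -> CameraPoint:
    """Orthographic projection dropping the optical-axis (z) coordinate."""
    xyz = p.to_xyz(geometry)
    return CameraPoint(x=float(xyz[0]), y=float(xyz[1]))


# ---------------------------------------------------------------------------
# vectorized origin-chart → camera mapping (simulation fast path)


def _camera_from_cyl_chart(
    x0: np.ndarray, phi0: np.ndarray, U: np.ndarray, V: np.ndarray,
    geometry: CellGeometry, mode: Mode,
) -> tuple[np.ndarray, np.ndarray]:
    """Map chart displacements (U, V) about cylinder origins to camera (x, y).

    Shapes: x0, phi0 are (n,); U, V are (n, T).
    """
    r, L = geometry.radius, geometry.cylinder_length
    ax = x0[:, None] + U
    phi = phi0[:, None] + V / r
    if mode is Mode.CYLINDER_ONLY:
        y = np.abs(np.mod(ax, 2.0 * L))
        ax = np.where(y > L, 2.0 * L - y, y)
        return ax, r * np.sin(phi)

    x_cam = ax.copy()
    y_cam = r * np.sin(phi)
    for right in (True, False):
        over = ax > L if right else ax < 0.0
        if not over.any():
            continue
        du = np.broadcast_to(U, ax.shape)[over]
        dv = np.broadcast_to(V, ax.shape)[over]
        x0b = np.broadcast_to(x0[:, None], ax.shape)[over]
        ph0b = np.broadcast_to(phi0[:, None], ax.shape)[over]
        f = (L - x0b) / du if right else x0b / (-du)
        phi_c = ph0b + f * dv / r
        s_tot = np.hypot(du, dv)
        s_rem = (1.0 - f) * s_tot
        dx, dy = du / s_tot, dv / s_tot
        # great circle from the junction point; the entry direction has a
        # definite axial sign, so the arc cannot re-cross before s = πr
        theta = s_rem / r
        sin_c, cos_c = np.sin(phi_c), np.cos(phi_c)
        wx = np.sin(theta) * dx
        wy = np.cos(theta) * sin_c + np.sin(theta) * dy * cos_c
        x_cam[over] = (L + r * wx) if right else r * wx
        y_cam[over] = r * wy
    return x_cam, y_cam


def _camera_from_cap_chart(
    u0: np.ndarray, side_right: np.ndarray, U: np.ndarray, V: np.ndarray,
    geometry: CellGeometry,
) -> tuple[np.ndarray, np.ndarray]:
    """Map chart displacements about cap origins to camera (x, y).

    u0 is (n, 3) unit vectors; side_right is a (n,) bool mask; U, V are (n, T).
    Uses the exponential map at the origin, transferring any arc that crosses
    the junction circle onto the cylinder with its intrinsic direction kept.

    Works in a mirrored local frame where every origin looks like a right cap:
    local axial coordinate ξ has the junction circle at ξ = 0, the cap pole at
    ξ = r, and the cylinder toward ξ < 0.  Left caps are mirrored (x → −x), an
    isometry, so the chart's axial component is negated on the way in and the
    resulting ξ is negated on the way out; y is untouched by the mirror.
    """
    r, L = geometry.radius, geometry.cylinder_length
    sign = np.where(side_right, 1.0, -1.0)
    v0 = u0.copy()
    v0[:, 0] *= sign  # all origins now have v0_x >= 0
    Ul = U * sign[:, None]

    sin2 = np.clip(1.0 - v0[:, 0] ** 2, 0.0, 1.0)
    pole = sin2 < 1e-24
    e_ax = -v0 * v0[:, [0]]
    e_ax[:, 0] += 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        e_ax /= np.sqrt(sin2)[:, None]
    e_ax[pole] = [0.0, 0.0, 1.0]
    phi0 = np.arctan2(v0[:, 1], v0[:, 2])
    e_az = np.stack([np.zeros_like(phi0), np.cos(phi0), -np.sin(phi0)], axis=1)

    s = np.hypot(Ul, V)
    safe = np.where(s > 0, s, 1.0)
    t = (Ul / safe)[..., None] * e_ax[:, None, :] + (V / safe)[..., None] * e_az[:, None, :]
    theta = s / r
    w = np.cos(theta)[..., None] * v0[:, None, :] + np.sin(theta)[..., None] * t

    xi = np.empty(s.shape)
    y_loc = np.empty(s.shape)
    on_cap = w[..., 0] >= 0.0
    xi[on_cap] = r * w[..., 0][on_cap]
    y_loc[on_cap] = r * w[..., 1][on_cap]

    crossed = ~on_cap
    if crossed.any():
        v0b = np.broadcast_to(v0[:, None, :], w.shape)[crossed]
        tb = t[crossed]
        theta_c = np.arctan2(v0b[:, 0], -tb[:, 0])  # first zero of w_x(θ)
        cos_tc, sin_tc = np.cos(theta_c)[:, None], np.sin(theta_c)[:, None]
        w_c = cos_tc * v0b + sin_tc * tb
        d_c = -sin_tc * v0b + cos_tc * tb
        phi_c = np.arctan2(w_c[:, 1], w_c[:, 2])
        a = d_c[:, 0]  # < 0: exit direction heads into the cylinder
        b = d_c[:, 1] * np.cos(phi_c) - d_c[:, 2] * np.sin(phi_c)
        s_rem = np.broadcast_to(s, crossed.shape)[crossed] - r * theta_c
        xi[crossed] = a * s_rem  # negative: depth into the cylinder
        y_loc[crossed] = r * np.sin(phi_c + b * s_rem / r)

    xi *= sign[:, None]
    x_cam = np.where(np.broadcast_to(side_right[:, None], s.shape), L + xi, xi)
    return x_cam, y_loc


def chart_to_camera(
    origin: SurfacePoint,
    uv: np.ndarray,
    geometry: CellGeometry,
    mode: Mode | str = Mode.WHOLE_SURFACE,
) -> np.ndarray:
    """Map chart displacements about one origin to camera positions.

    ``uv`` has shape (T, 2); returns (T, 2) camera coordinates.
    """
    mode = Mode(mode)
    uv = np.atleast_2d(np.asarray(uv, dtype=float))
    if origin.region is Region.CYLINDER:
        x, y = _camera_from_cyl_chart(
            np.array([origin.axial]), np.array([origin.azimuth]),
            uv[None, :, 0], uv[None, :, 1], geometry, mode,
        )
    else:
        if mode is Mode.CYLINDER_ONLY:
            raise ValueError("cylinder_only mode requires cylinder origins")
        x, y = _camera_from_cap_chart(
            np.asarray(origin.cap_dir, dtype=float)[None, :],
            np.array([origin.region is Region.CAP_RIGHT]),
            uv[None, :, 0], uv[None, :, 1], geometry,
        )
    return np.stack([x[0], y[0]], axis=-1)
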