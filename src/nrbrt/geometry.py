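"""Broken-ray geometry in the slice plane.

All geometry lives in the (y, z) plane of a sample slice: z increases into the
sample from the illuminated face at z = 0, the opposite face is at z = Lz, and
sources/detectors sit on lines parallel to y on those faces.  A broken ray is a
two-segment photon path with a single fluorescence event at its vertex R; the
two legs point from R toward the source and the detector along the fixed unit
vectors of the scan.

The angular machinery (acceptance-cone windows ``theta_window`` and the
geometric factors ``f_lk`` / ``f̄_lk``) quantifies how a finite, collimated
detector integrates the single-scattered specific intensity.  The closed-form
window is certified against a brute-force direction scan
(:func:`theta_window_scan`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "GeometryError",
    "DirectionSet",
    "DetectorSpec",
    "BrokenRay",
    "AngularWindow",
    "scan_directions",
    "vertex",
    "broken_ray",
    "theta_window",
    "theta_window_scan",
    "geom_factor_field",
    "geom_factor_bar",
]

_PARALLEL_TOL = 1e-12


class GeometryError(ValueError):
    """Raised for degenerate broken-ray configurations (parallel lines etc.)."""


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise GeometryError("zero direction vector")
    return v / n


def _cross2(a, b):
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


@dataclass(frozen=True)
class DirectionSet:
    """The three fixed outward leg directions of a complete scan.

    ``u1, u2, u3`` point *from the vertex toward* the source/detector stations.
    Direction 1 is normal to the illuminated surface (toward z = 0); for the
    transmission scan directions 2 and 3 point toward the exit face at +/-45
    degrees from its normal and are mutually orthogonal (at 135 degrees from
    direction 1); for the backscattering scan all three point back toward the
    illuminated face.
    """

    u1: np.ndarray
    u2: np.ndarray
    u3: np.ndarray
    scan_type: Literal["transmission", "backscattering"] = "transmission"

    def __post_init__(self):
        for name in ("u1", "u2", "u3"):
            object.__setattr__(self, name, _unit(getattr(self, name)))
        us = self.units
        for i in range(3):
            for j in range(i + 1, 3):
                if abs(_cross2(us[i], us[j])) < _PARALLEL_TOL:
                    raise GeometryError(f"directions {i+1} and {j+1} are parallel")

    @property
    def units(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.u1, self.u2, self.u3)

    def u(self, l: int) -> np.ndarray:
        """1-based access to the leg directions."""
        return self.units[l - 1]


def scan_directions(
    scan_type: str, angles_deg: Sequence[float] | None = None
) -> DirectionSet:
    """Build the three scan directions for a transmission or backscattering scan.

    Angles are measured in the slice plane relative to the surface normal of the
    face each leg exits through.  Defaults: transmission (0, +45, -45) with legs
    2 and 3 toward the exit face; backscattering (0, +45, -70) with all legs
    toward the illuminated face.

    Parameters
    ----------
    scan_type : {"transmission", "backscattering"}
    angles_deg : optional (a2, a3) override for the two oblique directions.
    """
    u1 = np.array([0.0, -1.0])  # toward the illuminated face
    if scan_type == "transmission":
        a2, a3 = (45.0, -45.0) if angles_deg is None else angles_deg
        # legs exit through the far face: +z component
        u2 = np.array([np.sin(np.deg2rad(a2)), np.cos(np.deg2rad(a2))])
        u3 = np.array([np.sin(np.deg2rad(a3)), np.cos(np.deg2rad(a3))])
    elif scan_type == "backscattering":
        a2, a3 = (45.0, -70.0) if angles_deg is None else angles_deg
        # all legs exit through the illuminated face: -z component
        u2 = np.array([np.sin(np.deg2rad(a2)), -np.cos(np.deg2rad(a2))])
        u3 = np.array([np.sin(np.deg2rad(a3)), -np.cos(np.deg2rad(a3))])
    else:
        raise ValueError(f"unknown scan_type {scan_type!r}")
    return DirectionSet(u1, u2, u3, scan_type=scan_type)  # type: ignore[arg-type]


@dataclass(frozen=True)
class DetectorSpec:
    """A square, angularly selective detector.

    Parameters
    ----------
    delta_d : side of the square detector, mm.
    beta_deg : acceptance half-angle, degrees (0 < beta < 90).
    eta0 : sensitivity constant.
    direction_index : 1-based index of the collimation direction in the scan's
        :class:`DirectionSet`.
    scoring_mode : "same-detector" projects the tilted detector onto the sample
        face (rectangle delta_d x delta_d/cos(alpha)); "per-direction-square"
        scores on a fixed square of side delta_d for every direction.
    """

    delta_d: float
    beta_deg: float
    eta0: float = 1.0
    direction_index: int = 1
    scoring_mode: Literal["same-detector", "per-direction-square"] = "same-detector"

    def __post_init__(self):
        if not (0.0 < self.beta_deg < 90.0):
            raise ValueError("acceptance half-angle must be in (0, 90) degrees")
        if self.delta_d <= 0:
            raise ValueError("detector side must be positive")

    @property
    def beta(self) -> float:
        """Acceptance half-angle in radians."""
        return float(np.deg2rad(self.beta_deg))

    def footprint_halfwidth(self, s_k: np.ndarray, face_normal: np.ndarray) -> float:
        """Half-width (along y, mm) of the scoring region on the sample face."""
        if self.scoring_mode == "per-direction-square":
            return 0.5 * self.delta_d
        cos_a = abs(float(np.dot(_unit(s_k), _unit(face_normal))))
        if cos_a < 1e-9:
            raise GeometryError("detector collimated parallel to the face")
        return 0.5 * self.delta_d / cos_a


@dataclass(frozen=True)
class BrokenRay:
    """A single broken ray: vertex, outward leg directions, leg lengths."""

    vertex: np.ndarray
    u_l: np.ndarray  # unit vector from vertex toward the source
    u_k: np.ndarray  # unit vector from vertex toward the detector
    L1: float
    L2: float

    @property
    def source(self) -> np.ndarray:
        return self.vertex + self.L1 * self.u_l

    @property
    def detector(self) -> np.ndarray:
        return self.vertex + self.L2 * self.u_k


@dataclass(frozen=True)
class AngularWindow:
    """Interval of polar angles theta accepted by the detector cone.

    ``width`` is the total angular measure; it equals ``theta_max - theta_min``
    except in the degenerate on-axis configuration where two symmetric arcs
    contribute (then ``width`` may reach 2*beta while the printed interval covers
    the principal arc).
    """

    theta_min: float
    theta_max: float
    width: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.width is None:
            object.__setattr__(self, "width", max(0.0, self.theta_max - self.theta_min))


def vertex(r_s, s_l, r_d, s_k, sample_box=None):
    """Intersection of the source ray and the detector line of sight.

    The source ray starts at ``r_s`` with (illumination) direction ``s_l``; the
    detector line passes through ``r_d`` with (detection) direction ``s_k``.
    Returns the intersection point; raises :class:`GeometryError` for parallel
    lines.  If ``sample_box = (Ly, Lz)`` (or ((y0, y1), (z0, z1))) is given, a
    vertex outside the box raises as well.
    """
    r_s = np.asarray(r_s, float)
    r_d = np.asarray(r_d, float)
    s_l = _unit(s_l)
    s_k = _unit(s_k)
    det = _cross2(s_l, -s_k)
    if abs(det) < _PARALLEL_TOL:
        raise GeometryError("source and detector lines are parallel")
    rhs = r_d - r_s
    a = _cross2(rhs, -s_k) / det  # distance from r_s along s_l
    R = r_s + a * s_l
    if sample_box is not None:
        (y0, y1), (z0, z1) = _box_bounds(sample_box)
        eps = 1e-9
        if not (y0 - eps <= R[0] <= y1 + eps and z0 - eps <= R[1] <= z1 + eps):
            raise GeometryError(f"vertex {R} outside the sample box")
    return R


def _box_bounds(sample_box):
    sample_box = np.asarray(sample_box, dtype=object)
    if np.shape(sample_box) == (2,):
        Ly, Lz = float(sample_box[0]), float(sample_box[1])
        return (0.0, Ly), (0.0, Lz)
    (y0, y1), (z0, z1) = sample_box
    return (float(y0), float(y1)), (float(z0), float(z1))


def broken_ray(r_s, s_l, r_d, s_k, sample_box=None) -> BrokenRay:
    """Construct the :class:`BrokenRay` for a source/detector pair."""
    r_s = np.asarray(r_s, float)
    r_d = np.asarray(r_d, float)
    R = vertex(r_s, s_l, r_d, s_k, sample_box=sample_box)
    L1 = float(np.linalg.norm(R - r_s))
    L2 = float(np.linalg.norm(r_d - R))
    u_l = (r_s - R) / L1 if L1 > 0 else -_unit(s_l)
    u_k = (r_d - R) / L2 if L2 > 0 else _unit(s_k)
    return BrokenRay(vertex=R, u_l=u_l, u_k=u_k, L1=L1, L2=L2)


def _signed_angle(v, e, e_perp):
    """Signed in-plane angle of v relative to axis e (perp = rot90(e))."""
    return np.arctan2(
        np.asarray(v)[..., 0] * e_perp[0] + np.asarray(v)[..., 1] * e_perp[1],
        np.asarray(v)[..., 0] * e[0] + np.asarray(v)[..., 1] * e[1],
    )


def theta_window(r, r_s, s_l, s_k, beta) -> AngularWindow:
    """Window of polar angles contributing to the signal at observation point r.

    The window is the set of in-plane arrival directions ``s`` at ``r`` whose
    back-projected ray meets the source ray (from ``r_s`` along ``s_l``) at a
    valid vertex, intersected with the detector acceptance cone of half-angle
    ``beta`` (radians) about ``s_k``.  theta is the polar angle of ``s`` in the
    frame whose z axis is the line of sight ``r - r_s``.
    """
    r = np.asarray(r, float)
    r_s = np.asarray(r_s, float)
    s_l = _unit(s_l)
    s_k = _unit(s_k)
    d = r - r_s
    dist = np.linalg.norm(d)
    if dist < _PARALLEL_TOL:
        raise GeometryError("observation point coincides with the source")
    e = d / dist
    e_perp = np.array([-e[1], e[0]])
    theta_l = float(np.arccos(np.clip(np.dot(s_l, e), -1.0, 1.0)))
    hi = np.pi - theta_l  # step function: theta + theta_l <= pi
    psi_k = float(_signed_angle(s_k, e, e_perp))
    side = -np.sign(np.dot(s_l, e_perp))
    if side == 0.0:
        # r lies on the source line: every direction back-projects onto the
        # ray at r itself (a zero-length detector leg), so the whole cone is
        # admissible when r is downstream of the source, none of it otherwise.
        if np.dot(s_l, e) < 0:
            return AngularWindow(0.0, 0.0, 0.0)
        th_k = abs(psi_k)
        lo_w = max(0.0, th_k - beta)
        hi_w = min(np.pi, th_k + beta)
        return AngularWindow(lo_w, hi_w, 2.0 * beta)
    theta_k = side * psi_k  # cone center in the signed-branch coordinate
    lo_w = max(0.0, theta_k - beta)
    hi_w = min(hi, theta_k + beta)
    if hi_w <= lo_w:
        return AngularWindow(0.0, 0.0, 0.0)
    return AngularWindow(lo_w, hi_w)


def _theta_window_width_arrays(ry, rz, r_s, s_l, s_k, beta):
    """Vectorized window width + sin(theta_l) for arrays of observation points.

    Returns (width, dist, sin_theta_l) with the same shape as ry/rz.
    """
    dy = np.asarray(ry, float) - r_s[0]
    dz = np.asarray(rz, float) - r_s[1]
    dist = np.hypot(dy, dz)
    ey, ez = dy / dist, dz / dist
    # e_perp = (-ez, ey)
    dot_l = s_l[0] * ey + s_l[1] * ez
    perp_l = -s_l[0] * ez + s_l[1] * ey
    theta_l = np.arccos(np.clip(dot_l, -1.0, 1.0))
    hi = np.pi - theta_l
    psi_k = np.arctan2(-s_k[0] * ez + s_k[1] * ey, s_k[0] * ey + s_k[1] * ez)
    side = -np.sign(perp_l)
    theta_k = np.where(side == 0, np.abs(psi_k), side * psi_k)
    lo_w = np.maximum(0.0, theta_k - beta)
    hi_w = np.minimum(hi, theta_k + beta)
    width = np.maximum(0.0, hi_w - lo_w)
    # points exactly on the source line (measure zero under quadrature): the
    # whole cone is admissible downstream of the source
    width = np.where(side == 0, np.where(dot_l > 0, 2.0 * beta, 0.0), width)
    return width, dist, np.sin(theta_l)


def theta_window_scan(r, r_s, s_l, s_k, beta, n=1_000_000):
    """Brute-force reference for :func:`theta_window`.

    Scans ``n`` uniformly spaced in-plane directions over the full signed circle
    and evaluates the defining step functions directly: the back-projected ray
    from ``r`` must meet the source ray at a vertex with ``theta + theta_l <= pi``,
    and the arrival direction must lie within ``beta`` of ``s_k``.  Returns
    ``(measure, theta_lo, theta_hi)`` where the endpoints bound the accepted set
    in polar angle (NaN if empty).  Resolution: 2*pi/n.
    """
    r = np.asarray(r, float)
    r_s = np.asarray(r_s, float)
    s_l = _unit(s_l)
    s_k = _unit(s_k)
    d = r - r_s
    dist = np.linalg.norm(d)
    e = d / dist
    e_perp = np.array([-e[1], e[0]])
    psi = -np.pi + (np.arange(n) + 0.5) * (2 * np.pi / n)
    s = np.outer(np.cos(psi), e) + np.outer(np.sin(psi), e_perp)  # (n, 2)
    theta = np.abs(psi)
    theta_l = float(np.arccos(np.clip(np.dot(s_l, e), -1.0, 1.0)))
    # vertex of the back-projected ray on the source ray: solve
    # r_s + xi*s_l = r - L2*s  ->  xi, L2 by 2x2 cross products
    den = _cross2(s_l[None, :], s)
    on_ray = np.abs(den) < 1e-14
    rhs = r - r_s
    with np.errstate(divide="ignore", invalid="ignore"):
        xi = _cross2(rhs[None, :], s) / den
        L2 = _cross2(s_l[None, :], rhs[None, :]) / den
    # r exactly on the source line: the intersection sits at r itself for
    # every direction (zero-length detector leg), which is admissible when r
    # is downstream of the source.
    r_on_line = abs(_cross2(s_l, rhs)) < 1e-12
    if r_on_line:
        valid = (xi > 0) & ~on_ray
    else:
        valid = (xi > 0) & (L2 > 0) & ~on_ray
    valid &= theta + theta_l <= np.pi
    cos_acc = s @ s_k
    valid &= cos_acc >= np.cos(beta)
    measure = valid.sum() * (2 * np.pi / n)
    if not valid.any():
        return 0.0, np.nan, np.nan
    th = theta[valid]
    return float(measure), float(th.min()), float(th.max())


def geom_factor_field(r, r_s, s_l, s_k, beta) -> float:
    """Geometric factor f_lk(r) = Delta_theta(r) / (|r - r_s| sin(theta_l))."""
    r = np.asarray(r, float)
    r_s = np.asarray(r_s, float)
    s_l = _unit(s_l)
    d = r - r_s
    dist = np.linalg.norm(d)
    sin_l = abs(_cross2(s_l, d / dist))
    if sin_l < 1e-12:
        raise GeometryError("detector line of sight along the source ray")
    w = theta_window(r, r_s, s_l, s_k, beta)
    return float(w.width / (dist * sin_l))


def geom_factor_bar(
    detector: DetectorSpec,
    r_d,
    s_k,
    r_s,
    s_l,
    face_normal=(0.0, -1.0),
    n_quad: int = 21,
) -> float:
    """Finite-detector geometric factor f̄_lk (quadrature of f_lk over δΣ').

    The scoring region δΣ' is the projection of the detector onto the sample
    face, centered at ``r_d``: its in-plane (y) extent is delta_d/cos(alpha) in
    "same-detector" mode or delta_d in "per-direction-square" mode, and its
    out-of-plane (x) extent enters only as the multiplicative length delta_d
    (the broken rays are coplanar).  Gauss-Legendre quadrature with ``n_quad``
    in-plane nodes.
    """
    r_d = np.asarray(r_d, float)
    r_s = np.asarray(r_s, float)
    s_l = _unit(s_l)
    s_k = _unit(s_k)
    half_w = detector.footprint_halfwidth(s_k, np.asarray(face_normal, float))
    nodes, wts = np.polynomial.legendre.leggauss(n_quad)
    ys = r_d[0] + half_w * nodes
    zs = np.full_like(ys, r_d[1])
    width, dist, sin_l = _theta_window_width_arrays(ys, zs, r_s, s_l, s_k, detector.beta)
    if np.any(sin_l < 1e-12):
        raise GeometryError("detector line of sight along the source ray")
    f = width / (dist * sin_l)
    return float(detector.delta_d * half_w * np.dot(wts, f))
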