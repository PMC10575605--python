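"""Noise-free single-scattering forward model.

The detector signal for a source/detector pair is, in the single-scattering
approximation with a finite collimated detector,

    dW = (eta0 * W / (2 pi sigma)) * fbar_lk * n_tilde(R)
         * exp( - int_leg1 mu_e  -  int_leg2 mu_f ),

where R is the vertex of the broken ray defined by the source ray and the
detector's central line of sight, leg 1 runs from the source to R (excitation
wavelength) and leg 2 from R to the detector (fluorescence wavelength), and
``fbar_lk`` is the finite-detector geometric factor.  Line integrals are exact
Siddon-style voxel traversals of the piecewise-constant slice maps.

A higher-fidelity variant resolving the detector footprint and the acceptance
cone (:func:`signal_area_integrated`) is retained as a validation mode; it
reduces to :func:`signal_single_scatter` for small acceptance angles and
smooth parameter maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    DetectorSpec,
    GeometryError,
    _theta_window_width_arrays,
    _unit,
    broken_ray,
)

__all__ = [
    "Constants",
    "ray_integral",
    "ray_exit_length",
    "signal_single_scatter",
    "signal_area_integrated",
]


@dataclass(frozen=True)
class Constants:
    """Physical constants of the measurement; all default to 1 (arbitrary units).

    The attenuation reconstruction is independent of these and concentrations
    are reported max-normalized, so their absolute values are bookkeeping only.
    """

    W: float = 1.0
    eta0: float = 1.0
    sigma: float = 1.0
    E_f: float = 1.0

    def __post_init__(self):
        if min(self.W, self.eta0, self.sigma, self.E_f) <= 0:
            raise ValueError("constants must be positive")

    @property
    def prefactor(self) -> float:
        return self.eta0 * self.W / (2.0 * np.pi * self.sigma)


def ray_exit_length(start, direction, extent) -> float:
    """Distance from ``start`` along ``direction`` to the boundary of the box
    [0, Ly] x [0, Lz] (2D, (y, z) coordinates)."""
    start = np.asarray(start, float)
    d = _unit(direction)
    t_exit = np.inf
    for ax in range(2):
        if abs(d[ax]) > 1e-14:
            for bound in (0.0, float(extent[ax])):
                t = (bound - start[ax]) / d[ax]
                if t > 1e-12:
                    t_exit = min(t_exit, t)
    if not np.isfinite(t_exit):
        return 0.0
    return float(t_exit)


def ray_integral(grid, start, direction, pitch, length=None) -> float:
    """Exact line integral of a piecewise-constant 2D field along a ray.

    ``grid`` is indexed ``[iz, iy]`` with voxel centers at ((i+0.5)*pitch);
    ``start`` and ``direction`` are (y, z).  Integrates from ``start`` to the
    grid boundary (or to ``length`` if given) by accumulating value x chord
    length over every traversed voxel.
    """
    grid = np.asarray(grid, float)
    start = np.asarray(start, float)
    d = _unit(direction)
    nz, ny = grid.shape
    extent = (ny * pitch, nz * pitch)
    t_end = ray_exit_length(start, d, extent)
    if length is not None:
        t_end = min(t_end, float(length))
    if t_end <= 0:
        return 0.0
    # gridline crossings along the ray
    ts = [np.array([0.0, t_end])]
    for ax, nvox in ((0, ny), (1, nz)):
        if abs(d[ax]) > 1e-14:
            edges = np.arange(nvox + 1) * pitch
            t = (edges - start[ax]) / d[ax]
            ts.append(t[(t > 1e-12) & (t < t_end - 1e-12)])
    t_all = np.unique(np.concatenate(ts))
    mids = 0.5 * (t_all[1:] + t_all[:-1])
    seg = np.diff(t_all)
    ys = start[0] + mids * d[0]
    zs = start[1] + mids * d[1]
    iy = np.clip((ys / pitch).astype(int), 0, ny - 1)
    iz = np.clip((zs / pitch).astype(int), 0, nz - 1)
    return float(np.dot(grid[iz, iy], seg))


def _sample_nearest(grid, point, pitch):
    nz, ny = grid.shape
    iy = int(np.clip(np.floor(point[0] / pitch), 0, ny - 1))
    iz = int(np.clip(np.floor(point[1] / pitch), 0, nz - 1))
    return float(grid[iz, iy])


def signal_single_scatter(
    slice_maps,
    r_s,
    s_l,
    r_d,
    s_k,
    detector: DetectorSpec,
    constants: Constants = Constants(),
    f_bar: float | None = None,
    face_normal=(0.0, -1.0),
) -> tuple[float, float]:
    """Detector signal dW for one broken ray; returns ``(dW, f_bar)``.

    ``r_s``/``s_l`` are the source position and illumination direction,
    ``r_d``/``s_k`` the detector-center position and collimation direction.
    The vertex is the intersection of the two central lines; legs are truncated
    at the sample boundary.  ``f_bar`` may be passed in to avoid recomputation.
    """
    from .geometry import geom_factor_bar

    extent = slice_maps.extent_mm
    ray = broken_ray(r_s, s_l, r_d, s_k, sample_box=(extent[0], extent[1]))
    if f_bar is None:
        f_bar = geom_factor_bar(detector, np.asarray(r_d, float), s_k,
                                np.asarray(r_s, float), s_l, face_normal=face_normal)
    tau_e = ray_integral(slice_maps.mu_e, np.asarray(r_s, float), -ray.u_l,
                         slice_maps.pitch, length=ray.L1)
    tau_f = ray_integral(slice_maps.mu_f, ray.vertex, ray.u_k,
                         slice_maps.pitch, length=ray.L2)
    n_t = _sample_nearest(slice_maps.n_tilde, ray.vertex, slice_maps.pitch)
    dW = constants.prefactor * f_bar * n_t * np.exp(-tau_e - tau_f)
    return float(dW), float(f_bar)


def signal_area_integrated(
    slice_maps,
    r_s,
    s_l,
    r_d,
    s_k,
    detector: DetectorSpec,
    constants: Constants = Constants(),
    face_normal=(0.0, -1.0),
    n_quad: int = 21,
    n_theta: int = 15,
) -> float:
    """Footprint- and cone-resolved signal (validation mode).

    Integrates n_tilde(R') exp(-tau_e - tau_f) over the detector footprint and
    over the angular window at each footprint point, instead of evaluating the
    integrand at the central vertex.  Quadrature: ``n_quad`` Gauss-Legendre
    nodes across the footprint, ``n_theta`` nodes across each angular window.
    """
    r_s = np.asarray(r_s, float)
    r_d = np.asarray(r_d, float)
    s_l = _unit(s_l)
    s_k = _unit(s_k)
    half_w = detector.footprint_halfwidth(s_k, np.asarray(face_normal, float))
    nodes, wts = np.polynomial.legendre.leggauss(n_quad)
    tnodes, twts = np.polynomial.legendre.leggauss(n_theta)
    extent = slice_maps.extent_mm
    total = 0.0
    for u, wu in zip(nodes, wts):
        r = r_d + np.array([half_w * u, 0.0])
        dy, dz = r - r_s
        dist = float(np.hypot(dy, dz))
        e = np.array([dy, dz]) / dist
        e_perp = np.array([-e[1], e[0]])
        sin_l = abs(s_l[0] * e_perp[0] + s_l[1] * e_perp[1])
        if sin_l < 1e-12:
            raise GeometryError("footprint point on the source ray")
        from .geometry import theta_window

        w = theta_window(r, r_s, s_l, s_k, detector.beta)
        if w.width <= 0:
            continue
        side = -np.sign(np.dot(s_l, e_perp))
        inner = 0.0
        for t, wt in zip(tnodes, twts):
            theta = 0.5 * (w.theta_max + w.theta_min) + 0.5 * (w.theta_max - w.theta_min) * t
            s = np.cos(theta) * e + side * np.sin(theta) * e_perp
            # vertex for this arrival direction
            den = s_l[0] * s[1] - s_l[1] * s[0]
            if abs(den) < 1e-14:
                continue
            rhs = r - r_s
            xi = (rhs[0] * s[1] - rhs[1] * s[0]) / den
            Rp = r_s + xi * s_l
            L2p = float(np.linalg.norm(r - Rp))
            tau_e = ray_integral(slice_maps.mu_e, r_s, s_l, slice_maps.pitch, length=xi)
            tau_f = ray_integral(slice_maps.mu_f, Rp, s, slice_maps.pitch, length=L2p)
            n_t = _sample_nearest(slice_maps.n_tilde, Rp, slice_maps.pitch)
            inner += wt * n_t * np.exp(-tau_e - tau_f)
        inner *= 0.5 * (w.theta_max - w.theta_min)
        total += wu * inner / (dist * sin_l)
    total *= half_w  # Gauss-Legendre scaling of the footprint integral
    return float(constants.prefactor * detector.delta_d * total)
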