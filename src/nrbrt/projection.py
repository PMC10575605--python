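"""Assemble measured signals into broken-ray data functions on the vertex grid.

For every ordered direction pair (l, k) the data function at a vertex R is

    phi_lk(R) = -ln[ dW_lk / (eta0 W fbar_lk / 2 pi sigma) ]
              = -ln n_tilde(R) + int_leg-l mu_e + int_leg-k mu_f ,

so the detector-geometry weight fbar and all physical constants drop out of
derivative-based reconstruction.  A *complete scan* measures all six ordered
pairs: scans are run for one configuration of sources and detectors and then
repeated with sources and detectors interchanged.  The symmetric and
antisymmetric combinations

    phi_lk(+) = (phi_lk + phi_kl)/2        phi_lk(-) = phi_lk - phi_kl

carry the average attenuation mu(+) and the spectral difference mu(-),
respectively; phi(-) vanishes identically when mu_e == mu_f (reciprocity).

Station placement: for every vertex pixel and leg direction the source/detector
surface positions are found by inverse geometry and snapped to a 0.1 mm station
grid anchored per direction.  Both orderings of a pair are measured on the
*same* snapped station pair (that is what interchanging sources and detectors
means), so the antisymmetric combination is exactly zero for reciprocal media
regardless of snapping residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .forward_analytic import Constants, ray_integral, signal_single_scatter
from .geometry import DetectorSpec, DirectionSet, GeometryError, vertex
from .phantoms import SliceMaps

__all__ = [
    "ProjectionSet",
    "data_function",
    "assemble_scan",
    "signal_profile",
    "noise_diagnostics",
]

_PAIRS = [(1, 2), (1, 3), (2, 3)]
_ORDERED = [(l, k) for l, k in _PAIRS] + [(k, l) for l, k in _PAIRS]


def data_function(deltaW, f_bar, constants: Constants = Constants()):
    """Projection data function phi = -ln[dW / (prefactor * fbar)].

    Nonpositive signals (possible for photon-starved Monte Carlo measurements)
    yield a masked value (NaN) rather than -inf.
    """
    deltaW = np.asarray(deltaW, float)
    f_bar = np.asarray(f_bar, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = -np.log(deltaW / (constants.prefactor * f_bar))
    phi = np.where(deltaW > 0, phi, np.nan)
    if phi.ndim == 0:
        return float(phi)
    return phi


@dataclass
class ProjectionSet:
    """Data functions phi_lk over the vertex grid for all ordered pairs.

    ``phi[(l, k)]`` are 2D maps indexed [iz, iy] over the region of interest;
    ``mask`` marks valid vertices (identical for (l,k) and (k,l) by
    construction).  ``signals`` keeps the raw dW for diagnostics.
    """

    phi: dict
    mask: dict
    signals: dict
    f_bars: dict
    direction_set: DirectionSet
    detector: DetectorSpec
    constants: Constants
    pitch: float
    roi_origin: tuple[int, int]  # (iz0, iy0) of the ROI in the slice grid
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return next(iter(self.phi.values())).shape

    def pair_mask(self, l: int, k: int) -> np.ndarray:
        return self.mask[(l, k)] & self.mask[(k, l)]

    def phi_plus(self, l: int, k: int) -> np.ndarray:
        return 0.5 * (self.phi[(l, k)] + self.phi[(k, l)])

    def phi_minus(self, l: int, k: int) -> np.ndarray:
        return self.phi[(l, k)] - self.phi[(k, l)]

    def vertex_grid(self):
        """Physical (y, z) coordinates of the ROI pixel centers."""
        nz, ny = self.shape
        iz0, iy0 = self.roi_origin
        ys = (np.arange(iy0, iy0 + ny) + 0.5) * self.pitch
        zs = (np.arange(iz0, iz0 + nz) + 0.5) * self.pitch
        return ys, zs

    # -- persistence --------------------------------------------------------
    def to_hdf5(self, path) -> None:
        import h5py, json

        with h5py.File(path, "w") as f:
            for (l, k), arr in self.phi.items():
                f.create_dataset(f"phi_{l}{k}", data=arr)
                f.create_dataset(f"mask_{l}{k}", data=self.mask[(l, k)])
                f.create_dataset(f"signal_{l}{k}", data=self.signals[(l, k)])
                f.create_dataset(f"fbar_{l}{k}", data=self.f_bars[(l, k)])
            f.attrs["scan_type"] = self.direction_set.scan_type
            f.attrs["pitch"] = self.pitch
            f.attrs["roi_origin"] = self.roi_origin
            f.attrs["beta_deg"] = self.detector.beta_deg
            f.attrs["delta_d"] = self.detector.delta_d
            f.attrs["scoring_mode"] = self.detector.scoring_mode
            f.attrs["meta"] = json.dumps(self.meta)

    @classmethod
    def from_hdf5(cls, path) -> "ProjectionSet":
        import h5py, json

        from .geometry import scan_directions

        phi, mask, signals, f_bars = {}, {}, {}, {}
        with h5py.File(path, "r") as f:
            for l, k in _ORDERED:
                phi[(l, k)] = f[f"phi_{l}{k}"][...]
                mask[(l, k)] = f[f"mask_{l}{k}"][...].astype(bool)
                signals[(l, k)] = f[f"signal_{l}{k}"][...]
                f_bars[(l, k)] = f[f"fbar_{l}{k}"][...]
            ds = scan_directions(f.attrs["scan_type"])
            det = DetectorSpec(
                delta_d=float(f.attrs["delta_d"]),
                beta_deg=float(f.attrs["beta_deg"]),
                scoring_mode=str(f.attrs["scoring_mode"]),
            )
            ps = cls(
                phi=phi, mask=mask, signals=signals, f_bars=f_bars,
                direction_set=ds, detector=det, constants=Constants(),
                pitch=float(f.attrs["pitch"]),
                roi_origin=tuple(int(v) for v in f.attrs["roi_origin"]),
                meta=json.loads(f.attrs["meta"]),
            )
        return ps


# ---------------------------------------------------------------------------
# station geometry
# ---------------------------------------------------------------------------

def _leg_endpoint(Ry, Rz, u, Lz):
    """Surface point reached from vertex (Ry, Rz) along leg direction u."""
    if abs(u[1]) < 1e-12:
        raise GeometryError("leg parallel to the faces never reaches a station line")
    t = (0.0 - Rz) / u[1] if u[1] < 0 else (Lz - Rz) / u[1]
    face = 0.0 if u[1] < 0 else Lz
    return Ry + t * u[0], face


def _snap(y, anchor, spacing):
    return anchor + np.round((y - anchor) / spacing) * spacing


def _fbar_batch(detector, half_w, r_d, s_k, r_s, s_l, n_quad=21):
    """fbar for arrays of detector/source positions sharing directions."""
    nodes, wts = np.polynomial.legendre.leggauss(n_quad)
    ys = r_d[:, 0:1] + half_w * nodes[None, :]          # (N, q)
    dy = ys - r_s[:, 0:1]
    dz = r_d[:, 1:2] - r_s[:, 1:2]
    dist = np.hypot(dy, dz)
    ey, ez = dy / dist, dz / dist
    dot_l = s_l[0] * ey + s_l[1] * ez
    perp_l = -s_l[0] * ez + s_l[1] * ey
    theta_l = np.arccos(np.clip(dot_l, -1.0, 1.0))
    hi = np.pi - theta_l
    psi_k = np.arctan2(-s_k[0] * ez + s_k[1] * ey, s_k[0] * ey + s_k[1] * ez)
    side = -np.sign(perp_l)
    theta_k = np.where(side == 0, np.abs(psi_k), side * psi_k)
    width = np.maximum(0.0, np.minimum(hi, theta_k + detector.beta)
                       - np.maximum(0.0, theta_k - detector.beta))
    sin_l = np.sin(theta_l)
    f = np.where(sin_l > 1e-12, width / (dist * np.maximum(sin_l, 1e-300)), np.nan)
    return detector.delta_d * half_w * (f @ wts)


def assemble_scan(
    slice_maps: SliceMaps,
    direction_set: DirectionSet,
    detector: DetectorSpec,
    constants: Constants = Constants(),
    roi=None,
    station_spacing: float = 0.1,
    snap: bool = True,
    engine: str | Callable = "analytic",
    require_full_coverage: bool = False,
) -> ProjectionSet:
    """Measure the six ordered data-function maps over a region of interest.

    Parameters
    ----------
    roi : ((iz0, iz1), (iy0, iy1)) half-open pixel index ranges of the vertex
        grid; default full slice in z and full width in y.
    engine : "analytic" for the noise-free single-scattering model, or a
        callable ``engine(r_s, s_l, r_d, s_k, pair) -> dW`` supplying measured
        signals (e.g. Monte Carlo scoring).
    require_full_coverage : raise with a coverage report if any ROI pixel
        cannot be reached by all six measurements.
    """
    nz, ny = slice_maps.shape
    p = slice_maps.pitch
    Ly, Lz = slice_maps.extent_mm
    if roi is None:
        roi = ((0, nz), (0, ny))
    (iz0, iz1), (iy0, iy1) = roi
    zs = (np.arange(iz0, iz1) + 0.5) * p
    ys = (np.arange(iy0, iy1) + 0.5) * p
    YY, ZZ = np.meshgrid(ys, zs)  # (nzr, nyr)
    shape = YY.shape

    units = {i + 1: direction_set.units[i] for i in range(3)}
    face_normals = {i: np.array([0.0, -1.0 if units[i][1] < 0 else 1.0])
                    for i in units}

    phi = {}
    mask = {}
    signals = {}
    f_bars = {}

    for l, k in _PAIRS:
        u_l, u_k = units[l], units[k]
        # exact stations, then snap each direction on its own anchored grid
        Pl_y = np.empty(shape)
        Pk_y = np.empty(shape)
        Pl_y[:] = YY + (0.0 - ZZ) / u_l[1] * u_l[0] if u_l[1] < 0 else YY + (Lz - ZZ) / u_l[1] * u_l[0]
        Pk_y[:] = YY + (0.0 - ZZ) / u_k[1] * u_k[0] if u_k[1] < 0 else YY + (Lz - ZZ) / u_k[1] * u_k[0]
        face_l = 0.0 if u_l[1] < 0 else Lz
        face_k = 0.0 if u_k[1] < 0 else Lz
        if snap:
            Pl_y = _snap(Pl_y, Pl_y.flat[0], station_spacing)
            Pk_y = _snap(Pk_y, Pk_y.flat[0], station_spacing)
        valid = (Pl_y >= -1e-9) & (Pl_y <= Ly + 1e-9) & \
                (Pk_y >= -1e-9) & (Pk_y <= Ly + 1e-9)

        # actual vertex of the snapped broken ray (pixel center when exact)
        P_l = np.stack([Pl_y, np.full(shape, face_l)], axis=-1)
        P_k = np.stack([Pk_y, np.full(shape, face_k)], axis=-1)
        den = u_l[0] * u_k[1] - u_l[1] * u_k[0]
        rhs = P_k - P_l
        a = (rhs[..., 0] * u_k[1] - rhs[..., 1] * u_k[0]) / den
        V = P_l + a[..., None] * np.stack([np.full(shape, u_l[0]),
                                           np.full(shape, u_l[1])], axis=-1)
        inside = (V[..., 0] > 0) & (V[..., 0] < Ly) & (V[..., 1] > 0) & (V[..., 1] < Lz)
        valid &= inside

        # geometric factors for both orderings (vectorized)
        flat = valid.ravel()
        fb_lk = np.full(shape, np.nan).ravel()
        fb_kl = np.full(shape, np.nan).ravel()
        Pl_f = P_l.reshape(-1, 2)[flat]
        Pk_f = P_k.reshape(-1, 2)[flat]
        hw_k = detector.footprint_halfwidth(u_k, face_normals[k])
        hw_l = detector.footprint_halfwidth(u_l, face_normals[l])
        fb_lk[flat] = _fbar_batch(detector, hw_k, Pk_f, u_k, Pl_f, -u_l)
        fb_kl[flat] = _fbar_batch(detector, hw_l, Pl_f, u_l, Pk_f, -u_k)
        fb_lk = fb_lk.reshape(shape)
        fb_kl = fb_kl.reshape(shape)

        W_lk = np.full(shape, np.nan)
        W_kl = np.full(shape, np.nan)
        if engine == "analytic":
            idx = np.argwhere(valid)
            for iz, iy in idx:
                rs = P_l[iz, iy]
                rd = P_k[iz, iy]
                try:
                    W_lk[iz, iy], _ = signal_single_scatter(
                        slice_maps, rs, -u_l, rd, u_k, detector, constants,
                        f_bar=fb_lk[iz, iy], face_normal=face_normals[k])
                    W_kl[iz, iy], _ = signal_single_scatter(
                        slice_maps, rd, -u_k, rs, u_l, detector, constants,
                        f_bar=fb_kl[iz, iy], face_normal=face_normals[l])
                except GeometryError:
                    valid[iz, iy] = False
        else:
            idx = np.argwhere(valid)
            for iz, iy in idx:
                rs = P_l[iz, iy]
                rd = P_k[iz, iy]
                W_lk[iz, iy] = engine(rs, -u_l, rd, u_k, (l, k))
                W_kl[iz, iy] = engine(rd, -u_k, rs, u_l, (k, l))

        phi[(l, k)] = data_function(W_lk, fb_lk, constants)
        phi[(k, l)] = data_function(W_kl, fb_kl, constants)
        m_lk = valid & np.isfinite(phi[(l, k)])
        m_kl = valid & np.isfinite(phi[(k, l)])
        mask[(l, k)], mask[(k, l)] = m_lk, m_kl
        signals[(l, k)], signals[(k, l)] = W_lk, W_kl
        f_bars[(l, k)], f_bars[(k, l)] = fb_lk, fb_kl

    if require_full_coverage:
        bad = ~np.logical_and.reduce([mask[o] for o in _ORDERED])
        if bad.any():
            n_bad = int(bad.sum())
            raise GeometryError(
                f"ROI not fully scanned: {n_bad}/{bad.size} vertex pixels lack "
                "one or more of the six measurements"
            )

    return ProjectionSet(
        phi=phi, mask=mask, signals=signals, f_bars=f_bars,
        direction_set=direction_set, detector=detector, constants=constants,
        pitch=p, roi_origin=(iz0, iy0),
        meta={"engine": "analytic" if engine == "analytic" else "custom",
              "snap": snap, "station_spacing": station_spacing},
    )


def signal_profile(
    slice_maps: SliceMaps,
    direction_set: DirectionSet,
    detector: DetectorSpec,
    pair: tuple[int, int],
    vertices,
    constants: Constants = Constants(),
    engine: Callable | None = None,
):
    """Signals along a line of vertices for one ordered pair (diagnostics).

    Returns a dict with station positions, source-detector y-separations, the
    analytic signals, the geometric factors, and (if ``engine`` is given) the
    measured signals.  This reproduces the theoretical-vs-simulated signal
    comparison used to characterize measurement noise.
    """
    l, k = pair
    u_l = direction_set.u(l)
    u_k = direction_set.u(k)
    Ly, Lz = slice_maps.extent_mm
    out = {"separation": [], "r_s": [], "r_d": [], "dW_model": [], "f_bar": [],
           "dW_measured": [] if engine is not None else None, "vertices": []}
    face_n_k = np.array([0.0, -1.0 if u_k[1] < 0 else 1.0])
    for Ry, Rz in np.atleast_2d(vertices):
        sy, sface = _leg_endpoint(Ry, Rz, u_l, Lz)
        dy, dface = _leg_endpoint(Ry, Rz, u_k, Lz)
        rs = np.array([sy, sface])
        rd = np.array([dy, dface])
        if not (0 <= sy <= Ly and 0 <= dy <= Ly):
            continue
        dW, fb = signal_single_scatter(
            slice_maps, rs, -u_l, rd, u_k, detector, constants,
            face_normal=face_n_k)
        out["separation"].append(abs(dy - sy))
        out["r_s"].append(rs)
        out["r_d"].append(rd)
        out["vertices"].append((Ry, Rz))
        out["dW_model"].append(dW)
        out["f_bar"].append(fb)
        if engine is not None:
            out["dW_measured"].append(engine(rs, -u_l, rd, u_k, (l, k)))
    for key in ("separation", "dW_model", "f_bar", "dW_measured"):
        if out.get(key) is not None:
            out[key] = np.asarray(out[key], float)
    return out


def noise_diagnostics(profile: dict) -> dict:
    """Percentage relative difference between measured and model signals.

    ``epsilon = 100 * (dW_measured - dW_model*scale) / (dW_model*scale)`` per
    source-detector separation, where ``scale`` is the least-squares constant
    matching the measured to the model profile (the absolute Monte Carlo scale
    is a global constant that drops out of reconstruction).
    """
    if profile.get("dW_measured") is None:
        raise ValueError("profile carries no measured signals")
    model = np.asarray(profile["dW_model"], float)
    meas = np.asarray(profile["dW_measured"], float)
    scale = float(np.dot(model, meas) / np.dot(model, model))
    ref = model * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        eps = 100.0 * (meas - ref) / ref
    return {
        "separation": np.asarray(profile["separation"], float),
        "epsilon_pct": eps,
        "scale": scale,
    }


def diagnostics_to_csv(diag: dict, path) -> None:
    """Write a noise-diagnostics table (separation, epsilon %) as CSV."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["separation_mm", "epsilon_pct"])
        for s, e in zip(diag["separation"], diag["epsilon_pct"]):
            w.writerow([float(s), float(e)])


def projection_identity_residual(
    ps: ProjectionSet, slice_maps: SliceMaps, l: int, k: int
) -> np.ndarray:
    """|phi_lk - (-ln n_tilde + int mu_e + int mu_f)| over the valid ROI.

    Recomputes the right-hand side with the ray-integral oracle; the residual
    is zero (to rounding) for the analytic engine and measures model mismatch
    plus noise for measured data.  Exact only for unsnapped or
    snapping-exact geometries (vertices at pixel centers).
    """
    u_l = ps.direction_set.u(l)
    u_k = ps.direction_set.u(k)
    ys, zs = ps.vertex_grid()
    res = np.full(ps.shape, np.nan)
    m = ps.pair_mask(l, k)
    for iz, _z in enumerate(zs):
        for iy, _y in enumerate(ys):
            if not m[iz, iy]:
                continue
            R = np.array([ys[iy], zs[iz]])
            Ie = ray_integral(slice_maps.mu_e, R, u_l, ps.pitch)
            If = ray_integral(slice_maps.mu_f, R, u_k, ps.pitch)
            iyv = int(R[0] / ps.pitch)
            izv = int(R[1] / ps.pitch)
            nt = slice_maps.n_tilde[izv, iyv]
            rhs = -np.log(nt) + Ie + If if nt > 0 else np.nan
            res[iz, iy] = abs(ps.phi[(l, k)][iz, iy] - rhs)
    return res
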