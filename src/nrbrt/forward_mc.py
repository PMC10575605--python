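"""Analog Monte Carlo photon transport with fluorescence conversion.

Physics (matching the modelling assumptions of the analytic forward model):
isotropic elastic scattering; fluorophore quantum efficiency of one;
monochromatic excitation and delta-function emission spectra (a single
fluorescence wavelength); no reabsorption of fluorescence light by the
fluorophore; index-matched boundaries (no refraction or reflection).

Each photon is tracked through the voxelized phantom with exponential free
paths against the local total attenuation at its current wavelength.  At an
interaction the channel is sampled proportionally to (mu_a: absorbed),
(mu_s: isotropic redirect) and, at the excitation wavelength only,
(n*sigma: convert to the fluorescence wavelength, isotropic re-emission).
Photons leaving the cuboid are recorded; fluorescence exits keep their exact
surface position and direction.  Conservation holds exactly:
absorbed + exited == N.

Scoring: an angularly selective detector of side ``delta_d`` collimated along
``s_k`` with acceptance half-angle ``beta`` sums, over fluorescence hits inside
its surface footprint and within the cone, the projection cos(angle) times the
photon energy:

    dW = eta0 * sum_hits (s_k . s_j) * E_f .

The default free-path sampler walks voxels exactly (piecewise-constant media);
Woodcock (delta) tracking against the majorant attenuation is available as an
option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .forward_analytic import Constants
from .geometry import DetectorSpec
from .phantoms import Phantom

__all__ = ["HitRecords", "propagate", "score", "MCEngine"]


@dataclass
class HitRecords:
    """Fluorescence photons recorded on the sample surface."""

    positions: np.ndarray  # (M, 3) mm
    directions: np.ndarray  # (M, 3) unit, outward
    tallies: dict
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.positions)

    def to_hdf5(self, path) -> None:
        import h5py, json

        with h5py.File(path, "w") as f:
            f.create_dataset("positions", data=self.positions)
            f.create_dataset("directions", data=self.directions)
            for k, v in self.tallies.items():
                f.attrs[f"tally_{k}"] = v
            f.attrs["meta"] = json.dumps(self.meta)

    @classmethod
    def from_hdf5(cls, path) -> "HitRecords":
        import h5py, json

        with h5py.File(path, "r") as f:
            tallies = {k[6:]: int(f.attrs[k]) for k in f.attrs if k.startswith("tally_")}
            return cls(
                positions=f["positions"][...],
                directions=f["directions"][...],
                tallies=tallies,
                meta=json.loads(f.attrs["meta"]),
            )


@njit(cache=False)
def _isotropic(out):
    cz = 2.0 * np.random.random() - 1.0
    sz = np.sqrt(max(0.0, 1.0 - cz * cz))
    ph = 2.0 * np.pi * np.random.random()
    out[0] = sz * np.cos(ph)
    out[1] = sz * np.sin(ph)
    out[2] = cz


@njit(cache=False)
def _transport(mu_t_e, mu_t_f, mu_a_e, mu_s_e, mu_a_f, mu_s_f,
               pitch, p0, d0, N, seed, hit_pos, hit_dir, woodcock):
    """Track N photons; returns (n_hits, n_absorbed, n_exit_exc, n_exit_fluo)."""
    np.random.seed(seed)
    nx, ny, nz = mu_t_e.shape
    Lx = nx * pitch
    Ly = ny * pitch
    Lz = nz * pitch
    n_abs = 0
    n_exit_e = 0
    n_exit_f = 0
    n_hits = 0
    p = np.empty(3)
    d = np.empty(3)
    mu_max_e = 0.0
    mu_max_f = 0.0
    if woodcock:
        mu_max_e = mu_t_e.max()
        mu_max_f = mu_t_f.max()
    eps = 1e-9
    for _ in range(N):
        for a in range(3):
            p[a] = p0[a]
            d[a] = d0[a]
        fluo = False
        alive = True
        while alive:
            if woodcock:
                # delta tracking against the wavelength's majorant
                mu_maj = mu_max_f if fluo else mu_max_e
                if mu_maj <= 0.0:
                    # vacuum: fly straight out
                    t_exit = 1e30
                    for a in range(3):
                        if d[a] > eps:
                            L = Lx if a == 0 else (Ly if a == 1 else Lz)
                            t = (L - p[a]) / d[a]
                            if t < t_exit:
                                t_exit = t
                        elif d[a] < -eps:
                            t = (0.0 - p[a]) / d[a]
                            if t < t_exit:
                                t_exit = t
                    for a in range(3):
                        p[a] = p[a] + t_exit * d[a]
                    if fluo:
                        if n_hits < hit_pos.shape[0]:
                            for a in range(3):
                                hit_pos[n_hits, a] = p[a]
                                hit_dir[n_hits, a] = d[a]
                            n_hits += 1
                        n_exit_f += 1
                    else:
                        n_exit_e += 1
                    alive = False
                    continue
                s = -np.log(np.random.random()) / mu_maj
                for a in range(3):
                    p[a] = p[a] + s * d[a]
                if (p[0] <= 0.0 or p[0] >= Lx or p[1] <= 0.0 or p[1] >= Ly
                        or p[2] <= 0.0 or p[2] >= Lz):
                    # left the box: project back to the exit face
                    t_exit = 1.0
                    for a in range(3):
                        pa = p[a] - s * d[a]
                        L = Lx if a == 0 else (Ly if a == 1 else Lz)
                        if d[a] > eps:
                            t = (L - pa) / d[a] / s
                        elif d[a] < -eps:
                            t = (0.0 - pa) / d[a] / s
                        else:
                            t = 2.0
                        if t < t_exit:
                            t_exit = t
                    for a in range(3):
                        p[a] = (p[a] - s * d[a]) + t_exit * s * d[a]
                    if fluo:
                        if n_hits < hit_pos.shape[0]:
                            for a in range(3):
                                hit_pos[n_hits, a] = p[a]
                                hit_dir[n_hits, a] = d[a]
                            n_hits += 1
                        n_exit_f += 1
                    else:
                        n_exit_e += 1
                    alive = False
                    continue
                ix = int(p[0] / pitch)
                iy = int(p[1] / pitch)
                iz = int(p[2] / pitch)
                if ix >= nx: ix = nx - 1
                if iy >= ny: iy = ny - 1
                if iz >= nz: iz = nz - 1
                mu_here = mu_t_f[ix, iy, iz] if fluo else mu_t_e[ix, iy, iz]
                if np.random.random() * mu_maj > mu_here:
                    continue  # virtual collision
                interact = True
            else:
                # exact voxel-by-voxel chord accumulation
                tau = -np.log(np.random.random())
                ix = int(p[0] / pitch)
                iy = int(p[1] / pitch)
                iz = int(p[2] / pitch)
                if ix >= nx: ix = nx - 1
                if iy >= ny: iy = ny - 1
                if iz >= nz: iz = nz - 1
                if ix < 0: ix = 0
                if iy < 0: iy = 0
                if iz < 0: iz = 0
                # DDA setup
                sx = 1 if d[0] > 0 else (-1 if d[0] < 0 else 0)
                sy = 1 if d[1] > 0 else (-1 if d[1] < 0 else 0)
                sz = 1 if d[2] > 0 else (-1 if d[2] < 0 else 0)
                big = 1e30
                tmx = ((ix + (1 if sx > 0 else 0)) * pitch - p[0]) / d[0] if sx != 0 else big
                tmy = ((iy + (1 if sy > 0 else 0)) * pitch - p[1]) / d[1] if sy != 0 else big
                tmz = ((iz + (1 if sz > 0 else 0)) * pitch - p[2]) / d[2] if sz != 0 else big
                tdx = pitch / abs(d[0]) if sx != 0 else big
                tdy = pitch / abs(d[1]) if sy != 0 else big
                tdz = pitch / abs(d[2]) if sz != 0 else big
                t_prev = 0.0
                interact = False
                exited = False
                t_int = 0.0
                while True:
                    if tmx <= tmy and tmx <= tmz:
                        t_next = tmx
                        axis = 0
                    elif tmy <= tmz:
                        t_next = tmy
                        axis = 1
                    else:
                        t_next = tmz
                        axis = 2
                    mu_here = mu_t_f[ix, iy, iz] if fluo else mu_t_e[ix, iy, iz]
                    seg = t_next - t_prev
                    if mu_here > 0.0 and mu_here * seg >= tau:
                        t_int = t_prev + tau / mu_here
                        interact = True
                        break
                    tau -= mu_here * seg
                    t_prev = t_next
                    if axis == 0:
                        ix += sx
                        tmx += tdx
                        if ix < 0 or ix >= nx:
                            exited = True
                            break
                    elif axis == 1:
                        iy += sy
                        tmy += tdy
                        if iy < 0 or iy >= ny:
                            exited = True
                            break
                    else:
                        iz += sz
                        tmz += tdz
                        if iz < 0 or iz >= nz:
                            exited = True
                            break
                if exited:
                    for a in range(3):
                        p[a] = p[a] + t_prev * d[a]
                    if fluo:
                        if n_hits < hit_pos.shape[0]:
                            for a in range(3):
                                hit_pos[n_hits, a] = p[a]
                                hit_dir[n_hits, a] = d[a]
                            n_hits += 1
                        n_exit_f += 1
                    else:
                        n_exit_e += 1
                    alive = False
                    continue
                for a in range(3):
                    p[a] = p[a] + t_int * d[a]
            # interaction in voxel (ix, iy, iz)
            if interact:
                if fluo:
                    mu_t = mu_t_f[ix, iy, iz]
                    xi = np.random.random() * mu_t
                    if xi < mu_a_f[ix, iy, iz]:
                        n_abs += 1
                        alive = False
                    else:
                        _isotropic(d)
                else:
                    mu_t = mu_t_e[ix, iy, iz]
                    xi = np.random.random() * mu_t
                    if xi < mu_a_e[ix, iy, iz]:
                        n_abs += 1
                        alive = False
                    elif xi < mu_a_e[ix, iy, iz] + mu_s_e[ix, iy, iz]:
                        _isotropic(d)
                    else:
                        # fluorophore absorption: convert and re-emit isotropically
                        fluo = True
                        _isotropic(d)
    return n_hits, n_abs, n_exit_e, n_exit_f


def propagate(
    phantom: Phantom,
    source_position,
    source_direction,
    N: int,
    seed: int,
    woodcock: bool = False,
) -> HitRecords:
    """Track ``N`` photons from a collimated source on the sample surface.

    ``source_position``/``source_direction`` are 3D (x, y, z) in mm; the
    position must lie on (or within one voxel of) a face with the direction
    pointing inward.  Returns the fluorescence surface hits and the exact
    termination tallies (absorbed + exited == N).
    """
    if N <= 0:
        raise ValueError("photon count N must be positive")
    p0 = np.asarray(source_position, float).copy()
    d0 = np.asarray(source_direction, float)
    d0 = d0 / np.linalg.norm(d0)
    # nudge the start just inside the box so voxel indexing is well defined
    p0 = p0 + 1e-9 * d0
    sigma = phantom.spec.sigma_e
    mu_t_e = np.ascontiguousarray(phantom.mu_e)
    mu_t_f = np.ascontiguousarray(phantom.mu_f)
    mu_a_e = np.ascontiguousarray(phantom.mu_a_e)
    mu_s_e = np.ascontiguousarray(phantom.mu_s_e)
    mu_a_f = np.ascontiguousarray(phantom.mu_a_f)
    mu_s_f = np.ascontiguousarray(phantom.mu_s_f)
    cap = int(N)
    hit_pos = np.empty((cap, 3), dtype=np.float32)
    hit_dir = np.empty((cap, 3), dtype=np.float32)
    seed32 = int(np.uint32(seed))
    n_hits, n_abs, n_exit_e, n_exit_f = _transport(
        mu_t_e, mu_t_f, mu_a_e, mu_s_e, mu_a_f, mu_s_f,
        phantom.pitch, p0, d0, int(N), seed32, hit_pos, hit_dir, woodcock,
    )
    tallies = {
        "N": int(N),
        "absorbed": int(n_abs),
        "exited_excitation": int(n_exit_e),
        "exited_fluorescence": int(n_exit_f),
    }
    return HitRecords(
        positions=hit_pos[:n_hits].copy(),
        directions=hit_dir[:n_hits].copy(),
        tallies=tallies,
        meta={"seed": seed32, "woodcock": bool(woodcock),
              "source_position": list(map(float, np.asarray(source_position, float))),
              "source_direction": list(map(float, d0))},
    )


def score(
    hits: HitRecords,
    detector: DetectorSpec,
    r_d,
    s_k,
    phantom_dims,
    constants: Constants = Constants(),
    x_center: float | None = None,
) -> float:
    """Signal of an angularly selective detector from recorded surface hits.

    ``r_d`` is the in-plane (y, z) detector-center position on a z-face,
    ``s_k`` the in-plane collimation direction (outward).  The footprint on
    the face spans ``delta_d`` out of plane (x, centered on ``x_center``,
    default the slab center) and ``delta_d/cos(alpha)`` (same-detector mode)
    or ``delta_d`` (per-direction-square mode) along y.
    """
    Lx, Ly, Lz = phantom_dims
    r_d = np.asarray(r_d, float)
    s_k = np.asarray(s_k, float)
    s_k = s_k / np.linalg.norm(s_k)
    face_z = 0.0 if abs(r_d[1]) < 1e-6 else Lz
    if abs(r_d[1] - face_z) > 1e-6:
        raise ValueError("detector must sit on a z-face of the sample")
    normal = np.array([0.0, -1.0]) if face_z == 0.0 else np.array([0.0, 1.0])
    half_y = detector.footprint_halfwidth(s_k, normal)
    xc = Lx / 2.0 if x_center is None else float(x_center)
    if len(hits) == 0:
        return 0.0
    pos = hits.positions.astype(float)
    dirs = hits.directions.astype(float)
    on_face = np.abs(pos[:, 2] - face_z) < 1e-6
    in_x = np.abs(pos[:, 0] - xc) <= detector.delta_d / 2.0
    in_y = np.abs(pos[:, 1] - r_d[0]) <= half_y
    s_k3 = np.array([0.0, s_k[0], s_k[1]])
    cos_j = dirs @ s_k3
    in_cone = cos_j >= np.cos(detector.beta)
    sel = on_face & in_x & in_y & in_cone
    return float(constants.eta0 * constants.E_f * cos_j[sel].sum())


class MCEngine:
    """Adapter exposing Monte Carlo measurements through the scan interface.

    Calls with the same source reuse the propagated photon set, so a complete
    scan costs one transport run of ``N`` photons per distinct source station.
    Per-source random streams are derived independently from the master seed
    (numpy ``SeedSequence``), so results do not depend on evaluation order.
    """

    def __init__(self, phantom: Phantom, N: int, seed: int,
                 constants: Constants = Constants(), woodcock: bool = False,
                 cache_size: int = 2):
        if N <= 0:
            raise ValueError("photon count N must be positive")
        self.phantom = phantom
        self.N = int(N)
        self.seed = int(seed)
        self.constants = constants
        self.woodcock = woodcock
        self.cache_size = cache_size
        self._cache: dict = {}
        self._order: list = []
        self._source_ids: dict = {}
        self.last_hits: HitRecords | None = None

    def _source_stream(self, key) -> int:
        if key not in self._source_ids:
            self._source_ids[key] = len(self._source_ids)
        idx = self._source_ids[key]
        ss = np.random.SeedSequence([self.seed, idx])
        return int(ss.generate_state(1, dtype=np.uint32)[0])

    def _hits_for(self, r_s, s_l) -> HitRecords:
        key = (round(r_s[0], 9), round(r_s[1], 9),
               round(s_l[0], 9), round(s_l[1], 9))
        if key in self._cache:
            return self._cache[key]
        Lx = self.phantom.spec.dims_mm[0]
        src3 = np.array([Lx / 2.0, r_s[0], r_s[1]])
        dir3 = np.array([0.0, s_l[0], s_l[1]])
        hits = propagate(self.phantom, src3, dir3, self.N,
                         self._source_stream(key), woodcock=self.woodcock)
        self._cache[key] = hits
        self._order.append(key)
        if len(self._order) > self.cache_size:
            self._cache.pop(self._order.pop(0), None)
        self.last_hits = hits
        return hits

    def __call__(self, r_s, s_l, r_d, s_k, pair=None) -> float:
        hits = self._hits_for(np.asarray(r_s, float), np.asarray(s_l, float))
        dims = self.phantom.spec.dims_mm
        return score(hits, self.detector_for(pair), np.asarray(r_d, float),
                     np.asarray(s_k, float), dims, self.constants)

    # the detector is attached by the caller (assemble_scan passes geometry
    # explicitly; profiles set .detector before use)
    detector: DetectorSpec | None = None

    def detector_for(self, pair) -> DetectorSpec:
        if self.detector is None:
            raise ValueError("MCEngine.detector must be set before scoring")
        return self.detector
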