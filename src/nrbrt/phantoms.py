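"""Voxelized numerical samples: cuboid background with spherical inclusions.

A sample is described by its intrinsic background optics at the excitation and
fluorescence wavelengths (scattering ``mu_s``, absorption ``mu_a``, per mm), a
background fluorophore concentration ``n`` with absorption cross-section
``sigma_e``, and a list of spherical inclusions specified by their intrinsic
scattering plus *total-attenuation contrasts* relative to the background.  The
total attenuation is

    mu_e = mu_a;e + mu_s;e + n * sigma_e        (excitation)
    mu_f = mu_a;f + mu_s;f                      (fluorescence; reabsorption of
                                                 fluorescence light neglected)

and the normalized concentration entering the forward model is
``n_tilde = sigma_e**1.5 * n``.

The module doubles as the repository's synthetic-data generator: the
:func:`sample_library` catalog of thirteen reference samples is defined by its
dimensionless products (optical depths, absorption ratios, concentration
ratios, inclusion contrasts), which fully determine reconstruction behaviour.
The absolute dimensions of several samples are not uniquely pinned down by
those products; the adopted values are stored as ordinary, overridable spec
fields.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Inclusion",
    "SampleSpec",
    "Phantom",
    "SliceMaps",
    "build_phantom",
    "extract_slice",
    "sample_library",
    "RECONSTRUCTION_PRESETS",
]


@dataclass(frozen=True)
class Inclusion:
    """A spherical inhomogeneity.

    ``mu_s_e``/``mu_s_f`` are the inclusion's intrinsic scattering coefficients
    (per mm); ``mu_e_contrast``/``mu_f_contrast`` are the ratios of its *total*
    attenuation to the background's; ``n_contrast`` is the concentration ratio
    n/n_bar (``None`` with ``n_abs`` set gives an absolute concentration, for
    samples whose background carries no contrast agent).
    """

    center_mm: tuple[float, float, float]
    diameter_mm: float
    mu_s_e: float
    mu_s_f: float
    mu_e_contrast: float
    mu_f_contrast: float
    n_contrast: float | None = None
    n_abs: float | None = None

    def concentration(self, bg_n: float) -> float:
        if self.n_contrast is not None:
            return self.n_contrast * bg_n
        if self.n_abs is not None:
            return self.n_abs
        raise ValueError("inclusion needs n_contrast or n_abs")


@dataclass
class SampleSpec:
    """Parameterization of a cuboid phantom with spherical inclusions."""

    dims_mm: tuple[float, float, float]
    voxel_pitch: float = 0.1
    bg_mu_s_e: float = 0.0
    bg_mu_s_f: float = 0.0
    bg_mu_a_e: float = 0.0
    bg_mu_a_f: float = 0.0
    bg_n: float = 0.0
    sigma_e: float = 1.0
    inclusions: list[Inclusion] = field(default_factory=list)
    scan_type: str = "transmission"
    name: str = ""

    def __post_init__(self):
        self.validate()

    # -- derived background quantities -------------------------------------
    @property
    def bg_mu_e(self) -> float:
        return self.bg_mu_a_e + self.bg_mu_s_e + self.bg_n * self.sigma_e

    @property
    def bg_mu_f(self) -> float:
        return self.bg_mu_a_f + self.bg_mu_s_f

    def validate(self) -> None:
        Lx, Ly, Lz = self.dims_mm
        p = self.voxel_pitch
        if p <= 0 or min(Lx, Ly, Lz) <= 0:
            raise ValueError("dimensions and pitch must be positive")
        for L, ax in zip((Lx, Ly, Lz), "xyz"):
            nv = round(L / p)
            if nv < 1 or abs(L - nv * p) > p + 1e-9:
                raise ValueError(f"pitch must divide L{ax} to within one voxel")
        for v in (
            self.bg_mu_s_e, self.bg_mu_s_f, self.bg_mu_a_e,
            self.bg_mu_a_f, self.bg_n, self.sigma_e,
        ):
            if v < 0:
                raise ValueError("optical coefficients must be nonnegative")
        for inc in self.inclusions:
            c = np.asarray(inc.center_mm, float)
            r = inc.diameter_mm / 2.0
            if np.any(c - r < -1e-9) or np.any(c + r > np.asarray(self.dims_mm) + 1e-9):
                raise ValueError(f"inclusion at {inc.center_mm} leaves the cuboid")
        for i, a in enumerate(self.inclusions):
            for b in self.inclusions[i + 1:]:
                d = np.linalg.norm(np.subtract(a.center_mm, b.center_mm))
                if d < (a.diameter_mm + b.diameter_mm) / 2.0:
                    raise ValueError("overlapping inclusions are not supported")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["inclusions"] = [dataclasses.asdict(i) for i in self.inclusions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SampleSpec":
        d = dict(d)
        d["dims_mm"] = tuple(d["dims_mm"])
        d["inclusions"] = [
            Inclusion(**{**i, "center_mm": tuple(i["center_mm"])})
            for i in d.get("inclusions", [])
        ]
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "SampleSpec":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class Phantom:
    """Voxel grids of the optical parameters, shape (nx, ny, nz), pitch in mm."""

    spec: SampleSpec
    mu_s_e: np.ndarray
    mu_s_f: np.ndarray
    mu_a_e: np.ndarray
    mu_a_f: np.ndarray
    n: np.ndarray

    @property
    def pitch(self) -> float:
        return self.spec.voxel_pitch

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mu_s_e.shape

    @property
    def mu_e(self) -> np.ndarray:
        return self.mu_a_e + self.mu_s_e + self.n * self.spec.sigma_e

    @property
    def mu_f(self) -> np.ndarray:
        return self.mu_a_f + self.mu_s_f

    @property
    def n_tilde(self) -> np.ndarray:
        return self.spec.sigma_e ** 1.5 * self.n

    def voxel_centers(self, axis: int) -> np.ndarray:
        return (np.arange(self.shape[axis]) + 0.5) * self.pitch

    def to_hdf5(self, path) -> None:
        import h5py, json

        with h5py.File(path, "w") as f:
            for name in ("mu_s_e", "mu_s_f", "mu_a_e", "mu_a_f", "n"):
                f.create_dataset(name, data=getattr(self, name))
            f.create_dataset("mu_e", data=self.mu_e)
            f.create_dataset("mu_f", data=self.mu_f)
            f.attrs["spec"] = json.dumps(self.spec.to_dict())

    def to_tiff(self, path) -> None:
        """Multi-page TIFF: for each x slice, pages mu_e, mu_f, n."""
        import tifffile

        pages = []
        for ix in range(self.shape[0]):
            for grid in (self.mu_e, self.mu_f, self.n):
                pages.append(grid[ix].T.astype(np.float32))  # (z, y) pages
        tifffile.imwrite(path, np.stack(pages))


@dataclass(frozen=True)
class SliceMaps:
    """2D optical-parameter maps of one yz slice, indexed [iz, iy]."""

    mu_e: np.ndarray
    mu_f: np.ndarray
    n: np.ndarray
    n_tilde: np.ndarray
    pitch: float

    @property
    def shape(self):
        return self.mu_e.shape

    @property
    def extent_mm(self):
        nz, ny = self.mu_e.shape
        return ny * self.pitch, nz * self.pitch  # (Ly, Lz)


def build_phantom(spec: SampleSpec) -> Phantom:
    """Rasterize a :class:`SampleSpec` onto the voxel grid.

    Membership is decided by the voxel-center-in-sphere test (no
    partial-volume weighting), matching a sharp, step-like inclusion boundary
    at the 0.1 mm discretization.
    """
    spec.validate()
    p = spec.voxel_pitch
    shape = tuple(int(round(L / p)) for L in spec.dims_mm)
    centers = [(np.arange(nv) + 0.5) * p for nv in shape]
    X, Y, Z = np.meshgrid(*centers, indexing="ij")

    mu_s_e = np.full(shape, spec.bg_mu_s_e)
    mu_s_f = np.full(shape, spec.bg_mu_s_f)
    mu_a_e = np.full(shape, spec.bg_mu_a_e)
    mu_a_f = np.full(shape, spec.bg_mu_a_f)
    n = np.full(shape, spec.bg_n)

    for inc in spec.inclusions:
        cx, cy, cz = inc.center_mm
        r2 = (inc.diameter_mm / 2.0) ** 2
        inside = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= r2
        n_inc = inc.concentration(spec.bg_n)
        mu_e_inc = inc.mu_e_contrast * spec.bg_mu_e
        mu_f_inc = inc.mu_f_contrast * spec.bg_mu_f
        mu_a_e_inc = mu_e_inc - inc.mu_s_e - n_inc * spec.sigma_e
        mu_a_f_inc = mu_f_inc - inc.mu_s_f
        if mu_a_e_inc < -1e-9 or mu_a_f_inc < -1e-9:
            raise ValueError(
                "inclusion contrasts imply negative intrinsic absorption; "
                "check mu_s / contrast consistency"
            )
        mu_s_e[inside] = inc.mu_s_e
        mu_s_f[inside] = inc.mu_s_f
        mu_a_e[inside] = max(mu_a_e_inc, 0.0)
        mu_a_f[inside] = max(mu_a_f_inc, 0.0)
        n[inside] = n_inc

    return Phantom(spec=spec, mu_s_e=mu_s_e, mu_s_f=mu_s_f,
                   mu_a_e=mu_a_e, mu_a_f=mu_a_f, n=n)


def extract_slice(phantom: Phantom, x_index: int) -> SliceMaps:
    """Parameter maps of the yz slice at voxel index ``x_index`` (0-based)."""
    if not 0 <= x_index < phantom.shape[0]:
        raise IndexError(f"x_index {x_index} outside grid of {phantom.shape[0]} slices")
    sl = (x_index, slice(None), slice(None))
    # stored [iz, iy] so rows run with depth, as in the reconstructed images
    return SliceMaps(
        mu_e=phantom.mu_e[sl].T.copy(),
        mu_f=phantom.mu_f[sl].T.copy(),
        n=phantom.n[sl].T.copy(),
        n_tilde=phantom.n_tilde[sl].T.copy(),
        pitch=phantom.pitch,
    )


# ---------------------------------------------------------------------------
# Sample catalog
# ---------------------------------------------------------------------------

# Per-sample rows: dims (Lx, Ly, Lz) and inclusion diameter(s) in mm, scan type,
# then the dimensionless products that define the optics:
#   od_e  = Lz * mu_s;e(bg)       od_f  = Lz * mu_s;f(bg)
#   a_over_s = mu_a;e / mu_s;e    c_over_a = sigma*n_bar / mu_a;e
#   d_e, d_f = D * mu_s;e,f (inclusion intrinsic scattering products)
#   ce, cf, cn = inclusion/background contrasts of mu_e, mu_f, n
# Samples 11-13 carry no contrast agent in the background (c_over_a = 0); their
# inclusion concentration is set through sigma*n / mu_a;e(bg) (inc_c_over_a).
_CATALOG = {
    1: dict(dims=(16.0, 44.0, 14.1), D=(8.0, 3.0), scan="transmission",
            od_e=0.7, od_f=0.63, a_over_s=0.43, c_over_a=4.3,
            d_e=(0.8, 0.6), d_f=(0.7, 0.5), ce=(2, 4), cf=(2, 4), cn=(2, 4)),
    2: dict(dims=(6.0, 92.0, 14.1), D=(6.0,), scan="backscattering",
            od_e=0.7, od_f=0.6, a_over_s=0.14, c_over_a=5.0,
            d_e=(0.6,), d_f=(0.5,), ce=(2.6,), cf=(2,), cn=(3.5,)),
    3: dict(dims=(3.0, 34.0, 5.1), D=(1.5,), scan="backscattering",
            od_e=0.7, od_f=0.6, a_over_s=0.14, c_over_a=5.0,
            d_e=(0.4,), d_f=(0.4,), ce=(3.2,), cf=(2,), cn=(5.1,)),
    4: dict(dims=(3.0, 26.0, 3.7), D=(2.3,), scan="backscattering",
            od_e=0.7, od_f=0.6, a_over_s=0.1, c_over_a=10.0,
            d_e=(1.1,), d_f=(0.9,), ce=(2.3,), cf=(2.5,), cn=(2,)),
    5: dict(dims=(6.0, 16.0, 5.1), D=(2.0,), scan="transmission",
            od_e=1.5, od_f=1.0, a_over_s=0.1, c_over_a=5.0,
            d_e=(1.8,), d_f=(1.2,), ce=(3,), cf=(3,), cn=(3,)),
    6: dict(dims=(6.0, 44.0, 4.1), D=(3.0,), scan="transmission",
            od_e=1.5, od_f=1.0, a_over_s=0.1, c_over_a=3.3,
            d_e=(1.3,), d_f=(0.9,), ce=(2.3,), cf=(2,), cn=(3.5,)),
    7: dict(dims=(6.0, 34.0, 5.1), D=(2.0,), scan="transmission",
            od_e=1.5, od_f=1.0, a_over_s=0.1, c_over_a=0.5,
            d_e=(1.8,), d_f=(1.2,), ce=(3.7,), cf=(3,), cn=(18,)),
    8: dict(dims=(6.0, 16.0, 5.1), D=(2.0,), scan="transmission",
            od_e=1.5, od_f=1.0, a_over_s=0.1, c_over_a=0.25,
            d_e=(1.8,), d_f=(1.2,), ce=(3.7,), cf=(3,), cn=(36,)),
    9: dict(dims=(6.0, 16.0, 5.1), D=(2.0,), scan="transmission",
            od_e=3.0, od_f=2.0, a_over_s=0.1, c_over_a=2.5,
            d_e=(3.5,), d_f=(2.4,), ce=(3,), cf=(3,), cn=(3,)),
    10: dict(dims=(6.0, 44.0, 4.1), D=(3.0,), scan="transmission",
             od_e=3.0, od_f=2.5, a_over_s=0.1, c_over_a=1.6,
             d_e=(2.6,), d_f=(2.1,), ce=(2.2,), cf=(2,), cn=(3.5,)),
    11: dict(dims=(6.0, 16.0, 5.1), D=(2.0,), scan="transmission",
             od_e=3.0, od_f=2.0, a_over_s=0.1, c_over_a=0.0,
             d_e=(3.5,), d_f=(2.4,), ce=(3.7,), cf=(3,), inc_c_over_a=(7.5,)),
    12: dict(dims=(3.0, 22.0, 3.1), D=(1.5,), scan="backscattering",
             od_e=3.0, od_f=2.0, a_over_s=0.1, c_over_a=0.0,
             d_e=(4.4,), d_f=(2.9,), ce=(3.7,), cf=(3,), inc_c_over_a=(7.5,)),
    13: dict(dims=(6.0, 16.0, 5.1), D=(2.0,), scan="transmission",
             od_e=4.0, od_f=3.6, a_over_s=0.1, c_over_a=0.0,
             d_e=(4.7,), d_f=(4.2,), ce=(3.8,), cf=(3,), inc_c_over_a=(9.0,)),
}

#: Recommended per-sample reconstruction settings (regularization weight and
#: detector parameters) for full-photon-budget runs.
RECONSTRUCTION_PRESETS = {
    1: {"lambda_reg": 50.0, "beta_deg": 0.5, "delta_d": 0.070},
    2: {"lambda_reg": 30.0, "beta_deg": 0.5, "delta_d": 0.1},
    3: {"lambda_reg": 100.0, "beta_deg": 0.5, "delta_d": 0.1},
    4: {"lambda_reg": 200.0, "beta_deg": 0.5, "delta_d": 0.1},
    5: {"lambda_reg": 250.0, "beta_deg": 0.25, "delta_d": 0.070},
    6: {"lambda_reg": 50.0, "beta_deg": 0.5, "delta_d": 0.070},
    7: {"lambda_reg": 100.0, "beta_deg": 0.25, "delta_d": 0.070},
    8: {"lambda_reg": 50.0, "beta_deg": 0.25, "delta_d": 0.070},
    9: {"lambda_reg": 50.0, "beta_deg": 0.25, "delta_d": 0.070},
    10: {"lambda_reg": 25.0, "beta_deg": 0.5, "delta_d": 0.070},
    11: {"lambda_reg": 50.0, "beta_deg": 0.25, "delta_d": 0.070},
    12: {"lambda_reg": 100.0, "beta_deg": 0.5, "delta_d": 0.1},
    13: {"lambda_reg": 50.0, "beta_deg": 0.25, "delta_d": 0.070},
}


def _spec_from_row(sid: int, row: dict, sigma_e: float = 1.0) -> SampleSpec:
    Lx, Ly, Lz = row["dims"]
    mu_s_e = row["od_e"] / Lz
    mu_s_f = row["od_f"] / Lz
    mu_a_e = row["a_over_s"] * mu_s_e
    mu_a_f = row["a_over_s"] * mu_s_f  # mu_a;f/mu_s;f equals mu_a;e/mu_s;e
    bg_n = row["c_over_a"] * mu_a_e / sigma_e
    centers = _inclusion_centers(row["dims"], row["D"])
    inclusions = []
    for i, D in enumerate(row["D"]):
        kw: dict = {}
        if "inc_c_over_a" in row:
            kw["n_abs"] = row["inc_c_over_a"][i] * mu_a_e / sigma_e
        else:
            kw["n_contrast"] = float(row["cn"][i])
        inclusions.append(
            Inclusion(
                center_mm=centers[i],
                diameter_mm=D,
                mu_s_e=row["d_e"][i] / D,
                mu_s_f=row["d_f"][i] / D,
                mu_e_contrast=float(row["ce"][i]),
                mu_f_contrast=float(row["cf"][i]),
                **kw,
            )
        )
    return SampleSpec(
        dims_mm=(Lx, Ly, Lz),
        bg_mu_s_e=mu_s_e,
        bg_mu_s_f=mu_s_f,
        bg_mu_a_e=mu_a_e,
        bg_mu_a_f=mu_a_f,
        bg_n=bg_n,
        sigma_e=sigma_e,
        inclusions=inclusions,
        scan_type=row["scan"],
        name=f"sample-{sid}",
    )


def _inclusion_centers(dims, diameters):
    """Centers at mid-depth; multiple inclusions spread symmetrically along y."""
    Lx, Ly, Lz = dims
    if len(diameters) == 1:
        return [(Lx / 2, Ly / 2, Lz / 2)]
    gap = 0.2 * Ly
    offs = np.linspace(-gap, gap, len(diameters))
    return [(Lx / 2, Ly / 2 + o, Lz / 2) for o in offs]


def sample_library(sigma_e: float = 1.0) -> dict[int, SampleSpec]:
    """The thirteen-sample reference catalog as :class:`SampleSpec` objects.

    Absolute scales (sigma_e, and hence n) are arbitrary: the attenuation
    reconstruction is scale-free and concentrations are reported max-normalized.
    """
    return {sid: _spec_from_row(sid, row, sigma_e) for sid, row in _CATALOG.items()}
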