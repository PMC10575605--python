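import numpy as np
import pytest

from nrbrt.forward_analytic import Constants
from nrbrt.geometry import DetectorSpec, scan_directions
from nrbrt.phantoms import Inclusion, SampleSpec, build_phantom, extract_slice


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same derandomized stream
    # regardless of execution order
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def homogeneous_spec():
    """Weakly scattering homogeneous sample with distinct mu_e, mu_f."""
    return SampleSpec(
        dims_mm=(1.0, 22.1, 5.1),
        bg_mu_s_e=0.137, bg_mu_s_f=0.124,
        bg_mu_a_e=0.059, bg_mu_a_f=0.053,
        bg_n=0.254, sigma_e=1.0,
    )


@pytest.fixture(scope="session")
def homogeneous_maps(homogeneous_spec):
    ph = build_phantom(homogeneous_spec)
    return extract_slice(ph, 5)


@pytest.fixture(scope="session")
def inclusion_spec():
    """Sample-1-like optics (optical depth 0.7) with one spherical inclusion."""
    mu_s_e = 0.7 / 5.1
    mu_a_e = 0.43 * mu_s_e
    mu_s_f = 0.63 / 5.1
    mu_a_f = 0.43 * mu_s_f
    Ly = 22.1
    return SampleSpec(
        dims_mm=(3.0, Ly, 5.1),
        bg_mu_s_e=mu_s_e, bg_mu_s_f=mu_s_f,
        bg_mu_a_e=mu_a_e, bg_mu_a_f=mu_a_f,
        bg_n=4.3 * mu_a_e,
        inclusions=[Inclusion(
            center_mm=(1.5, Ly / 2, 2.55), diameter_mm=1.5,
            mu_s_e=2 * mu_s_e, mu_s_f=2 * mu_s_f,
            mu_e_contrast=2.0, mu_f_contrast=2.0, n_contrast=2.0,
        )],
    )


@pytest.fixture(scope="session")
def inclusion_maps(inclusion_spec):
    ph = build_phantom(inclusion_spec)
    return extract_slice(ph, ph.shape[0] // 2)


@pytest.fixture(scope="session")
def transmission():
    return scan_directions("transmission")


@pytest.fixture(scope="session")
def backscattering():
    return scan_directions("backscattering")


@pytest.fixture(scope="session")
def detector():
    return DetectorSpec(delta_d=0.07, beta_deg=0.5)


@pytest.fixture(scope="session")
def constants():
    return Constants()


def fine_ray_integral(grid, start, direction, pitch, length, n_steps=200_000):
    """Independent dense-midpoint oracle for line integrals (tests only)."""
    grid = np.asarray(grid, float)
    nz, ny = grid.shape
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    ts = (np.arange(n_steps) + 0.5) * (length / n_steps)
    ys = start[0] + ts * direction[0]
    zs = start[1] + ts * direction[1]
    iy = np.clip((ys / pitch).astype(int), 0, ny - 1)
    iz = np.clip((zs / pitch).astype(int), 0, nz - 1)
    inside = (ys >= 0) & (ys <= ny * pitch) & (zs >= 0) & (zs <= nz * pitch)
    return float(np.sum(grid[iz[inside], iy[inside]]) * (length / n_steps))


def exact_ray_integral_oracle(grid, start, direction, pitch, length=None):
    """Independent exact integral for piecewise-constant grids (tests only).

    Uses parametric gridline crossings computed per axis and a cumulative
    segment sum; written independently of the package's traversal.
    """
    grid = np.asarray(grid, float)
    nz, ny = grid.shape
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    start = np.asarray(start, float)
    # exit parameter
    t_hi = np.inf
    for ax, L in ((0, ny * pitch), (1, nz * pitch)):
        if d[ax] > 1e-15:
            t_hi = min(t_hi, (L - start[ax]) / d[ax])
        elif d[ax] < -1e-15:
            t_hi = min(t_hi, (0.0 - start[ax]) / d[ax])
    if length is not None:
        t_hi = min(t_hi, length)
    if t_hi <= 0:
        return 0.0
    cand = [0.0, t_hi]
    for ax in (0, 1):
        if abs(d[ax]) > 1e-15:
            k = np.arange(0, (ny if ax == 0 else nz) + 1)
            t = (k * pitch - start[ax]) / d[ax]
            cand.extend(t[(t > 0) & (t < t_hi)])
    t_sorted = np.array(sorted(set(np.round(np.array(cand), 15))))
    total = 0.0
    for a, b in zip(t_sorted[:-1], t_sorted[1:]):
        tm = 0.5 * (a + b)
        y = start[0] + tm * d[0]
        z = start[1] + tm * d[1]
        iy = min(max(int(y // pitch), 0), ny - 1)
        iz = min(max(int(z // pitch), 0), nz - 1)
        total += grid[iz, iy] * (b - a)
    return float(total)
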