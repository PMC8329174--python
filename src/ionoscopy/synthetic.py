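"""Synthetic correlative iono-nanoscopy data with known ground truth.

Every input the analysis pipeline consumes can be generated here with the
statistical structure the downstream models assume:

* an elliptical cell containing an elliptical nucleus (binary masks);
* nanodiamonds placed uniformly in the cytoplasm, optionally excluded from
  a band around the nuclear boundary (nanoparticles do not enter the
  nucleus);
* an ionoluminescence map of independent per-pixel Poisson draws whose mean
  is a flat background plus, for each particle, its emission rate spread
  over a Gaussian footprint (particle size and a ~25 nm beam PSF added in
  quadrature);
* a transmission energy-loss (STIM) map proportional to areal density — a
  smooth cell dome peaking at the nucleus plus diamond columns under each
  particle — with sqrt(dE)-proportional Gaussian straggling noise;
* TCSPC decay histograms (exponential arrivals jittered by a Gaussian IRF);
* 3D two-channel confocal stacks with ellipsoidal nuclei containing
  Poisson-distributed DNA-damage foci.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import CorrelativePair
from .photophysics import DecayHistogram

#: default beam point-spread FWHM, nm (geometric mean of the measured
#: 22 nm x 27 nm spot)
DEFAULT_PSF_FWHM_NM = 25.0
#: default expected IL photons per nanodiamond per frame
DEFAULT_PARTICLE_RATE = 200.0
#: default lognormal CV of per-particle brightness on top of the volume
#: scaling (NV loading and detection efficiency vary between particles)
DEFAULT_BRIGHTNESS_CV = 0.5
#: default flat IL background, photons/pixel
DEFAULT_BACKGROUND_RATE = 0.05

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class PlacementError(RuntimeError):
    """Raised when particles cannot be placed under the given constraints."""


@dataclass
class SizeDistribution:
    """Nanodiamond diameter distribution (nm)."""

    family: str = "lognormal"  # lognormal | normal | fixed
    mean_diameter: float = 35.0
    cv: float = 0.2

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "normal", "fixed"):
            raise ValueError(f"unknown size family {self.family!r}")
        if self.mean_diameter <= 0:
            raise ValueError("mean diameter must be positive")
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")

    def sample(self, n: int, rng) -> np.ndarray:
        rng = np.random.default_rng(rng)
        if self.family == "fixed" or self.cv == 0:
            return np.full(n, self.mean_diameter)
        if self.family == "lognormal":
            sigma2 = math.log(1.0 + self.cv**2)
            mu = math.log(self.mean_diameter) - sigma2 / 2.0
            return rng.lognormal(mu, math.sqrt(sigma2), size=n)
        d = rng.normal(self.mean_diameter, self.cv * self.mean_diameter, size=n)
        # truncate to positive diameters by resampling
        while np.any(d <= 0):
            bad = d <= 0
            d[bad] = rng.normal(self.mean_diameter, self.cv * self.mean_diameter,
                                size=int(bad.sum()))
        return d


@dataclass
class CellGeometry:
    """Cell and nucleus masks on a raster with physical pixel size."""

    image_shape: tuple[int, int]
    pixel_size_nm: float
    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")
        if not self.cell_mask.any() or not self.nucleus_mask.any():
            raise ValueError("masks must be non-empty")
        if np.any(self.nucleus_mask & ~self.cell_mask):
            raise ValueError("nucleus mask must lie inside the cell mask")

    @property
    def cytoplasm_mask(self) -> np.ndarray:
        return self.cell_mask & ~self.nucleus_mask


@dataclass
class ParticlePlacement:
    """Ground-truth particle positions (nm, pixel-center convention) and sizes."""

    centers_nm: np.ndarray  # (n, 2) as (x, y)
    diameters_nm: np.ndarray
    per_particle_rate: float = DEFAULT_PARTICLE_RATE  # mean photons/particle
    rates: np.ndarray | None = None  # per-particle rates; scaled with volume

    def __post_init__(self) -> None:
        if self.rates is None:
            # emission scales with the number of NV centres, i.e. with
            # particle volume
            d = np.asarray(self.diameters_nm, dtype=float)
            if d.size and d.mean() > 0:
                vol = (d / d.mean()) ** 3
                self.rates = self.per_particle_rate * vol / vol.mean()
            else:
                self.rates = np.full(d.size, float(self.per_particle_rate))

    def __len__(self) -> int:
        return len(self.centers_nm)


def _ellipse_mask(shape, center_rc, semi_rc, theta) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center_rc[0]
    dc = cc - center_rc[1]
    ct, st = math.cos(theta), math.sin(theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    return (u / semi_rc[0]) ** 2 + (v / semi_rc[1]) ** 2 <= 1.0


def make_cell_geometry(shape=(1024, 1024), pixel_size_nm: float = 20.0,
                       seed: int = 0) -> CellGeometry:
    """Random elliptical cell with an elliptical nucleus strictly inside it.

    Axes, orientation and centre offsets are randomized; deterministic for
    a given seed.  Shapes below 64 x 64 cannot host a nucleus and are
    rejected.
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 64:
        raise ValueError("image shape must be at least 64 x 64 to host a nucleus")
    rng = np.random.default_rng(seed)
    m = min(shape)
    for _ in range(50):
        center = (shape[0] / 2.0 + rng.uniform(-0.03, 0.03) * shape[0],
                  shape[1] / 2.0 + rng.uniform(-0.03, 0.03) * shape[1])
        cell_ax = (rng.uniform(0.30, 0.40) * m, rng.uniform(0.30, 0.40) * m)
        theta = rng.uniform(0.0, math.pi)
        nuc_scale = rng.uniform(0.38, 0.48)
        nuc_ax = (nuc_scale * cell_ax[0], nuc_scale * cell_ax[1])
        off = (rng.uniform(-0.1, 0.1) * cell_ax[0], rng.uniform(-0.1, 0.1) * cell_ax[1])
        nuc_center = (center[0] + off[0], center[1] + off[1])
        cell = _ellipse_mask(shape, center, cell_ax, theta)
        nucleus = _ellipse_mask(shape, nuc_center, nuc_ax, theta + rng.uniform(-0.2, 0.2))
        if nucleus.any() and cell.any() and not np.any(nucleus & ~cell):
            return CellGeometry(
                image_shape=shape, pixel_size_nm=pixel_size_nm,
                cell_mask=cell, nucleus_mask=nucleus, seed=int(seed),
                params={"cell_axes_px": cell_ax, "nucleus_axes_px": nuc_ax,
                        "theta": theta},
            )
    raise ValueError("could not generate a nucleus inside the cell (shape too small?)")


# ---------------------------------------------------------------------------
# particle placement
# ---------------------------------------------------------------------------

def nucleus_distance_field_nm(geometry: CellGeometry) -> np.ndarray:
    """Distance (nm) of each pixel to the nearest nucleus pixel (0 inside)."""
    return ndimage.distance_transform_edt(~geometry.nucleus_mask) * geometry.pixel_size_nm


def _interp(field: np.ndarray, x_nm, y_nm, pixel_size_nm: float) -> np.ndarray:
    # pixel-center convention: pixel (r, c) is at ((c+0.5) px, (r+0.5) px)
    rows = np.atleast_1d(np.asarray(y_nm, dtype=float)) / pixel_size_nm - 0.5
    cols = np.atleast_1d(np.asarray(x_nm, dtype=float)) / pixel_size_nm - 0.5
    return ndimage.map_coordinates(field, [rows, cols], order=1, mode="nearest")


def place_nanodiamonds(geometry: CellGeometry, n: int,
                       sizes: SizeDistribution | None = None,
                       min_nucleus_gap_nm: float = 0.0,
                       seed: int = 0,
                       per_particle_rate: float = DEFAULT_PARTICLE_RATE,
                       brightness_cv: float = DEFAULT_BRIGHTNESS_CV,
                       min_separation_nm: float = 0.0,
                       max_tries: int = 2000) -> ParticlePlacement:
    """Place ``n`` nanodiamonds uniformly in the cytoplasm.

    Every particle lies inside the cell, outside the nucleus, and at least
    ``min_nucleus_gap_nm`` from the nuclear boundary (measured on the
    interpolated Euclidean distance field, the same metric the morphometry
    stage uses).  ``min_separation_nm`` optionally enforces a minimum
    inter-particle distance (useful for well-separated test scenes).
    """
    if n < 0 or min_nucleus_gap_nm < 0:
        raise ValueError("n and min_nucleus_gap must be nonnegative")
    sizes = sizes or SizeDistribution()
    rng = np.random.default_rng(seed)
    px = geometry.pixel_size_nm
    if n == 0:
        return ParticlePlacement(centers_nm=np.empty((0, 2)),
                                 diameters_nm=np.empty(0),
                                 per_particle_rate=per_particle_rate)

    dist_nm = nucleus_distance_field_nm(geometry)
    allowed = geometry.cytoplasm_mask & (dist_nm >= min_nucleus_gap_nm)
    idx = np.flatnonzero(allowed)
    if idx.size < n:
        raise PlacementError(
            f"cytoplasm annulus has only {idx.size} admissible pixels for {n} particles"
        )
    rows_all, cols_all = np.unravel_index(idx, geometry.image_shape)

    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries * max(n, 1):
            raise PlacementError("bounded retries exhausted during placement")
        j = rng.integers(0, idx.size)
        # uniform jitter within the pixel, pixel-center convention
        x = (cols_all[j] + rng.uniform(0.0, 1.0)) * px
        y = (rows_all[j] + rng.uniform(0.0, 1.0)) * px
        if min_nucleus_gap_nm > 0:
            d = float(_interp(dist_nm, x, y, px)[0])
            if d < min_nucleus_gap_nm:
                continue
        if min_separation_nm > 0 and centers:
            arr = np.asarray(centers)
            if np.min(np.hypot(arr[:, 0] - x, arr[:, 1] - y)) < min_separation_nm:
                continue
        centers.append((x, y))

    diameters = sizes.sample(n, rng)
    # brightness scales with particle volume (NV count) times a lognormal
    # heterogeneity factor for NV loading / detection efficiency
    vol = diameters**3 / np.mean(diameters**3)
    if brightness_cv > 0:
        s2 = math.log(1.0 + brightness_cv**2)
        factor = rng.lognormal(-s2 / 2.0, math.sqrt(s2), size=n)
    else:
        factor = np.ones(n)
    return ParticlePlacement(
        centers_nm=np.asarray(centers),
        diameters_nm=diameters,
        per_particle_rate=per_particle_rate,
        rates=per_particle_rate * vol * factor,
    )


# ---------------------------------------------------------------------------
# correlative image rendering
# ---------------------------------------------------------------------------

def _gaussian_pixel_mass(shape, center_xy_nm, sigma_nm, pixel_size_nm,
                         n_sigma: float = 5.0):
    """Exact Gaussian mass per pixel (product of erf differences), windowed."""
    from scipy.special import erf

    x0, y0 = center_xy_nm
    half = sigma_nm * n_sigma
    c_lo = max(int((x0 - half) / pixel_size_nm), 0)
    c_hi = min(int((x0 + half) / pixel_size_nm) + 1, shape[1])
    r_lo = max(int((y0 - half) / pixel_size_nm), 0)
    r_hi = min(int((y0 + half) / pixel_size_nm) + 1, shape[0])
    if c_lo >= c_hi or r_lo >= r_hi:
        return None
    edges_x = np.arange(c_lo, c_hi + 1) * pixel_size_nm
    edges_y = np.arange(r_lo, r_hi + 1) * pixel_size_nm
    s = sigma_nm * math.sqrt(2.0)
    fx = 0.5 * (erf((edges_x[1:] - x0) / s) - erf((edges_x[:-1] - x0) / s))
    fy = 0.5 * (erf((edges_y[1:] - y0) / s) - erf((edges_y[:-1] - y0) / s))
    return (slice(r_lo, r_hi), slice(c_lo, c_hi)), np.outer(fy, fx)


def _cell_dome(geometry: CellGeometry) -> np.ndarray:
    """Smooth unit-height thickness dome over the cell, peaking at the nucleus."""
    px_cell = ndimage.distance_transform_edt(geometry.cell_mask)
    px_nuc = ndimage.distance_transform_edt(geometry.nucleus_mask)
    dome = np.zeros(geometry.image_shape, dtype=float)
    if px_cell.max() > 0:
        dome += 0.5 * np.sqrt(px_cell / px_cell.max())
    if px_nuc.max() > 0:
        dome += 0.5 * np.sqrt(px_nuc / px_nuc.max())
    return dome


def render_correlative_pair(placement: ParticlePlacement, geometry: CellGeometry,
                            psf_fwhm_nm: float = DEFAULT_PSF_FWHM_NM,
                            background_rate: float = DEFAULT_BACKGROUND_RATE,
                            de_cell_kev: float = 60.0,
                            de_particle_kev_per_nm: float = 0.05,
                            de_noise_coeff: float = 0.3,
                            seed: int = 0) -> CorrelativePair:
    """Render the IL / STIM correlative image pair for a synthetic cell.

    IL map: independent per-pixel Poisson draws with mean = background +
    sum over particles of rate x Gaussian footprint mass in the pixel (the
    footprint FWHM is sqrt(d^2 + psf^2)).  STIM map: energy loss
    proportional to areal density (cell dome + diamond columns) with
    Gaussian straggling noise of sigma = de_noise_coeff * sqrt(dE).
    """
    if psf_fwhm_nm <= 0:
        raise ValueError("psf_fwhm must be positive")
    if background_rate < 0:
        raise ValueError("background rate must be nonnegative")
    rng = np.random.default_rng(seed)
    shape = geometry.image_shape
    px = geometry.pixel_size_nm
    extent = (shape[1] * px, shape[0] * px)

    il_mean = np.full(shape, float(background_rate))
    de_mean = de_cell_kev * _cell_dome(geometry)

    for (x, y), d, rate in zip(placement.centers_nm, placement.diameters_nm,
                               placement.rates):
        if not (0 <= x <= extent[0] and 0 <= y <= extent[1]):
            raise ValueError(f"particle at ({x:.0f}, {y:.0f}) nm lies outside the image")
        fwhm = math.sqrt(d * d + psf_fwhm_nm * psf_fwhm_nm)
        res = _gaussian_pixel_mass(shape, (x, y), fwhm * _FWHM_TO_SIGMA, px)
        if res is None:
            continue
        window, mass = res
        il_mean[window] += rate * mass
        # diamond column: the particle's diameter worth of extra areal density
        de_mean[window] += de_particle_kev_per_nm * d * (mass / mass.max() if mass.max() > 0 else mass)

    il = rng.poisson(il_mean).astype(np.int64)
    de = de_mean + rng.normal(0.0, 1.0, size=shape) * de_noise_coeff * np.sqrt(de_mean)
    de = np.clip(de, 0.0, None)
    return CorrelativePair(
        il_map=il, de_map=de, pixel_size_nm=px,
        provenance={"generator": "ionoscopy.synthetic", "seed": int(seed),
                    "psf_fwhm_nm": psf_fwhm_nm, "background_rate": background_rate,
                    "n_particles": len(placement)},
    )


# ---------------------------------------------------------------------------
# decay histograms
# ---------------------------------------------------------------------------

def render_decay_histogram(tau_ns: float = 28.5, irf_fwhm_ns: float = 0.5,
                           total_counts: int = 1_000_000,
                           bin_width_ps: float = 50.0,
                           window_ns: float | None = None,
                           seed: int = 0) -> DecayHistogram:
    """TCSPC histogram of exponential arrivals jittered by a Gaussian IRF.

    Arrival time = t0 + Exp(tau) + N(0, irf_fwhm/2.355); the true IRF curve
    (unit area, centred at t0) is stored alongside the counts.
    """
    if tau_ns <= 0 or bin_width_ps <= 0:
        raise ValueError("tau and bin width must be positive")
    if irf_fwhm_ns < 0 or total_counts < 0:
        raise ValueError("irf width and total counts must be nonnegative")
    rng = np.random.default_rng(seed)
    window_ns = window_ns or 10.0 * tau_ns
    t0 = max(5.0 * irf_fwhm_ns, 0.02 * window_ns)
    sigma = irf_fwhm_ns * _FWHM_TO_SIGMA

    times = t0 + rng.exponential(tau_ns, size=int(total_counts))
    if sigma > 0:
        times = times + rng.normal(0.0, sigma, size=times.size)
    n_bins = int(np.ceil(window_ns * 1e3 / bin_width_ps))
    edges = np.arange(n_bins + 1) * bin_width_ps * 1e-3
    counts, _ = np.histogram(times, bins=edges)

    centers = (edges[:-1] + edges[1:]) / 2.0
    if sigma > 0:
        irf = np.exp(-0.5 * ((centers - t0) / sigma) ** 2)
    else:  # delta response in the bin containing t0
        irf = np.zeros(n_bins)
        irf[min(int(t0 * 1e3 / bin_width_ps), n_bins - 1)] = 1.0
    return DecayHistogram(bin_width_ps=bin_width_ps, counts=counts.astype(float),
                          irf=irf, meta={"tau_ns": tau_ns, "t0_ns": t0,
                                         "irf_fwhm_ns": irf_fwhm_ns, "seed": int(seed)})


# ---------------------------------------------------------------------------
# 3D foci stacks
# ---------------------------------------------------------------------------

def render_foci_stack(n_nuclei: int = 4, foci_per_nucleus_mean: float = 12.0,
                      voxel_size_um: tuple[float, float, float] = (0.5, 0.2, 0.2),
                      shape: tuple[int, int, int] = (16, 160, 160),
                      focus_sigma_um: float = 0.3,
                      focus_amplitude: float = 60.0,
                      nucleus_level: float = 120.0,
                      background: float = 2.0,
                      seed: int = 0) -> tuple[np.ndarray, dict]:
    """Two-channel 3D stack: ellipsoidal nuclei + Gaussian DNA-damage foci.

    Returns ``(stack, truth)`` where ``stack`` has shape (2, z, y, x)
    (channel 0 = nucleus stain, channel 1 = damage marker) and ``truth``
    carries the labelled nucleus mask, per-nucleus foci counts and nuclear
    volumes in um^3.
    """
    if n_nuclei < 1:
        raise ValueError("need at least one nucleus")
    rng = np.random.default_rng(seed)
    vz, vy, vx = voxel_size_um
    nz, ny, nx = shape
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx]
    zz = zz * vz
    yy = yy * vy
    xx = xx * vx

    labels = np.zeros(shape, dtype=np.int32)
    nuc_params = []
    for i in range(1, n_nuclei + 1):
        for attempt in range(200):
            a = rng.uniform(2.5, 3.5)  # z semi-axis, um
            b = rng.uniform(3.0, 4.5)
            c = rng.uniform(3.0, 4.5)
            cz = rng.uniform(a, nz * vz - a)
            cy = rng.uniform(b + 0.5, ny * vy - b - 0.5)
            cx = rng.uniform(c + 0.5, nx * vx - c - 0.5)
            ell = (((zz - cz) / a) ** 2 + ((yy - cy) / b) ** 2 + ((xx - cx) / c) ** 2) <= 1.0
            if not np.any(ell & (labels > 0)):
                labels[ell] = i
                nuc_params.append((cz, cy, cx, a, b, c))
                break
        else:
            raise PlacementError("could not place non-overlapping nuclei")

    voxel_volume = vz * vy * vx
    volumes = [float((labels == i).sum()) * voxel_volume for i in range(1, n_nuclei + 1)]

    damage = np.full(shape, background, dtype=float)
    foci_counts = []
    foci_centers: list[tuple[float, float, float]] = []
    sz = max(focus_sigma_um / vz, 0.5)
    sy = max(focus_sigma_um / vy, 0.5)
    sx = max(focus_sigma_um / vx, 0.5)
    for (cz, cy, cx, a, b, c) in nuc_params:
        k = int(rng.poisson(foci_per_nucleus_mean))
        foci_counts.append(k)
        placed = 0
        tries = 0
        while placed < k:
            tries += 1
            if tries > 5000:
                break  # extremely dense request; truth reflects what was placed
            u = rng.normal(size=3)
            r = rng.uniform(0, 0.8) ** (1 / 3)
            u = u / np.linalg.norm(u) * r
            fz, fy, fx = cz + u[0] * a, cy + u[1] * b, cx + u[2] * c
            if foci_centers and min(
                (fz - p[0]) ** 2 + (fy - p[1]) ** 2 + (fx - p[2]) ** 2
                for p in foci_centers
            ) < 1.0**2:
                continue
            foci_centers.append((fz, fy, fx))
            placed += 1
            iz, iy, ix = fz / vz, fy / vy, fx / vx
            z0, z1 = max(int(iz - 4 * sz), 0), min(int(iz + 4 * sz) + 1, nz)
            y0, y1 = max(int(iy - 4 * sy), 0), min(int(iy + 4 * sy) + 1, ny)
            x0, x1 = max(int(ix - 4 * sx), 0), min(int(ix + 4 * sx) + 1, nx)
            gz, gy, gx = np.mgrid[z0:z1, y0:y1, x0:x1]
            blob = focus_amplitude * np.exp(
                -0.5 * (((gz - iz) / sz) ** 2 + ((gy - iy) / sy) ** 2 + ((gx - ix) / sx) ** 2)
            )
            damage[z0:z1, y0:y1, x0:x1] += blob
        foci_counts[-1] = placed

    nucleus_channel = np.where(labels > 0, nucleus_level, background)
    stack = np.stack([
        rng.poisson(nucleus_channel).astype(float),
        rng.poisson(damage).astype(float),
    ])
    truth = {
        "labels": labels,
        "foci_counts": foci_counts,
        "total_foci": int(sum(foci_counts)),
        "nuclear_volumes_um3": volumes,
        "total_nuclear_volume_um3": float(sum(volumes)),
        "foci_centers_um": foci_centers,
        "voxel_size_um": voxel_size_um,
        "seed": int(seed),
    }
    return stack, truth
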