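"""Compound-Poisson (Neyman Type A) nanodiamond counting.

A pixel of an ionoluminescence image that belongs to a segmented particle
footprint registers ``N`` photons.  If the pixel holds ``N_p`` nanodiamonds,
``N_p ~ Poisson(beta)`` and, conditionally, ``N | N_p ~ Poisson(lam * N_p)``:
the marginal law of ``N`` is the Neyman Type A distribution

    P(N | lam, beta) = sum_{Np>=0} e^{-beta} beta^Np / Np!
                       * e^{-lam*Np} (lam*Np)^N / N!

with mean ``lam*beta`` and variance ``lam*beta*(1 + lam)``.  Fitting
``(lam, beta)`` to the pixel-value histogram of the particle mask, and
knowing the total background-subtracted counts ``C`` and the mean imaged
footprint ``A`` (pixels per particle), the total particle number is the
plug-in estimator ``C / (A * lam * beta)``; ``C / (lam * beta)`` estimates
the number of occupied pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, stats
from scipy.special import gammaln, logsumexp


class PoissonDegenerateError(ValueError):
    """Raised when pixel counts are not overdispersed (var <= mean).

    Under equidispersion the compound model collapses to a plain Poisson
    law and ``lam`` is unidentifiable.
    """


@dataclass
class CountModel:
    """Fitted counting model and the derived particle-number estimate."""

    lam: float
    beta: float
    A: float
    C: float
    n_total: float
    n_occupied_pixels: float
    log_likelihood: float = float("nan")
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# pmf
# ---------------------------------------------------------------------------

def _np_truncation(n_max: int, lam: float, beta: float) -> int:
    # Poisson tails decay super-exponentially; this covers both the prior
    # Poisson(beta) mass and the Np needed to make lam*Np reach N.
    extra = n_max / lam if lam > 0 else 0.0
    return int(np.ceil(beta + 10.0 * np.sqrt(beta) + 10.0 + extra))


def neyman_logpmf(n, lam: float, beta: float, tol: float = 1e-12) -> np.ndarray:
    """Log-pmf of the Neyman Type A law, evaluated by truncated summation.

    Parameters
    ----------
    n : int or array of int
        Photon counts (``>= 0``).
    lam, beta : float
        Mean photons per particle and mean particles per occupied pixel.
    tol : float
        Bound on the neglected tail of the sum over the latent particle
        number; the truncation point is extended until a Chernoff-style
        Poisson tail bound falls below ``tol``.
    """
    if lam < 0 or beta < 0:
        raise ValueError("lam and beta must be nonnegative")
    n = np.atleast_1d(np.asarray(n))
    if np.any(n < 0) or not np.issubdtype(n.dtype, np.integer):
        n = n.astype(np.int64)
        if np.any(n < 0):
            raise ValueError("counts must be nonnegative integers")
    out = np.full(n.shape, -np.inf, dtype=float)

    if lam == 0.0 or beta == 0.0:
        # all mass at N = 0
        out[n == 0] = 0.0
        return out

    n_max = int(n.max())
    kmax = _np_truncation(n_max, lam, beta)
    # extend until the Poisson(beta) upper tail bound is below tol
    while kmax < 10_000_000:
        # Chernoff bound: P(X >= k) <= exp(-beta) (e*beta/k)^k for k > beta
        k = kmax + 1
        bound = -beta + k * (1.0 + np.log(beta) - np.log(k))
        if bound < np.log(tol):
            break
        kmax = int(kmax * 1.5) + 10

    ks = np.arange(0, kmax + 1)  # latent particle numbers Np
    # log of e^{-beta} beta^k / k!
    log_prior = -beta + ks * np.log(beta) - gammaln(ks + 1)
    nn = n[:, None].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_kern = -lam * ks[None, :] + nn * np.log(lam * ks[None, :]) - gammaln(nn + 1)
    # Np = 0 term: 0^0 = 1 convention -> contributes only at N = 0
    log_kern[:, 0] = np.where(n == 0, 0.0, -np.inf)
    out = logsumexp(log_prior[None, :] + log_kern, axis=1)
    return out


def neyman_pmf(n, lam: float, beta: float, tol: float = 1e-12):
    """Probability mass function of the Neyman Type A distribution.

    ``P(0) = exp(-beta * (1 - exp(-lam)))`` in closed form; general ``N``
    by log-domain truncated summation over the latent particle number.
    """
    res = np.exp(neyman_logpmf(n, lam, beta, tol=tol))
    if np.isscalar(n) or np.ndim(n) == 0:
        return float(res[0])
    return res


def simulate_neyman(lam: float, beta: float, size: int, rng) -> np.ndarray:
    """Draw pixel counts by the explicit two-stage Poisson mechanism.

    Independent of :func:`neyman_pmf`; used as a simulation oracle and by
    the synthetic-data pathway.
    """
    rng = np.random.default_rng(rng)
    n_p = rng.poisson(beta, size=size)
    return rng.poisson(lam * n_p)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def moment_estimates(mean: float, var: float) -> tuple[float, float]:
    """Method-of-moments start values: lam0 = var/mean - 1, beta0 = mean/lam0."""
    if mean <= 0 or var <= mean:
        raise PoissonDegenerateError(
            "sample variance must exceed the mean for the compound model"
        )
    lam0 = var / mean - 1.0
    return lam0, mean / lam0


def fit_count_model(pixel_values, tol: float = 1e-10) -> dict:
    """Maximum-likelihood fit of (lam, beta) to particle-mask pixel counts.

    Parameters
    ----------
    pixel_values : array of int
        IL photon counts over the pixels of the particle mask (>= 30 pixels).

    Returns
    -------
    dict with keys ``lam``, ``beta``, ``log_likelihood``, ``converged``,
    ``lam0``, ``beta0``, ``n_pixels``.
    """
    x = np.asarray(pixel_values).astype(np.int64).ravel()
    if x.size < 30:
        raise ValueError("need at least 30 pixels to fit the counting model")
    if np.any(x < 0):
        raise ValueError("pixel counts must be nonnegative")
    mean = float(x.mean())
    var = float(x.var(ddof=1))
    lam0, beta0 = moment_estimates(mean, var)  # raises if underdispersed

    values, counts = np.unique(x, return_counts=True)

    def nll(theta):
        lam, beta = np.exp(theta)
        lp = neyman_logpmf(values, lam, beta, tol=tol)
        return -float(np.dot(counts, lp))

    res = optimize.minimize(
        nll,
        x0=np.log([lam0, beta0]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    lam, beta = np.exp(res.x)
    if not res.success:
        raise RuntimeError(f"counting-model fit did not converge: {res.message}")
    return {
        "lam": float(lam),
        "beta": float(beta),
        "log_likelihood": float(-res.fun),
        "converged": bool(res.success),
        "lam0": float(lam0),
        "beta0": float(beta0),
        "n_pixels": int(x.size),
    }


# ---------------------------------------------------------------------------
# pixels per particle and the estimator
# ---------------------------------------------------------------------------

def footprint_diameter(diameter_nm, psf_fwhm_nm: float):
    """Imaged footprint diameter: particle size and PSF added in quadrature."""
    return np.sqrt(np.square(diameter_nm) + psf_fwhm_nm**2)


#: FWHM (in units of the pixel pitch) of the square pixel aperture treated
#: as an equivalent Gaussian: 2 sqrt(2 ln 2) / sqrt(12)
PIXEL_APERTURE_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0)) / np.sqrt(12.0)


def pixels_per_particle(sizes, pixel_size_nm: float, psf_fwhm_nm: float = 0.0,
                        include_pixel_aperture: bool = False) -> float:
    """Mean imaged footprint A, in pixels, of one nanodiamond.

    ``A = E[pi * ((d (+) psf)/2)^2] / pixel^2`` with ``d (+) psf =
    sqrt(d^2 + psf^2)``; the expectation over the size distribution is
    taken by Gauss quadrature of the footprint area against the size pdf.
    With ``include_pixel_aperture`` the finite pixel integration window is
    added in quadrature as well (FWHM ~0.68 pixel), which matches the
    footprint measured on rasterized images.

    Parameters
    ----------
    sizes : SizeDistribution or float
        A size distribution (with ``family``, ``mean_diameter``, ``cv``
        attributes) or a fixed diameter in nm.
    """
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size must be positive")
    broaden = psf_fwhm_nm**2
    if include_pixel_aperture:
        broaden += (PIXEL_APERTURE_FWHM * pixel_size_nm) ** 2
    eff_psf = np.sqrt(broaden)

    def area_px(d):
        return np.pi * (footprint_diameter(d, eff_psf) / 2.0) ** 2 / pixel_size_nm**2

    if np.isscalar(sizes):
        d = float(sizes)
        if d <= 0:
            raise ValueError("diameter must be positive")
        return float(area_px(d))

    family = sizes.family
    m, cv = float(sizes.mean_diameter), float(sizes.cv)
    if m <= 0:
        raise ValueError("mean diameter must be positive")
    if family == "fixed" or cv == 0:
        return float(area_px(m))
    if family == "lognormal":
        sigma2 = np.log(1.0 + cv**2)
        mu = np.log(m) - sigma2 / 2.0
        dist = stats.lognorm(s=np.sqrt(sigma2), scale=np.exp(mu))
    elif family == "normal":
        dist = stats.norm(loc=m, scale=cv * m)
    else:
        raise ValueError(f"unknown size family: {family!r}")
    lo, hi = dist.ppf(1e-9), dist.ppf(1.0 - 1e-9)
    lo = max(lo, 1e-6)  # diameters truncated to > 0
    val, _ = integrate.quad(lambda d: area_px(d) * dist.pdf(d), lo, hi, limit=200)
    norm, _ = integrate.quad(dist.pdf, lo, hi, limit=200)
    return float(val / norm)


def estimate_particle_number(C: float, A: float, lam: float, beta: float) -> dict:
    """Total-particle estimator ``C / (A lam beta)``.

    Also returns the occupied-pixel estimate ``C / (lam beta)``.
    """
    if min(C, A, lam, beta) <= 0:
        raise ValueError("C, A, lam and beta must all be positive")
    occ = C / (lam * beta)
    return {"n_total": occ / A, "n_occupied_pixels": occ}


def count_particles(segmentation, sizes, psf_fwhm_nm: float, pixel_size_nm: float) -> CountModel:
    """End-to-end counting from a segmentation result.

    Fits (lam, beta) on the particle-mask pixel values, computes A from the
    size distribution and returns the full :class:`CountModel`.
    """
    fit = fit_count_model(segmentation.mask_pixel_values)
    A = pixels_per_particle(sizes, pixel_size_nm, psf_fwhm_nm,
                            include_pixel_aperture=True)
    est = estimate_particle_number(segmentation.C, A, fit["lam"], fit["beta"])
    return CountModel(
        lam=fit["lam"],
        beta=fit["beta"],
        A=A,
        C=segmentation.C,
        n_total=est["n_total"],
        n_occupied_pixels=est["n_occupied_pixels"],
        log_likelihood=fit["log_likelihood"],
        converged=fit["converged"],
        diagnostics=fit,
    )
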