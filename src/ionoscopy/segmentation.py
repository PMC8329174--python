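"""Segmentation of correlative IL / STIM image pairs.

Nanodiamond footprints are separated from the IL background with a robust
threshold: the background level is the median of the image, its scale a
MAD-based sigma with a Poisson floor (integer count images at low rates
have zero MAD), and particle pixels are those above median + k_sigma *
sigma, cleaned by 8-connectivity and a minimum area.  The total
background-subtracted count C over the particle mask feeds the compound-
Poisson counting model.

Cell and nucleus come from the STIM map: the nucleus is the densest
region, so a 3-class multilevel (multi-Otsu) split of the energy-loss
histogram yields a lower threshold (cell outline) and an upper threshold
(nucleus), each taken as the largest connected component and
morphologically closed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage import filters, measure, morphology

from .io import CorrelativePair


@dataclass
class SegmentationResult:
    particle_mask: np.ndarray
    clusters: pd.DataFrame  # label, centroid_x_nm, centroid_y_nm, area_px, counts
    background_rate: float  # photons / pixel
    C: float  # total background-subtracted IL counts over the mask
    threshold: float
    mask_pixel_values: np.ndarray = field(repr=False, default=None)
    saturated: bool = False

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def segment_particles(pair: CorrelativePair, k_sigma: float = 3.0,
                      min_area: int = 2,
                      half_max_refine: bool = True) -> SegmentationResult:
    """Threshold-and-label segmentation of nanodiamond footprints.

    Background is estimated twice: a robust median/MAD pass sets the
    detection threshold; the mean of the non-particle pixels then provides
    the rate subtracted when accumulating C (medians of low-rate integer
    images are biased to zero).  With ``half_max_refine`` (default) each
    detected cluster is trimmed to the pixels above half of its
    background-subtracted peak, so the retained footprint matches the
    full-width-half-maximum area that the counting model's pixels-per-
    particle factor A describes, independently of particle brightness.
    """
    il = np.asarray(pair.il_map, dtype=float)
    if il.size == 0:
        raise ValueError("empty IL map")
    med = float(np.median(il))
    mad = float(np.median(np.abs(il - med)))
    # Poisson floor: for sparse integer images MAD collapses to 0
    sigma = max(1.4826 * mad, np.sqrt(med + 1.0))
    threshold = med + k_sigma * sigma

    raw = il > threshold
    saturated = False
    if raw.mean() > 0.5 or (med > 0 and (il == il.max()).mean() > 0.5):
        warnings.warn("image is saturated (most pixels at or above the "
                      "detection level); result flagged", stacklevel=2)
        saturated = True

    labels = measure.label(raw, connectivity=2)  # 8-connectivity
    if min_area > 1 and labels.max() > 0:
        areas = np.bincount(labels.ravel())
        keep = np.flatnonzero(areas >= min_area)
        keep = keep[keep > 0]
        mask = np.isin(labels, keep)
        labels = measure.label(mask, connectivity=2)
    else:
        mask = labels > 0

    background = float(il[~mask].mean()) if np.any(~mask) else med

    if half_max_refine and labels.max() > 0:
        peaks = ndimage.maximum(il, labels=labels, index=np.arange(1, labels.max() + 1))
        cutoff_by_label = np.concatenate(
            ([np.inf], background + 0.5 * (peaks - background)))
        cutoff = cutoff_by_label[labels]
        mask = mask & (il >= np.maximum(cutoff, threshold))
        labels = measure.label(mask, connectivity=2)

    C = float(np.maximum(il[mask] - background, 0.0).sum()) if mask.any() else 0.0

    px = pair.pixel_size_nm
    rows = []
    for rp in measure.regionprops(labels, intensity_image=il):
        r, c = rp.centroid_weighted
        rows.append({
            "label": rp.label,
            "centroid_x_nm": (c + 0.5) * px,
            "centroid_y_nm": (r + 0.5) * px,
            "area_px": int(rp.area),
            "counts": float(max(rp.image_intensity.sum() - background * rp.area, 0.0)),
        })
    clusters = pd.DataFrame(rows, columns=["label", "centroid_x_nm", "centroid_y_nm",
                                           "area_px", "counts"])
    return SegmentationResult(
        particle_mask=mask, clusters=clusters, background_rate=background,
        C=C, threshold=threshold,
        mask_pixel_values=np.asarray(pair.il_map)[mask], saturated=saturated,
    )


def segment_cell_and_nucleus(pair: CorrelativePair,
                             closing_radius: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Cell and nucleus masks from the STIM energy-loss map.

    Three-class multilevel histogram split: pixels above the lower
    threshold form the cell (largest component), pixels above the upper
    threshold inside the cell form the nucleus (largest component).
    """
    de = np.asarray(pair.de_map, dtype=float)
    if de.size == 0:
        raise ValueError("empty energy-loss map")
    if np.ptp(de) <= 0 or np.unique(de).size < 3:
        raise ValueError("energy-loss map has no structure to segment")
    t_lo, t_hi = filters.threshold_multiotsu(de, classes=3)

    footprint = morphology.disk(closing_radius)

    cell = de > t_lo
    cell = ndimage.binary_closing(cell, structure=footprint)
    cell_labels = measure.label(cell)
    if cell_labels.max() == 0:
        raise ValueError("no cell component found")
    cell = cell_labels == (np.argmax(np.bincount(cell_labels.ravel())[1:]) + 1)
    cell = ndimage.binary_fill_holes(cell)

    nucleus = (de > t_hi) & cell
    nucleus = ndimage.binary_closing(nucleus, structure=footprint)
    nuc_labels = measure.label(nucleus)
    if nuc_labels.max() == 0:
        raise ValueError("no nucleus component found")
    nucleus = nuc_labels == (np.argmax(np.bincount(nuc_labels.ravel())[1:]) + 1)
    nucleus = ndimage.binary_fill_holes(nucleus) & cell
    return cell, nucleus


# ---------------------------------------------------------------------------
# line-profile resolution fitting
# ---------------------------------------------------------------------------

_SIG2FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _multi_gauss(x, baseline, *params):
    y = np.full_like(x, baseline, dtype=float)
    for i in range(0, len(params), 3):
        amp, mu, sig = params[i : i + 3]
        y = y + amp * np.exp(-0.5 * ((x - mu) / sig) ** 2)
    return y


def fit_line_profile(position_nm, counts, n_peaks: int = 1) -> dict:
    """Fit a sum of Gaussians on a constant baseline to a line profile.

    Returns per-peak FWHM (nm), centres, amplitudes, and the separations
    between adjacent peak centres.  The fit is a plain least-squares
    problem and is invariant to the ordering of the input samples.
    """
    x = np.asarray(position_nm, dtype=float)
    y = np.asarray(counts, dtype=float)
    if x.size < 8:
        raise ValueError("need at least 8 samples along the profile")
    order = np.argsort(x)
    x, y = x[order], y[order]

    baseline0 = float(np.percentile(y, 10))
    resid = np.clip(y - baseline0, 0, None)
    # initial centres: split the profile into n_peaks windows, take the
    # local maximum of each
    p0 = [baseline0]
    edges = np.linspace(0, x.size, n_peaks + 1).astype(int)
    span = x[-1] - x[0]
    for a, b in zip(edges[:-1], edges[1:]):
        j = a + int(np.argmax(resid[a:b]))
        p0 += [max(resid[j], 1e-9), x[j], max(span / (6.0 * n_peaks), 1e-3)]

    lower = [-np.inf] + [0.0, x[0] - span, 1e-6] * n_peaks
    upper = [np.inf] + [np.inf, x[-1] + span, span * 10] * n_peaks
    try:
        popt, _ = optimize.curve_fit(_multi_gauss, x, y, p0=p0,
                                     bounds=(lower, upper), maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"line-profile fit did not converge (n_peaks={n_peaks}, "
            f"init={p0}): {exc}"
        ) from None
    baseline = popt[0]
    peaks = sorted(
        ({"amplitude": popt[i], "center_nm": popt[i + 1],
          "sigma_nm": abs(popt[i + 2]), "fwhm_nm": abs(popt[i + 2]) * _SIG2FWHM}
         for i in range(1, len(popt), 3)),
        key=lambda p: p["center_nm"],
    )
    seps = [peaks[i + 1]["center_nm"] - peaks[i]["center_nm"]
            for i in range(len(peaks) - 1)]
    return {"baseline": float(baseline), "peaks": peaks,
            "fwhm_nm": [p["fwhm_nm"] for p in peaks],
            "separations_nm": seps}
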