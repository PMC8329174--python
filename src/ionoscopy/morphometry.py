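"""Nanodiamond-to-nucleus distance morphometry.

Distances are measured in 2D (the correlative maps are projections): the
Euclidean distance transform of the nucleus mask gives, for every pixel,
the physical distance to the nearest nucleus pixel; sampling it with
bilinear interpolation at each particle centroid yields the particle's
distance to the nuclear boundary.  Particles inside the nucleus get a
negative sign (distance to the nearest cytoplasm pixel) and trigger a
warning, since nanoparticles are not expected in the nucleus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class DistanceResult:
    distances_nm: np.ndarray
    bin_edges_nm: np.ndarray
    histogram: np.ndarray
    d_min_nm: float | None  # None when there are no particles

    @property
    def n(self) -> int:
        return int(self.distances_nm.size)


def distance_to_nucleus(centroids_nm, nucleus_mask, pixel_size_nm: float) -> np.ndarray:
    """Distance (nm) of each centroid to the nuclear boundary.

    ``centroids_nm`` is (n, 2) as (x, y) with the pixel-centre convention:
    pixel (row, col) sits at ((col+0.5) px, (row+0.5) px).  The boundary
    is the set of nucleus pixels adjacent to the outside; the value is the
    (interpolated) Euclidean distance-transform distance to the nearest
    boundary-pixel centre, negated for points strictly inside the nucleus.
    A centroid on a boundary pixel therefore measures zero.
    """
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if not nucleus_mask.any():
        raise ValueError("nucleus mask is empty")
    centroids = np.atleast_2d(np.asarray(centroids_nm, dtype=float))
    if centroids.size == 0:
        return np.empty(0)
    rows = centroids[:, 1] / pixel_size_nm - 0.5
    cols = centroids[:, 0] / pixel_size_nm - 0.5
    nr, nc = nucleus_mask.shape
    if np.any((rows < -0.5) | (rows > nr - 0.5) | (cols < -0.5) | (cols > nc - 0.5)):
        raise ValueError("centroid outside the image")

    boundary = nucleus_mask & ~ndimage.binary_erosion(nucleus_mask)
    dist = ndimage.distance_transform_edt(~boundary) * pixel_size_nm
    interior = ndimage.binary_erosion(nucleus_mask)
    field = np.where(interior, -dist, dist)  # signed: negative strictly inside
    vals = ndimage.map_coordinates(field, [rows, cols], order=1, mode="nearest")
    if np.any(vals < 0):
        warnings.warn(f"{int((vals < 0).sum())} particle(s) located inside the "
                      "nucleus (negative distance)", stacklevel=2)
    return vals


def brute_force_distance_to_nucleus(centroids_nm, nucleus_mask,
                                    pixel_size_nm: float) -> np.ndarray:
    """O(n^2) oracle: minimum distance to any boundary-pixel centre.

    Boundary pixels are nucleus pixels 4-adjacent to at least one outside
    pixel.  Intended for small masks in tests.
    """
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    eroded = ndimage.binary_erosion(nucleus_mask)
    boundary = nucleus_mask & ~eroded
    br, bc = np.nonzero(boundary)
    bx = (bc + 0.5) * pixel_size_nm
    by = (br + 0.5) * pixel_size_nm
    centroids = np.atleast_2d(np.asarray(centroids_nm, dtype=float))
    out = np.empty(len(centroids))
    for i, (x, y) in enumerate(centroids):
        out[i] = np.min(np.hypot(bx - x, by - y))
    return out


def distance_histogram(distances_nm, bin_width_nm: float = 250.0) -> DistanceResult:
    """Left-closed, right-open histogram of distances from 0, plus d_min."""
    if bin_width_nm <= 0:
        raise ValueError("bin width must be positive")
    d = np.asarray(distances_nm, dtype=float).ravel()
    if d.size == 0:
        return DistanceResult(distances_nm=d, bin_edges_nm=np.array([0.0]),
                              histogram=np.empty(0, dtype=int), d_min_nm=None)
    top = max(float(d.max()), 0.0)
    n_bins = int(np.floor(top / bin_width_nm)) + 1
    edges = np.arange(n_bins + 1) * bin_width_nm
    # np.histogram closes the last bin on the right; an extra bin keeps all
    # interior bins left-closed right-open
    hist, _ = np.histogram(d, bins=np.append(edges, edges[-1] + bin_width_nm))
    return DistanceResult(distances_nm=d, bin_edges_nm=edges,
                          histogram=hist[: n_bins], d_min_nm=float(d.min()))
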