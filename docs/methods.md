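# Methods

This note records the models implemented in `ionoscopy`, the assumptions
behind them, the defaults that matter, and what the synthetic-data tests
do and do not demonstrate.

## Imaging model and synthetic data

A correlative acquisition is modelled as two registered rasters over the
same scan: an ionoluminescence (IL) map of integer photon counts per
pixel and a STIM map of mean energy loss ΔE (keV) per pixel.  The
generator (`synthetic`) produces:

* **Geometry** — an elliptical cell containing an elliptical nucleus with
  randomized axes, orientation and offset.  Default raster 1024×1024 at
  20 nm/pixel (a ~20 µm field).
* **Particles** — nanodiamonds placed uniformly in the cytoplasm.
  Diameters follow a lognormal distribution, mean 35 nm, CV 0.2 (single
  particles of ~35–38 nm dominate such samples; the exact supplier
  distribution is a free parameter).  An exclusion band of configurable
  width around the nuclear boundary models the observed absence of
  nanoparticles near the nucleus; the placement verifies the gap on the
  same interpolated distance field the morphometry stage uses.
* **Brightness** — each particle's expected photon yield is
  `per_particle_rate` (default 200 photons/frame) scaled by its relative
  volume (NV count grows with d³) and by a lognormal heterogeneity
  factor, CV 0.5.  Brightness heterogeneity is a documented property of
  NV-nanodiamond ensembles, and it is what makes the per-pixel count
  histogram overdispersed — the regime the compound-Poisson counting
  model is built for.  With perfectly uniform emitters the particle-mask
  histogram is *under*dispersed (threshold truncation removes the lower
  Poisson tail) and the fit correctly refuses it.
* **IL map** — independent per-pixel Poisson draws with mean = flat
  background (default 0.05 photons/pixel) + each particle's rate spread
  over a Gaussian footprint whose FWHM is `sqrt(d² + PSF²)`.  Default PSF
  FWHM 25 nm (geometric mean of a ~22×27 nm beam spot).
* **STIM map** — ΔE proportional to areal density: a smooth dome over the
  cell peaking at the nucleus (the nucleus is the thickest, densest
  region in dried whole cells) plus a diamond column under each particle;
  Gaussian straggling noise with σ ∝ √ΔE.
* **Decay histograms** — exponential arrival times (default τ = 28.5 ns,
  the measured NV⁰ ionoluminescence decay) jittered by a Gaussian IRF,
  binned at 50 ps; the true IRF curve is stored with the histogram.
* **Foci stacks** — two-channel (nucleus stain, damage marker) 3D arrays
  with ellipsoidal nuclei and Poisson-distributed Gaussian foci of σ
  ≈ 0.3 µm at ≥1 µm mutual distance, voxel (0.5, 0.2, 0.2) µm.

What the generator does **not** emulate: optical diffraction, detector
afterpulsing, beam-current drift, sample charging, spatially structured
autofluorescence, nanodiamond aggregation into endosomes, or 3D particle
depth.  Passing tests therefore demonstrate correctness of the estimators
under the stated statistical model, not robustness to every instrument
artifact.

## Particle counting

Segmentation (`segment_particles`) estimates the background from the
image median with a MAD-based scale (floored at √(median+1), since MAD
collapses to zero on sparse integer images), thresholds at
`median + k_σ·scale` (k_σ = 3), labels 8-connected components, discards
those smaller than 2 pixels, and then trims each cluster to the pixels
above half of its background-subtracted peak.  The half-maximum
refinement makes the retained footprint match the FWHM-area definition of
the pixels-per-particle factor A regardless of particle brightness; it is
the package's own choice where the original segmentation procedure is
not fully specified.

`C` is the background-subtracted sum over the particle mask.  The
pixel-value histogram of the mask is fitted with the Neyman Type A
likelihood: the pmf is evaluated by a log-domain truncated sum over the
latent particle number (truncation `⌈β + 10√β + 10 + N/λ⌉`, extended
until a Chernoff bound on the Poisson tail is below tolerance), and
`(λ, β)` are maximized with Nelder–Mead from the moment start values
`λ₀ = var/mean − 1`, `β₀ = mean/λ₀`.  Underdispersed input raises an
explicit Poisson-degenerate error — λ is unidentifiable there.

The footprint factor is `A = E[π((d ⊕ b)/2)²] / px²` with quadrature
broadening `d ⊕ b = sqrt(d² + b²)`.  The public function defaults to
broadening by the PSF alone; the counting pipeline additionally folds in
the pixel aperture (a square pixel acts as a smoothing kernel of
equivalent Gaussian FWHM ≈ 0.68 px), because the footprint measured on a
rasterized image includes pixel integration.  On synthetic whole cells
with 300 planted particles the estimator `C/(Aλβ)` is accurate to within
a few percent (acceptance band ±15%).

## Morphometry

Distances are 2D (the maps are projections through the cell; no 3D
correction is attempted).  The nuclear boundary is the set of nucleus
pixels adjacent to the outside; each particle centroid samples the
Euclidean distance transform of that boundary with bilinear
interpolation, signed negative strictly inside the nucleus.  A centroid
on a boundary pixel measures zero.  This agrees with a brute-force scan
over boundary-pixel centres to within half a pixel on all tested masks.
Histogram bins are left-closed right-open from zero, default width
250 nm.

## Radiosensitization reach

The reach analysis deliberately replaces a full track-structure Monte
Carlo with a transparent parameterized model; its outputs are order-of-
magnitude physics, adequate for the yes/no question "can secondary
products bridge the measured exclusion distance?":

* **Impacts per nanoparticle.**  Fluence Φ = D / (S/ρ · 1.602×10⁻¹⁰) and
  impacts = Φ·πr² with the geometric cross-section.  S/ρ comes from the
  uncorrected Bethe formula with tabulated Z/A, I and density for water,
  Kapton, air, Mylar and diamond.  For 2 Gy of 2 MeV protons on a 100 nm
  particle this gives ≈6×10⁻³ impacts; published figures based on
  different geometric assumptions can differ by an order of magnitude,
  which does not affect the conclusion (counts ≪ 1 either way).
* **Secondary-electron spectrum.**  A binary-encounter shape
  dN/dW ∝ 1/(W+B)² on 0 ≤ W ≤ T_free − B, with T_free = 4(m_e/M)E and B
  the target valence binding energy (diamond default 6.6 eV, chosen so
  the endpoint reproduces the measured 870.8 eV spectrum edge for
  1.6 MeV alphas; diamond's gap is 5.47 eV, and the effective valence
  binding seen by fast ions is slightly above the gap).  The electron
  number per ion is the electronic stopping budget along the chord
  through the particle divided by the mean energy cost ⟨W+B⟩, so the
  spectrum can never carry more energy than the ion deposits.
* **Electron transport.**  Condensed-history walk: 5 nm geometric steps,
  energy from an empirical log-log range–energy table for sub-10-keV
  electrons in liquid water, tracking cutoff 10 eV, isotropic emission
  from the particle surface.  Angular diffusion per step has an RMS polar
  deflection scaling as 1/E, capped at π/2, with the 1 keV value (0.72
  rad) calibrated once so the detour factor (endpoint displacement /
  path length) is ≈0.5 at 1 keV.  Endpoints are straight-line distances
  from the particle surface.  Electron re-entry into the particle is
  ignored.
* **Hydroxyl radicals.**  Created along the track with Poisson mean
  `G·ΔE/100 eV` (G = 2.5 per 100 eV), then displaced by Gaussian
  diffusion with RMS total displacement √(6Dt), D = 2.8×10⁻⁹ m²/s,
  t = 1 µs.  Only •OH is modelled; the other radiolysis species would
  only add to a count that is already negligible at the distances of
  interest.
* **Slow-down.**  Midpoint-rule integration of Bethe dE/dx through
  layered slabs; flagged "stopped" below 0.25 MeV where the uncorrected
  formula loses validity.  2.5 MeV protons exit a 12.5 µm Kapton +
  5 mm air + 12 µm Mylar stack at ≈1.94 MeV.

Default problem sizes (10⁴–10⁵ electron histories) give per-impact reach
counts with sub-percent absolute uncertainty at the 457 nm distance; the
far tail (>300 nm) of the radical distribution is rare-event dominated
and carries larger relative spread.

## Photophysics

Relative yield = (ΣIL / (n_ions · mean ΔE)) of the sample divided by the
same quantity for a reference scintillator acquisition, making the
reference unity by construction.  Lifetimes are fitted by least squares
of `amplitude · (IRF ⊛ exp(−t/τ)) + background` on the binned counts —
unweighted, because √N weights systematically pull τ low in sparsely
filled tail bins while the high-count regime makes weighting unnecessary.
A tail-only pure-exponential fit is used when no IRF is supplied.
Recovery bias is below 2% for τ ∈ {5, 28.5, 100} ns at 10⁶ counts.

## Foci counting

The damage channel is Gaussian-smoothed (σ = 1 voxel), thresholded per
nucleus at mean + 2σ (staining intensity varies between cells, so
thresholds are never global), 26-connected components are split by a
watershed seeded at local maxima, and components smaller than 5 voxels
or peaking less than 6 robust (MAD-based) sigmas above the nucleus
median are rejected — the latter prevents correlated noise from
registering as damage in undamaged nuclei.  Nuclear volume is an Otsu
threshold of the stain channel with hole filling, times the voxel
volume.  Foci rates are normalized to a 1000 µm³ reference nucleus.
Group comparisons use the two-tailed Mann–Whitney U test (exact null for
small tie-free samples, tie-corrected normal approximation otherwise; two
identical groups therefore return p ≈ 1 rather than exactly 1).

## Numerical and interface choices

* All stochastic stages take explicit integer seeds and are
  bit-reproducible; the pipeline derives per-cell seeds from the run
  seed.
* List-mode data is a headered TSV (inspectable, lossless round trip);
  maps are 16-bit (IL) and float (ΔE) TIFFs; tables CSV; reports JSON.
* Pixel coordinates are 0-based row-major with the origin top-left;
  physical positions use pixel centres, `x = (col + 0.5)·px`.
* Config-driven runs validate keys up front, record per-cell failures
  without aborting the remaining cells, and reproduce byte-identically
  apart from the timestamp field.

## Known limitations

* The counting estimator assumes particles occupy disjoint footprints;
  heavy aggregation (many particles per pixel) biases the count toward
  the number of occupied sites.
* Binding energies, G-values, the electron range table and the angular-
  diffusion calibration are effective parameters of a simplified model,
  not a substitute for condensed-phase track-structure physics.
* Distances are projected 2D distances; a particle above or below the
  nucleus appears closer than it is in 3D.
* The Bethe stopping power omits shell and density corrections and is
  restricted to ions above ~0.25 MeV.
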