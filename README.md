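# ionoscopy

Analysis toolkit for correlative iono-nanoscopy of whole cells: quantifying
fluorescent nanodiamonds inside single cells from simultaneous
ionoluminescence (IL) and scanning-transmission-ion (STIM) maps, and using
those measurements to assess nanoparticle radiosensitization.

A focused beam of MeV ions scanned across a whole cell produces two
registered images at once: photon counts per pixel from ion-excited
nitrogen-vacancy (NV) centers in nanodiamonds, and the mean energy loss
ΔE of transmitted ions, which is proportional to the areal density of the
cell and reveals its ultrastructure (the nucleus is the densest region).
This package implements the full downstream analysis:

* **Nanodiamond counting** with a compound-Poisson (Neyman Type A) pixel
  model.  A particle-mask pixel holding `N_p ~ Poisson(β)` nanodiamonds,
  each contributing `Poisson(λ)` photons, registers

  ```
  P(N | λ, β) = Σ_{N_p ≥ 0}  e^{−β} β^{N_p} / N_p!  ·  e^{−λN_p} (λN_p)^N / N!
  ```

  with mean `λβ` and variance `λβ(1+λ)`.  With the total
  background-subtracted counts `C` over the particle mask and the mean
  imaged footprint `A` (pixels per particle, from the size distribution,
  PSF and pixel aperture), the total particle number is `C / (A λ β)`.
* **Segmentation** of particle footprints (robust threshold + half-maximum
  refinement) and of cell/nucleus from the ΔE map (3-class multi-Otsu),
  plus sum-of-Gaussian line-profile fits for resolution estimation.
* **Morphometry**: Euclidean distance-transform distances of each particle
  to the nuclear boundary, and their histogram (nanoparticles stay out of
  the nucleus; the minimum distance d_min is the key input to the
  radiosensitization question).
* **Radiosensitization reach** (`radioreach`): dose → mean proton impacts
  per nanoparticle; binary-encounter secondary-electron spectra with
  kinematic endpoint `4 (m_e/M) E − B`; condensed-history electron
  transport on an empirical sub-10-keV range–energy table for liquid
  water; hydroxyl-radical generation (G-value) and diffusion; counts of
  either species ending beyond d_min; Bethe slow-down of protons through
  layered targets (Kapton window / air / Mylar substrate).
* **Photophysics**: relative IL yield from list-mode data and TCSPC
  lifetime fitting by IRF reconvolution (50 ps bins).
* **3D foci counting** (γH2AX / 53BP1 DNA damage markers): per-nucleus
  thresholding with watershed splitting, nuclear volume, normalization to
  a reference 10×10×10 µm³ nucleus, and two-tailed Mann–Whitney group
  comparison.
* **Synthetic data** for every stage, with ground truth, so the whole
  pipeline is testable end to end without instrument data.

## Worked example

Simulate a whole cell with 300 nanodiamonds excluded from a 457 nm band
around the nucleus, then run segmentation → counting → morphometry:

```python
from ionoscopy import synthetic, segmentation, counting, morphometry

geom = synthetic.make_cell_geometry((1024, 1024), pixel_size_nm=20.0, seed=1)
sizes = synthetic.SizeDistribution("lognormal", 35.0, 0.2)
placement = synthetic.place_nanodiamonds(geom, 300, sizes,
                                         min_nucleus_gap_nm=457.0, seed=2)
pair = synthetic.render_correlative_pair(placement, geom, seed=3)

seg = segmentation.segment_particles(pair)
model = counting.count_particles(seg, sizes, psf_fwhm_nm=25.0, pixel_size_nm=20.0)
cents = seg.clusters[["centroid_x_nm", "centroid_y_nm"]].to_numpy()
d = morphometry.distance_to_nucleus(cents, geom.nucleus_mask, 20.0)
hist = morphometry.distance_histogram(d[d >= 0], bin_width_nm=250.0)
```

Output:

```
clusters found      : 290
C (bg-subtracted)   : 28899 photons
lambda, beta, A     : 6.22, 3.82, 4.09
estimated particles : 297  (300 planted)
minimum distance    : 474 nm  (>= 457 nm gap imposed)
```

The counting model recovers the planted particle number to 1% here
(acceptance band ±15%), and the measured minimum nanodiamond-to-nucleus
distance respects the imposed exclusion gap.

The same workflows are available from the shell:

```sh
ionoscopy simulate --out run/ --seed 1          # synthetic pair + ground truth
ionoscopy analyze --config cfg.yaml --out run/  # full multi-cell analysis
ionoscopy radioreach --ion proton --energy-mev 2 --diameter-nm 100 \
    --dose-gy 2 --dmin-nm 457 --n-electrons 100000 --seed 1
ionoscopy foci stacks/ --voxel-size 0.5 0.2 0.2
```

`radioreach` prints, among others, the number of secondary electrons and
hydroxyl radicals per mean proton impact that end up farther than 457 nm
from the nanoparticle surface — both far below one, i.e. a cytoplasmic
nanodiamond cannot meaningfully attack nuclear DNA through either channel
at a 2 Gy proton dose.

## Layout

```
src/ionoscopy/
  synthetic.py     # ground-truth generators (images, decays, 3D stacks)
  io.py            # list-mode TSV, TIFF maps, metadata
  segmentation.py  # particle mask, cell/nucleus, line profiles
  counting.py      # Neyman Type A pmf, MLE, C/(Aλβ) estimator
  morphometry.py   # distances to the nuclear boundary
  radioreach.py    # spectra, electron transport, radicals, slow-down
  photophysics.py  # relative yield, lifetime reconvolution
  foci3d.py        # 3D foci detection and group statistics
  pipeline.py      # config-driven workflows
  cli.py           # command-line interface
docs/methods.md    # model assumptions, parameters, limitations
```
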