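"""Generator invariants: geometry, placement, rendering, decay, foci stacks."""

import numpy as np
import pytest

from ionoscopy import morphometry, synthetic


class TestCellGeometry:
    def test_nucleus_strictly_inside_cell(self):
        geom = synthetic.make_cell_geometry((1024, 1024), 20.0, seed=1)
        assert not np.any(geom.nucleus_mask & ~geom.cell_mask)
        assert geom.nucleus_mask.any() and geom.cell_mask.any()

    def test_deterministic_for_fixed_seed(self):
        a = synthetic.make_cell_geometry((256, 256), 20.0, seed=5)
        b = synthetic.make_cell_geometry((256, 256), 20.0, seed=5)
        assert np.array_equal(a.cell_mask, b.cell_mask)
        assert np.array_equal(a.nucleus_mask, b.nucleus_mask)

    def test_minimum_shape_has_smaller_nucleus(self):
        geom = synthetic.make_cell_geometry((64, 64), 20.0, seed=7)
        assert geom.nucleus_mask.sum() < geom.cell_mask.sum()

    def test_too_small_shape_rejected(self):
        with pytest.raises(ValueError):
            synthetic.make_cell_geometry((32, 32), 20.0, seed=1)


class TestPlacement:
    def test_zero_particles_gives_empty_placement(self, small_geometry):
        pl = synthetic.place_nanodiamonds(small_geometry, 0,
                                          min_nucleus_gap_nm=457.0, seed=3)
        assert len(pl) == 0

    def test_exclusion_gap_respected_by_every_particle(self):
        geom = synthetic.make_cell_geometry((1024, 1024), 20.0, seed=2)
        sizes = synthetic.SizeDistribution("fixed", 35.0, 0.0)
        pl = synthetic.place_nanodiamonds(geom, 300, sizes,
                                          min_nucleus_gap_nm=457.0, seed=4)
        d = morphometry.distance_to_nucleus(pl.centers_nm, geom.nucleus_mask, 20.0)
        assert len(pl) == 300
        assert np.all(d >= 457.0)

    def test_sampled_mean_diameter_matches_distribution(self, small_geometry):
        sizes = synthetic.SizeDistribution("lognormal", 35.0, 0.2)
        pl = synthetic.place_nanodiamonds(small_geometry, 50, sizes, seed=6)
        se = 35.0 * 0.2 / np.sqrt(50)
        assert abs(pl.diameters_nm.mean() - 35.0) < 3 * se

    def test_impossible_placement_raises(self, small_geometry):
        with pytest.raises(synthetic.PlacementError):
            synthetic.place_nanodiamonds(small_geometry, 10,
                                         min_nucleus_gap_nm=1e6, seed=1)

    def test_particles_in_cytoplasm(self, synthetic_cell_scene):
        geom, pl, _ = synthetic_cell_scene
        rows = (pl.centers_nm[:, 1] / 20.0).astype(int)
        cols = (pl.centers_nm[:, 0] / 20.0).astype(int)
        assert geom.cytoplasm_mask[rows, cols].all()


class TestRenderPair:
    def test_no_particles_no_background_gives_empty_il(self, small_geometry):
        pl = synthetic.place_nanodiamonds(small_geometry, 0, seed=1)
        pair = synthetic.render_correlative_pair(pl, small_geometry,
                                                 background_rate=0.0, seed=1)
        assert pair.il_map.sum() == 0

    def test_total_flux_is_poisson_around_rate(self, small_geometry):
        pl = synthetic.ParticlePlacement(
            centers_nm=np.array([[2560.0, 2560.0]]),
            diameters_nm=np.array([35.0]), per_particle_rate=1000.0)
        pair = synthetic.render_correlative_pair(pl, small_geometry,
                                                 background_rate=0.0, seed=2)
        assert abs(pair.il_map.sum() - 1000.0) < 4 * np.sqrt(1000.0)

    def test_particle_columns_denser_than_cytoplasm(self, small_geometry):
        sizes = synthetic.SizeDistribution("fixed", 35.0, 0.0)
        pl = synthetic.place_nanodiamonds(small_geometry, 40, sizes, seed=8)
        pair = synthetic.render_correlative_pair(pl, small_geometry, seed=9)
        rows = (pl.centers_nm[:, 1] / 20.0).astype(int)
        cols = (pl.centers_nm[:, 0] / 20.0).astype(int)
        particle_px = np.zeros(pair.shape, bool)
        particle_px[rows, cols] = True
        cyto = small_geometry.cytoplasm_mask & ~particle_px
        assert pair.de_map[particle_px].mean() > pair.de_map[cyto].mean()

    def test_render_bit_reproducible(self, small_geometry):
        pl = synthetic.place_nanodiamonds(small_geometry, 20, seed=5)
        a = synthetic.render_correlative_pair(pl, small_geometry, seed=7)
        b = synthetic.render_correlative_pair(pl, small_geometry, seed=7)
        assert np.array_equal(a.il_map, b.il_map)
        assert np.array_equal(a.de_map, b.de_map)

    def test_particle_outside_image_rejected(self, small_geometry):
        pl = synthetic.ParticlePlacement(centers_nm=np.array([[1e6, 1e6]]),
                                         diameters_nm=np.array([35.0]))
        with pytest.raises(ValueError):
            synthetic.render_correlative_pair(pl, small_geometry, seed=1)


def test_uniform_region_pixel_counts_follow_compound_poisson(rng):
    """Poisson particle placement + Poisson emission per pixel reproduces
    the Neyman Type A mean lam*beta and variance lam*beta*(1+lam)."""
    lam, beta, n_px = 3.0, 0.5, 10**5
    # explicit placement oracle: Poisson(beta) particles per pixel, each
    # emitting Poisson(lam) photons into its pixel
    n_particles = rng.poisson(beta * n_px)
    pixel_of = rng.integers(0, n_px, size=n_particles)
    photons = rng.poisson(lam, size=n_particles)
    counts = np.zeros(n_px)
    np.add.at(counts, pixel_of, photons)
    mean, var = counts.mean(), counts.var()
    se_mean = counts.std() / np.sqrt(n_px)
    assert abs(mean - lam * beta) < 3 * se_mean
    m4 = np.mean((counts - mean) ** 4)
    se_var = np.sqrt((m4 - var**2) / n_px)
    assert abs(var - lam * beta * (1 + lam)) < 3 * se_var


class TestDecayHistogram:
    def test_tail_log_slope_matches_lifetime(self):
        h = synthetic.render_decay_histogram(28.5, 0.01, 10**6, 50.0, seed=1)
        t = h.t_ns
        sel = (t > h.meta["t0_ns"] + 5.0) & (h.counts > 30)
        slope = np.polyfit(t[sel], np.log(h.counts[sel]), 1)[0]
        assert abs(-1.0 / slope - 28.5) / 28.5 < 0.02

    def test_zero_irf_width_gives_pure_exponential(self):
        h = synthetic.render_decay_histogram(10.0, 0.0, 200000, 50.0, seed=2)
        # nothing before the trigger bin
        i0 = int(np.argmax(h.irf))
        assert h.counts[:i0].sum() == 0

    def test_mass_scales_with_total_counts(self):
        h1 = synthetic.render_decay_histogram(10.0, 0.2, 10**5, 50.0, seed=3)
        h2 = synthetic.render_decay_histogram(10.0, 0.2, 2 * 10**5, 50.0, seed=4)
        ratio = h2.total_counts / h1.total_counts
        assert abs(ratio - 2.0) < 0.05

    def test_empty_histogram_allowed(self):
        h = synthetic.render_decay_histogram(10.0, 0.2, 0, 50.0, seed=5)
        assert h.total_counts == 0


class TestFociStack:
    def test_zero_mean_gives_no_blobs(self):
        stack, truth = synthetic.render_foci_stack(n_nuclei=2,
                                                   foci_per_nucleus_mean=0.0, seed=1)
        assert truth["total_foci"] == 0
        # damage channel is pure Poisson background
        assert stack[1].max() < 15

    def test_total_foci_poisson_around_mean(self):
        stack, truth = synthetic.render_foci_stack(
            n_nuclei=10, foci_per_nucleus_mean=12.0, shape=(16, 256, 256), seed=2)
        assert abs(truth["total_foci"] - 120) < 3 * np.sqrt(120)

    def test_ground_truth_volume_is_voxel_count_times_voxel_volume(self):
        stack, truth = synthetic.render_foci_stack(n_nuclei=3, seed=3)
        voxel_volume = np.prod(truth["voxel_size_um"])
        counted = [(truth["labels"] == i + 1).sum() * voxel_volume for i in range(3)]
        assert np.allclose(counted, truth["nuclear_volumes_um3"])
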