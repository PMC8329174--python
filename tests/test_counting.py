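"""Compound-Poisson pmf, maximum-likelihood fitting and the C/(A lam beta) estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ionoscopy import counting, segmentation, synthetic
from ionoscopy.counting import (PoissonDegenerateError, estimate_particle_number,
                                fit_count_model, moment_estimates, neyman_pmf,
                                pixels_per_particle, simulate_neyman)


class TestPmf:
    @pytest.mark.parametrize("lam,beta", [(0.5, 0.2), (3.0, 0.5), (8.0, 2.0)])
    def test_zero_count_closed_form(self, lam, beta):
        expected = np.exp(-beta * (1.0 - np.exp(-lam)))
        assert neyman_pmf(0, lam, beta) == pytest.approx(expected, rel=1e-10)

    def test_zero_lambda_degenerates_to_point_mass(self):
        assert neyman_pmf(0, 0.0, 0.7) == pytest.approx(1.0)
        assert neyman_pmf(3, 0.0, 0.7) == 0.0

    @given(lam=st.floats(0.1, 10.0), beta=st.floats(0.05, 3.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_normalization_and_moments(self, lam, beta):
        n = np.arange(0, 600)
        p = neyman_pmf(n, lam, beta)
        assert p.sum() == pytest.approx(1.0, abs=1e-8)
        assert (n * p).sum() == pytest.approx(lam * beta, abs=1e-6, rel=1e-6)
        var = (n**2 * p).sum() - (n * p).sum() ** 2
        assert var == pytest.approx(lam * beta * (1 + lam), abs=1e-6, rel=1e-6)

    def test_matches_two_stage_simulation(self, rng):
        lam, beta, n_draw = 3.0, 0.5, 200_000
        x = simulate_neyman(lam, beta, n_draw, rng)
        for k in range(0, 15):
            p = neyman_pmf(k, lam, beta)
            freq = np.mean(x == k)
            se = np.sqrt(p * (1 - p) / n_draw)
            assert abs(freq - p) < max(3 * se, 1e-5)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            neyman_pmf(1, -1.0, 0.5)
        with pytest.raises(ValueError):
            neyman_pmf(1, 1.0, -0.5)


class TestFit:
    def test_moment_initialization_arithmetic(self):
        lam0, beta0 = moment_estimates(2.0, 10.0)
        assert lam0 == pytest.approx(4.0)
        assert beta0 == pytest.approx(0.5)

    def test_parameter_recovery_on_large_sample(self, rng):
        x = simulate_neyman(4.0, 0.5, 10**5, rng)
        fit = fit_count_model(x)
        assert fit["converged"]
        assert abs(fit["lam"] - 4.0) / 4.0 < 0.05
        assert abs(fit["beta"] - 0.5) / 0.5 < 0.05

    def test_bias_shrinks_with_sample_size(self):
        errs = {}
        for n in (10**3, 10**5):
            e = []
            for seed in range(3):
                x = simulate_neyman(4.0, 0.5, n, np.random.default_rng(seed))
                fit = fit_count_model(x)
                e.append(abs(fit["lam"] - 4.0))
            errs[n] = np.mean(e)
        assert errs[10**5] < errs[10**3]

    def test_constant_histogram_is_poisson_degenerate(self):
        with pytest.raises(PoissonDegenerateError):
            fit_count_model(np.full(100, 5))

    def test_underdispersed_data_rejected(self, rng):
        x = rng.binomial(10, 0.5, size=1000)  # var < mean
        with pytest.raises(PoissonDegenerateError):
            fit_count_model(x)

    def test_too_few_pixels_rejected(self):
        with pytest.raises(ValueError):
            fit_count_model(np.arange(10))


class TestPixelsPerParticle:
    def test_fixed_size_closed_form_without_psf(self):
        A = pixels_per_particle(35.0, 20.0, 0.0)
        assert A == pytest.approx(np.pi * 17.5**2 / 400.0, rel=1e-12)
        assert A == pytest.approx(2.405, abs=5e-4)

    def test_fixed_size_with_quadrature_psf(self):
        A = pixels_per_particle(35.0, 20.0, 25.0)
        assert np.sqrt(35**2 + 25**2) == pytest.approx(43.01, abs=0.01)
        assert A == pytest.approx(3.632, abs=1e-3)

    def test_lognormal_expectation_matches_monte_carlo(self, rng):
        sizes = synthetic.SizeDistribution("lognormal", 35.0, 0.2)
        A = pixels_per_particle(sizes, 20.0, 25.0)
        d = sizes.sample(10**6, rng)
        mc = np.mean(np.pi * ((d**2 + 25.0**2) / 4.0) / 400.0)
        assert abs(A - mc) / mc < 0.005

    def test_degenerate_diameter_rejected(self):
        with pytest.raises(ValueError):
            pixels_per_particle(-1.0, 20.0)


class TestEstimator:
    def test_single_particle_identity(self):
        res = estimate_particle_number(3.0 * 5.0 * 0.6, 3.0, 5.0, 0.6)
        assert res["n_total"] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        res = estimate_particle_number(9000.0, 3.0, 5.0, 0.6)
        assert res["n_total"] == pytest.approx(1000.0)
        assert res["n_occupied_pixels"] == pytest.approx(3000.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            estimate_particle_number(100.0, 0.0, 5.0, 0.6)

    def test_end_to_end_recovers_planted_particle_number(self):
        geom = synthetic.make_cell_geometry((1024, 1024), 20.0, seed=31)
        sizes = synthetic.SizeDistribution("lognormal", 35.0, 0.2)
        pl = synthetic.place_nanodiamonds(geom, 300, sizes,
                                          min_nucleus_gap_nm=457.0, seed=32)
        pair = synthetic.render_correlative_pair(pl, geom, seed=33)
        seg = segmentation.segment_particles(pair)
        model = counting.count_particles(seg, sizes, 25.0, 20.0)
        assert abs(model.n_total - 300) / 300 < 0.15

    def test_estimate_invariant_under_brightness_rescaling(self):
        """Doubling every particle's emission doubles C and lam*beta but
        leaves the particle-number estimate unchanged."""
        geom = synthetic.make_cell_geometry((512, 512), 20.0, seed=41)
        sizes = synthetic.SizeDistribution("lognormal", 35.0, 0.2)
        # homogeneous brightness so detection is complete at both scales and
        # the comparison isolates the estimator itself
        pl = synthetic.place_nanodiamonds(geom, 120, sizes, seed=42,
                                          brightness_cv=0.0)
        results = {}
        for scale in (1.0, 2.0):
            pl_s = synthetic.ParticlePlacement(
                centers_nm=pl.centers_nm, diameters_nm=pl.diameters_nm,
                per_particle_rate=pl.per_particle_rate * scale,
                rates=pl.rates * scale)
            pair = synthetic.render_correlative_pair(pl_s, geom, seed=43)
            seg = segmentation.segment_particles(pair)
            model = counting.count_particles(seg, sizes, 25.0, 20.0)
            results[scale] = model
        c_ratio = results[2.0].C / results[1.0].C
        lb_ratio = (results[2.0].lam * results[2.0].beta) / (
            results[1.0].lam * results[1.0].beta)
        assert c_ratio == pytest.approx(2.0, rel=0.10)
        assert lb_ratio == pytest.approx(2.0, rel=0.10)
        n_ratio = results[2.0].n_total / results[1.0].n_total
        assert n_ratio == pytest.approx(1.0, rel=0.10)
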