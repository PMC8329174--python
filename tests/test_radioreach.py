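"""Radiosensitization reach: dose-to-impacts, electron spectrum and transport,
radical diffusion, reach counting and proton slow-down."""

import numpy as np
import pytest
from scipy import stats

from ionoscopy import radioreach as rr


@pytest.fixture(scope="module")
def proton2():
    return rr.BeamSpec("proton", 2.0)


@pytest.fixture(scope="module")
def proton_spectrum(proton2):
    return rr.secondary_electron_spectrum(proton2, target="diamond", path_nm=100.0)


@pytest.fixture(scope="module")
def proton_transport(proton_spectrum):
    return rr.transport_electrons(proton_spectrum, 20000,
                                  particle_diameter_nm=100.0, seed=7)


class TestDoseToImpacts:
    def test_zero_dose_zero_impacts(self, proton2):
        assert rr.dose_to_mean_impacts(0.0, proton2, 100.0) == 0.0

    def test_hand_arithmetic_at_fixed_fluence(self, proton2):
        # dose chosen so the fluence is exactly 1e8 cm^-2
        s = 100.0
        dose = 1e8 * s * rr.GY_PER_MEV_CM2_G
        impacts = rr.dose_to_mean_impacts(dose, proton2, 100.0,
                                          mass_stopping_power_mev_cm2_g=s)
        assert impacts == pytest.approx(1e8 * np.pi * (5e-6) ** 2, rel=1e-9)
        assert impacts == pytest.approx(7.85e-3, rel=0.01)

    def test_linear_in_dose_quadratic_in_diameter(self, proton2):
        i1 = rr.dose_to_mean_impacts(1.0, proton2, 100.0)
        i2 = rr.dose_to_mean_impacts(2.0, proton2, 100.0)
        assert i2 == pytest.approx(2 * i1, rel=1e-12)
        d1 = rr.dose_to_mean_impacts(2.0, proton2, 50.0)
        d2 = rr.dose_to_mean_impacts(2.0, proton2, 100.0)
        assert d2 == pytest.approx(4 * d1, rel=1e-12)

    def test_bad_stopping_power_rejected(self, proton2):
        with pytest.raises(ValueError):
            rr.dose_to_mean_impacts(2.0, proton2, 100.0,
                                    mass_stopping_power_mev_cm2_g=-1.0)


class TestSpectrum:
    def test_alpha_kinematic_maximum(self):
        beam = rr.BeamSpec("alpha", 1.6)
        assert rr.kinematic_endpoint_ev(beam) == pytest.approx(877.4, abs=0.5)

    def test_proton_kinematic_maximum(self, proton2):
        assert rr.kinematic_endpoint_ev(proton2) == pytest.approx(4357.0, abs=2.0)

    def test_diamond_endpoint_with_binding(self):
        spec = rr.secondary_electron_spectrum(rr.BeamSpec("alpha", 1.6), "diamond")
        assert spec.t_max_ev == pytest.approx(870.8, abs=0.05)

    def test_binding_above_kinematic_max_gives_empty_flagged_spectrum(self):
        beam = rr.BeamSpec("alpha", 0.001)  # T_free ~0.5 eV
        spec = rr.secondary_electron_spectrum(beam, "diamond", binding_ev=6.6)
        assert spec.empty
        assert spec.electrons_per_ion == 0.0

    def test_energy_budget_not_exceeded(self, proton_spectrum, proton2):
        w = proton_spectrum.energies_ev
        dndw = proton_spectrum.yield_per_ev
        carried = np.trapezoid(dndw * (w + proton_spectrum.binding_ev), w)
        budget = (rr.mass_stopping_power(proton2, "diamond")
                  * rr.MATERIALS["diamond"][2] * 1e6 * 1e-7 * 100.0)
        assert carried <= budget * 1.01

    def test_sampled_energies_within_support(self, proton_spectrum, rng):
        e = proton_spectrum.sample(5000, rng)
        assert e.min() >= 0.0
        assert e.max() <= proton_spectrum.t_max_ev + 1e-9


class TestTransport:
    def test_cutoff_energy_electrons_stop_immediately(self):
        res = rr.transport_electrons(None, 100, particle_diameter_nm=0.0, seed=1,
                                     initial_energies_ev=np.full(100, 10.0),
                                     record_deposition=False)
        assert res.endpoints_nm.max() < 10.0

    def test_4kev_mean_endpoint_in_csda_ballpark(self):
        res = rr.transport_electrons(None, 2000, particle_diameter_nm=0.0, seed=2,
                                     initial_energies_ev=np.full(2000, 4000.0),
                                     record_deposition=False)
        assert 200.0 < res.endpoints_nm.mean() < 1000.0

    def test_detour_factor_calibration_at_1kev(self):
        assert rr.detour_factor(1000.0, n=3000, seed=3) == pytest.approx(0.5, abs=0.1)

    def test_few_spectrum_electrons_pass_the_exclusion_distance(self, proton_transport):
        frac = np.mean(proton_transport.endpoints_nm > 457.0)
        assert frac < 0.1

    def test_reproducible_under_fixed_seed(self, proton_spectrum):
        a = rr.transport_electrons(proton_spectrum, 500, seed=9)
        b = rr.transport_electrons(proton_spectrum, 500, seed=9)
        assert np.array_equal(a.endpoints_nm, b.endpoints_nm)

    def test_endpoint_distribution_stable_across_seeds(self, proton_spectrum):
        a = rr.transport_electrons(proton_spectrum, 10000, seed=11,
                                   record_deposition=False).endpoints_nm
        b = rr.transport_electrons(proton_spectrum, 10000, seed=12,
                                   record_deposition=False).endpoints_nm
        ks = stats.ks_2samp(a, b).statistic
        assert ks < 0.05

    def test_empty_spectrum_rejected(self):
        spec = rr.secondary_electron_spectrum(rr.BeamSpec("alpha", 0.001), "diamond")
        with pytest.raises(ValueError):
            rr.transport_electrons(spec, 100, seed=1)


class TestRadicals:
    def test_zero_g_value_gives_no_radicals(self, proton_transport):
        res = rr.simulate_radicals(proton_transport, g_oh=0.0, seed=1)
        assert res.endpoints_nm.size == 0

    def test_diffusion_displacement_scale(self):
        # single deposition site at the surface; RMS displacement sqrt(6 D t)
        tr = rr.TransportResult(
            endpoints_nm=np.zeros(1), deposition_xyz_nm=np.zeros((1, 3)),
            deposition_ev=np.array([2e5]), n_histories=1,
            electrons_per_ion=1.0, surface_radius_nm=0.0)
        res = rr.simulate_radicals(tr, g_oh=2.5, seed=2)
        rms = np.sqrt(np.mean(res.endpoints_nm**2))
        expected = np.sqrt(6 * 2.8e-9 * 1e-6) * 1e9  # ~130 nm
        assert expected == pytest.approx(129.6, abs=0.5)
        assert rms == pytest.approx(expected, rel=0.05)

    def test_radical_count_linear_in_deposited_energy(self):
        for e, seed in ((1e4, 3), (2e4, 4)):
            tr = rr.TransportResult(
                endpoints_nm=np.zeros(1), deposition_xyz_nm=np.zeros((1, 3)),
                deposition_ev=np.array([e]), n_histories=1,
                electrons_per_ion=1.0, surface_radius_nm=0.0)
            res = rr.simulate_radicals(tr, g_oh=2.5, seed=seed)
            expected = 2.5 * e / 100.0
            assert abs(res.endpoints_nm.size - expected) < 4 * np.sqrt(expected)

    def test_bad_diffusion_parameters_rejected(self, proton_transport):
        with pytest.raises(ValueError):
            rr.simulate_radicals(proton_transport, diffusion_coefficient_m2_s=-1.0)
        with pytest.raises(ValueError):
            rr.simulate_radicals(proton_transport, t_end_s=0.0)


class TestCountReaching:
    def test_zero_distance_counts_everything(self, proton_transport):
        reach = rr.electron_reach(proton_transport)
        res = rr.count_reaching(reach, 0.0, impacts=1.0)
        total_per_primary = proton_transport.endpoints_nm.size / reach.n_primaries
        # endpoints exactly at 0 (stopped at the surface) are not "beyond 0"
        assert res["per_primary"] <= total_per_primary
        assert res["per_primary"] == reach.count_beyond(0.0)

    def test_infinite_distance_counts_nothing(self, proton_transport):
        reach = rr.electron_reach(proton_transport)
        assert rr.count_reaching(reach, 1e12, impacts=1.0)["per_primary"] == 0.0

    def test_monotone_nonincreasing_in_distance(self, proton_transport):
        reach = rr.electron_reach(proton_transport)
        grid = np.linspace(0, 1000, 21)
        counts = reach.count_beyond(grid)
        assert np.all(np.diff(counts) <= 1e-12)


class TestSlowDown:
    def test_empty_stack_preserves_energy(self):
        res = rr.slow_down_through_stack(rr.BeamSpec("proton", 2.5), [])
        assert res["exit_energy_mev"] == 2.5
        assert not res["stopped"]

    def test_exit_energy_through_window_air_substrate(self):
        res = rr.slow_down_through_stack(
            rr.BeamSpec("proton", 2.5),
            [("kapton", 12.5), ("air", 5000.0), ("mylar", 12.0)])
        assert not res["stopped"]
        assert res["exit_energy_mev"] == pytest.approx(2.0, abs=0.2)

    def test_exit_energy_decreases_with_added_thickness(self):
        beam = rr.BeamSpec("proton", 2.5)
        e = [rr.slow_down_through_stack(beam, [("mylar", t)])["exit_energy_mev"]
             for t in (5.0, 10.0, 20.0, 40.0)]
        assert np.all(np.diff(e) < 0)

    def test_particle_stopping_inside_stack_is_flagged(self):
        res = rr.slow_down_through_stack(rr.BeamSpec("proton", 0.5),
                                         [("kapton", 100.0)])
        assert res["stopped"]
        assert res["stopped_in"] == "kapton"
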