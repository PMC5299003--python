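"""Steady-state reaction–diffusion generator and its parameter-recovery loop."""

import numpy as np
import pytest
from pydantic import ValidationError

from benthifilter.fluxes import diffusive_flux, fit_gradient
from benthifilter.synthetic_data import (
    Scenario,
    generate_chamber_series,
    generate_profile,
    generate_voltammogram,
    recovery_scenario,
)
from benthifilter.chamber import chamber_flux


class TestScenarioValidation:
    def test_depth_step_below_instrument_minimum_rejected(self):
        with pytest.raises(ValidationError):
            Scenario(depth_step=0.1)

    @pytest.mark.parametrize("porosity", [0.0, 1.2])
    def test_porosity_outside_unit_interval_rejected(self, porosity):
        with pytest.raises(ValidationError):
            Scenario(porosity=porosity)

    def test_negative_production_rate_rejected(self):
        with pytest.raises(ValidationError):
            Scenario(production_zone=(5.0, 20.0, -1.0), max_depth_mm=30.0)

    def test_production_zone_outside_domain_rejected(self):
        with pytest.raises(ValidationError):
            Scenario(production_zone=(5.0, 200.0, 10.0), max_depth_mm=30.0)

    def test_yaml_round_trip(self, tmp_path):
        scenario = Scenario(
            station_label="yaml-test",
            production_zone=(5.0, 25.0, 150.0),
            mat_layer=(0.0, 1.0),
            max_depth_mm=25.0,
            seed=7,
        )
        path = tmp_path / "scenario.yaml"
        scenario.to_yaml(path)
        assert Scenario.from_yaml(path) == scenario


class TestGenerateProfile:
    def test_no_reaction_gives_uniform_field_and_zero_flux(self):
        scenario = Scenario(
            bottom_water_conc={"H2S": 100.0},
            noise_sd=0.0,
            max_depth_mm=20.0,
            depth_step=0.5,
        )
        profile, truth = generate_profile(scenario)
        field = truth.true_concentration_field["H2S"]
        assert field == pytest.approx(np.full_like(field, 100.0), rel=1e-9)
        assert truth.true_flux_at_swi["H2S"] == pytest.approx(0.0, abs=1e-9)
        # sampled values equal the field exactly at zero noise
        sediment = profile.depth_mm >= 0
        assert profile.concentrations["H2S"][sediment] == pytest.approx(100.0, rel=1e-9)

    def test_mat_scenario_linear_gradient_and_flux_recovery(self):
        scenario = Scenario(
            production_zone=(5.0, 25.0, 150.0),
            mat_layer=(0.0, 1.0),
            max_depth_mm=25.0,
            depth_step=0.25,
            noise_sd=2.0,
            seed=3,
        )
        profile, truth = generate_profile(scenario)
        # analytic: all production (150 μM/day * 20 mm) flows up into the mat
        assert truth.true_flux_to_mat["H2S"] == pytest.approx(3.0, rel=0.01)
        # the mat consumes everything: essentially no efflux at the interface
        assert abs(truth.true_flux_at_swi["H2S"]) < 0.05 * truth.true_flux_to_mat["H2S"]
        # noiseless field is linear between mat base and production top
        grid, field = truth.grid_mm, truth.true_concentration_field["H2S"]
        inside = (grid >= 1.5) & (grid <= 4.5)
        fitted = np.polyfit(grid[inside], field[inside], 1)
        assert np.max(np.abs(np.polyval(fitted, grid[inside]) - field[inside])) < 1e-6 * field.max()
        # refitting the sampled (noisy) profile recovers the mat-base flux
        slope, se = fit_gradient(profile, "H2S", (1.0, 5.0))
        recovered = diffusive_flux(slope, se, scenario.porosity, truth.Ds["H2S"]).value
        assert recovered == pytest.approx(truth.true_flux_to_mat["H2S"], rel=0.05)

    def test_mat_consumption_closes_the_budget(self):
        scenario = Scenario(
            production_zone=(5.0, 25.0, 150.0),
            mat_layer=(0.0, 1.0),
            max_depth_mm=25.0,
            depth_step=0.25,
        )
        _, truth = generate_profile(scenario)
        grid, conc = truth.grid_mm, truth.true_concentration_field["H2S"]
        h_m = scenario.internal_step_mm / 1000.0
        phi_ds = scenario.porosity * truth.Ds["H2S"]
        idx = np.where((grid >= 0.0) & (grid <= 1.0))[0]
        j2 = idx[-1]
        # telescoped discrete balance over the mat nodes (top node is the
        # Dirichlet row, so the sum starts below it)
        consumption = np.sum(
            scenario.mat_sink_rate_per_day * conc[idx[1] : j2 + 1] * h_m
        )
        net_diffusive = phi_ds * (
            (conc[j2 + 1] - conc[j2]) / h_m - (conc[1] - conc[0]) / h_m
        )
        assert net_diffusive == pytest.approx(consumption, rel=0.01)

    def test_mat_top_concentration_effectively_zero(self):
        scenario = Scenario(
            bottom_water_conc={"H2S": 0.0},
            production_zone=(5.0, 25.0, 150.0),
            mat_layer=(0.0, 1.0),
            max_depth_mm=25.0,
        )
        _, truth = generate_profile(scenario)
        grid = truth.grid_mm
        conc = truth.true_concentration_field["H2S"]
        assert conc[grid <= 0.1].max() < 0.1

    def test_deep_iron_source_separated_from_sulfide(self):
        scenario = Scenario(
            bottom_water_conc={"H2S": 0.0, "Fe": 0.0},
            production_zone=(20.0, 80.0, 100.0),
            fe_source=(100.0, 0.01),
            max_depth_mm=120.0,
            depth_step=0.5,
            seed=7,
        )
        _, truth = generate_profile(scenario)
        grid = truth.grid_mm
        sulfide = truth.true_concentration_field["H2S"]
        iron = truth.true_concentration_field["Fe"]
        # sulfide maximum sits inside the production zone, gone by 100 mm
        assert grid[np.argmax(sulfide)] < 80.0
        assert sulfide[grid >= 100.0].max() < 0.01 * sulfide.max()
        # Fe(II) appears only below the sulfide-depletion depth
        assert iron.max() > 0
        assert iron[sulfide > 1.0].max() < 0.1 * iron.max()
        assert truth.true_flux_at_swi["Fe"] == pytest.approx(0.0, abs=1e-6)

    def test_surface_flux_monotone_in_production_rate(self):
        fluxes = []
        for rate in (50.0, 100.0, 200.0, 400.0):
            scenario = Scenario(
                production_zone=(10.0, 30.0, rate), max_depth_mm=30.0
            )
            _, truth = generate_profile(scenario)
            fluxes.append(truth.true_flux_at_swi["H2S"])
        assert all(b > a for a, b in zip(fluxes, fluxes[1:]))

    def test_identical_seeds_reproduce_identical_profiles(self):
        scenario = Scenario(
            production_zone=(5.0, 25.0, 150.0), max_depth_mm=25.0, seed=42
        )
        p1, _ = generate_profile(scenario)
        p2, _ = generate_profile(scenario)
        assert np.array_equal(p1.concentrations["H2S"], p2.concentrations["H2S"])
        p3, _ = generate_profile(scenario.model_copy(update={"seed": 43}))
        assert not np.array_equal(p1.concentrations["H2S"], p3.concentrations["H2S"])

    def test_sampled_concentrations_never_negative(self):
        scenario = Scenario(
            bottom_water_conc={"H2S": 1.0}, noise_sd=5.0, max_depth_mm=20.0, seed=1
        )
        profile, _ = generate_profile(scenario)
        assert (profile.concentrations["H2S"] >= 0).all()


class TestGenerateVoltammogram:
    def test_zero_concentration_gives_flat_trace(self, calib):
        scan = generate_voltammogram({"H2S": 0.0}, calib, noise_sd_nA=0.0)
        assert np.abs(scan.current).max() == pytest.approx(0.0, abs=1e-12)

    def test_forward_peak_and_wave_heights_match_concentration(self, calib):
        from benthifilter.voltammetry import detect_peaks, measure_backward_wave

        scan = generate_voltammogram({"H2S": 100.0}, calib, noise_sd_nA=0.0)
        peaks = detect_peaks(scan, {"H2S": (-0.95, -0.60)})
        assert peaks[0].height == pytest.approx(100.0, rel=0.01)
        assert measure_backward_wave(scan) == pytest.approx(100.0, rel=0.01)

    def test_forward_peak_clips_at_saturation(self, calib):
        from benthifilter.voltammetry import detect_peaks, measure_backward_wave

        scan = generate_voltammogram({"H2S": 600.0}, calib, noise_sd_nA=0.0)
        peaks = detect_peaks(scan, {"H2S": (-0.95, -0.60)})
        assert peaks[0].height == pytest.approx(250.0, rel=0.01)
        assert measure_backward_wave(scan) == pytest.approx(600.0, rel=0.01)

    def test_unconfigured_analyte_rejected(self, calib):
        with pytest.raises(ValueError):
            generate_voltammogram({"NO3": 10.0}, calib)


class TestGenerateChamberSeries:
    def test_zero_flux_is_constant_within_noise(self):
        inc = generate_chamber_series(0.0, noise_sd=0.0, start_conc_uM=20.0)
        assert np.ptp(inc.conc_uM) == pytest.approx(0.0, abs=1e-12)

    def test_worked_example_ten_micromolar_rise(self):
        inc = generate_chamber_series(
            0.8, height=0.1, n_samples=6, duration=30.0, noise_sd=0.0
        )
        assert inc.conc_uM[-1] - inc.conc_uM[0] == pytest.approx(10.0, rel=1e-9)

    def test_zero_noise_round_trip_is_exact(self):
        inc = generate_chamber_series(0.8, height=0.1, duration=30.0, noise_sd=0.0)
        est = chamber_flux(inc)
        assert est is not None
        assert est.value == pytest.approx(0.8, rel=1e-9)

    def test_non_positive_height_rejected(self):
        with pytest.raises(ValueError):
            generate_chamber_series(1.0, height=0.0)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            generate_chamber_series(1.0, n_samples=1)


class TestRecoveryScenario:
    def test_fluxes_span_the_requested_range(self):
        rng = np.random.default_rng(5)
        fluxes = []
        for _ in range(50):
            scenario, _ = recovery_scenario(rng)
            _, truth = generate_profile(scenario)
            fluxes.append(truth.true_flux_at_swi["H2S"])
        assert min(fluxes) < 0.5 and max(fluxes) > 5.0
        assert all(f > 0 for f in fluxes)
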