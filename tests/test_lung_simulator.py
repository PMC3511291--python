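"""Unit-population sampling and recruitment-manoeuvre simulation."""

import numpy as np
import pytest

from pulmorecruit import (
    ConfigurationError,
    InfeasibleVentilationError,
    ParameterError,
    RecruitmentParams,
    VentilatorSettings,
    fraction_recruited,
    quasi_static_inflation,
    sample_unit_population,
    simulate_rm,
)
from pulmorecruit.scenarios import default_settings


class TestSampleUnitPopulation:
    def test_sample_mean_matches_generating_distribution(self):
        # tolerance 3*sd/sqrt(n) around the nominal mean
        pop = sample_unit_population(100_000, 42.4, 23.0, 10.2, 4.0, 0.01, seed=1)
        assert pop.top.mean() == pytest.approx(42.4, abs=0.25)
        assert pop.top.std() == pytest.approx(23.0, rel=0.01)

    def test_degenerate_sd_collapses_to_mean(self):
        pop = sample_unit_population(1, 30.0, 1e-6, 5.0, 1e-6, 0.01, seed=3)
        assert pop.top[0] == pytest.approx(30.0, abs=1e-4)

    def test_identical_seed_gives_bit_identical_population(self):
        a = sample_unit_population(5000, 40.0, 10.0, 10.0, 3.0, 0.05, seed=7)
        b = sample_unit_population(5000, 40.0, 10.0, 10.0, 3.0, 0.05, seed=7)
        assert np.array_equal(a.top, b.top) and np.array_equal(a.tcp, b.tcp)

    def test_hysteresis_constraint_enforced(self):
        # heavy overlap between the two distributions
        pop = sample_unit_population(20_000, 20.0, 10.0, 15.0, 10.0, 0.05, seed=2)
        assert np.all(pop.tcp < pop.top)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_units=0),
            dict(sd_top=-1.0),
            dict(sd_tcp=0.0),
            dict(unit_volume=0.0),
        ],
    )
    def test_parameter_errors(self, kwargs):
        base = dict(n_units=10, mu_top=40.0, sd_top=10.0, mu_tcp=10.0,
                    sd_tcp=3.0, unit_volume=0.05, seed=0)
        base.update(kwargs)
        with pytest.raises(ParameterError):
            sample_unit_population(**base)

    def test_tcp_far_above_top_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            sample_unit_population(100, 10.0, 2.0, 40.0, 2.0, 0.05, seed=0)


class TestQuasiStaticInflation:
    def test_converges_to_erf_curve(self):
        pop = sample_unit_population(100_000, 42.4, 23.0, 10.2, 4.0, 0.01, seed=11)
        p = np.linspace(42.4 - 4 * 23, 42.4 + 4 * 23, 201)
        truth = fraction_recruited(p, RecruitmentParams(42.4, 23.0, 1.0))
        assert np.max(np.abs(quasi_static_inflation(pop, p) - truth)) < 0.01


class TestSimulateRM:
    def test_record_is_internally_consistent(self, healthy_record_clean):
        rec = healthy_record_clean
        dt = rec.dt
        assert np.all(np.diff(rec.time) > 0)
        # volume is the running trapezoid of flow
        left = np.concatenate(([0.0], rec.flow[:-1]))
        expected = np.cumsum(0.5 * (left + rec.flow) * dt)
        assert np.allclose(rec.volume, expected, atol=1e-9)

    def test_determinism(self, binary_population, settings):
        a = simulate_rm(binary_population, settings, noise_sd_frac=0.02, seed=5)
        b = simulate_rm(binary_population, settings, noise_sd_frac=0.02, seed=5)
        assert np.array_equal(a.paw, b.paw) and np.array_equal(a.flow, b.flow)

    def test_end_expiratory_volume_non_decreasing_with_peep(self, healthy_record_clean):
        eev = [healthy_record_clean.truth.eev_ml[l] for l in (5.0, 10.0, 15.0, 20.0)]
        assert all(b >= a - 1e-6 for a, b in zip(eev, eev[1:]))

    def test_mass_balance_per_breath(self, binary_record_clean):
        """Inspired minus expired volume equals the end-expiratory change."""
        from pulmorecruit import segment_breaths

        rec = binary_record_clean
        for b in segment_breaths(rec)[:-1]:
            delta_eev = rec.volume[b.exp_end] - rec.volume[b.insp_start]
            assert b.inspired_volume - b.expired_volume == pytest.approx(
                delta_eev, abs=0.5
            )

    def test_steady_state_after_two_breaths_single_level(self):
        pop = sample_unit_population(10_000, 42.4, 23.0, 18.0, 8.0, 0.05, seed=4)
        settings = default_settings(peep_schedule=(5.0,), breaths_per_level=8)
        rec = simulate_rm(pop, settings, noise_sd_frac=0.0, seed=5)
        from pulmorecruit import segment_breaths

        breaths = segment_breaths(rec)
        vt = settings.tidal_volume
        for b in breaths[2:]:
            assert abs(b.inspired_volume - b.expired_volume) < 0.01 * vt

    def test_volume_bounded_by_capacity(self, binary_record_clean, binary_population):
        assert binary_record_clean.volume.max() <= binary_population.capacity + 1.0

    def test_end_expiratory_pressure_floor(self, binary_record_clean):
        """Airway pressure has returned to (at least) PEEP at end-expiration."""
        from pulmorecruit import segment_breaths

        rec = binary_record_clean
        for b in segment_breaths(rec):
            assert rec.paw[b.exp_end] >= rec.peep[b.exp_end] - 1e-6

    def test_auto_peep_raises_end_expiratory_pressure(self, binary_population):
        short = default_settings(peep_schedule=(5.0, 10.0), breaths_per_level=6)
        rec = simulate_rm(binary_population, short, noise_sd_frac=0.0,
                          auto_peep=3.0, seed=6)
        from pulmorecruit import segment_breaths

        b = segment_breaths(rec)[5]
        assert rec.paw[b.exp_end] >= rec.peep[b.exp_end] + 3.0 - 1e-6

    def test_oversized_tidal_volume_is_infeasible(self, settings):
        pop = sample_unit_population(1000, 42.4, 23.0, 18.0, 8.0, 0.05, seed=1)
        with pytest.raises(InfeasibleVentilationError):
            simulate_rm(pop, settings, noise_sd_frac=0.0, seed=1)

    def test_fully_recruited_binary_lung_cannot_cycle(self):
        """With every TOP below baseline PEEP nothing can close, so a pure
        all-or-none lung cannot release the tidal volume."""
        pop = sample_unit_population(20_000, 3.0, 0.5, -2.0, 0.5, 0.05, seed=1)
        with pytest.raises(InfeasibleVentilationError):
            simulate_rm(pop, default_settings(), noise_sd_frac=0.0, seed=1)

    def test_fully_recruited_lung_has_no_recruitable_volume_above_peep(self):
        """Quasi-statically, a population with all TOP < 5 cmH2O is fully
        open at every level of the schedule: zero recruitment per step."""
        pop = sample_unit_population(20_000, 3.0, 0.5, -2.0, 0.5, 0.05, seed=1)
        frac = quasi_static_inflation(pop, np.array([5.0, 10.0, 15.0, 20.0]))
        assert np.allclose(frac, 1.0)
        assert np.allclose(np.diff(frac), 0.0)

    def test_empty_schedule_rejected(self):
        with pytest.raises(ParameterError):
            VentilatorSettings(weight_kg=24.0, peep_schedule=())

    def test_csv_round_trip(self, tmp_path, binary_record_clean):
        from pulmorecruit import WaveformRecord

        path = tmp_path / "wf.csv"
        binary_record_clean.to_csv(path)
        back = WaveformRecord.from_csv(path)
        assert np.allclose(back.paw, binary_record_clean.paw)
        assert np.allclose(back.volume, binary_record_clean.volume)
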