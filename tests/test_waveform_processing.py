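"""Breath segmentation, trapped-volume estimation and PV-curve assembly."""

import numpy as np
import pytest

from pulmorecruit import (
    InputError,
    NoBreathsError,
    RecruitmentParams,
    WaveformRecord,
    build_pv_curves,
    estimate_trapped_volume,
    fraction_recruited,
    sample_unit_population,
    segment_breaths,
    select_representative_breath,
    simulate_rm,
    transition_window,
)
from pulmorecruit.scenarios import default_settings
from pulmorecruit.waveform_processing import Breath, curves_to_frame


class TestSegmentBreaths:
    def test_counts_all_simulated_breaths(self, healthy_record_noisy, settings):
        breaths = segment_breaths(healthy_record_noisy)
        expected = len(settings.peep_schedule) * settings.breaths_per_level
        assert len(breaths) == expected

    def test_zero_flow_raises(self):
        n = 100
        rec = WaveformRecord(
            time=np.arange(n) / 50.0, paw=np.full(n, 5.0),
            flow=np.zeros(n), volume=np.zeros(n), peep=np.full(n, 5.0),
        )
        with pytest.raises(NoBreathsError):
            segment_breaths(rec)

    def test_inspired_volume_matches_delivered_tidal_volume(
        self, binary_record_clean, settings
    ):
        breaths = segment_breaths(binary_record_clean)
        vt = settings.tidal_volume
        # skip the very first breath whose onset interval is clipped
        for b in breaths[1:]:
            assert b.inspired_volume == pytest.approx(vt, rel=0.01)

    def test_breaths_are_labelled_with_their_peep(self, binary_record_clean, settings):
        breaths = segment_breaths(binary_record_clean)
        labels = [b.peep_level for b in breaths]
        per_level = settings.breaths_per_level
        for i, level in enumerate(settings.peep_schedule):
            assert labels[i * per_level:(i + 1) * per_level] == [level] * per_level


class TestRepresentativeBreath:
    def test_mean_of_identical_breaths_equals_either(self, triangle_record):
        breaths = segment_breaths(triangle_record)
        assert len(breaths) == 2
        rep = select_representative_breath(breaths, triangle_record)
        b = breaths[-1]
        s, e = b.insp_start, b.insp_end
        grid = np.linspace(s, e, rep.paw_insp.size)
        expected = np.interp(grid, np.arange(s, e + 1), triangle_record.paw[s:e + 1])
        assert np.allclose(rep.paw_insp, expected, atol=1e-9)

    def test_steady_state_representative_matches_final_breath(
        self, binary_record_clean
    ):
        breaths = [b for b in segment_breaths(binary_record_clean)
                   if b.peep_level == 10.0]
        rep = select_representative_breath(breaths, binary_record_clean)
        assert rep.inspired_volume == pytest.approx(
            breaths[-1].inspired_volume, rel=0.005
        )

    def test_single_breath_returned_with_warning(self, triangle_record):
        breaths = segment_breaths(triangle_record)[:1]
        with pytest.warns(UserWarning):
            rep = select_representative_breath(breaths, triangle_record)
        assert rep.single_breath

    def test_missing_level_raises(self, triangle_record):
        breaths = segment_breaths(triangle_record)
        from pulmorecruit import MissingLevelError

        with pytest.raises(MissingLevelError):
            select_representative_breath(breaths, triangle_record, peep_level=99.0)


class TestTrappedVolume:
    def test_noise_free_estimate_matches_simulator_truth(self, healthy_record_clean):
        rec = healthy_record_clean
        breaths = segment_breaths(rec)
        for (lo, hi), truth in rec.truth.trapped_ml.items():
            window = transition_window([b for b in breaths if b.peep_level == hi])
            est = estimate_trapped_volume(rec, window)
            assert est == pytest.approx(truth, rel=0.05)

    def test_complete_expiration_traps_nothing(self, triangle_record):
        breaths = segment_breaths(triangle_record)
        assert estimate_trapped_volume(triangle_record, breaths) == pytest.approx(
            0.0, abs=1.0
        )

    def test_nothing_stays_open_traps_nothing(self):
        """All TCP above the top PEEP: full derecruitment at every level."""
        pop = sample_unit_population(
            12_000, 50.0, 10.0, 30.0, 3.0, 0.05, seed=9
        )
        rec = simulate_rm(pop, default_settings(), noise_sd_frac=0.0, seed=10)
        breaths = segment_breaths(rec)
        for hi in (10.0, 15.0, 20.0):
            window = transition_window([b for b in breaths if b.peep_level == hi])
            assert estimate_trapped_volume(rec, window) == pytest.approx(0.0, abs=3.0)

    def test_negative_estimate_clamped_with_warning(self, triangle_record):
        b = segment_breaths(triangle_record)[0]
        shrunk = Breath(
            insp_start=b.insp_start, insp_end=b.insp_end, exp_end=b.exp_end,
            peep_level=b.peep_level, inspired_volume=b.inspired_volume,
            expired_volume=b.inspired_volume + 10.0,
        )
        with pytest.warns(UserWarning):
            assert estimate_trapped_volume(triangle_record, [shrunk]) == 0.0

    def test_empty_window_raises(self, triangle_record):
        with pytest.raises(InputError):
            estimate_trapped_volume(triangle_record, [])


class TestBuildPVCurves:
    def test_two_curves_per_level_ordered(self, healthy_record_noisy, settings):
        curves = build_pv_curves(
            healthy_record_noisy, segment_breaths(healthy_record_noisy)
        )
        assert len(curves) == 2 * len(settings.peep_schedule)
        limbs = {(c.peep, c.limb) for c in curves}
        for level in settings.peep_schedule:
            assert (level, "inflation") in limbs and (level, "deflation") in limbs

    def test_baseline_curve_has_zero_offset(self, healthy_record_noisy):
        curves = build_pv_curves(
            healthy_record_noisy, segment_breaths(healthy_record_noisy)
        )
        assert min(c.offset for c in curves if c.peep == 5.0) == 0.0

    def test_offsets_are_running_sums_of_trapped_volumes(self, healthy_record_clean):
        rec = healthy_record_clean
        breaths = segment_breaths(rec)
        curves = build_pv_curves(rec, breaths)
        levels = sorted({b.peep_level for b in breaths})
        running = 0.0
        for lo, hi in zip(levels, levels[1:]):
            window = transition_window([b for b in breaths if b.peep_level == hi])
            running += estimate_trapped_volume(rec, window)
            offset = {c.peep: c.offset for c in curves}[hi]
            assert offset == pytest.approx(running, abs=1e-9)

    def test_inflation_curves_monotone(self, healthy_record_clean):
        for c in build_pv_curves(
            healthy_record_clean, segment_breaths(healthy_record_clean)
        ):
            if c.limb == "inflation":
                assert np.all(np.diff(c.pressure) > 0)
                assert np.all(np.diff(c.volume) >= -1e-9)
            else:
                assert np.all(np.diff(c.pressure) < 0)

    def test_round_trip_onto_static_curve(self):
        """With full derecruitment and no elasticity, every inflation curve
        lies on the generating error-function curve."""
        settings = default_settings()
        pop = sample_unit_population(100_000, 50.0, 10.0, 30.0, 3.0, 0.01, seed=3)
        rec = simulate_rm(pop, settings, noise_sd_frac=0.0, seed=4)
        curves = build_pv_curves(
            rec, segment_breaths(rec), resistance=settings.resistance
        )
        params = RecruitmentParams(50.0, 10.0, pop.capacity)
        for c in curves:
            if c.limb != "inflation":
                continue
            static = pop.capacity * fraction_recruited(c.pressure, params)
            dev = np.max(np.abs(c.volume - static)) / pop.capacity
            assert dev < 0.01

    def test_curves_frame_layout(self, healthy_record_noisy):
        curves = build_pv_curves(
            healthy_record_noisy, segment_breaths(healthy_record_noisy)
        )
        frame = curves_to_frame(curves)
        assert list(frame.columns) == [
            "limb", "peep_cmH2O", "pressure_cmH2O", "volume_ml"
        ]
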