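"""Streaming decision loop, setpoint mapping and the simulated plant."""

import numpy as np
import pytest

import myowrist as mw
from myowrist.synthetic_data import DEFAULT_MVC_NM, ProtocolSpec


@pytest.fixture(scope="module")
def steady_excerpt(tiny_study):
    """A mid-level flexion excerpt with a known class id."""
    for ex in tiny_study:
        if ex.direction is mw.Direction.FLEXION and ex.level == pytest.approx(0.3):
            return ex
    raise AssertionError("fixture study lacks a 30 % flexion excerpt")


class TestStreamClassify:
    def test_decision_count_matches_window_count(self, tiny_model, steady_excerpt):
        rec = steady_excerpt.recording  # 3072 samples
        ds = mw.stream_classify(rec, tiny_model)
        assert len(ds) == len(mw.segment_starts(rec.n_samples))

    def test_single_window_single_decision(self, tiny_model, steady_excerpt):
        rec = steady_excerpt.recording.slice(0, 256)
        ds = mw.stream_classify(rec, tiny_model)
        assert len(ds) == 1
        assert ds.times_s[0] == pytest.approx(0.25)

    def test_too_short_recording_rejected(self, tiny_model, steady_excerpt):
        with pytest.raises(ValueError, match="shorter"):
            mw.stream_classify(steady_excerpt.recording.slice(0, 255), tiny_model)

    def test_cadence_is_exact(self, tiny_model, steady_excerpt):
        ds = mw.stream_classify(steady_excerpt.recording, tiny_model)
        np.testing.assert_allclose(np.diff(ds.times_s), 128 / 1024.0)

    def test_modal_decision_matches_excerpt_class(self, tiny_model, steady_excerpt):
        ds = mw.stream_classify(steady_excerpt.recording, tiny_model)
        ids, counts = np.unique(ds.class_ids, return_counts=True)
        assert ids[np.argmax(counts)] == steady_excerpt.class_id

    def test_causality(self, tiny_model, steady_excerpt):
        """Corrupting the second half must not change first-half decisions."""
        rec = steady_excerpt.recording
        ds_clean = mw.stream_classify(rec, tiny_model)
        corrupted = rec.slice(0, rec.n_samples)
        half = rec.n_samples // 2
        corrupted.emg[half:] = np.random.default_rng(0).normal(0, 5.0,
                                                               (rec.n_samples - half, 4))
        ds_corr = mw.stream_classify(corrupted, tiny_model)
        unaffected = ds_clean.times_s * rec.sample_rate <= half
        np.testing.assert_array_equal(ds_clean.class_ids[unaffected],
                                      ds_corr.class_ids[unaffected])


class TestClassToSetpoint:
    def test_rest_maps_to_zero(self, config19):
        cfg = config19.with_mvc(DEFAULT_MVC_NM)
        assert mw.class_to_setpoint(1, cfg, assist_gain=0.7) == 0.0

    def test_flexion_positive(self, config19):
        cfg = config19.with_mvc({**DEFAULT_MVC_NM, mw.Direction.FLEXION: 10.0})
        assert mw.class_to_setpoint(2, cfg, assist_gain=1.0) == pytest.approx(+1.0)

    def test_extension_negative_scaled(self, config19):
        cfg = config19.with_mvc({**DEFAULT_MVC_NM, mw.Direction.EXTENSION: 8.0})
        assert mw.class_to_setpoint(11, cfg, assist_gain=0.5) == pytest.approx(-2.0)

    def test_monotone_in_level_within_direction(self, config19):
        cfg = config19.with_mvc(DEFAULT_MVC_NM)
        for d in (mw.Direction.FLEXION, mw.Direction.EXTENSION,
                  mw.Direction.ULNAR, mw.Direction.RADIAL):
            mags = [abs(mw.class_to_setpoint(c.class_id, cfg))
                    for c in cfg.classes_for(d)]
            assert np.all(np.diff(mags) > 0)

    def test_unknown_class_rejected(self, config19):
        with pytest.raises(KeyError):
            mw.class_to_setpoint(99, config19.with_mvc(DEFAULT_MVC_NM))

    def test_missing_mvc_rejected(self, config19):
        with pytest.raises(ValueError, match="MVC"):
            mw.class_to_setpoint(2, config19)


class TestControlStep:
    def test_zero_setpoint_stays_at_rest(self):
        state = mw.PlantState()
        for _ in range(20):
            state = mw.control_step(state, 0.0, 0.125)
        assert state.output_nm == 0.0

    def test_step_response_settles(self):
        state = mw.PlantState()
        for _ in range(40):  # 5 s at 125 ms
            state = mw.control_step(state, 1.0, 0.125)
        assert state.output_nm == pytest.approx(1.0, rel=0.02)

    def test_saturation_at_actuator_limit(self):
        state = mw.PlantState(limit_nm=2.0)
        for _ in range(200):
            state = mw.control_step(state, 50.0, 0.125)
        assert state.output_nm == pytest.approx(2.0)

    def test_bad_dt_rejected(self):
        with pytest.raises(ValueError):
            mw.control_step(mw.PlantState(), 1.0, 0.0)


@pytest.fixture(scope="module")
def staircase(amap):
    """Clean flexion staircase (no tracking drift) with 6 s holds."""
    spec = ProtocolSpec(direction=mw.Direction.FLEXION, hold_seconds=6.0)
    return mw.synth_protocol_run(spec, amap, DEFAULT_MVC_NM[mw.Direction.FLEXION],
                                 seed=13, tracking_drift_std=0.0)


class TestClosedLoop:
    def test_plant_tracks_staircase(self, staircase, tiny_model19, config19):
        cfg = config19.with_mvc(DEFAULT_MVC_NM)
        ds, trace = mw.run_closed_loop(staircase, tiny_model19, cfg)
        assert len(trace) == len(ds)
        fs = staircase.sample_rate
        for start, stop, level in staircase.metadata["plateaus"]:
            # decisions whose window lies fully in the last second of the hold
            sel = (ds.times_s * fs >= stop - fs) & (ds.times_s * fs <= stop)
            terminal_out = trace[sel]
            assert len(terminal_out) > 0
            sp = mw.class_to_setpoint(cfg.lookup(mw.Direction.FLEXION, level).class_id, cfg)
            # median over the final second: robust to isolated decision flips
            tol = max(0.05 * abs(sp), 0.05)
            assert abs(np.median(terminal_out) - sp) <= tol

    def test_all_rest_recording_stays_near_zero(self, amap, tiny_model, config13):
        emg = mw.synth_emg_block([0, 0, 0, 0], duration_s=4.0, seed=8,
                                 baseline_noise_mv=amap.baseline_noise_mv,
                                 gain_mv=amap.gain_mv)
        rec = mw.Recording(1024.0, amap.channels, emg, np.zeros(len(emg)))
        cfg = config13.with_mvc(DEFAULT_MVC_NM)
        ds, trace = mw.run_closed_loop(rec, tiny_model, cfg)
        assert np.all(np.abs(trace) < 0.15)

    def test_transients_confined_to_ramps(self, staircase, tiny_model19, config19):
        cfg = config19.with_mvc(DEFAULT_MVC_NM)
        ds, _ = mw.run_closed_loop(staircase, tiny_model19, cfg)
        fs = staircase.sample_rate
        ladder = [cfg.rest_class().class_id] + \
            [c.class_id for c in cfg.classes_for(mw.Direction.FLEXION)]
        for start, stop, level in staircase.metadata["plateaus"]:
            sel = (ds.times_s * fs >= start + 256) & (ds.times_s * fs <= stop)
            expected = cfg.lookup(mw.Direction.FLEXION, level).class_id
            decisions = ds.class_ids[sel]
            # the plateau is identified: most windows agree exactly, nearly
            # all stay within one torque level of the truth
            assert np.mean(decisions == expected) > 0.8
            ids, counts = np.unique(decisions, return_counts=True)
            assert ids[np.argmax(counts)] == expected
            pos = ladder.index(expected)
            allowed = set(ladder[max(0, pos - 1) : pos + 2])
            assert np.mean([d in allowed for d in decisions]) >= 0.95


class TestAssistRmsComparison:
    def test_unity_scale_gives_unity_ratios(self):
        ratios = mw.assist_rms_comparison(1.0, seed=3)
        for v in ratios.values():
            assert v == pytest.approx(1.0)

    def test_half_scale_halves_dominant_muscle(self):
        ratios = mw.assist_rms_comparison(0.5, activation=(0.2, 1.0, 0.1, 0.1), seed=3)
        # ED fully active: ratio ~ (baseline + 0.5) / (baseline + 1)
        assert ratios["ED"] == pytest.approx(0.505, abs=0.03)
        assert ratios["ED"] < ratios["PL"]  # weakly active muscles change less

    def test_zero_scale_rejected(self):
        with pytest.raises(ValueError):
            mw.assist_rms_comparison(0.0)


class TestMajorityFilter:
    def test_isolated_flip_removed(self):
        out = mw.majority_filter([4, 4, 2, 4, 4], width=3)
        assert out.tolist() == [4, 4, 4, 4, 4][:len(out)]
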