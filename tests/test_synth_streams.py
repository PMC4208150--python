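"""Scripts, the signal model and stream synthesis."""

import io

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from promptlab import synth_streams as ss
from promptlab.labels import ACTIVITIES, BUS, JOGGING, STANDING, WALKING


class TestScripts:
    def test_task1_is_nine_alternating_30s_bouts(self, task1_script):
        assert len(task1_script.bouts) == 9
        assert task1_script.total_duration == 270.0
        assert all(b.duration == 30.0 for b in task1_script.bouts)
        # odd positions (1-based) are standing still
        for i in (0, 2, 4, 6, 8):
            assert task1_script.bouts[i].label == STANDING
        assert [task1_script.bouts[i].label for i in (1, 3, 5, 7)] == \
            [WALKING, JOGGING, WALKING, JOGGING]

    def test_task1_has_four_moving_episodes_each_followed_by_standing(self, task1_script):
        labels = [b.label for b in task1_script.bouts]
        episodes = [(a, b) for a, b in zip(labels, labels[1:])
                    if a != STANDING and b == STANDING]
        assert len(episodes) == 4

    def test_task2_fixed_order_with_caller_durations(self):
        script = ss.make_task2_script(range(1, 11))
        assert [b.label for b in script.bouts] == list(ss.TASK2_ORDER)
        assert script.total_duration == 55.0

    def test_task2_has_five_transitions_into_standing(self, task2_script):
        labels = [b.label for b in task2_script.bouts]
        n = sum(a != STANDING and b == STANDING for a, b in zip(labels, labels[1:]))
        assert n == 5

    def test_task2_rejects_wrong_duration_count(self):
        with pytest.raises(ValueError, match="10 durations"):
            ss.make_task2_script([30.0] * 9)

    def test_bout_validation(self):
        with pytest.raises(ValueError):
            ss.ActivityBout(WALKING, 0.0)
        with pytest.raises(ValueError):
            ss.ActivityBout("swimming", 10.0)

    def test_label_at_covers_bouts_end_exclusive(self, task1_script):
        assert task1_script.label_at(0.0) == STANDING
        assert task1_script.label_at(45.0) == WALKING
        assert task1_script.label_at(30.0) == WALKING
        with pytest.raises(ValueError):
            task1_script.label_at(270.0)

    def test_yaml_round_trip(self, tmp_path, task2_script):
        path = tmp_path / "script.yaml"
        task2_script.to_yaml(path)
        back = ss.ActivityScript.from_yaml(path)
        assert back == task2_script

    def test_free_living_script_alternates_and_bounds_durations(self):
        script = ss.make_free_living_script(seed=3)
        assert all(10.0 <= b.duration <= 300.0 for b in script.bouts)
        assert all(a.label != b.label for a, b in zip(script.bouts, script.bouts[1:]))


class TestSignalModel:
    def test_default_amplitude_ordering(self, default_model):
        p = default_model.params
        assert p[STANDING].amplitude < p[WALKING].amplitude < p[JOGGING].amplitude

    def test_rejects_inverted_amplitudes(self, default_model):
        from dataclasses import replace
        bad = dict(default_model.params)
        bad[WALKING] = replace(bad[WALKING], amplitude=2.0)
        with pytest.raises(ValueError, match="amplitudes"):
            ss.SignalModel(params=bad)

    def test_noiseless_removes_all_stochastic_terms(self, default_model):
        quiet = default_model.noiseless()
        assert all(p.noise_sd == 0 for p in quiet.params.values())
        assert quiet.jitter_sd == 0 and quiet.speed_noise_sd == 0


class TestSynthesizeStream:
    def test_task1_sample_count_and_uniform_time(self, task1_stream):
        assert task1_stream.n_samples == 13_500
        dt = np.diff(task1_stream.t)
        assert np.allclose(dt, 0.02) and np.all(dt > 0)

    def test_seed_determinism(self, task1_script, default_model):
        a = ss.synthesize_stream(task1_script, default_model, seed=7)
        b = ss.synthesize_stream(task1_script, default_model, seed=7)
        for f in ("t", "x", "y", "z", "speed", "lat", "lon"):
            assert np.array_equal(getattr(a, f), getattr(b, f))
        c = ss.synthesize_stream(task1_script, default_model, seed=8)
        assert not np.array_equal(a.z, c.z)

    def test_standing_windows_quieter_than_jogging_all_windows(self, task1_stream,
                                                               task1_script):
        mag = task1_stream.magnitude()
        win_sd = mag.reshape(-1, 150).std(axis=1)
        truth = ss.window_truth_labels(task1_script, len(win_sd))
        stand = win_sd[[t == STANDING for t in truth]]
        jog = win_sd[[t == JOGGING for t in truth]]
        assert stand.max() < jog.min()

    def test_speed_trace_matches_bout_speeds(self, task1_stream, task1_script):
        assert len(task1_stream.speed) == 270
        truth = [task1_script.label_at(s + 0.5) for s in range(270)]
        expected = {STANDING: 0.0, WALKING: 1.4, JOGGING: 2.8, BUS: 8.0}
        for v, lbl in zip(task1_stream.speed, truth):
            assert abs(v - expected[lbl]) < 0.3

    def test_variance_oracle_recovers_stand_vs_move(self, task1_stream, task1_script):
        moving = ss.stand_vs_move_oracle(task1_stream)
        truth = ss.window_truth_labels(task1_script, len(moving))
        bnd = ss.boundary_windows(task1_script, len(moving))
        hits = [m == (t != STANDING) for i, (m, t) in enumerate(zip(moving, truth))
                if i not in bnd]
        assert np.mean(hits) >= 0.99

    @given(st.lists(st.tuples(st.sampled_from(ACTIVITIES),
                              st.floats(0.5, 90.0)), min_size=1, max_size=8),
           st.integers(0, 2 ** 31 - 1))
    def test_length_conservation_any_script(self, bouts, seed):
        script = ss.ActivityScript("h", tuple(ss.ActivityBout(l, d) for l, d in bouts))
        stream = ss.synthesize_stream(script, seed=seed)
        assert stream.n_samples == sum(int(round(d * 50)) for _, d in bouts)


class TestVibrationInjection:
    def test_zero_amplitude_leaves_stream_unchanged(self, task1_stream):
        out = ss.inject_prompt_vibration(task1_stream, at=10.0, duration=1.0,
                                         amplitude=0.0)
        assert np.array_equal(out.z, task1_stream.z)

    def test_untouched_samples_bit_identical_and_burst_raises_variance(self, task1_stream):
        out = ss.inject_prompt_vibration(task1_stream, at=6.0, duration=1.0,
                                         amplitude=0.5, freq_hz=20.0)
        burst = slice(300, 350)
        assert np.array_equal(out.z[:300], task1_stream.z[:300])
        assert np.array_equal(out.z[350:], task1_stream.z[350:])
        pre_var = task1_stream.z[250:300].var()
        assert out.z[burst].var() > 10 * max(pre_var, 1e-12)

    def test_two_injections_give_two_disjoint_bursts(self, task1_stream):
        # 20 Hz: high-frequency but below Nyquist (25 Hz aliases to zero)
        out = ss.inject_prompt_vibration(task1_stream, 3.0, 1.0, 0.8, 20.0)
        out = ss.inject_prompt_vibration(out, 12.0, 1.0, 0.8, 20.0)
        sd = np.abs(out.z - task1_stream.z).reshape(-1, 50).max(axis=1)
        hot = np.nonzero(sd > 0.1)[0]
        # two separated runs of elevated deviation
        gaps = np.nonzero(np.diff(hot) > 1)[0]
        assert len(hot) > 0 and len(gaps) == 1

    def test_out_of_range_burst_rejected(self, task1_stream):
        with pytest.raises(ValueError, match="outside stream span"):
            ss.inject_prompt_vibration(task1_stream, 269.5, 1.0)


class TestCsvRoundTrip:
    def test_values_survive_at_six_decimals_and_idempotent_bytes(self, task1_stream):
        buf = io.StringIO()
        task1_stream.to_csv(buf)
        buf.seek(0)
        back = ss.SensorStream.from_csv(buf)
        for f in ("t", "x", "y", "z", "lat", "lon"):
            assert np.abs(getattr(back, f) - getattr(task1_stream, f)).max() < 1e-6
        assert back.speed.shape == task1_stream.speed.shape
        buf2 = io.StringIO()
        back.to_csv(buf2)
        assert buf.getvalue() == buf2.getvalue()

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing column"):
            ss.SensorStream.from_csv(io.StringIO("t,x,y\n0,0,0\n"))
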