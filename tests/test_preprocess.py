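"""Beat detection, detrending, quality rules and window construction."""

import numpy as np
import pandas as pd
import pytest

from ppgchaos.preprocess import (
    InclusionError,
    NoBeatsError,
    VitalRecord,
    beat_features,
    detect_feet,
    detrend_ppg,
    filter_subject,
    flag_outlier_beats,
    make_windows,
)


def pulse_train(n_pulses=30, fs=50, period=1.0, width=0.3):
    t = np.arange(int(n_pulses * period * fs)) / fs
    x = np.zeros_like(t)
    for k in range(n_pulses):
        m = (t >= k * period) & (t < k * period + width)
        x[m] = np.sin(np.pi * (t[m] - k * period) / width)
    return x


class TestDetectFeet:
    def test_simulated_feet_near_true_onsets(self, sim_noiseless):
        feet = detect_feet(sim_noiseless.ppg, 50)
        onsets = sim_noiseless.truth.onset_idx.to_numpy()
        assert len(feet) == pytest.approx(70, abs=1)
        err_s = np.array([np.abs(onsets - f).min() for f in feet]) / 50.0
        assert err_s.max() <= 0.040 + 1e-9

    def test_pulse_train_feet_at_onsets(self):
        x = pulse_train()
        feet = detect_feet(x, 50)
        assert len(feet) == 30
        assert all(min(abs(f - 50 * k) for k in range(30)) <= 1 for f in feet)

    def test_constant_signal_raises(self):
        with pytest.raises(NoBeatsError):
            detect_feet(np.full(500, 3.7), 50)

    def test_feet_strictly_increasing(self, sim_noiseless):
        feet = detect_feet(sim_noiseless.ppg, 50)
        assert np.all(np.diff(feet) > 0)


class TestDetrend:
    def test_pulsatile_zero_at_feet(self, sim_noiseless):
        feet = detect_feet(sim_noiseless.ppg, 50)
        pulsatile, baseline = detrend_ppg(sim_noiseless.ppg, feet)
        assert np.abs(pulsatile[feet]).max() == 0.0
        assert np.allclose(pulsatile + baseline, sim_noiseless.ppg)

    def test_straight_line_between_feet_gives_zero(self):
        x = np.linspace(0.0, 10.0, 200)
        feet = np.array([0, 50, 100, 199])
        pulsatile, _ = detrend_ppg(x, feet)
        assert np.abs(pulsatile).max() < 1e-12

    def test_sawtooth_ac_equals_amplitude(self):
        # sawtooth with feet at troughs, amplitude A
        A = 2.5
        one = np.concatenate([np.linspace(0, A, 10), np.linspace(A, 0, 41)[1:]])
        x = np.tile(one, 6)
        feet = np.arange(0, len(x), 50)
        pulsatile, baseline = detrend_ppg(x, feet)
        for a, b in zip(feet[:-1], feet[1:]):
            ac = pulsatile[a:b].max() - pulsatile[a:b].min()
            assert ac == pytest.approx(A, abs=A / 10)

    def test_idempotent_on_pulsatile(self, sim_noiseless):
        feet = detect_feet(sim_noiseless.ppg, 50)
        pulsatile, _ = detrend_ppg(sim_noiseless.ppg, feet)
        feet2 = detect_feet(pulsatile + 1.0, 50)
        # rerunning on the detrended signal finds the same feet (+/- 1 sample)
        common = [f2 for f2 in feet2 if np.abs(feet - f2).min() <= 1]
        assert len(common) >= 0.95 * len(feet2)


class TestBeatFeatures:
    def test_map_matches_time_average(self, vital_noiseless, prep_noiseless):
        beats = prep_noiseless["beats"]
        abp = vital_noiseless.abp
        for _, b in beats.iloc[15:20].iterrows():
            span = abp[int(b.foot_idx):int(b.next_foot_idx)]
            assert b.MAP == pytest.approx(span.mean(), abs=1.0)

    def test_affine_bp_gives_unit_correlation(self):
        x = pulse_train()
        rec = VitalRecord("s", 50, ppg=x, abp=3.0 * x + 7.0)
        feet = detect_feet(x, 50)
        pulsatile, baseline = detrend_ppg(x, feet)
        beats = beat_features(rec, feet, pulsatile, baseline)
        assert np.allclose(beats.ppg_bp_corr, 1.0, atol=1e-6)

    def test_sbp_dbp_pp_from_fixture(self):
        x = pulse_train(n_pulses=5)
        abp = 80.0 + 40.0 * pulse_train(n_pulses=5)
        rec = VitalRecord("s", 50, ppg=x, abp=abp)
        feet = detect_feet(x, 50)
        pulsatile, baseline = detrend_ppg(x, feet)
        beats = beat_features(rec, feet, pulsatile, baseline)
        row = beats.iloc[1]
        assert row.SBP == pytest.approx(120.0, abs=0.5)
        assert row.DBP == pytest.approx(80.0, abs=0.5)
        assert row.PP == pytest.approx(40.0, abs=0.5)


def ten_beat_table():
    rows = []
    for i in range(10):
        rows.append({
            "foot_idx": i * 50, "next_foot_idx": (i + 1) * 50,
            "interval_s": 1.0, "AC": 2.0, "DC": 5.0,
            "SBP": 120.0, "DBP": 80.0, "MAP": 93.0, "PP": 40.0,
            "ppg_bp_corr": 0.95, "co_mean": 5.0,
        })
    return pd.DataFrame(rows)


class TestOutlierRules:
    def test_planted_violations_and_reasons(self):
        beats = ten_beat_table()
        beats.loc[3, "PP"] = 10.0
        beats.loc[6, "interval_s"] = 1.8
        beats.loc[8, "ppg_bp_corr"] = 0.5
        out = flag_outlier_beats(beats)
        assert out.valid.sum() == 7
        assert out.loc[3, "reject_reason"] == "PP_LOW"
        assert out.loc[6, "reject_reason"] == "INTERVAL"
        assert out.loc[8, "reject_reason"] == "CORR_LOW"

    def test_all_clean(self):
        out = flag_outlier_beats(ten_beat_table())
        assert out.valid.all()
        assert (out.reject_reason == "NONE").all()

    def test_negative_skew_window_flags_all_beats(self):
        beats = ten_beat_table()
        out = flag_outlier_beats(
            beats, fs=50, window_skew=[(0.0, 10.0, -0.2)]
        )
        assert (~out.valid).all()
        assert (out.reject_reason == "SKEW").all()

    def test_negative_skew_signal_detected(self):
        # symmetric sine plus a rare deep negative spike -> negative skewness
        fs, dur = 50, 100
        t = np.arange(dur * fs) / fs
        x = np.sin(2 * np.pi * 1.0 * t)
        x[::500] -= 5.0
        beats = ten_beat_table()
        out = flag_outlier_beats(beats, ppg=x, fs=fs)
        assert (out.reject_reason == "SKEW").all()

    def test_rule_priority_order(self):
        beats = ten_beat_table()
        beats.loc[2, "PP"] = 5.0
        beats.loc[2, "ppg_bp_corr"] = 0.1
        beats.loc[2, "interval_s"] = 2.0
        out = flag_outlier_beats(beats)
        assert out.loc[2, "reject_reason"] == "PP_LOW"

    def test_each_reject_has_exactly_one_reason(self):
        beats = ten_beat_table()
        beats.loc[[1, 4], "PP"] = 3.0
        beats.loc[5, "interval_s"] = 0.2
        out = flag_outlier_beats(beats)
        rejected = out[~out.valid]
        assert (rejected.reject_reason != "NONE").all()
        assert len(rejected) == rejected.reject_reason.notna().sum() == 3
        assert out[out.valid].reject_reason.eq("NONE").all()


def synthetic_record(duration_s=600.0, fs=50.0):
    n_beats = int(duration_s)
    rows = []
    for i in range(n_beats):
        rows.append({
            "foot_idx": int(i * fs), "next_foot_idx": int((i + 1) * fs),
            "interval_s": 1.0, "AC": 2.0, "DC": 5.0, "valid": True,
            "reject_reason": "NONE",
        })
    beats = pd.DataFrame(rows)
    rec = VitalRecord("s", fs, ppg=np.zeros(int(duration_s * fs)) + np.tile(
        np.sin(np.linspace(0, 2 * np.pi, int(fs))), n_beats))
    return rec, beats


class TestWindows:
    def test_time_window_count(self):
        rec, beats = synthetic_record(600.0)
        ws = make_windows(rec, beats, "TIME_100S")
        assert len(ws) == 101  # floor((600-100)/5)+1
        assert ws.frame.usable.all()

    def test_corrupt_window_unusable(self):
        rec, beats = synthetic_record(600.0)
        beats.loc[20:31, "valid"] = False  # 12 s of invalid beats
        ws = make_windows(rec, beats, "TIME_100S")
        w0 = ws.frame.iloc[0]  # [0, 100) contains all 12 bad seconds
        assert w0.corrupt_s >= 12.0
        assert not w0.usable

    def test_beats_scheme_chunks_of_100(self):
        rec, beats = synthetic_record(600.0)
        beats.loc[250:, "valid"] = False  # 250 valid beats
        ws = make_windows(rec, beats, "BEATS_100")
        assert len(ws) == 2
        spans = ws.frame[["beat_start", "beat_stop"]].to_numpy()
        assert (spans[:, 1] - spans[:, 0] == 100).all()

    def test_short_record_warns_empty(self):
        rec, beats = synthetic_record(50.0)
        with pytest.warns(UserWarning):
            ws = make_windows(rec, beats, "TIME_100S")
        assert len(ws) == 0

    def test_usability_monotone_under_corruption(self):
        rec, beats = synthetic_record(300.0)
        ws1 = make_windows(rec, beats, "TIME_100S")
        beats2 = beats.copy()
        beats2.loc[10:25, "valid"] = False
        ws2 = make_windows(rec, beats2, "TIME_100S")
        # corrupting beats never turns an unusable window usable
        assert not np.any(~ws1.frame.usable & ws2.frame.usable)


class TestFilterSubject:
    def test_cohort_typical_included(self):
        assert filter_subject({"age": 55, "weight": 62, "height": 164})

    @pytest.mark.parametrize("meta", [
        {"age": 17, "weight": 62, "height": 164},
        {"age": 55, "weight": 150, "height": 160},  # BMI 58.6
        {"age": 55, "weight": 35, "height": 164},
        {"age": 55, "weight": 62, "height": 140},
    ])
    def test_out_of_bounds_excluded(self, meta):
        assert not filter_subject(meta)

    def test_low_sbp_excluded(self):
        meta = {"age": 55, "weight": 62, "height": 164}
        assert not filter_subject(meta, window_sbp_medians=[110.0, 75.0])

    def test_missing_field_raises(self):
        with pytest.raises(InclusionError, match="weight"):
            filter_subject({"age": 55, "height": 164})
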