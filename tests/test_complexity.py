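"""Complexity measures: brute-force oracle equality, known limits, and the
per-window driver."""

import numpy as np
import pytest

from ppgchaos.complexity import (
    ComplexityConfig,
    apen,
    complexity_over_windows,
    fnn_dimension,
    fnn_fractions,
    fuzzen,
    hfd,
    hfd_fit,
    kfd,
    lf_hf,
    rqa_entr,
    sampen,
)
from ppgchaos.signals import fbm, powerlaw_noise, roessler

from oracles import ar1_fixture, naive_apen, naive_fuzzen, naive_rqa_entr, naive_sampen

class TestEntropyOracles:
    @pytest.fixture(scope="class")
    def series(self):
        # smooth AR(1) fixture so length-5 template matches exist at m=4
        return ar1_fixture()

    def test_sampen_matches_bruteforce(self, series):
        r = 0.2 * series.std()
        assert sampen(series, 4, r) == pytest.approx(
            naive_sampen(series, 4, r), abs=1e-12)

    def test_apen_matches_bruteforce(self, series):
        r = 0.2 * series.std()
        assert apen(series, 4, r) == pytest.approx(
            naive_apen(series, 4, r), abs=1e-12)

    def test_fuzzen_matches_bruteforce(self, series):
        r = 0.2 * series.std()
        assert fuzzen(series, 4, r, 2) == pytest.approx(
            naive_fuzzen(series, 4, r, 2), abs=1e-12)

    def test_rqa_matches_bruteforce(self):
        x = np.random.default_rng(7).standard_normal(300)
        assert rqa_entr(x, 4, 1, 0.1, 2) == pytest.approx(
            naive_rqa_entr(x, 4, 1, 0.1, 2), abs=1e-12)

    def test_constant_series(self):
        c = np.full(100, 3.0)
        assert sampen(c, 4, 0.1) == pytest.approx(0.0)
        assert apen(c, 4, 0.1) == pytest.approx(0.0, abs=1e-12)
        assert fuzzen(c, 4, 0.1) == pytest.approx(0.0, abs=1e-12)

    def test_periodic_below_shuffled(self):
        # repeating patterns -> lower SampEn than the shuffled same values
        wins = 0
        base = np.tile(np.sin(2 * np.pi * np.arange(20) / 20), 10)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = base + 0.05 * rng.standard_normal(len(base))
            shuffled = rng.permutation(noisy)
            r = 0.2 * noisy.std()
            if sampen(noisy, 2, r) < sampen(shuffled, 2, r):
                wins += 1
        assert wins >= 17

    def test_fuzzen_monotone_in_noise(self):
        wins = 0
        t = np.arange(400)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            clean = np.sin(2 * np.pi * t / 25)
            lo = clean + 0.05 * rng.standard_normal(len(t))
            hi = clean + 0.4 * rng.standard_normal(len(t))
            if fuzzen(lo, 2, 0.2 * lo.std()) < fuzzen(hi, 2, 0.2 * hi.std()):
                wins += 1
        assert wins >= 17

    def test_rqa_sinusoid_low_noise_high(self):
        t = np.arange(300)
        sin_entr = rqa_entr(np.sin(2 * np.pi * t / 25), 4, 1, 0.1, 2)
        assert sin_entr <= 0.5
        wins = 0
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(300)
            if rqa_entr(x, 4, 1, 0.1, 2) > sin_entr:
                wins += 1
        assert wins >= 17


class TestFractalDimensions:
    def test_hfd_line(self):
        assert hfd(2.0 + 0.5 * np.arange(1000)) == pytest.approx(1.0, abs=1e-3)

    def test_hfd_white_noise_limit(self):
        vals = [hfd(np.random.default_rng(s).standard_normal(5000))
                for s in range(50)]
        assert np.median(vals) == pytest.approx(2.0, abs=0.05)

    @pytest.mark.parametrize("hurst", [0.3, 0.5, 0.7])
    def test_hfd_fbm(self, hurst):
        vals = [hfd(fbm(5000, hurst, s)) for s in range(10)]
        assert np.median(vals) == pytest.approx(2.0 - hurst, abs=0.1)

    def test_hfd_constant_degenerate(self):
        assert hfd(np.full(500, 1.0)) == 1.0

    def test_kfd_line_exact(self):
        assert kfd(1.0 + 3.0 * np.arange(100)) == 1.0

    def test_kfd_alternating_matches_hand_formula(self):
        x = np.tile([0.0, 1.0], 50)
        # direct evaluation of the definition on the normalized polyline
        y = x  # already in [0, 1]
        i = np.arange(100.0)
        L = np.hypot(np.diff(i), np.diff(y)).sum()
        d = np.hypot(i, y).max()
        expected = np.log10(99) / (np.log10(99) + np.log10(d / L))
        assert kfd(x) == pytest.approx(expected, abs=1e-12)

    def test_kfd_scale_invariant(self):
        x = np.random.default_rng(3).standard_normal(200)
        assert kfd(5.0 * x) == pytest.approx(kfd(x), abs=1e-12)
        assert kfd(0.01 * x) == pytest.approx(kfd(x), abs=1e-12)

    def test_affine_invariance(self):
        x = np.random.default_rng(9).standard_normal(2000)
        assert hfd(3 * x + 10) == pytest.approx(hfd(x), rel=1e-9)
        assert kfd(3 * x + 10) == pytest.approx(kfd(x), rel=1e-9)
        # entropies with scaled r are likewise scale invariant
        r = 0.2 * x.std()
        assert sampen(3 * x, 3, 3 * r) == pytest.approx(sampen(x, 3, r))


class TestFNN:
    def test_roessler_embedding_dimension_three(self):
        x = roessler(5000, dt=0.12)
        # delay ~ quarter orbital period; Theiler window one delay
        assert fnn_dimension(x, max_m=6, tau=12, theiler=12) == 3

    def test_iid_noise_fraction_stays_high(self):
        x = np.random.default_rng(0).standard_normal(5000)
        fracs = fnn_fractions(x, max_m=8, theiler=10)
        assert np.all(fracs >= 0.05)


class TestLFHF:
    def _beats(self, f_mod, amp=0.05, n=300):
        t = np.cumsum(np.full(n, 1.0))
        if np.isscalar(f_mod):
            f_mod = [f_mod]
        iv = 1.0 + sum(amp * np.sin(2 * np.pi * f * t) for f in f_mod)
        return iv, t

    def test_lf_only_modulation(self):
        assert lf_hf(*self._beats(0.10)) > 5.0

    def test_hf_only_modulation(self):
        assert lf_hf(*self._beats(0.25)) < 0.2

    def test_balanced_modulation(self):
        assert 0.5 <= lf_hf(*self._beats([0.10, 0.25])) <= 2.0

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            lf_hf(np.ones(30), np.arange(30.0))


def _manual_windows(starts, length=100.0):
    import pandas as pd

    from ppgchaos.preprocess import WindowSet

    frame = pd.DataFrame({
        "start_s": starts, "end_s": [s + length for s in starts],
        "beat_start": 0, "beat_stop": 0, "corrupt_s": 0.0, "usable": True,
    })
    return WindowSet(frame, "TIME_100S", length, 5.0)


class TestOverWindows:
    def test_constant_record_degenerate(self):
        wt = _manual_windows([0.0, 5.0, 10.0])
        flat = np.ones(150 * 50)
        out = complexity_over_windows(
            wt, "RAW_50HZ", ComplexityConfig(), raw=flat, fs=50.0,
            measures=("HFD", "KFD"))
        assert out.degenerate.all()

    def test_deterministic(self):
        x = powerlaw_noise(150 * 50, 1.0, 3)
        wt = _manual_windows([0.0, 5.0, 10.0])
        args = dict(raw=x, fs=50.0, measures=("HFD", "KFD", "SampEn"))
        a = complexity_over_windows(wt, "RAW_50HZ", ComplexityConfig(), **args)
        b = complexity_over_windows(wt, "RAW_50HZ", ComplexityConfig(), **args)
        assert a.equals(b)

    def test_c1_fluctuation_changes_hfd(self):
        """OU-driven compliance fluctuation alters waveform complexity:
        median per-window HFD is higher than in the steady run (direction
        recorded from the oracle run of this generator)."""
        from ppgchaos.preprocess import VitalRecord, preprocess_record
        from ppgchaos.wk4 import SimConfig, simulate_wk4

        def median_hfd(fluct):
            sim = simulate_wk4(SimConfig(
                duration_s=220.0, seed=17, fluct=fluct,
                frac_noise=(1.0, 1.0), meas_noise_sd=0.1))
            rec = VitalRecord.from_simulation(sim)
            beats, _, _, wt, _ = preprocess_record(rec)
            out = complexity_over_windows(
                wt, "RAW_50HZ", ComplexityConfig(), raw=rec.ppg, fs=50.0,
                measures=("HFD",))
            return out.HFD.median()

        steady = median_hfd({})
        fluct = median_hfd({"C1": (0.15, 20.0)})
        assert fluct != steady
        assert fluct > steady

    def test_per_beat_scheme(self, prep_noiseless):
        beats = prep_noiseless["beats"]
        wb = prep_noiseless["beat_windows"]
        out = complexity_over_windows(
            wb, "PER_BEAT_AC", ComplexityConfig(k_max=2, m=2),
            beats=beats, fs=50.0, measures=("KFD", "SampEn"))
        # 70 s record has no 100-beat window; table is empty but well-formed
        assert len(out) == len(wb.usable())

    def test_wavelet_scheme_rows_per_frequency(self):
        from ppgchaos.irasa import wavelet_components

        x = powerlaw_noise(150 * 50, 1.0, 5)
        bank = wavelet_components(x, 50.0, center_freqs=(4.11, 2.06))
        wt = _manual_windows([0.0, 5.0])
        out = complexity_over_windows(
            wt, "WAVELET", ComplexityConfig(), fs=50.0,
            wavelet_bank=bank, measures=("HFD", "KFD"))
        assert len(out) == 2 * 2  # windows x frequencies
        assert set(out.wavelet_freq) == {4.11, 2.06}
        assert out.HFD.notna().all()
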