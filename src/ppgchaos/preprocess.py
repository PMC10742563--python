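"""Beat-level preprocessing of PPG/ABP/CO records.

Foot detection (slope-sum transform with adaptive threshold), piecewise-linear
detrending into AC (pulsatile) and DC (baseline) components, per-beat feature
extraction, the four per-beat quality rules

    1. pulse pressure < 15 mmHg,
    2. PPG-BP waveform correlation < 0.8,
    3. beat interval outside [0.5, 1.5] s,
    4. PPG skewness of the analysis window < 0,

and construction of the two sliding-window schemes (100 s windows with a 5 s
hop for waveform analyses; 100-valid-beat windows for beat-to-beat analyses).
A window with more than 10 s of corrupt/outlier signal is discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import pearsonr, skew

__all__ = [
    "VitalRecord",
    "WindowSet",
    "NoBeatsError",
    "InclusionError",
    "detect_feet",
    "detrend_ppg",
    "beat_features",
    "flag_outlier_beats",
    "make_windows",
    "filter_subject",
    "preprocess_record",
]

REJECT_REASONS = ("PP_LOW", "CORR_LOW", "INTERVAL", "SKEW", "NONE")

PP_MIN_MMHG = 15.0
CORR_MIN = 0.8
INTERVAL_BOUNDS_S = (0.5, 1.5)
MAX_CORRUPT_S = 10.0


class NoBeatsError(ValueError):
    """Signal is flat or contains no detectable cardiac cycles."""


class InclusionError(ValueError):
    """Subject metadata incomplete for the inclusion criteria."""


@dataclass
class VitalRecord:
    """Synchronized vital-sign channels at a fixed sampling rate.

    ``abp`` (mmHg) and ``co`` (L/min) are optional; ``meta`` carries subject
    metadata (age y, sex, height cm, weight kg).  0-based sample indexing.
    """

    subject_id: str
    fs: float
    ppg: np.ndarray
    abp: np.ndarray | None = None
    co: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ppg = np.asarray(self.ppg, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for name in ("abp", "co"):
            ch = getattr(self, name)
            if ch is not None:
                ch = np.asarray(ch, dtype=float)
                if len(ch) != len(self.ppg):
                    raise ValueError(f"channel {name} length mismatch")
                setattr(self, name, ch)

    @property
    def duration_s(self) -> float:
        return len(self.ppg) / self.fs

    @classmethod
    def from_simulation(cls, sim, subject_id: str = "sim", meta: dict | None = None):
        """Wrap a :class:`ppgchaos.wk4.SimRecord` (ABP := p_p, CO := co_track)."""
        return cls(
            subject_id=subject_id,
            fs=sim.fs,
            ppg=sim.ppg,
            abp=sim.p_p,
            co=sim.co_track,
            meta=meta or {},
        )


@dataclass
class WindowSet:
    """Analysis windows under one scheme (TIME_100S or BEATS_100).

    ``frame`` columns: start_s, end_s (half-open), beat_start, beat_stop
    (half-open beat-index span), corrupt_s, usable.
    """

    frame: pd.DataFrame
    scheme: str
    window_s: float | None = None
    hop_s: float | None = None

    def usable(self) -> pd.DataFrame:
        return self.frame[self.frame["usable"]]

    def __len__(self) -> int:
        return len(self.frame)


def detect_feet(ppg: np.ndarray, fs: float) -> np.ndarray:
    """Foot (pre-upstroke minimum) indices, one per cardiac cycle.

    Slope-sum transform (windowed sum of positive slopes, 128 ms) followed by
    peak picking with an adaptive threshold at half the median slope-sum peak
    and a 0.3 s refractory period; the foot is the last sample attaining the
    local minimum in the 0.35 s preceding each slope-sum peak.
    """
    x = np.asarray(ppg, dtype=float)
    if fs < 25:
        raise ValueError("fs must be >= 25 Hz")
    if len(x) < 2 * fs:
        raise ValueError("need at least 2 s of signal")
    sd = x.std()
    if sd == 0 or sd < 1e-12 * abs(x.mean()):
        raise NoBeatsError("flat signal: no cardiac cycles detectable")

    d = np.diff(x)
    w = max(int(round(0.128 * fs)), 1)
    ssf = np.convolve(np.maximum(d, 0.0), np.ones(w), mode="full")[: len(d)]
    refractory = int(round(0.3 * fs))
    cands, props = find_peaks(ssf, distance=refractory, height=1e-3 * ssf.max())
    if len(cands) == 0:
        raise NoBeatsError("no slope-sum peaks found")
    heights = props["peak_heights"]
    # sequential adaptive threshold: accept a candidate at >= 45% of the
    # exponential moving average of recently accepted upstroke heights, so
    # slow amplitude modulation is tracked while noise/dicrotic bumps
    # (well below half a beat's slope sum) are rejected
    ema = float(np.percentile(heights[: max(10, len(heights) // 50)], 75))
    peaks = []
    for p, h in zip(cands, heights):
        if h >= 0.45 * ema:
            peaks.append(p)
            ema = 0.75 * ema + 0.25 * h

    back = int(round(0.35 * fs))
    feet = []
    for p in peaks:
        lo = max(p - back, 0)
        seg = x[lo : p + 1]
        if len(seg) == 0:
            continue
        mn = seg.min()
        tol = 1e-9 * (x.max() - x.min() + 1e-300)
        foot = lo + np.flatnonzero(seg <= mn + tol)[-1]
        if feet and foot - feet[-1] < refractory:  # same cardiac cycle
            continue
        feet.append(int(foot))
    if len(feet) < 1:
        raise NoBeatsError("no feet located")
    return np.asarray(feet, dtype=int)


def detrend_ppg(ppg: np.ndarray, feet: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Split PPG into (pulsatile, baseline) by straight lines through the feet.

    The baseline is the piecewise-linear interpolant through the foot samples
    (constant-extended beyond the first/last foot); pulsatile = ppg - baseline
    and is exactly zero at every foot.
    """
    feet = np.asarray(feet, dtype=int)
    if len(feet) < 2:
        raise ValueError("need at least 2 feet to detrend")
    x = np.asarray(ppg, dtype=float)
    idx = np.arange(len(x))
    baseline = np.interp(idx, feet, x[feet])
    return x - baseline, baseline


def _resample50(seg: np.ndarray) -> np.ndarray:
    src = np.linspace(0.0, 1.0, len(seg))
    return np.interp(np.linspace(0.0, 1.0, 50), src, seg)


def beat_features(
    record: VitalRecord,
    feet: Sequence[int],
    pulsatile: np.ndarray,
    baseline: np.ndarray,
) -> pd.DataFrame:
    """Per-beat feature table over half-open spans [foot, next_foot).

    AC = peak-to-peak pulsatile amplitude, DC = mean baseline; with ABP
    present also SBP/DBP/MAP/PP and the Pearson correlation between the
    beat's ABP and PPG waveforms (both resampled to 50 points); with CO
    present the beat-mean CO.
    """
    feet = np.asarray(feet, dtype=int)
    fs = record.fs
    have_bp = record.abp is not None
    have_co = record.co is not None
    rows = []
    for a, b in zip(feet[:-1], feet[1:]):
        row = {
            "foot_idx": int(a),
            "next_foot_idx": int(b),
            "interval_s": (b - a) / fs,
            "AC": float(pulsatile[a:b].max() - pulsatile[a:b].min()),
            "DC": float(baseline[a:b].mean()),
        }
        if have_bp:
            seg_bp = record.abp[a:b]
            row["SBP"] = float(seg_bp.max())
            row["DBP"] = float(seg_bp.min())
            row["MAP"] = float(seg_bp.mean())
            row["PP"] = row["SBP"] - row["DBP"]
            seg_ppg = record.ppg[a:b]
            if b - a >= 3 and seg_bp.std() > 0 and seg_ppg.std() > 0:
                r, _ = pearsonr(_resample50(seg_bp), _resample50(seg_ppg))
                row["ppg_bp_corr"] = float(r)
            else:
                row["ppg_bp_corr"] = np.nan
        if have_co:
            row["co_mean"] = float(record.co[a:b].mean())
        rows.append(row)
    beats = pd.DataFrame(rows)
    beats["skew_flag"] = False
    beats["valid"] = True
    beats["reject_reason"] = "NONE"
    return beats


def flag_outlier_beats(
    beats: pd.DataFrame,
    *,
    ppg: np.ndarray | None = None,
    fs: float | None = None,
    window_s: float = 100.0,
    hop_s: float = 5.0,
    window_skew: Sequence[tuple[float, float, float]] | None = None,
) -> pd.DataFrame:
    """Apply the four per-beat quality rules; first matching reason wins.

    Rule order: PP_LOW (PP < 15 mmHg) -> CORR_LOW (r < 0.8) -> INTERVAL
    (outside [0.5, 1.5] s) -> SKEW (beat overlaps an analysis window whose
    raw-PPG Fisher-Pearson skewness is negative).  Window skewness is computed
    from ``ppg``/``fs`` on the TIME-scheme grid, or supplied directly as
    ``window_skew`` = [(start_s, end_s, skewness), ...].  Rules whose input
    column is absent are skipped.
    """
    beats = beats.copy()
    if window_skew is None and ppg is not None and fs is not None:
        window_skew = []
        duration = len(ppg) / fs
        start = 0.0
        while start + window_s <= duration + 1e-9:
            i0, i1 = int(round(start * fs)), int(round((start + window_s) * fs))
            window_skew.append((start, start + window_s, float(skew(ppg[i0:i1]))))
            start += hop_s

    skew_flag = np.zeros(len(beats), dtype=bool)
    if window_skew:
        fs_eff = fs if fs is not None else 1.0
        t0 = beats["foot_idx"].to_numpy() / fs_eff
        t1 = beats["next_foot_idx"].to_numpy() / fs_eff
        for ws, we, sk in window_skew:
            if sk < 0:
                skew_flag |= (t0 < we) & (t1 > ws)
    beats["skew_flag"] = skew_flag

    reasons = np.full(len(beats), "NONE", dtype=object)
    valid = np.ones(len(beats), dtype=bool)

    def apply(mask, reason):
        hit = mask & (reasons == "NONE")
        reasons[hit] = reason
        valid[mask] = False

    if "PP" in beats:
        apply(beats["PP"].to_numpy() < PP_MIN_MMHG, "PP_LOW")
    if "ppg_bp_corr" in beats:
        r = beats["ppg_bp_corr"].to_numpy()
        apply(np.isnan(r) | (r < CORR_MIN), "CORR_LOW")
    iv = beats["interval_s"].to_numpy()
    apply((iv < INTERVAL_BOUNDS_S[0]) | (iv > INTERVAL_BOUNDS_S[1]), "INTERVAL")
    apply(skew_flag, "SKEW")

    beats["valid"] = valid
    beats["reject_reason"] = reasons
    return beats


def make_windows(
    record: VitalRecord,
    beats: pd.DataFrame,
    scheme: str = "TIME_100S",
    *,
    window_s: float = 100.0,
    hop_s: float = 5.0,
    beats_per_window: int = 100,
    max_corrupt_s: float = MAX_CORRUPT_S,
) -> WindowSet:
    """Build analysis windows.

    TIME_100S: half-open [start, start+window_s) windows stepped by ``hop_s``;
    corrupt_s is the window time not covered by valid beats, and windows with
    corrupt_s > ``max_corrupt_s`` are unusable.  BEATS_100: disjoint runs of
    ``beats_per_window`` consecutive valid beats.
    """
    fs = record.fs
    duration = record.duration_s
    foot_t = beats["foot_idx"].to_numpy() / fs
    next_t = beats["next_foot_idx"].to_numpy() / fs
    valid = beats["valid"].to_numpy()

    if scheme == "TIME_100S":
        if duration < window_s:
            warnings.warn("record shorter than one window; empty window set")
            return WindowSet(_empty_windows(), scheme, window_s, hop_s)
        rows = []
        start = 0.0
        while start + window_s <= duration + 1e-9:
            end = start + window_s
            ov = np.clip(np.minimum(next_t, end) - np.maximum(foot_t, start), 0, None)
            covered = float(ov[valid].sum())
            corrupt = window_s - covered
            inwin = np.flatnonzero(ov > 0)
            rows.append(
                {
                    "start_s": start,
                    "end_s": end,
                    "beat_start": int(inwin[0]) if len(inwin) else -1,
                    "beat_stop": int(inwin[-1]) + 1 if len(inwin) else -1,
                    "corrupt_s": corrupt,
                    "usable": corrupt <= max_corrupt_s,
                }
            )
            start += hop_s
        return WindowSet(pd.DataFrame(rows), scheme, window_s, hop_s)

    if scheme == "BEATS_100":
        vidx = np.flatnonzero(valid)
        rows = []
        for k in range(len(vidx) // beats_per_window):
            grp = vidx[k * beats_per_window : (k + 1) * beats_per_window]
            start_s, end_s = foot_t[grp[0]], next_t[grp[-1]]
            span = slice(grp[0], grp[-1] + 1)
            bad = ~valid[span]
            corrupt = float((next_t[span][bad] - foot_t[span][bad]).sum())
            rows.append(
                {
                    "start_s": start_s,
                    "end_s": end_s,
                    "beat_start": int(grp[0]),
                    "beat_stop": int(grp[-1]) + 1,
                    "corrupt_s": corrupt,
                    "usable": True,
                }
            )
        frame = pd.DataFrame(rows) if rows else _empty_windows()
        return WindowSet(frame, scheme, None, None)

    raise ValueError(f"unknown window scheme {scheme!r}")


def _empty_windows() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["start_s", "end_s", "beat_start", "beat_stop", "corrupt_s", "usable"]
    )


def filter_subject(meta: dict, window_sbp_medians: Sequence[float] | None = None) -> bool:
    """Cohort inclusion: age > 18, weight > 40 kg, height > 145 cm,
    16 <= BMI <= 35; excluded if any window's median SBP < 80 mmHg
    (suspected excessive blood loss)."""
    missing = [k for k in ("age", "weight", "height") if meta.get(k) is None]
    if missing:
        raise InclusionError(f"missing metadata fields: {missing}")
    age, weight, height = meta["age"], meta["weight"], meta["height"]
    bmi = weight / (height / 100.0) ** 2
    ok = age > 18 and weight > 40 and height > 145 and 16 <= bmi <= 35
    if ok and window_sbp_medians is not None:
        ok = all(m >= 80.0 for m in window_sbp_medians)
    return bool(ok)


def preprocess_record(
    record: VitalRecord,
    *,
    window_s: float = 100.0,
    hop_s: float = 5.0,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, WindowSet, WindowSet]:
    """Full stage: feet -> detrend -> features -> quality rules -> windows.

    Returns (beats, pulsatile, baseline, time_windows, beat_windows).
    """
    feet = detect_feet(record.ppg, record.fs)
    pulsatile, baseline = detrend_ppg(record.ppg, feet)
    beats = beat_features(record, feet, pulsatile, baseline)
    beats = flag_outlier_beats(
        beats, ppg=record.ppg, fs=record.fs, window_s=window_s, hop_s=hop_s
    )
    wt = make_windows(record, beats, "TIME_100S", window_s=window_s, hop_s=hop_s)
    wb = make_windows(record, beats, "BEATS_100")
    return beats, pulsatile, baseline, wt, wb
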