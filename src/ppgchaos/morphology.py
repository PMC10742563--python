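"""Per-beat morphological features of the PPG contour.

Features: AREA (area under the time- and amplitude-normalized waveform),
SPMEAN/SPVAR (mean/sd of the upstroke slope, foot -> systolic peak),
DPMEAN/DPVAR (same for the downstroke, peak -> next foot) and b/a, the ratio
of the early negative to the early positive peak of the second derivative of
the pulse (the acceleration-pulse a and b waves), a classic vascular-
compliance correlate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MorphVector", "morph_features", "morph_table"]

SMOOTH_POINTS = 5  # moving-average width before the second derivative (50 Hz)
EARLY_FRACTION = 0.4  # a,b waves are sought in the first 40% of the beat


@dataclass
class MorphVector:
    AREA: float
    SPMEAN: float
    SPVAR: float
    DPMEAN: float
    DPVAR: float
    b_a: float
    valid: bool = True


def _second_derivative(x: np.ndarray, fs: float) -> np.ndarray:
    w = min(SMOOTH_POINTS, len(x))
    sm = np.convolve(x, np.ones(w) / w, mode="same")
    return np.gradient(np.gradient(sm)) * fs * fs


def _first_peak(seg: np.ndarray, sign: int, start: int = 0) -> int | None:
    """Index of the first local extremum of given sign at/after ``start``."""
    s = sign * seg
    for i in range(max(start, 1), len(s) - 1):
        if s[i] > 0 and s[i] >= s[i - 1] and s[i] >= s[i + 1]:
            return i
    return None


def morph_features(beat: np.ndarray, fs: float) -> MorphVector:
    """Morphological features of one detrended beat (foot to next foot).

    AREA is the trapezoidal area after normalizing amplitude and duration to
    [0, 1]; slopes are first differences times fs (signal units / s); the
    second derivative uses 5-point smoothing and central differences, with
    the a and b waves restricted to the first 40% of the beat.
    """
    x = np.asarray(beat, dtype=float)
    if len(x) < 10:
        raise ValueError("beat must have at least 10 samples")
    peak = int(np.argmax(x))
    if peak == 0 or peak == len(x) - 1:
        return MorphVector(*([np.nan] * 6), valid=False)

    rng = x.max() - x.min()
    if rng == 0:
        return MorphVector(*([np.nan] * 6), valid=False)
    xn = (x - x.min()) / rng
    tn = np.linspace(0.0, 1.0, len(x))
    area = float(np.trapezoid(xn, tn))

    slope = np.diff(x) * fs
    up, down = slope[:peak], slope[peak:]
    spmean = float(up.mean())
    spvar = float(up.std(ddof=0)) if len(up) > 1 else 0.0
    dpmean = float(down.mean())
    dpvar = float(down.std(ddof=0)) if len(down) > 1 else 0.0

    d2 = _second_derivative(x, fs)
    early = d2[: max(int(EARLY_FRACTION * len(x)), 3)]
    b_a = np.nan
    ia = _first_peak(early, +1)
    if ia is not None:
        ib = _first_peak(early, -1, start=ia + 1)
        if ib is not None and early[ia] != 0:
            b_a = float(early[ib] / early[ia])
    return MorphVector(area, spmean, spvar, dpmean, dpvar, b_a)


def morph_table(pulsatile: np.ndarray, beats: pd.DataFrame, fs: float) -> pd.DataFrame:
    """Morphology columns for every beat in a beat table."""
    rows = []
    for a, b in zip(beats["foot_idx"], beats["next_foot_idx"]):
        seg = pulsatile[a:b]
        if len(seg) < 10:
            rows.append(MorphVector(*([np.nan] * 6), valid=False))
        else:
            rows.append(morph_features(seg, fs))
    return pd.DataFrame([vars(m) for m in rows], index=beats.index)
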