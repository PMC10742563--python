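"""Fractal-dimension and entropy measures of signal complexity.

Higuchi and Katz fractal dimensions, sample/approximate/fuzzy entropy,
recurrence-quantification diagonal-line entropy (ENTR), the Kennel
false-nearest-neighbors embedding dimension and the HRV LF/HF ratio, plus an
orchestrator applying them per analysis window under the three sampling
schemes (raw 50 Hz waveform, wavelet components, per-beat AC/DC series).

Defaults follow common practice for PPG: k_max = 10 for Higuchi, embedding
dimension m = 4 (chosen by FNN), tolerance r = 0.2 sd per window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import interp1d
from scipy.signal import welch
from scipy.spatial import cKDTree
from scipy.stats import linregress

__all__ = [
    "ComplexityConfig",
    "hfd",
    "hfd_fit",
    "kfd",
    "sampen",
    "apen",
    "fuzzen",
    "rqa_entr",
    "fnn_dimension",
    "lf_hf",
    "complexity_over_windows",
]

_CHUNK = 512  # row block for pairwise-distance computations


@dataclass
class ComplexityConfig:
    k_max: int = 10          # Higuchi maximum segment count
    m: int = 4               # embedding dimension (FNN-chosen default)
    r_frac: float = 0.2      # entropy tolerance as a fraction of window sd
    fuzz_gradient: int = 2   # fuzzy membership exponent
    rqa_eps_frac: float = 0.1  # recurrence threshold, fraction of diameter
    rqa_lmin: int = 2        # minimum diagonal line length
    tau: int = 1             # embedding delay (samples)
    fnn_max_m: int = 10
    fnn_rtol: float = 10.0
    fnn_atol: float = 2.0

    def __post_init__(self):
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0 < self.r_frac < 1:
            raise ValueError("r_frac must be in (0, 1)")


# ---------------------------------------------------------------- fractal dims

def hfd_fit(x: np.ndarray, k_max: int = 10) -> tuple[float, float]:
    """Higuchi fractal dimension with its relative fit uncertainty (%).

    Normalized curve lengths L(k) for k = 1..k_max averaged over offsets;
    the HFD is the OLS slope of ln<L(k)> on ln(1/k) and the uncertainty is
    100 * SE(slope)/slope from the fit's variance-covariance matrix.
    Degenerate (constant) series return (1.0, 0.0).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10 * k_max:
        raise ValueError("series too short for k_max")
    lk = []
    ks = []
    for k in range(1, k_max + 1):
        lengths = []
        for m0 in range(k):
            idx = np.arange(m0, n, k)
            nm = len(idx) - 1
            if nm < 1:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            lengths.append(dist * (n - 1) / (nm * k) / k)
        if lengths:
            lk.append(np.mean(lengths))
            ks.append(k)
    lk = np.asarray(lk)
    if np.any(lk <= 0):
        return 1.0, 0.0
    res = linregress(np.log(1.0 / np.asarray(ks)), np.log(lk))
    rel = 100.0 * res.stderr / abs(res.slope) if res.slope != 0 else float("inf")
    return float(res.slope), float(rel)


def hfd(x: np.ndarray, k_max: int = 10) -> float:
    """Higuchi fractal dimension (see :func:`hfd_fit`)."""
    return hfd_fit(x, k_max)[0]


def kfd(x: np.ndarray) -> float:
    """Katz fractal dimension of the amplitude-normalized waveform.

    The series is scaled to unit amplitude range (making the measure exactly
    scale invariant) and treated as a planar polyline with unit index
    spacing.  KFD = log10(n) / (log10(n) + log10(d / L)) with L the total
    polyline length, d the maximum Euclidean distance from the first vertex
    and n the number of steps.  A constant series returns 1.0.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    rng = x.max() - x.min()
    if rng == 0:
        return 1.0
    y = (x - x.min()) / rng
    i = np.arange(len(y), dtype=float)
    steps = np.hypot(np.diff(i), np.diff(y))
    total = steps.sum()
    d = np.hypot(i - i[0], y - y[0]).max()
    n = len(x) - 1
    if d == 0 or total == 0:
        return 1.0
    if abs(total - d) <= 1e-9 * total:  # numerically straight segment
        return 1.0
    return float(np.log10(n) / (np.log10(n) + np.log10(d / total)))


# ------------------------------------------------------------------- entropies

def _embed(x: np.ndarray, m: int, tau: int = 1) -> np.ndarray:
    n = len(x) - (m - 1) * tau
    if n < 1:
        raise ValueError("series too short to embed")
    return np.lib.stride_tricks.sliding_window_view(x, (m - 1) * tau + 1)[:, ::tau]


def _pair_counts_cheb(E: np.ndarray, E1: np.ndarray, r: float) -> tuple[int, int]:
    """Counts of template pairs (i < j) within Chebyshev distance r at lengths
    m (E) and m+1 (E1); both use the same number of templates."""
    N = len(E)
    b = a = 0
    for i0 in range(0, N, _CHUNK):
        i1 = min(i0 + _CHUNK, N)
        dm = np.abs(E[i0:i1, None, :] - E[None, :, :]).max(axis=2)
        dm1 = np.maximum(dm, np.abs(E1[i0:i1, -1][:, None] - E1[:, -1][None, :]))
        jj = np.arange(N)[None, :]
        upper = jj > np.arange(i0, i1)[:, None]
        b += int(np.count_nonzero((dm <= r) & upper))
        a += int(np.count_nonzero((dm1 <= r) & upper))
    return b, a


def sampen(x: np.ndarray, m: int = 4, r_abs: float | None = None) -> float:
    """Sample entropy (Richman-Moorman), Chebyshev distance, no self-matches.

    -ln(A/B) with B, A the numbers of template pairs matching within
    ``r_abs`` at lengths m and m+1 (n - m templates each).  When no length
    m+1 pair matches the value is capped at ln(B) + ln(2).
    """
    x = np.asarray(x, dtype=float)
    if r_abs is None or r_abs <= 0:
        raise ValueError("r_abs must be positive")
    if len(x) < 4 * m:
        raise ValueError("series too short")
    N = len(x) - m
    E = _embed(x, m)[:N]
    E1 = _embed(x, m + 1)
    b, a = _pair_counts_cheb(E, E1, r_abs)
    if b == 0:
        return float("nan")
    if a == 0:
        return float(np.log(b) + np.log(2.0))
    return float(-np.log(a / b))


def apen(x: np.ndarray, m: int = 4, r_abs: float | None = None) -> float:
    """Approximate entropy (Pincus): Phi_m - Phi_{m+1}, self-matches included."""
    x = np.asarray(x, dtype=float)
    if r_abs is None or r_abs <= 0:
        raise ValueError("r_abs must be positive")
    if len(x) < 4 * m:
        raise ValueError("series too short")

    def phi(mm: int) -> float:
        E = _embed(x, mm)
        N = len(E)
        logs = np.empty(N)
        for i0 in range(0, N, _CHUNK):
            i1 = min(i0 + _CHUNK, N)
            d = np.abs(E[i0:i1, None, :] - E[None, :, :]).max(axis=2)
            logs[i0:i1] = np.log(np.count_nonzero(d <= r_abs, axis=1) / N)
        return float(logs.mean())

    return phi(m) - phi(m + 1)


def fuzzen(
    x: np.ndarray, m: int = 4, r_abs: float | None = None, gradient: int = 2
) -> float:
    """Fuzzy entropy (Chen): exponential membership exp(-(d/r)^gradient) on
    mean-subtracted templates; -ln(phi_{m+1} / phi_m)."""
    x = np.asarray(x, dtype=float)
    if r_abs is None or r_abs <= 0:
        raise ValueError("r_abs must be positive")
    if len(x) < 4 * m:
        raise ValueError("series too short")
    N = len(x) - m

    def phi(mm: int) -> float:
        E = _embed(x, mm)[:N]
        E = E - E.mean(axis=1, keepdims=True)
        total = 0.0
        for i0 in range(0, N, _CHUNK):
            i1 = min(i0 + _CHUNK, N)
            d = np.abs(E[i0:i1, None, :] - E[None, :, :]).max(axis=2)
            mu = np.exp(-((d / r_abs) ** gradient))
            jj = np.arange(N)[None, :]
            upper = jj > np.arange(i0, i1)[:, None]
            total += float(mu[upper].sum())
        return 2.0 * total / (N * (N - 1))

    p_m, p_m1 = phi(m), phi(m + 1)
    if p_m <= 0 or p_m1 <= 0:
        return float("nan")
    return float(-np.log(p_m1 / p_m))


def rqa_entr(
    x: np.ndarray,
    m: int = 4,
    tau: int = 1,
    eps_frac: float = 0.1,
    lmin: int = 2,
) -> float:
    """Shannon entropy (nats) of the recurrence-plot diagonal-line lengths.

    Delay embedding (m, tau); recurrence by Chebyshev distance below
    ``eps_frac`` times the attractor diameter; diagonal lines of length >=
    ``lmin`` from the upper triangle (the main diagonal excluded).  Returns 0
    when no qualifying line exists.
    """
    x = np.asarray(x, dtype=float)
    E = _embed(x, m, tau)
    N = len(E)
    if N < 50:
        raise ValueError("series too short after embedding")
    # pairwise Chebyshev distances (chunked); diameter in the same pass
    R = np.zeros((N, N), dtype=bool)
    diam = 0.0
    dists = []
    for i0 in range(0, N, _CHUNK):
        i1 = min(i0 + _CHUNK, N)
        d = np.abs(E[i0:i1, None, :] - E[None, :, :]).max(axis=2)
        dists.append(d)
        diam = max(diam, float(d.max()))
    eps = eps_frac * diam
    for k, i0 in enumerate(range(0, N, _CHUNK)):
        i1 = min(i0 + _CHUNK, N)
        R[i0:i1] = dists[k] < eps
    lengths = []
    for k in range(1, N):
        diag = np.diagonal(R, offset=k)
        if not diag.any():
            continue
        padded = np.concatenate([[0], diag.view(np.int8), [0]])
        edges = np.flatnonzero(np.diff(padded))
        runs = edges[1::2] - edges[0::2]
        lengths.extend(int(r) for r in runs if r >= lmin)
    if not lengths:
        return 0.0
    _, counts = np.unique(lengths, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


# ------------------------------------------------------- embedding / HRV

def fnn_fractions(
    x: np.ndarray,
    max_m: int = 10,
    rtol: float = 10.0,
    atol: float = 2.0,
    tau: int = 1,
    theiler: int = 10,
) -> np.ndarray:
    """False-nearest-neighbor fraction (Kennel) for each m = 1..max_m.

    The nearest neighbor of every delay vector is searched excluding
    temporally close points (|i - j| <= ``theiler``); a neighbor is false if
    the distance gained by the (m+1)-th coordinate exceeds ``rtol`` times the
    m-dimensional distance, or the augmented distance exceeds ``atol``
    standard deviations of the series.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 500:
        raise ValueError("need at least 500 samples")
    sigma = x.std()
    if sigma == 0:
        raise ValueError("constant series")
    fracs = []
    for m in range(1, max_m + 1):
        n_vec = len(x) - m * tau  # leave room for the (m+1)-th coordinate
        if n_vec < 10:
            break
        E = _embed(x, m, tau)[:n_vec]
        tree = cKDTree(E)
        k = min(2 + 2 * theiler, n_vec)
        dist, nbr = tree.query(E, k=k)
        idx = np.arange(n_vec)
        rd = np.full(n_vec, np.nan)
        j = np.zeros(n_vec, dtype=int)
        for c in range(1, k):
            sel = np.isnan(rd) & (np.abs(nbr[:, c] - idx) > theiler)
            rd[sel] = dist[sel, c]
            j[sel] = nbr[sel, c]
        ok = ~np.isnan(rd) & (rd > 0)
        extra = np.abs(x[idx + m * tau] - x[j + m * tau])
        false1 = extra[ok] / rd[ok] > rtol
        false2 = np.sqrt(rd[ok] ** 2 + extra[ok] ** 2) / sigma > atol
        fracs.append(float(np.mean(false1 | false2)))
    return np.asarray(fracs)


def fnn_dimension(
    x: np.ndarray,
    max_m: int = 10,
    rtol: float = 10.0,
    atol: float = 2.0,
    tau: int = 1,
    theiler: int = 10,
    threshold: float = 0.05,
) -> int:
    """Embedding dimension: smallest m whose FNN fraction drops below
    ``threshold`` (argmin over m if it never does, as for irregular noise)."""
    fracs = fnn_fractions(x, max_m, rtol, atol, tau, theiler)
    below = np.flatnonzero(fracs < threshold)
    if len(below):
        return int(below[0]) + 1
    return int(np.argmin(fracs)) + 1


def lf_hf(beat_intervals: np.ndarray, beat_times: np.ndarray) -> float:
    """HRV LF/HF ratio from beat-to-beat intervals.

    Intervals are cubic-interpolated onto a uniform 4 Hz grid, the PSD is
    estimated by Welch, and LF (0.04-0.15 Hz) over HF (0.15-0.40 Hz) band
    powers are integrated trapezoidally.  NaN if the HF power vanishes.
    """
    t = np.asarray(beat_times, dtype=float)
    iv = np.asarray(beat_intervals, dtype=float)
    if t[-1] - t[0] < 60.0:
        raise ValueError("need at least 60 s of beats")
    fs_i = 4.0
    grid = np.arange(t[0], t[-1], 1.0 / fs_i)
    ivu = interp1d(t, iv, kind="cubic")(grid)
    ivu = ivu - ivu.mean()
    nperseg = min(len(ivu), 1024)
    f, psd = welch(ivu, fs=fs_i, nperseg=nperseg, noverlap=nperseg // 2)
    lf_mask = (f >= 0.04) & (f < 0.15)
    hf_mask = (f >= 0.15) & (f <= 0.40)
    lf = np.trapezoid(psd[lf_mask], f[lf_mask])
    hf = np.trapezoid(psd[hf_mask], f[hf_mask])
    if hf <= 0:
        return float("nan")
    return float(lf / hf)


# ----------------------------------------------------------- per-window driver

DEFAULT_MEASURES = ("HFD", "KFD", "SampEn", "ApEn", "FuzzEn", "RQA_ENTR", "LF_HF")


def _window_measures(seg: np.ndarray, cfg: ComplexityConfig, measures) -> dict:
    out: dict[str, float] = {}
    degenerate = seg.std() == 0 or len(seg) < max(10 * cfg.k_max, 4 * cfg.m + 2)
    out["degenerate"] = degenerate
    if degenerate:
        for name in measures:
            if name != "LF_HF":
                out[name] = np.nan
        return out
    r = cfg.r_frac * seg.std()
    if "HFD" in measures:
        v, unc = hfd_fit(seg, cfg.k_max)
        out["HFD"], out["HFD_unc_pct"] = v, unc
    if "KFD" in measures:
        out["KFD"] = kfd(seg)
    if "SampEn" in measures:
        out["SampEn"] = sampen(seg, cfg.m, r)
    if "ApEn" in measures:
        out["ApEn"] = apen(seg, cfg.m, r)
    if "FuzzEn" in measures:
        out["FuzzEn"] = fuzzen(seg, cfg.m, r, cfg.fuzz_gradient)
    if "RQA_ENTR" in measures:
        try:
            out["RQA_ENTR"] = rqa_entr(seg, cfg.m, cfg.tau, cfg.rqa_eps_frac, cfg.rqa_lmin)
        except ValueError:
            out["RQA_ENTR"] = np.nan
    return out


def complexity_over_windows(
    windows,
    scheme: str,
    config: ComplexityConfig | None = None,
    *,
    raw: np.ndarray | None = None,
    fs: float | None = None,
    wavelet_bank=None,
    beats: pd.DataFrame | None = None,
    measures: tuple[str, ...] = DEFAULT_MEASURES,
) -> pd.DataFrame:
    """Complexity measures for every usable window under one sampling scheme.

    Schemes: RAW_50HZ (raw signal samples, TIME windows), WAVELET (each
    Morse component, TIME windows), PER_BEAT_AC / PER_BEAT_DC (per-beat
    amplitude/baseline series on a beat-index abscissa, BEAT windows).
    The entropy tolerance r is recomputed per window; LF/HF uses the valid
    beat intervals of the window.  Unusable windows are skipped.
    """
    cfg = config or ComplexityConfig()
    rows = []
    per_beat = scheme in ("PER_BEAT_AC", "PER_BEAT_DC")
    col = "AC" if scheme == "PER_BEAT_AC" else "DC"
    for wid, w in windows.frame.iterrows():
        if not w["usable"]:
            continue
        base = {"window_id": wid, "scheme": scheme,
                "start_s": w["start_s"], "end_s": w["end_s"]}
        if per_beat:
            if beats is None:
                raise ValueError("per-beat schemes require a beat table")
            span = beats.iloc[int(w["beat_start"]) : int(w["beat_stop"])]
            span = span[span["valid"]]
            seg = span[col].to_numpy(dtype=float)
            row = base | _window_measures(seg, cfg, measures)
            if "LF_HF" in measures:
                row["LF_HF"] = _safe_lfhf(span, fs)
            rows.append(row)
        elif scheme == "RAW_50HZ":
            if raw is None or fs is None:
                raise ValueError("RAW_50HZ requires raw signal and fs")
            i0, i1 = int(round(w["start_s"] * fs)), int(round(w["end_s"] * fs))
            seg = raw[i0:i1]
            row = base | _window_measures(seg, cfg, measures)
            if "LF_HF" in measures and beats is not None:
                span = beats.iloc[int(w["beat_start"]) : int(w["beat_stop"])]
                row["LF_HF"] = _safe_lfhf(span[span["valid"]], fs)
            rows.append(row)
        elif scheme == "WAVELET":
            if wavelet_bank is None or fs is None:
                raise ValueError("WAVELET requires a wavelet bank and fs")
            i0, i1 = int(round(w["start_s"] * fs)), int(round(w["end_s"] * fs))
            for fc, comp in zip(wavelet_bank.center_freqs, wavelet_bank.components):
                row = dict(base)
                row["wavelet_freq"] = fc
                row |= _window_measures(comp[i0:i1], cfg, measures)
                rows.append(row)
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
    return pd.DataFrame(rows)


def _safe_lfhf(span: pd.DataFrame, fs: float | None) -> float:
    if fs is None or len(span) < 3:
        return np.nan
    try:
        return lf_hf(span["interval_s"].to_numpy(),
                     span["foot_idx"].to_numpy() / fs)
    except ValueError:
        return np.nan
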