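"""Per-beat hemodynamic estimation on the WK4 basis.

Two-stage estimation: R and C1 first from simple ratios,

    R  = MAP / CO            (mmHg*min/L)
    C1 = AC / PP             (ppg a.u. / mmHg; trend-only, no calibration)

then C2 and L by fitting the WK4 frequency response from the Fourier series
of the reconstructed inflow to the measured peripheral pressure, minimizing
RMS = sqrt(SSE / (N - 1)).  Hemodynamic fluctuation is summarized as the
windowed standard deviation sigma of each per-beat parameter track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .preprocess import WindowSet
from .wk4 import _inflow_on_grid

__all__ = [
    "estimate_R",
    "estimate_C1",
    "reconstruct_inflow",
    "wk4_transfer",
    "fit_C2_L",
    "WK4Fit",
    "hemo_track",
    "windowed_sigma",
    "windowed_median",
]

# fixed search bounds of the (C2, L) grid, in model units (mL/mmHg, mmHg*s^2/mL)
C2_BOUNDS_REL = (0.01, 10.0)  # relative to C1
L_BOUNDS = (1e-4, 1.0)


def estimate_R(map_mmhg, co_lmin):
    """Peripheral resistance R = MAP / CO in mmHg*min/L; NaN where CO <= 0."""
    map_mmhg = np.asarray(map_mmhg, dtype=float)
    co = np.asarray(co_lmin, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(co > 0, map_mmhg / co, np.nan)
    return r if r.ndim else float(r)


def estimate_C1(ac, pp_mmhg):
    """Proximal compliance surrogate C1 = AC / PP (a.u./mmHg); NaN if PP <= 0."""
    ac = np.asarray(ac, dtype=float)
    pp = np.asarray(pp_mmhg, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        c1 = np.where(pp > 0, ac / pp, np.nan)
    return c1 if c1.ndim else float(c1)


def reconstruct_inflow(
    co_mean_lmin: float,
    interval_s: float,
    fs: float,
    systole_fraction: float = 0.35,
) -> np.ndarray:
    """One-beat half-sine inflow with integral = CO * interval / 60 * 1000 mL."""
    if co_mean_lmin <= 0:
        raise ValueError("co_mean must be positive")
    sv_ml = co_mean_lmin * interval_s / 60.0 * 1000.0
    n = int(round(interval_s * fs))
    t = np.arange(n) / fs
    return _inflow_on_grid(
        t, np.array([0.0]), np.array([interval_s]), np.array([sv_ml]),
        systole_fraction, fs,
    )


def wk4_transfer(f_hz, R, C1, C2, L):
    """WK4 input-impedance transfer q_in -> p_p at frequencies ``f_hz``.

    From the model ODEs in the frequency domain:
    H = 1 / [ (1 + (jw)^2 L C1)(jw C2 + 1/R) + jw C1 ], with H(0) = R.
    Units: R mmHg*s/mL, C mL/mmHg, L mmHg*s^2/mL.
    """
    jw = 2j * np.pi * np.asarray(f_hz, dtype=float)
    return 1.0 / ((1.0 + jw**2 * L * C1) * (jw * C2 + 1.0 / R) + jw * C1)


@dataclass
class WK4Fit:
    """Result of the (C2, L) frequency-domain fit."""

    C2: float
    L: float
    rms: float  # sqrt(SSE / (N - 1)), mmHg
    converged: bool
    n_eval: int
    poor_fit: bool  # rms above 10% of the pulse pressure


def _harmonic_model(q_in, fs, n_harmonics, f0):
    n = len(q_in)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    Q = np.fft.rfft(q_in)
    if f0 is None:
        mag = np.abs(Q).copy()
        mag[0] = 0.0
        f0 = freqs[int(np.argmax(mag))]
    keep = freqs <= n_harmonics * f0 + 1e-9
    return freqs[keep], Q[keep], n


def fit_C2_L(
    q_in: np.ndarray,
    p_p: np.ndarray,
    R: float,
    C1: float,
    fs: float,
    n_harmonics: int = 10,
    f0: float | None = None,
    grid_size: int = 24,
) -> WK4Fit:
    """Estimate (C2, L) from an inflow/pressure window with R and C1 fixed.

    The inflow is truncated to its first ``n_harmonics`` cardiac harmonics
    (fundamental ``f0``, auto-detected from the inflow spectrum if omitted),
    pushed through the WK4 transfer, and (C2, L) are grid-searched over
    C2 in [0.01, 10]*C1, L in [1e-4, 1], then refined by Nelder-Mead on the
    log-parameters (at most 200 iterations; on non-convergence the best grid
    point reached so far is returned with ``converged=False``).
    """
    q_in = np.asarray(q_in, dtype=float)
    p_p = np.asarray(p_p, dtype=float)
    if len(q_in) != len(p_p):
        raise ValueError("q_in and p_p must have equal length")
    n = len(p_p)
    if n < 3:
        raise ValueError("window too short")
    freqs, Qk, _ = _harmonic_model(q_in, fs, n_harmonics, f0)

    def rms_of(c2, l):
        H = wk4_transfer(freqs, R, C1, c2, l)
        model = np.fft.irfft(H * Qk, n)
        return float(np.sqrt(np.sum((model - p_p) ** 2) / (n - 1)))

    c2_grid = np.geomspace(C2_BOUNDS_REL[0] * C1, C2_BOUNDS_REL[1] * C1, grid_size)
    l_grid = np.geomspace(L_BOUNDS[0], L_BOUNDS[1], grid_size)
    best = (np.inf, c2_grid[0], l_grid[0])
    for c2 in c2_grid:
        for l in l_grid:
            r = rms_of(c2, l)
            if r < best[0]:
                best = (r, c2, l)

    x0 = np.log10([best[1], best[2]])
    res = minimize(
        lambda x: rms_of(10 ** x[0], 10 ** x[1]),
        x0,
        method="Nelder-Mead",
        options={"maxiter": 200, "xatol": 1e-6, "fatol": 1e-10},
    )
    converged = bool(res.success)
    if res.fun <= best[0]:
        rms, c2, l = float(res.fun), 10 ** res.x[0], 10 ** res.x[1]
    else:  # refinement failed to improve; keep grid optimum
        rms, c2, l = best
        converged = False
    pp_range = float(p_p.max() - p_p.min())
    return WK4Fit(
        C2=float(c2), L=float(l), rms=rms, converged=converged,
        n_eval=grid_size * grid_size + int(res.nfev),
        poor_fit=bool(pp_range > 0 and rms > 0.1 * pp_range),
    )


def hemo_track(beats: pd.DataFrame) -> pd.DataFrame:
    """Per-beat R (mmHg*min/L) and C1 (a.u./mmHg) track from a beat table."""
    out = beats[["foot_idx", "next_foot_idx", "interval_s", "valid"]].copy()
    out["R"] = estimate_R(beats["MAP"], beats["co_mean"]) if {"MAP", "co_mean"} <= set(beats) else np.nan
    out["C1"] = estimate_C1(beats["AC"], beats["PP"]) if {"AC", "PP"} <= set(beats) else np.nan
    if "SBP" in beats:
        out[["SBP", "DBP", "MAP", "PP"]] = beats[["SBP", "DBP", "MAP", "PP"]]
    if "co_mean" in beats:
        out["CO"] = beats["co_mean"]
    return out


def windowed_sigma(
    track: pd.DataFrame,
    windows: WindowSet,
    fs: float,
    params: list[str] | None = None,
    valid_only: bool = True,
) -> pd.DataFrame:
    """Sample standard deviation of per-beat parameters within each window.

    Windows with fewer than 2 contributing beats yield NaN.
    """
    if params is None:
        params = [c for c in ("R", "C1", "CO", "SBP", "DBP", "MAP", "PP") if c in track]
    t0 = track["foot_idx"].to_numpy() / fs
    ok = track["valid"].to_numpy() if (valid_only and "valid" in track) else np.ones(len(track), bool)
    rows = []
    for _, w in windows.frame.iterrows():
        inwin = ok & (t0 >= w["start_s"]) & (t0 < w["end_s"])
        row = {"start_s": w["start_s"], "end_s": w["end_s"], "n_beats": int(inwin.sum())}
        for p in params:
            vals = track.loc[inwin, p].dropna()
            row[f"sigma_{p}"] = float(vals.std(ddof=1)) if len(vals) >= 2 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def windowed_median(
    track: pd.DataFrame,
    windows: WindowSet,
    fs: float,
    params: list[str] | None = None,
    valid_only: bool = True,
) -> pd.DataFrame:
    """Per-window median of per-beat parameters (the window-level hemodynamic
    state series used by the association stage)."""
    if params is None:
        params = [c for c in ("R", "C1", "CO", "SBP", "DBP", "MAP", "PP") if c in track]
    t0 = track["foot_idx"].to_numpy() / fs
    ok = track["valid"].to_numpy() if (valid_only and "valid" in track) else np.ones(len(track), bool)
    rows = []
    for _, w in windows.frame.iterrows():
        inwin = ok & (t0 >= w["start_s"]) & (t0 < w["end_s"])
        row = {"start_s": w["start_s"], "end_s": w["end_s"], "n_beats": int(inwin.sum())}
        for p in params:
            vals = track.loc[inwin, p].dropna()
            row[p] = float(vals.median()) if len(vals) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
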