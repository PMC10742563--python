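"""Closed-loop four-element Windkessel (WK4) simulator.

The arterial tree is lumped into a proximal compliance C1, a distal compliance
C2, a peripheral resistance R and an inertance L, driven by a pulsatile inflow
q_in delivered by the heart:

    dq/dt   = (p_c - p_p) / L
    dp_c/dt = (q_in - q) / C1(t)
    dp_p/dt = (q - p_p / R) / C2

where p_c and p_p are central and peripheral pressures (mmHg) and q the flow
through the inertance (mL/s).  Slow hemodynamic drift is modelled by seeded
Ornstein--Uhlenbeck modulation of R, C1, stroke volume and heart rate; the
optical PPG surrogate is proportional to the distal vascular distension
C1(t) * p_p plus power-law ("fractal") and white observation noise.

Units: pressures mmHg, flows mL/s, R mmHg*s/mL, C mL/mmHg, L mmHg*s^2/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .signals import ou_track, powerlaw_noise

__all__ = [
    "SimConfig",
    "SimRecord",
    "IntegrationError",
    "make_inflow",
    "simulate_wk4",
]

TRANSIENT_S = 10.0  # initial span discarded by downstream analyses


class IntegrationError(RuntimeError):
    """Raised when the pressure state blows up (stiff/bad parameter set)."""


@dataclass
class SimConfig:
    """Configuration of one synthetic subject.

    ``fluct`` maps a parameter name in {"R", "C1", "sv", "hr"} to a pair
    (relative sigma, correlation time in s) for OU modulation; "sv" modulates
    cardiac output via the per-beat stroke volume.  ``frac_noise`` is the
    (amplitude in ppg units, spectral exponent beta) of additive 1/f^beta
    observation noise; ``noise_coupling_gain`` > 0 modulates that noise
    amplitude by the (delayed, smoothed, standardized) peripheral pressure,
    coupling fractal power to the hemodynamic state.
    """

    duration_s: float = 120.0
    fs: float = 50.0
    hr_bpm: float = 60.0
    sv_ml: float = 70.0
    R0: float = 1.0
    C1_0: float = 1.5
    C2_0: float = 0.1
    L0: float = 0.005
    fluct: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    frac_noise: tuple[float, float] = (0.0, 1.0)
    meas_noise_sd: float = 0.0
    seed: int = 0
    systole_fraction: float = 0.35
    ppg_gain: float = 1.0
    ppg_offset: float = 0.0
    optical_scale: float | None = 60.0  # Beer-Lambert curvature; None = linear
    noise_coupling_gain: float = 0.0
    noise_coupling_delay_s: float = 15.0

    def validate(self) -> None:
        for name in ("hr_bpm", "sv_ml", "R0", "C1_0", "C2_0", "L0", "fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fs * self.duration_s < 2:
            raise ValueError("duration too short for sampling rate")
        if not 0 < self.systole_fraction < 1:
            raise ValueError("systole_fraction must be in (0, 1)")
        for key, (rel, tau) in self.fluct.items():
            if key not in ("R", "C1", "sv", "hr"):
                raise ValueError(f"unknown fluctuation target {key!r}")
            if not 0 <= rel <= 0.5:
                raise ValueError("relative sigma must be in [0, 0.5]")
            if tau <= 0:
                raise ValueError("correlation time must be positive")
        amp, beta = self.frac_noise
        if amp < 0:
            raise ValueError("noise amplitude must be >= 0")
        if not 0 <= beta <= 2:
            raise ValueError("spectral exponent beta must be in [0, 2]")


@dataclass
class SimRecord:
    """Simulated record: state channels, observation channel, ground truth."""

    t: np.ndarray
    q_in: np.ndarray
    q: np.ndarray
    p_c: np.ndarray
    p_p: np.ndarray
    ppg: np.ndarray
    co_track: np.ndarray
    truth: pd.DataFrame  # per-beat parameter ground truth
    fs: float
    config: SimConfig

    def to_frame(self) -> pd.DataFrame:
        """Channels as a DataFrame with columns t, ppg, abp, co (ABP := p_p)."""
        return pd.DataFrame(
            {"t": self.t, "ppg": self.ppg, "abp": self.p_p, "co": self.co_track}
        )


def make_inflow(
    hr_bpm: float,
    sv_ml: float,
    fs: float,
    n_beats: int,
    systole_fraction: float = 0.35,
) -> np.ndarray:
    """Half-sine systolic ejection inflow train, zero in diastole.

    Each beat's numeric integral equals ``sv_ml`` (mL): the sampled half-sine
    is renormalized beat-by-beat so the discrete integral is exact.
    """
    if sv_ml <= 0 or hr_bpm <= 0:
        raise ValueError("hr_bpm and sv_ml must be positive")
    if not 30 <= hr_bpm <= 200:
        raise ValueError("hr_bpm outside physiological range [30, 200]")
    if not 0 < systole_fraction < 1:
        raise ValueError("systole_fraction must be in (0, 1)")
    period = 60.0 / hr_bpm
    onsets = period * np.arange(n_beats)
    n = int(round(n_beats * period * fs))
    t = np.arange(n) / fs
    return _inflow_on_grid(t, onsets, np.full(n_beats, period),
                           np.full(n_beats, sv_ml), systole_fraction, fs)


def _inflow_on_grid(t, onsets, periods, svs, systole_fraction, fs):
    """Sample per-beat half-sines onto grid ``t``, exact per-beat integrals."""
    q = np.zeros_like(t)
    dt = 1.0 / fs
    for onset, period, sv in zip(onsets, periods, svs):
        t_sys = systole_fraction * period
        i0 = int(np.ceil(onset * fs - 1e-9))
        i1 = int(np.ceil((onset + t_sys) * fs - 1e-9))
        i1 = min(i1, len(t))
        if i1 <= i0:
            continue
        phase = (t[i0:i1] - onset) / t_sys
        pulse = np.sin(np.pi * phase)
        area = pulse.sum() * dt
        if area > 0:
            q[i0:i1] += pulse * (sv / area)
    return q


def simulate_wk4(config: SimConfig) -> SimRecord:
    """Integrate the WK4 system with stochastic parameter drift.

    Fixed output grid at ``config.fs`` with 5 RK4 substeps per sample;
    parameters and inflow are linearly interpolated at substep times.  Fully
    reproducible for a given ``config.seed``.
    """
    config.validate()
    fs = config.fs
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs
    dt = 1.0 / fs

    seeds = np.random.SeedSequence(config.seed).spawn(6)
    rngs = [np.random.default_rng(s) for s in seeds]

    def track(name, base, rng):
        rel, tau = config.fluct.get(name, (0.0, 1.0))
        return ou_track(base, rel, tau, n, fs, rng)

    r_track = track("R", config.R0, rngs[0])
    c1_track = track("C1", config.C1_0, rngs[1])
    hr_track = track("hr", config.hr_bpm, rngs[2])
    sv_track = track("sv", config.sv_ml, rngs[3])

    # beat schedule from the instantaneous heart rate at each onset
    onsets, periods, svs = [], [], []
    t_beat = 0.0
    while t_beat < config.duration_s:
        idx = min(int(t_beat * fs), n - 1)
        hr = float(np.clip(hr_track[idx], 30.0, 200.0))
        onsets.append(t_beat)
        periods.append(60.0 / hr)
        svs.append(float(sv_track[idx]))
        t_beat += 60.0 / hr
    onsets = np.asarray(onsets)
    periods = np.asarray(periods)
    svs = np.asarray(svs)

    q_in = _inflow_on_grid(t, onsets, periods, svs, config.systole_fraction, fs)

    # instantaneous CO (L/min), piecewise constant per beat
    co_beats = (60.0 / periods) * svs / 1000.0
    beat_of_sample = np.searchsorted(onsets, t, side="right") - 1
    co_track = co_beats[np.clip(beat_of_sample, 0, len(co_beats) - 1)]

    p_p = np.empty(n)
    p_c = np.empty(n)
    q = np.empty(n)
    mean_inflow = config.hr_bpm * config.sv_ml / 60.0
    sq, sc, sp = 0.0, config.R0 * mean_inflow, config.R0 * mean_inflow
    q[0], p_c[0], p_p[0] = sq, sc, sp
    n_sub = 5
    h = dt / n_sub
    C2 = config.C2_0
    L = config.L0

    qi_l = q_in.tolist()
    c1_l = c1_track.tolist()
    r_l = r_track.tolist()
    for i in range(n - 1):
        j = i + 1 if i + 1 < n else i
        qi0, dqi = qi_l[i], qi_l[j] - qi_l[i]
        c10, dc1 = c1_l[i], c1_l[j] - c1_l[i]
        r0, dr = r_l[i], r_l[j] - r_l[i]
        for k in range(n_sub):
            f0 = k / n_sub
            f1 = (k + 0.5) / n_sub
            f2 = (k + 1.0) / n_sub
            # RK4 with parameters/inflow linearly interpolated at substeps
            qi_a, c1_a, r_a = qi0 + dqi * f0, c10 + dc1 * f0, r0 + dr * f0
            qi_b, c1_b, r_b = qi0 + dqi * f1, c10 + dc1 * f1, r0 + dr * f1
            qi_c, c1_c, r_c = qi0 + dqi * f2, c10 + dc1 * f2, r0 + dr * f2
            k1q = (sc - sp) / L
            k1c = (qi_a - sq) / c1_a
            k1p = (sq - sp / r_a) / C2
            q2, c2_, p2 = sq + 0.5 * h * k1q, sc + 0.5 * h * k1c, sp + 0.5 * h * k1p
            k2q = (c2_ - p2) / L
            k2c = (qi_b - q2) / c1_b
            k2p = (q2 - p2 / r_b) / C2
            q3, c3_, p3 = sq + 0.5 * h * k2q, sc + 0.5 * h * k2c, sp + 0.5 * h * k2p
            k3q = (c3_ - p3) / L
            k3c = (qi_b - q3) / c1_b
            k3p = (q3 - p3 / r_b) / C2
            q4, c4_, p4 = sq + h * k3q, sc + h * k3c, sp + h * k3p
            k4q = (c4_ - p4) / L
            k4c = (qi_c - q4) / c1_c
            k4p = (q4 - p4 / r_c) / C2
            sq += (h / 6.0) * (k1q + 2 * k2q + 2 * k3q + k4q)
            sc += (h / 6.0) * (k1c + 2 * k2c + 2 * k3c + k4c)
            sp += (h / 6.0) * (k1p + 2 * k2p + 2 * k3p + k4p)
        if abs(sc) > 1e4 or abs(sp) > 1e4:
            raise IntegrationError(
                f"pressure blow-up at t={t[i]:.2f}s with R0={config.R0}, "
                f"C1_0={config.C1_0}, C2_0={C2}, L0={L}"
            )
        q[i + 1], p_c[i + 1], p_p[i + 1] = sq, sc, sp

    # optical surrogate: distension volume v = C1(t) * p_p through a
    # Beer-Lambert-like exponential transduction (positive skewness, as in
    # transmission PPG); optical_scale=None degrades to the linear map
    v = c1_track * p_p
    if config.optical_scale is None:
        ppg = config.ppg_gain * v + config.ppg_offset
    else:
        v_ref = float(v.mean())
        ppg = (config.ppg_gain * v_ref
               * np.exp((v - v_ref) / config.optical_scale) + config.ppg_offset)
    amp, beta = config.frac_noise
    if amp > 0:
        noise = powerlaw_noise(n, beta, rngs[4], std=amp)
        # optical noise scales with local perfusion (pulsatile amplitude):
        # amplitude drift moves signal and noise power together, within and
        # across subjects, so the fractal power *fraction* is amplitude-
        # neutral; the amplitude parameter is calibrated at a reference
        # pulsatile sd of 25 signal units
        w10 = max(int(round(10.0 * fs)), 2)
        kern = np.ones(w10) / w10
        mean10 = np.convolve(ppg, kern, mode="same")
        var10 = np.convolve(ppg**2, kern, mode="same") - mean10**2
        rel = np.sqrt(np.clip(var10, 0.0, None)) / PULSATILE_REF_SD
        noise = noise * rel
        if config.noise_coupling_gain > 0:
            env = _pressure_envelope(
                p_p, fs, config.noise_coupling_delay_s, config.noise_coupling_gain
            )
            noise = noise * env
        ppg = ppg + noise
    if config.meas_noise_sd > 0:
        ppg = ppg + config.meas_noise_sd * rngs[5].standard_normal(n)

    onset_idx = np.round(onsets * fs).astype(int).clip(0, n - 1)
    truth = pd.DataFrame(
        {
            "onset_idx": onset_idx,
            "t": onsets,
            "period_s": periods,
            "hr_bpm": 60.0 / periods,
            "sv_ml": svs,
            "co_lmin": co_beats,
            "R": r_track[onset_idx],
            "C1": c1_track[onset_idx],
        }
    )
    return SimRecord(
        t=t, q_in=q_in, q=q, p_c=p_c, p_p=p_p, ppg=ppg,
        co_track=co_track, truth=truth, fs=fs, config=config,
    )


PRESSURE_ENVELOPE_SCALE_MMHG = 5.0
PULSATILE_REF_SD = 25.0  # reference pulsatile sd (a.u.) for noise calibration


def _pressure_envelope(p_p, fs, delay_s, gain):
    """Noise-amplitude envelope exp(gain * dp(t - delay) / 5 mmHg), where dp
    is the deviation of the 10 s moving-average peripheral pressure from its
    record mean.  Monotone in the pressure excursion (so a lagged, linear
    causal footprint is present) and, via the fixed 5 mmHg reference, the
    injected fractal power grows with the subject's absolute hemodynamic
    fluctuation."""
    w = max(int(round(10.0 * fs)), 1)
    kernel = np.ones(w) / w
    slow = np.convolve(p_p, kernel, mode="same")
    z = (slow - slow.mean()) / PRESSURE_ENVELOPE_SCALE_MMHG
    d = int(round(delay_s * fs))
    z_del = np.concatenate([np.full(d, z[0]), z[:-d]]) if d > 0 else z
    return np.exp(gain * np.clip(z_del, -6.0, 6.0))
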