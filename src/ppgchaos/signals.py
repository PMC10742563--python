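"""Reference synthetic signals: colored (power-law) noise, fractional Brownian
motion, Ornstein--Uhlenbeck tracks and the Roessler attractor.

These generators provide signals with *known* spectral or fractal properties
(spectral exponent beta, Hurst exponent H, embedding dimension) against which
the spectral-separation and complexity estimators can be validated.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "powerlaw_noise",
    "fgn",
    "fbm",
    "ou_track",
    "roessler",
]


def powerlaw_noise(
    n: int,
    beta: float,
    rng: np.random.Generator | int | None = None,
    *,
    std: float = 1.0,
) -> np.ndarray:
    """Gaussian noise with power spectral density ~ 1/f**beta.

    Generated by shaping the Fourier amplitudes of white Gaussian noise with
    f**(-beta/2); beta=0 gives white noise, beta=2 a Brownian-like walk.
    The output is normalized to zero mean and standard deviation ``std``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(rng)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.empty_like(f)
    scale[0] = 0.0  # no DC power
    scale[1:] = f[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spec * scale, n)
    x -= x.mean()
    s = x.std()
    if s > 0:
        x *= std / s
    return x


def fgn(n: int, hurst: float, rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Fractional Gaussian noise via Davies-Harte circulant embedding.

    Exact stationary increments of fBm with Hurst exponent ``hurst`` in (0, 1),
    unit variance per step.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must be in (0, 1)")
    rng = np.random.default_rng(rng)
    if abs(hurst - 0.5) < 1e-12:
        return rng.standard_normal(n)
    # autocovariance of fGn
    k = np.arange(n + 1)
    gamma = 0.5 * (
        np.abs(k - 1) ** (2 * hurst) - 2 * k ** (2 * hurst) + (k + 1) ** (2 * hurst)
    )
    # circulant embedding of size 2n
    row = np.concatenate([gamma[:-1], gamma[n:0:-1]])
    eig = np.fft.fft(row).real
    if eig.min() < -1e-8:
        raise RuntimeError("circulant embedding not nonnegative definite")
    eig = np.clip(eig, 0.0, None)
    m = 2 * n
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    w = np.fft.fft(z * np.sqrt(eig / (2 * m)))
    return w[:n].real * np.sqrt(2.0)


def fbm(n: int, hurst: float, rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Fractional Brownian motion path of length ``n`` (cumulated fGn)."""
    return np.cumsum(fgn(n, hurst, rng))


def ou_track(
    base: float,
    rel_sigma: float,
    tau_s: float,
    n: int,
    fs: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck modulation track.

    Mean ``base``, stationary standard deviation ``rel_sigma * base`` and
    correlation time ``tau_s`` seconds, sampled at ``fs`` Hz using the exact
    discretization x_{k+1} = mu + a (x_k - mu) + s sqrt(1 - a^2) z_k with
    a = exp(-dt / tau).  Values are clipped to [0.2 base, 5 base] to keep
    physiological parameters positive and bounded.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    if rel_sigma < 0:
        raise ValueError("rel_sigma must be >= 0")
    rng = np.random.default_rng(rng)
    if rel_sigma == 0:
        return np.full(n, float(base))
    a = np.exp(-1.0 / (fs * tau_s))
    s = rel_sigma * base
    innov = s * np.sqrt(1.0 - a * a) * rng.standard_normal(n)
    x = np.empty(n)
    x[0] = base + s * rng.standard_normal()
    for k in range(1, n):
        x[k] = base + a * (x[k - 1] - base) + innov[k]
    return np.clip(x, 0.2 * base, 5.0 * base)


def roessler(
    n: int,
    dt: float = 0.12,
    a: float = 0.2,
    b: float = 0.2,
    c: float = 5.7,
    x0: tuple[float, float, float] = (1.0, 1.0, 0.0),
    transient: float = 200.0,
) -> np.ndarray:
    """x-coordinate of the Roessler attractor, the canonical 3D chaotic flow.

    Integrated with an adaptive RK45 and sampled every ``dt`` time units after
    discarding ``transient`` time units.  Used as a ground-truth series whose
    minimal delay-embedding dimension is 3.
    """
    def rhs(_t, s):
        x, y, z = s
        return [-y - z, x + a * y, b + z * (x - c)]

    t_end = transient + n * dt
    t_eval = transient + dt * np.arange(n)
    sol = solve_ivp(rhs, (0.0, t_end), x0, t_eval=t_eval, rtol=1e-9, atol=1e-9)
    if not sol.success:
        raise RuntimeError("Roessler integration failed")
    return sol.y[0]
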