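"""IRASA separation of fractal and oscillatory spectral components.

Irregular-resampling auto-spectral analysis: the signal is resampled by
noninteger factor pairs (h, 1/h); oscillatory peaks shift by h-dependent
offsets while a power-law (fractal) spectrum is h-invariant, so the median
over h of the geometric-mean PSDs sqrt(S_h * S_1/h) isolates the fractal
component.  The fractal power fraction, the log-log power-law fit (spectral
exponent beta with its variance-covariance uncertainty) and a Morse-wavelet
component decomposition complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly, welch
from scipy.stats import linregress

__all__ = [
    "SpectralSplit",
    "PowerLawFit",
    "WaveletBank",
    "DEFAULT_HSET",
    "MORSE_CENTER_FREQS",
    "irasa_split",
    "fractal_fraction",
    "fit_powerlaw",
    "wavelet_components",
]

# original IRASA convention: 17 factors 1.1, 1.15, ..., 1.9
DEFAULT_HSET = tuple(np.round(np.arange(1.1, 1.901, 0.05), 2))

DEFAULT_BAND = (0.5, 10.0)  # Hz, raw 50 Hz PPG
WELCH_SEG_S = 10.0  # Welch segment length (s), 50% overlap, Hann

# Morse component center frequencies: sqrt(2)-spaced from 11.63 Hz down to 0.4 Hz
MORSE_CENTER_FREQS = tuple(
    float(f) for f in np.round(11.63 * 2.0 ** (-0.5 * np.arange(10)), 2) if f >= 0.4
)


@dataclass
class SpectralSplit:
    """Total/fractal/oscillatory PSD triple on a common frequency grid.

    The oscillatory PSD is the raw difference total - fractal and may be
    negative pointwise; clipping happens only when integrating the fraction.
    """

    freqs: np.ndarray
    psd_total: np.ndarray
    psd_fractal: np.ndarray
    band: tuple[float, float]
    hset: tuple[float, ...]

    @property
    def psd_oscillatory(self) -> np.ndarray:
        return self.psd_total - self.psd_fractal


@dataclass
class PowerLawFit:
    beta: float  # spectral exponent (PSD ~ 1/f^beta)
    log_intercept: float
    rel_uncertainty_pct: float  # 100 * SE(slope) / |slope|


def _welch_psd(x, fs, nperseg):
    nperseg = min(nperseg, len(x))
    return welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2, window="hann")


def irasa_split(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = DEFAULT_BAND,
    hset: tuple[float, ...] = DEFAULT_HSET,
    seg_s: float = WELCH_SEG_S,
) -> SpectralSplit:
    """Split the PSD of ``x`` into fractal and oscillatory parts.

    For each h the signal is polyphase-resampled (anti-aliased) by h and 1/h,
    both PSDs are estimated by Welch (``seg_s``-second Hann segments, 50%
    overlap) *at the nominal rate fs*, and the fractal PSD is the median over
    h of the geometric means sqrt(S_h * S_1/h), restricted to ``band``.
    """
    x = np.asarray(x, dtype=float)
    f_lo, f_hi = band
    if f_lo <= 0 or f_hi <= f_lo:
        raise ValueError("band must satisfy 0 < f_lo < f_hi")
    hmax = max(hset)
    feasible = fs / 2.0 / hmax
    if f_hi > feasible + 1e-9:
        raise ValueError(
            f"band upper edge {f_hi} Hz exceeds Nyquist/max(h) = {feasible:.3g} Hz"
        )
    if len(x) < 2 * fs / f_lo:
        raise ValueError("signal too short for the requested lower band edge")
    if any(h <= 1.0 for h in hset):
        raise ValueError("resampling factors must be > 1")

    nperseg = int(round(seg_s * fs))
    freqs, total = _welch_psd(x, fs, nperseg)

    frac_layers = []
    for h in hset:
        fr = Fraction(h).limit_denominator(100)
        up = resample_poly(x, fr.numerator, fr.denominator)
        dn = resample_poly(x, fr.denominator, fr.numerator)
        _, s_up = _welch_psd(up, fs, nperseg)
        _, s_dn = _welch_psd(dn, fs, nperseg)
        m = min(len(s_up), len(s_dn), len(total))
        layer = np.sqrt(s_up[:m] * s_dn[:m])
        frac_layers.append(np.pad(layer, (0, len(total) - m), constant_values=np.nan))
    fractal = np.nanmedian(np.vstack(frac_layers), axis=0)

    keep = (freqs >= f_lo) & (freqs <= f_hi)
    return SpectralSplit(
        freqs=freqs[keep], psd_total=total[keep], psd_fractal=fractal[keep],
        band=band, hset=tuple(hset),
    )


def fractal_fraction(split: SpectralSplit) -> float:
    """Percentage of band power attributed to the fractal component.

    100 * integral(psd_fractal) / integral(psd_total), trapezoidal over the
    band, clipped to [0, 100].  NaN if the total power is zero.
    """
    total = np.trapezoid(split.psd_total, split.freqs)
    if total <= 0:
        return float("nan")
    frac = np.trapezoid(split.psd_fractal, split.freqs)
    return float(np.clip(100.0 * frac / total, 0.0, 100.0))


def fit_powerlaw(split: SpectralSplit) -> PowerLawFit:
    """OLS power-law fit of the fractal PSD: log10 S = c - beta * log10 f.

    The relative uncertainty is the slope's standard error (from the fit's
    variance-covariance matrix) as a percentage of |slope|.
    """
    pos = split.psd_fractal > 0
    if pos.sum() < 10:
        raise ValueError("need >= 10 positive fractal-PSD bins for the fit")
    lx = np.log10(split.freqs[pos])
    ly = np.log10(split.psd_fractal[pos])
    res = linregress(lx, ly)
    beta = -res.slope
    rel = 100.0 * res.stderr / abs(res.slope) if res.slope != 0 else float("inf")
    return PowerLawFit(beta=float(beta), log_intercept=float(res.intercept),
                       rel_uncertainty_pct=float(rel))


@dataclass
class WaveletBank:
    """Real component time series per Morse-wavelet center frequency."""

    center_freqs: tuple[float, ...]  # Hz, descending
    components: np.ndarray  # shape (n_freqs, n_samples)
    fs: float


def _morse_filter(omega: np.ndarray, scale: float, gamma: float, beta: float) -> np.ndarray:
    """Generalized Morse wavelet in the frequency domain, peak value 2."""
    w = scale * omega
    psi = np.zeros_like(w)
    pos = w > 0
    wp = (beta / gamma) ** (1.0 / gamma)  # peak (radian) frequency
    lognorm = beta * np.log(wp) - wp**gamma
    psi[pos] = 2.0 * np.exp(beta * np.log(w[pos]) - w[pos] ** gamma - lognorm)
    return psi


def wavelet_components(
    x: np.ndarray,
    fs: float,
    center_freqs: tuple[float, ...] = MORSE_CENTER_FREQS,
    gamma: float = 3.0,
    time_bandwidth: float = 60.0,
) -> WaveletBank:
    """Morse-wavelet (analytic CWT) component decomposition.

    Each component is the real part of the continuous wavelet transform of
    ``x`` at the scale whose peak frequency equals the requested center
    frequency, computed by frequency-domain filtering with a generalized
    Morse wavelet (symmetry gamma = 3, time-bandwidth product 60).
    Frequencies above Nyquist are skipped with a warning.
    """
    import warnings

    x = np.asarray(x, dtype=float)
    n = len(x)
    beta = time_bandwidth / gamma
    omega = 2.0 * np.pi * np.fft.rfftfreq(n, 1.0 / fs)
    wp = (beta / gamma) ** (1.0 / gamma)
    X = np.fft.rfft(x)
    kept, comps = [], []
    for fc in center_freqs:
        if fc >= fs / 2.0:
            warnings.warn(f"center frequency {fc} Hz >= Nyquist; skipped")
            continue
        scale = wp / (2.0 * np.pi * fc)
        psi = _morse_filter(omega, scale, gamma, beta)
        w = np.fft.irfft(X * psi, n)  # real part of the analytic CWT
        kept.append(fc)
        comps.append(w)
    return WaveletBank(tuple(kept), np.vstack(comps) if comps else np.empty((0, n)), fs)
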