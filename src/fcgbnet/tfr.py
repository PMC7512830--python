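"""Wavelet time-frequency transform of the network-entropy series.

The entropy series NE_k rides on a large offset (near log2(n_edges) bits),
so it is mean-removed by default and then decomposed with a continuous
wavelet transform on a geometric grid of 1024 scales whose
pseudo-frequencies tile the band (0, fs_ne / 2].  The mother wavelet is the
discrete Meyer wavelet ("dmey"), which has no closed form: its waveform is
sampled on a fine grid via the cascade construction and the transform is
evaluated through the wavelet's precomputed spectrum (frequency-domain
CWT), the standard discrete approximation for such wavelets.  L1
normalization (kernel scaled by 1/a) is used so a pure tone attains its
power maximum at the scale whose pseudo-frequency equals the tone
frequency.

Pseudo-frequency follows the usual map  f = f_c / (a * dt)  with f_c the
wavelet center frequency (spectral peak of the sampled waveform).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Tuple

import numpy as np
import pywt

from .entropy import NESeries
from .io import AnalysisConfig

__all__ = ["Scalogram", "scale_to_frequency", "frequency_grid", "cwt", "ne_scalogram"]


@dataclass
class Scalogram:
    """Time x scale power map of the entropy series.

    ``power`` is (n_scales x K); rows follow ``scales`` (ascending), so
    ``freqs_hz`` is descending.  ``coi_halfwidth_s[j]`` is the half-width of
    the wavelet support at scale j: within that distance of either edge,
    coefficients are affected by the boundary (cone of influence).
    """

    power: np.ndarray
    freqs_hz: np.ndarray
    scales: np.ndarray
    times_s: np.ndarray
    band_interest_hz: Tuple[float, float]
    coi_halfwidth_s: np.ndarray


def scale_to_frequency(scale: float, wavelet_center_freq_hz: float, dt_s: float) -> float:
    """Pseudo-frequency (Hz) of a scale: f_c / (scale * dt)."""
    if scale <= 0 or dt_s <= 0 or wavelet_center_freq_hz <= 0:
        raise ValueError("scale, center frequency and dt must be positive")
    return wavelet_center_freq_hz / (scale * dt_s)


def frequency_to_scale(freq_hz: float, wavelet_center_freq_hz: float, dt_s: float) -> float:
    if freq_hz <= 0:
        raise ValueError("frequency must be positive")
    return wavelet_center_freq_hz / (freq_hz * dt_s)


@lru_cache(maxsize=8)
def _mother(wavelet_name: str, precision: int = 10):
    """Finely sampled mother wavelet psi(x) and its grid."""
    if wavelet_name in pywt.wavelist(kind="discrete"):
        w = pywt.Wavelet(wavelet_name)
        _, psi, x = w.wavefun(level=precision)
    else:
        w = pywt.ContinuousWavelet(wavelet_name)
        psi, x = w.wavefun(precision=precision)
        psi = np.real(psi)
    return np.asarray(psi, float), np.asarray(x, float)


@lru_cache(maxsize=8)
def _mother_spectrum(wavelet_name: str, n_pad: int = 1 << 19):
    """Spectrum of the mother wavelet, phase-centered at its magnitude peak.

    Returns (nu, spec): positive frequencies nu in cycles per natural unit
    and the complex spectrum of psi(t + t_peak).  Centering the phase here
    is what keeps the time-domain transform aligned (an impulse peaks at
    its own epoch at every scale).
    """
    psi, x = _mother(wavelet_name)
    dx = x[1] - x[0]
    t_peak = x[np.argmax(np.abs(psi))]
    spec = np.fft.rfft(psi, n_pad) * dx
    nu = np.fft.rfftfreq(n_pad, dx)
    spec *= np.exp(2j * np.pi * nu * (t_peak - x[0]))
    return nu, spec


def center_frequency(wavelet_name: str) -> float:
    """Spectral-peak frequency of the mother wavelet, cycles per unit x.

    Computed as the argmax of the same finely sampled spectrum the
    transform itself evaluates, so the scale-to-frequency map and the
    transform's frequency response peak are consistent by construction.
    """
    nu, spec = _mother_spectrum(wavelet_name)
    return float(nu[np.argmax(np.abs(spec))])


def frequency_grid(
    n_scales: int, f_max_hz: float, f_min_hz: float
) -> np.ndarray:
    """Geometric (log-uniform) frequency grid, descending from f_max to f_min."""
    if not (0 < f_min_hz < f_max_hz):
        raise ValueError("require 0 < f_min < f_max")
    if n_scales < 2:
        raise ValueError("need at least 2 scales")
    return np.geomspace(f_max_hz, f_min_hz, n_scales)


def cwt(
    signal: np.ndarray,
    scales: np.ndarray,
    wavelet_name: str = "dmey",
    dt_s: float = 1.0,
) -> np.ndarray:
    """Continuous wavelet transform, evaluated in the frequency domain.

    W(a, b) = (1/a) * integral x(t) psi((t - b)/a) dt, computed as
    irfft(X(f) * conj(Psi(a f))) with one precomputed mother spectrum Psi,
    so every scale samples the same smooth frequency response (no per-scale
    kernel resampling noise).  The signal is extended periodically (plain
    length-N DFT); the series is mean-removed upstream, which keeps the
    wrap discontinuity small, and edge trust is described by the cone of
    influence.  L1 normalization: a pure tone's power is maximal at the
    scale whose pseudo-frequency equals the tone frequency.
    """
    x = np.asarray(signal, dtype=float)
    scales = np.asarray(scales, dtype=float)
    if np.any(scales <= 0):
        raise ValueError("scales must be positive")
    n = x.size
    n_fft = n  # periodic extension
    X = np.fft.rfft(x, n_fft)
    f = np.fft.rfftfreq(n_fft)  # cycles per sample
    nu, spec = _mother_spectrum(wavelet_name)
    coefs = np.empty((len(scales), n))
    for j, a in enumerate(scales):
        arg = a * f  # natural-unit frequency seen by this scale
        resp_re = np.interp(arg, nu, spec.real, right=0.0)
        resp_im = np.interp(arg, nu, spec.imag, right=0.0)
        w = np.fft.irfft(X * (resp_re - 1j * resp_im), n_fft)
        coefs[j] = w[:n]
    return coefs


def ne_scalogram(ne: NESeries, cfg: Optional[AnalysisConfig] = None) -> Scalogram:
    """Power scalogram of a network-entropy series.

    The series is mean-removed (unless ``cfg.keep_dc``), transformed on
    ``cfg.n_scales`` scales spanning pseudo-frequencies from
    ``min(cfg.band_max_hz, fs_ne / 2)`` down to ``cfg.min_freq_hz``, and
    squared into power.  The default grid floor keeps only frequencies the
    series can resolve: at least two full cycles over the record, but never
    above f_max / 16 so the grid always spans a usable range.
    """
    cfg = cfg or AnalysisConfig()
    K = len(ne)
    if K < 16:
        raise ValueError(f"series too short for time-frequency analysis (K={K})")
    nyq = ne.fs_ne / 2.0
    f_max = min(cfg.band_max_hz, nyq)
    if abs(cfg.band_max_hz - nyq) > 1e-9 * max(nyq, 1.0):
        warnings.warn(
            f"configured band_max_hz={cfg.band_max_hz} differs from the "
            f"series Nyquist {nyq} Hz implied by SL; using {f_max} Hz",
            stacklevel=2,
        )
    if cfg.min_freq_hz is not None:
        f_min = cfg.min_freq_hz
    else:
        f_min = min(2.0 * ne.fs_ne / K, f_max / 16.0)
    freqs = frequency_grid(cfg.n_scales, f_max, f_min)
    dt = 1.0 / ne.fs_ne
    fc = center_frequency(cfg.wavelet_name)
    scales = fc / (freqs * dt)

    x = ne.values.astype(float)
    if not cfg.keep_dc:
        x = x - x.mean()
    if np.ptp(x) == 0.0:
        warnings.warn("constant entropy series: scalogram power is zero", stacklevel=2)
        power = np.zeros((cfg.n_scales, K))
    else:
        coefs = cwt(x, scales, wavelet_name=cfg.wavelet_name, dt_s=dt)
        power = coefs**2

    psi, grid = _mother(cfg.wavelet_name)
    half_support = (grid[-1] - grid[0]) / 2.0
    coi = half_support * scales * dt
    return Scalogram(
        power=power,
        freqs_hz=freqs,
        scales=scales,
        times_s=np.asarray(ne.epoch_times, float),
        band_interest_hz=tuple(cfg.band_interest_hz),
        coi_halfwidth_s=coi,
    )
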