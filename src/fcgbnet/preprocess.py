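"""Wavelet band selection and coefficient thresholding for artifact control.

Raw EEG is reduced to a single dyadic detail band of a multilevel discrete
wavelet decomposition (discrete Meyer wavelet by default).  At fs = 300 Hz
the band 18.75-37.50 Hz is exactly the level-3 detail band
[fs / 2^4, fs / 2^3]; the decomposition depth is derived from the requested
band and the sampling rate, and non-dyadic requests are rejected rather
than approximated.

Movement and muscle artifacts are then suppressed by zeroing, per channel
and per pass, every retained-band coefficient exceeding
mean(C) + k * std(C) (k = 2, population std, one-sided on the signed
values); the rule is applied twice by default.  The corrected signal is
reconstructed from the retained band alone, so output energy never exceeds
input energy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pywt

from .io import EEGRecording

__all__ = ["WaveletBandSpec", "dyadic_level", "band_select", "threshold_correct"]


@dataclass
class WaveletBandSpec:
    """A dyadic detail band to retain: [fs / 2^(level+1), fs / 2^level]."""

    wavelet_name: str = "dmey"
    level: Optional[int] = None  # derived from keep_band when None
    keep_band: Tuple[float, float] = (18.75, 37.50)

    def resolve_level(self, fs: float) -> int:
        if self.level is not None:
            return self.level
        return dyadic_level(fs, self.keep_band)


def dyadic_level(fs: float, keep_band: Tuple[float, float], rtol: float = 1e-9) -> int:
    """Depth d such that [fs / 2^(d+1), fs / 2^d] equals ``keep_band``.

    Raises when the band is not representable as a dyadic detail band of
    this sampling rate (no silent approximation).
    """
    low, high = keep_band
    if not (0 < low < high <= fs / 2 * (1 + rtol)):
        raise ValueError(f"invalid band {keep_band} for fs={fs}")
    for d in range(1, 32):
        lo, hi = fs / 2 ** (d + 1), fs / 2**d
        if abs(lo - low) <= rtol * lo and abs(hi - high) <= rtol * hi:
            return d
    raise ValueError(
        f"band {keep_band} Hz is not a dyadic detail band at fs={fs} Hz; "
        "choose [fs/2^(d+1), fs/2^d] for some integer d"
    )


def _check_length(n_samples: int, wavelet: pywt.Wavelet, level: int) -> None:
    max_level = pywt.dwt_max_level(n_samples, wavelet.dec_len)
    if level > max_level:
        raise ValueError(
            f"signal of {n_samples} samples too short for level {level} "
            f"decomposition with '{wavelet.name}' (max usable level {max_level})"
        )


def _band_coeffs(x: np.ndarray, wavelet: pywt.Wavelet, level: int):
    """Full coefficient list and the index of the retained detail band."""
    coeffs = pywt.wavedec(x, wavelet, level=level)
    # coeffs = [cA_level, cD_level, cD_{level-1}, ..., cD_1]; the deepest
    # detail band cD_level spans [fs/2^(level+1), fs/2^level]
    return coeffs, 1


def _reconstruct_band_only(coeffs, keep_idx: int, wavelet, n: int) -> np.ndarray:
    kept = [np.zeros_like(c) for c in coeffs]
    kept[keep_idx] = coeffs[keep_idx]
    y = pywt.waverec(kept, wavelet)
    return y[:n]


def band_select(rec: EEGRecording, spec: WaveletBandSpec) -> EEGRecording:
    """Retain one dyadic detail band of every channel; zero all other subbands."""
    level = spec.resolve_level(rec.fs)
    lo, hi = rec.fs / 2 ** (level + 1), rec.fs / 2**level
    blo, bhi = spec.keep_band
    if abs(lo - blo) > 1e-9 * lo or abs(hi - bhi) > 1e-9 * hi:
        raise ValueError(
            f"level {level} detail band [{lo}, {hi}] Hz does not match "
            f"keep_band {spec.keep_band}"
        )
    wavelet = pywt.Wavelet(spec.wavelet_name)
    _check_length(rec.n_samples, wavelet, level)
    out = np.empty_like(rec.data)
    for i in range(rec.n_channels):
        coeffs, keep = _band_coeffs(rec.data[i], wavelet, level)
        out[i] = _reconstruct_band_only(coeffs, keep, wavelet, rec.n_samples)
    return EEGRecording(out, fs=rec.fs, channels=list(rec.channels), t0=rec.t0)


def threshold_coefficients(
    C: np.ndarray, k_sigma: float = 2.0, use_abs: bool = False
) -> np.ndarray:
    """One pass of the artifact rule: zero coefficients above mean + k*std.

    ``std`` is the population standard deviation.  The default rule is
    one-sided on the signed coefficient values (strict '>');
    ``use_abs=True`` switches to the symmetric |C| variant.
    """
    C = np.asarray(C, dtype=float).copy()
    ref = np.abs(C) if use_abs else C
    thr = ref.mean() + k_sigma * ref.std()
    C[ref > thr] = 0.0
    return C


def threshold_correct(
    rec: EEGRecording,
    spec: WaveletBandSpec,
    n_passes: int = 2,
    k_sigma: float = 2.0,
    use_abs: bool = False,
) -> EEGRecording:
    """Band-select and artifact-threshold every channel.

    Per channel: decompose, keep the configured detail band, apply the
    mean + k*std zeroing rule ``n_passes`` times to that band's
    coefficients (recomputing mean and std each pass), reconstruct from the
    corrected band.
    """
    if n_passes < 1:
        raise ValueError("n_passes must be >= 1")
    if k_sigma <= 0:
        raise ValueError("k_sigma must be positive")
    level = spec.resolve_level(rec.fs)
    wavelet = pywt.Wavelet(spec.wavelet_name)
    _check_length(rec.n_samples, wavelet, level)
    out = np.empty_like(rec.data)
    for i in range(rec.n_channels):
        coeffs, keep = _band_coeffs(rec.data[i], wavelet, level)
        C = coeffs[keep]
        for _ in range(n_passes):
            C = threshold_coefficients(C, k_sigma=k_sigma, use_abs=use_abs)
        coeffs[keep] = C
        out[i] = _reconstruct_band_only(coeffs, keep, wavelet, rec.n_samples)
    return EEGRecording(out, fs=rec.fs, channels=list(rec.channels), t0=rec.t0)
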