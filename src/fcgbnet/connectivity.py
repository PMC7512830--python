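"""Sliding-window cross-correlation connectivity.

Each analysis window yields one functional connectivity matrix F whose
off-diagonal entry gamma_ij is the absolute normalized equal-time
cross-correlation of channels i and j over the window,

    gamma_ij = | CC(s_i, s_j)(0) | / sqrt( CC(s_i, s_i)(0) * CC(s_j, s_j)(0) ),

with CC the raw (not mean-removed) lagged inner product

    CC(x, y)(tau) = sum_{t=1}^{N - tau} x(t + tau) * y(t),   tau >= 0,
    CC(x, y)(-tau) = CC(y, x)(tau).

gamma_ij lies in [0, 1] by Cauchy-Schwarz; the diagonal is forced to zero
so self-connections never enter the edge-weight distribution.  The window
of length L = window_mult * SL slides in steps of SL samples, producing one
matrix per epoch k covering samples [1 + m, L + m] with m = (k - 1) * SL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List

import numpy as np

from .exceptions import DegenerateSignalError
from .io import AnalysisConfig, EEGRecording

__all__ = [
    "ConnectivityMatrix",
    "FCGBSequence",
    "crosscorr_pair",
    "connectivity_matrix",
    "build_fcgb_sequence",
]


@dataclass
class ConnectivityMatrix:
    """One epoch's symmetric connectivity matrix with zero diagonal."""

    values: np.ndarray
    epoch_index: int = 0
    epoch_time_s: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != m:
            raise ValueError("connectivity matrix must be square")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2


@dataclass
class FCGBSequence:
    """Ordered connectivity matrices from a sliding-window sweep."""

    matrices: List[ConnectivityMatrix]
    sl_samples: int
    window_samples: int
    fs: float

    def __len__(self) -> int:
        return len(self.matrices)

    @property
    def epoch_times(self) -> np.ndarray:
        return np.array([m.epoch_time_s for m in self.matrices])

    @property
    def fs_ne(self) -> float:
        """Sampling rate (Hz) of any per-epoch series derived from this sequence."""
        return self.fs / self.sl_samples


def crosscorr_pair(x, y, tau: int = 0, pearson: bool = False) -> float:
    """Normalized absolute cross-correlation of two windows at lag ``tau``.

    The lag machinery implements the full signed-lag rule
    CC(x, y)(-tau) = CC(y, x)(tau); the pipeline itself always uses tau = 0.
    With ``pearson=True`` the channel means are removed first (a common
    variant; the default is the raw inner product).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 2:
        raise ValueError("vectors must have length >= 2")
    if abs(tau) >= n:
        raise ValueError(f"|tau| must be < N (got tau={tau}, N={n})")
    if pearson:
        x = x - x.mean()
        y = y - y.mean()
    if tau < 0:
        x, y, tau = y, x, -tau
    ex = float(np.dot(x, x))
    ey = float(np.dot(y, y))
    if ex == 0.0 or ey == 0.0:
        raise DegenerateSignalError("zero-energy signal: correlation undefined")
    num = float(np.dot(x[tau:], y[: n - tau]))
    return abs(num) / math.sqrt(ex * ey)


def connectivity_matrix(
    window: np.ndarray,
    epoch_index: int = 0,
    epoch_time_s: float = 0.0,
    pearson: bool = False,
    channels=None,
) -> ConnectivityMatrix:
    """Equal-time connectivity matrix of one channels x samples window."""
    w = np.asarray(window, dtype=float)
    if w.ndim != 2:
        raise ValueError("window must be channels x samples")
    n_ch, n_s = w.shape
    if n_s < 2:
        raise ValueError("window must span at least 2 samples")
    if pearson:
        w = w - w.mean(axis=1, keepdims=True)
    gram = w @ w.T
    energy = np.diag(gram)
    dead = np.flatnonzero(energy == 0.0)
    if dead.size:
        name = channels[dead[0]] if channels is not None else f"index {dead[0]}"
        raise DegenerateSignalError(
            f"channel {name} has zero energy in epoch {epoch_index}"
        )
    norm = np.sqrt(energy)
    values = np.abs(gram) / np.outer(norm, norm)
    np.clip(values, 0.0, 1.0, out=values)  # guard rounding above 1
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(values, epoch_index, epoch_time_s)


def n_epochs(n_samples: int, sl: int, window: int) -> int:
    """Number of full windows: floor((n_samples - L) / SL) + 1."""
    if n_samples < window:
        raise ValueError(
            f"recording shorter than one window ({n_samples} < {window} samples)"
        )
    return (n_samples - window) // sl + 1


def build_fcgb_sequence(rec: EEGRecording, cfg: AnalysisConfig) -> FCGBSequence:
    """Slide the analysis window over a recording, one matrix per epoch.

    Epoch k (1-based) covers samples [1 + m, L + m], m = (k - 1) * SL, and
    is stamped with its window-start time (k - 1) * SL / fs seconds.
    Incomplete tail windows are dropped rather than zero-padded.
    """
    sl = cfg.resolve_sl(rec.fs)
    window = cfg.window_mult * sl
    k_total = n_epochs(rec.n_samples, sl, window)
    matrices = []
    for k in range(k_total):
        start = k * sl
        mat = connectivity_matrix(
            rec.data[:, start : start + window],
            epoch_index=k,
            epoch_time_s=rec.t0 + start / rec.fs,
            pearson=cfg.pearson,
            channels=rec.channels,
        )
        matrices.append(mat)
    return FCGBSequence(matrices, sl_samples=sl, window_samples=window, fs=rec.fs)
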