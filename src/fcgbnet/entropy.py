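"""Network entropy of connectivity graphs.

The upper-triangular edge weights {gamma_1 ... gamma_n}, n = E(E-1)/2, of a
symmetric connectivity matrix are normalized to a probability vector
p_i = gamma_i / sum_j gamma_j and scored with the Shannon entropy

    NE = - sum_i p_i log2 p_i        (bits),

with the continuity convention 0 * log 0 = 0.  NE is maximal (log2 n) when
interactive information is spread evenly over all edges and falls as weight
concentrates on few edges; applied per sliding-window epoch it yields a
time series NE_k sampled at fs / SL Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivityMatrix, FCGBSequence
from .exceptions import DegenerateGraphError

__all__ = ["NESeries", "correlation_sequence", "network_entropy", "ne_series"]


@dataclass
class NESeries:
    """Per-epoch network entropy in bits, with the epoch time axis."""

    values: np.ndarray
    epoch_times: np.ndarray
    n_edges: int
    fs_ne: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.epoch_times = np.asarray(self.epoch_times, dtype=float)
        if self.values.shape != self.epoch_times.shape:
            raise ValueError("values and epoch_times must have equal length")

    def __len__(self) -> int:
        return self.values.size

    @property
    def max_bits(self) -> float:
        return float(np.log2(self.n_edges))


def correlation_sequence(F: ConnectivityMatrix) -> np.ndarray:
    """Normalized upper-triangular edge-weight sequence of one matrix.

    Returns p with p_i = gamma_i / sum(gamma), enumerated row-major over the
    strict upper triangle.  Raises when every edge weight is zero.
    """
    vals = F.values if isinstance(F, ConnectivityMatrix) else np.asarray(F, float)
    iu = np.triu_indices(vals.shape[0], k=1)
    gamma = vals[iu]
    total = gamma.sum()
    if total <= 0.0:
        raise DegenerateGraphError(
            "all upper-triangular weights are zero; entropy undefined"
        )
    p = gamma / total
    # pin the sum to 1 exactly against accumulated rounding
    p[-1] += 1.0 - p.sum()
    return p


def network_entropy(p) -> float:
    """Shannon entropy (bits) of a probability vector; 0*log0 := 0."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1 (got {p.sum()!r})")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def ne_series(seq: FCGBSequence) -> NESeries:
    """Network entropy of every epoch of an FCGB sequence."""
    if len(seq) == 0:
        raise ValueError("empty FCGB sequence")
    values = np.empty(len(seq))
    for i, mat in enumerate(seq.matrices):
        try:
            values[i] = network_entropy(correlation_sequence(mat))
        except DegenerateGraphError as exc:
            raise DegenerateGraphError(f"epoch {i}: {exc}") from exc
    return NESeries(
        values=values,
        epoch_times=seq.epoch_times,
        n_edges=seq.matrices[0].n_edges,
        fs_ne=seq.fs_ne,
    )
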