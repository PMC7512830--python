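"""Shared fixtures and independent oracle helpers.

All fixtures are generated programmatically; the EDF fixture is written by
a minimal synthetic EDF writer (16-bit, unit gain) so EDF reading can be
round-tripped without any binary files in the repository.
"""

from __future__ import annotations

import struct

import numpy as np
import pytest

from fcgbnet import AnalysisConfig, SynthSpec, generate


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; never call package internals)


def oracle_crosscorr(x, y, tau=0):
    """Literal double-sum evaluation of the lagged correlation ratio."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    if tau < 0:
        return oracle_crosscorr(y, x, -tau)
    cc = sum(x[t + tau] * y[t] for t in range(n - tau))
    exx = sum(v * v for v in x)
    eyy = sum(v * v for v in y)
    return abs(cc) / (exx * eyy) ** 0.5


def oracle_entropy(weights):
    """Normalize + Shannon entropy, written independently of the package."""
    import math

    s = float(sum(weights))
    out = 0.0
    for w in weights:
        p = w / s
        if p > 0:
            out -= p * math.log2(p)
    return out


def oracle_bfs_distances(adj):
    """All-pairs shortest-path lengths by breadth-first search; None if unreachable."""
    n = len(adj)
    dist = [[None] * n for _ in range(n)]
    for s in range(n):
        dist[s][s] = 0
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in range(n):
                    if adj[u][v] and dist[s][v] is None:
                        dist[s][v] = d
                        nxt.append(v)
            frontier = nxt
    return dist


def oracle_connected(adj):
    dist = oracle_bfs_distances(adj)
    return all(d is not None for row in dist for d in row)


def oracle_path_length_and_efficiency(adj):
    """Mean distance and mean inverse distance over unordered distinct pairs."""
    n = len(adj)
    dist = oracle_bfs_distances(adj)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    lengths = [dist[i][j] for i, j in pairs]
    cpl = sum(lengths) / len(pairs)
    eff = sum(1.0 / d for d in lengths) / len(pairs)
    return cpl, eff


# ---------------------------------------------------------------------------
# synthetic EDF writer (plain 16-bit EDF with unit gain)


def write_synthetic_edf(path, data, fs, labels):
    """Write an integer-valued channels x samples matrix as a minimal EDF file.

    Physical and digital ranges are both [-32768, 32767] so sample values
    survive exactly; one data record holds the whole recording.
    """
    data = np.asarray(data)
    assert np.all(np.abs(data) < 32767) and np.allclose(data, np.round(data))
    n_ch, n_s = data.shape
    header_bytes = 256 * (1 + n_ch)

    def pad(value, width):
        s = str(value)
        assert len(s) <= width
        return s.ljust(width).encode("ascii")

    with open(path, "wb") as fh:
        fh.write(pad("0", 8))
        fh.write(pad("synthetic", 80))
        fh.write(pad("synthetic fixture", 80))
        fh.write(pad("01.01.20", 8))
        fh.write(pad("00.00.00", 8))
        fh.write(pad(header_bytes, 8))
        fh.write(pad("", 44))
        fh.write(pad(1, 8))                       # one data record
        fh.write(pad(f"{n_s / fs:g}", 8))         # record duration (s)
        fh.write(pad(n_ch, 4))
        for lab in labels:
            fh.write(pad(lab, 16))
        for _ in labels:
            fh.write(pad("", 80))                 # transducer
        for _ in labels:
            fh.write(pad("uV", 8))
        for _ in labels:
            fh.write(pad(-32768, 8))              # physical min
        for _ in labels:
            fh.write(pad(32767, 8))               # physical max
        for _ in labels:
            fh.write(pad(-32768, 8))              # digital min
        for _ in labels:
            fh.write(pad(32767, 8))               # digital max
        for _ in labels:
            fh.write(pad("", 80))                 # prefiltering
        for _ in labels:
            fh.write(pad(n_s, 8))                 # samples per record
        for _ in labels:
            fh.write(pad("", 32))
        for ch in range(n_ch):
            fh.write(struct.pack(f"<{n_s}h", *data[ch].astype(int)))


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_recording():
    """60 s, 5-channel, 300 Hz coupled recording (no events); session-cached."""
    spec = SynthSpec(
        n_channels=5, fs=300.0, duration_s=60.0, event_times_s=[], seed=7
    )
    rec, _ = generate(spec)
    return rec


@pytest.fixture(scope="session")
def default_config():
    return AnalysisConfig()
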