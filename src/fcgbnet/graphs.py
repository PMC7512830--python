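"""Connectedness-based binarization and classical graph metrics.

For statistical comparison against the entropy statistic, each weighted
connectivity matrix is binarized at the largest threshold T for which the
resulting 0/1 graph is connected.  Starting from T = 1 the threshold is
lowered in steps (default 0.01); connectivity is declared when the second
smallest eigenvalue lambda_2 of the combinatorial Laplacian L = D - A (the
algebraic connectivity / Fiedler value) becomes positive.  When no grid
point down to T = 0 connects the graph, the step is refined by a factor of
ten before giving up.

On the binary graph four classical metrics are computed: average clustering
coefficient, characteristic path length, global efficiency, and
vulnerability (the maximal relative drop in global efficiency caused by
deleting one node).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List

import networkx as nx
import numpy as np

from .connectivity import ConnectivityMatrix, FCGBSequence
from .exceptions import UnconnectableGraphError

__all__ = [
    "BinaryGraph",
    "GraphMetricsRow",
    "laplacian_lambda2",
    "find_threshold",
    "compute_metrics",
    "metrics_series",
]

#: absolute tolerance below which lambda_2 counts as zero (disconnected)
LAMBDA2_TOL = 1e-9


@dataclass
class BinaryGraph:
    """Binarized connectivity: adjacency[i][j] = 1 iff F[i][j] > threshold_T."""

    adjacency: np.ndarray
    threshold_T: float
    step_used: float

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class GraphMetricsRow:
    epoch_time_s: float
    clustering: float
    char_path_length: float
    global_efficiency: float
    vulnerability: float
    threshold_T: float

    @property
    def is_missing(self) -> bool:
        return math.isnan(self.clustering)


def laplacian_lambda2(adjacency: np.ndarray) -> float:
    """Second-smallest eigenvalue of L = D - A for a symmetric 0/1 matrix."""
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1] or A.shape[0] < 2:
        raise ValueError("adjacency must be square with >= 2 nodes")
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    L = np.diag(A.sum(axis=1)) - A
    w = np.linalg.eigvalsh(L)
    lam2 = float(w[1])
    return max(lam2, 0.0)


def _binarize(values: np.ndarray, T: float) -> np.ndarray:
    A = (values > T).astype(float)
    np.fill_diagonal(A, 0.0)
    return A


def find_threshold(
    F: ConnectivityMatrix, step: float = 0.01, min_step: float = 1e-4
) -> BinaryGraph:
    """Largest grid threshold whose binarization is connected.

    The grid is {1, 1 - step, ..., step}; edges use the strict rule F > T.
    T = 0 is deliberately not on the grid (it would admit every positive
    weight however small, defeating the discarding of weak links), so when
    no positive grid point connects the graph the precision is insufficient:
    the step is divided by 10 and the sweep repeated, down to ``min_step``.
    A graph still disconnected at that precision is reported unconnectable
    (some node pair is joined only by zero- or sub-precision-weight paths).
    """
    values = F.values if isinstance(F, ConnectivityMatrix) else np.asarray(F, float)
    if not (0 < min_step <= step <= 1):
        raise ValueError("require 0 < min_step <= step <= 1")
    s = step
    while True:
        n_grid = int(round(1.0 / s))
        for i in range(n_grid):  # T runs 1, 1-s, ..., s (0 excluded)
            T = round(1.0 - i * s, 12)
            A = _binarize(values, T)
            if (A.sum(axis=1) == 0).any():
                continue  # isolated node: cannot be connected
            if laplacian_lambda2(A) > LAMBDA2_TOL:
                return BinaryGraph(adjacency=A, threshold_T=T, step_used=s)
        nxt = s / 10.0
        if nxt >= min_step * (1 - 1e-12):
            s = nxt
        else:
            raise UnconnectableGraphError(
                f"no positive threshold connects the graph at precision {s:g}"
            )


def _global_efficiency(G: nx.Graph) -> float:
    if G.number_of_nodes() < 2:
        return 0.0
    return nx.global_efficiency(G)


def compute_metrics(g: BinaryGraph, epoch_time_s: float = 0.0) -> GraphMetricsRow:
    """Clustering, path length, efficiency and vulnerability of a connected graph."""
    G = nx.from_numpy_array(g.adjacency)
    if not nx.is_connected(G):
        raise ValueError("compute_metrics requires a connected graph")
    clustering = nx.average_clustering(G)
    cpl = nx.average_shortest_path_length(G)
    eff = _global_efficiency(G)
    # vulnerability: worst-case relative efficiency loss under single-node removal
    worst = -math.inf
    for node in G.nodes:
        H = G.subgraph(n for n in G.nodes if n != node)
        drop = (eff - _global_efficiency(H)) / eff
        worst = max(worst, drop)
    return GraphMetricsRow(
        epoch_time_s=epoch_time_s,
        clustering=float(clustering),
        char_path_length=float(cpl),
        global_efficiency=float(eff),
        vulnerability=float(worst),
        threshold_T=g.threshold_T,
    )


def metrics_series(
    seq: FCGBSequence, step: float = 0.01, min_step: float = 1e-4
) -> List[GraphMetricsRow]:
    """Per-epoch binarization + metrics; unconnectable epochs become NaN rows."""
    import logging

    log = logging.getLogger(__name__)
    rows: List[GraphMetricsRow] = []
    for mat in seq.matrices:
        try:
            g = find_threshold(mat, step=step, min_step=min_step)
            rows.append(compute_metrics(g, epoch_time_s=mat.epoch_time_s))
        except UnconnectableGraphError:
            log.warning("epoch %d unconnectable; emitting missing row", mat.epoch_index)
            nan = float("nan")
            rows.append(
                GraphMetricsRow(mat.epoch_time_s, nan, nan, nan, nan, nan)
            )
    return rows
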