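"""Pairwise Pearson correlation of binarized activity and network statistics.

All statistics work on the zero-lag Pearson coefficient between the 0/1
frame vectors of neuron pairs.  A neuron whose binarized trace is constant
has no defined correlation with anything; such entries are stored as zero in
the matrix but flagged undefined, and are excluded from every percentile and
mean (never zero-filled into them).

The derived statistics mirror a standard co-activation network analysis:
mean coefficient above a threshold, network degree (fraction of connected
pairs) across a threshold grid, per-neuron connectivity, a data-derived
"strong correlation" threshold (mean 95th percentile over baseline
recordings, snapped to the threshold grid), and clusters formed by linking
pairs whose coefficient exceeds the 80th percentile of all pair
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .binarize import BinaryRaster

DEFAULT_GRID = tuple(np.round(np.arange(0.0, 0.3001, 0.05), 2))
STRONG_PERCENTILE = 95.0
CLUSTER_PERCENTILE = 80.0


@dataclass
class CorrelationGraph:
    """Symmetric pairwise Pearson matrix with an undefined-entry mask.

    ``matrix[i, j]`` is the coefficient between neurons i and j (0.0 where
    undefined); ``defined[i, j]`` is False when either column was constant.
    The diagonal is excluded from all statistics.
    """

    matrix: np.ndarray
    defined: np.ndarray
    neuron_ids: list[str]
    method: str = "spike"
    threshold_grid: tuple[float, ...] = DEFAULT_GRID

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("correlation matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, equal_nan=True):
            raise ValueError("correlation matrix must be symmetric")
        self.defined = np.asarray(self.defined, dtype=bool)
        if self.defined.shape != self.matrix.shape:
            raise ValueError("defined mask must match matrix shape")
        grid = tuple(float(t) for t in self.threshold_grid)
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("threshold grid must be strictly ascending")
        self.threshold_grid = grid
        if not self.neuron_ids:
            self.neuron_ids = [f"n{i}" for i in range(n)]

    @property
    def n_neurons(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(self.n_neurons, k=1)
        return int(np.sum(~self.defined[iu]))

    def pair_values(self) -> np.ndarray:
        """Defined off-diagonal coefficients, one entry per unordered pair."""
        iu = np.triu_indices(self.n_neurons, k=1)
        vals = self.matrix[iu]
        return vals[self.defined[iu]]


@dataclass
class ClusterAssignment:
    """Cluster labels from the 80th-percentile linkage rule.

    ``labels[neuron_id]`` is an integer cluster index, or ``None`` for
    unclustered (singleton) neurons.
    """

    labels: dict[str, int | None]
    cutoff: float

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for nid, lab in self.labels.items():
            if lab is not None:
                out.setdefault(lab, []).append(nid)
        return out


def pairwise_pearson(raster: BinaryRaster,
                     threshold_grid: Sequence[float] = DEFAULT_GRID) -> CorrelationGraph:
    """Pearson correlation between every pair of binarized neuron traces."""
    if raster.n_neurons < 2:
        raise ValueError("pairwise correlation requires at least 2 neurons")
    x = raster.states.astype(float)
    sd = x.std(axis=0)
    valid = sd > 0
    matrix = np.zeros((raster.n_neurons, raster.n_neurons))
    if valid.sum() >= 2:
        sub = np.corrcoef(x[:, valid].T)
        idx = np.flatnonzero(valid)
        matrix[np.ix_(idx, idx)] = sub
    elif valid.sum() == 1:
        matrix[np.flatnonzero(valid)[0], np.flatnonzero(valid)[0]] = 1.0
    defined = np.outer(valid, valid)
    matrix[~defined] = 0.0
    # the diagonal is definitional (r_ii = 1) and excluded from statistics
    np.fill_diagonal(matrix, 1.0)
    np.fill_diagonal(defined, True)
    np.clip(matrix, -1.0, 1.0, out=matrix)
    return CorrelationGraph(matrix, defined, list(raster.neuron_ids),
                            method=raster.method, threshold_grid=tuple(threshold_grid))


def mean_correlation_above(graph: CorrelationGraph, threshold: float) -> float:
    """Mean of the defined pair coefficients strictly above ``threshold``.

    Returns NaN when no pair exceeds the threshold (undefined, not zero).
    """
    if not -1.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [-1, 1]")
    vals = graph.pair_values()
    sel = vals[vals > threshold]
    return float(sel.mean()) if sel.size else float("nan")


def network_degree(graph: CorrelationGraph,
                   thresholds: Sequence[float] | None = None) -> dict[float, float]:
    """Fraction of all unordered neuron pairs with coefficient above each threshold."""
    thresholds = graph.threshold_grid if thresholds is None else thresholds
    n = graph.n_neurons
    n_pairs = n * (n - 1) // 2
    vals = graph.pair_values()
    return {float(t): float(np.sum(vals > t) / n_pairs) if n_pairs else 0.0
            for t in thresholds}


def connectivity(graph: CorrelationGraph, threshold: float) -> dict[str, float]:
    """Per-neuron percent of possible partners with coefficient above ``threshold``."""
    n = graph.n_neurons
    if n < 2:
        raise ValueError("connectivity requires at least 2 neurons")
    above = (graph.matrix > threshold) & graph.defined
    np.fill_diagonal(above, False)
    return {nid: float(100.0 * above[i].sum() / (n - 1))
            for i, nid in enumerate(graph.neuron_ids)}


def strong_threshold(baseline_graphs: Sequence[CorrelationGraph],
                     percentile: float = STRONG_PERCENTILE,
                     grid_step: float = 0.05) -> float:
    """Data-derived threshold separating strongly from weakly correlated pairs.

    Takes the given percentile (default 95th, linear interpolation) of the
    defined pair coefficients of every baseline recording, averages across
    recordings, and snaps the mean to the nearest multiple of ``grid_step``
    (exact ties round up).
    """
    if not baseline_graphs:
        raise ValueError("strong_threshold requires at least one baseline graph")
    percs = []
    for g in baseline_graphs:
        vals = g.pair_values()
        if vals.size == 0:
            raise ValueError("a baseline graph has no defined pair coefficients")
        percs.append(np.percentile(vals, percentile))
    mean_perc = float(np.mean(percs))
    return float(np.floor(mean_perc / grid_step + 0.5 + 1e-12) * grid_step)


def cluster_assign(graph: CorrelationGraph,
                   percentile: float = CLUSTER_PERCENTILE) -> ClusterAssignment:
    """Group neurons whose pairwise coefficients beat the network-wide cut.

    A pair is linked when its coefficient strictly exceeds the given
    percentile (default 80th) of all defined pair coefficients; clusters are
    the connected components with at least two members, and all remaining
    neurons are unclustered (label ``None``).
    """
    if graph.n_neurons < 2:
        raise ValueError("cluster_assign requires at least 2 neurons")
    vals = graph.pair_values()
    if vals.size == 0:
        return ClusterAssignment({nid: None for nid in graph.neuron_ids}, float("nan"))
    cutoff = float(np.percentile(vals, percentile))
    adj = (graph.matrix > cutoff) & graph.defined
    np.fill_diagonal(adj, False)
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    sizes = np.bincount(comp, minlength=n_comp)
    relabel: dict[int, int] = {}
    labels: dict[str, int | None] = {}
    for i, nid in enumerate(graph.neuron_ids):
        c = comp[i]
        if sizes[c] >= 2:
            relabel.setdefault(c, len(relabel))
            labels[nid] = relabel[c]
        else:
            labels[nid] = None
    return ClusterAssignment(labels, cutoff)


def intra_inter_cluster(graph: CorrelationGraph,
                        assignment: ClusterAssignment) -> tuple[dict[int, float], dict[str, float]]:
    """Within- and out-of-cluster mean correlation.

    Returns ``(intra, inter)``: ``intra[c]`` is the mean coefficient over
    pairs inside cluster ``c``; ``inter[nid]`` is, for each clustered neuron,
    the mean coefficient with all out-of-cluster neurons.  Both are empty
    when there are no clusters; means over no defined pairs are NaN.
    """
    index = {nid: i for i, nid in enumerate(graph.neuron_ids)}
    intra: dict[int, float] = {}
    for c, members in assignment.clusters().items():
        vals = [graph.matrix[index[a], index[b]]
                for k, a in enumerate(members) for b in members[k + 1:]
                if graph.defined[index[a], index[b]]]
        intra[c] = float(np.mean(vals)) if vals else float("nan")
    inter: dict[str, float] = {}
    for nid, lab in assignment.labels.items():
        if lab is None:
            continue
        i = index[nid]
        others = [graph.matrix[i, index[o]] for o, ol in assignment.labels.items()
                  if ol != lab and graph.defined[i, index[o]] and o != nid]
        inter[nid] = float(np.mean(others)) if others else float("nan")
    return intra, inter
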