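"""Spatial statistics of correlated neuron pairs.

Two distances are computed between members of a neuron pair: the Euclidean
distance between their ROI centroids, and the radial distance — the absolute
difference of the two neurons' distances from the unweighted center of mass
of all neurons in the recording.  Pairs are stratified by correlation
strength into a weak band (0 < r <= strong threshold by default) and a
strong band (r > strong threshold, 0.3 being the operating point derived
from baseline recordings), and each band is summarized by its mean
distances.  All distances are in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlation import CorrelationGraph
from .io import NeuronMap

DEFAULT_STRONG_THRESHOLD = 0.3


@dataclass
class PairDistanceSummary:
    band: str  # "weak" or "strong"
    mean_euclidean_px: float  # NaN when the band is empty
    mean_radial_px: float
    n_pairs: int


def euclidean_pair_distance(nmap: NeuronMap, i: str, j: str) -> float:
    """Straight-line centroid distance between neurons ``i`` and ``j``."""
    return float(np.linalg.norm(nmap.position(i) - nmap.position(j)))


def radial_pair_distance(nmap: NeuronMap, i: str, j: str) -> float:
    """Difference of the two neurons' distances from the ensemble center of mass."""
    c = nmap.center_of_mass()
    ri = np.linalg.norm(nmap.position(i) - c)
    rj = np.linalg.norm(nmap.position(j) - c)
    return float(abs(ri - rj))


def band_distance_summary(graph: CorrelationGraph, nmap: NeuronMap,
                          strong_threshold: float = DEFAULT_STRONG_THRESHOLD,
                          weak_band: tuple[float, float] | None = None,
                          ) -> dict[str, PairDistanceSummary]:
    """Mean pair distances for weakly and strongly correlated neuron pairs.

    The strong band holds pairs with r > ``strong_threshold``; the weak band
    pairs with ``weak_band[0] < r <= weak_band[1]`` (default
    ``(0, strong_threshold]``).  Undefined coefficients are excluded.  Empty
    bands yield NaN means with ``n_pairs = 0``.
    """
    lo, hi = weak_band if weak_band is not None else (0.0, strong_threshold)
    for nid in graph.neuron_ids:
        if nid not in nmap:
            raise KeyError(f"neuron {nid!r} missing from the position map")
    euclid: dict[str, list[float]] = {"weak": [], "strong": []}
    radial: dict[str, list[float]] = {"weak": [], "strong": []}
    index = graph.neuron_ids
    for a in range(graph.n_neurons):
        for b in range(a + 1, graph.n_neurons):
            if not graph.defined[a, b]:
                continue
            r = graph.matrix[a, b]
            if r > strong_threshold:
                band = "strong"
            elif lo < r <= hi:
                band = "weak"
            else:
                continue
            euclid[band].append(euclidean_pair_distance(nmap, index[a], index[b]))
            radial[band].append(radial_pair_distance(nmap, index[a], index[b]))
    out = {}
    for band in ("weak", "strong"):
        e, r = euclid[band], radial[band]
        out[band] = PairDistanceSummary(
            band=band,
            mean_euclidean_px=float(np.mean(e)) if e else float("nan"),
            mean_radial_px=float(np.mean(r)) if r else float("nan"),
            n_pairs=len(e),
        )
    return out
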