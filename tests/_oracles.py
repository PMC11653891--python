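"""Brute-force double-loop reference implementations.

Deliberately naive (explicit loops, textbook formulas) and independent of
the package's vectorized code paths; used to cross-check every metric on
small random instances.
"""

from __future__ import annotations

import math

import numpy as np


def pearson(a, b) -> float:
    """Textbook Pearson coefficient; NaN for constant inputs."""
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    va = sum((x - ma) ** 2 for x in a)
    vb = sum((y - mb) ** 2 for y in b)
    if va == 0 or vb == 0:
        return float("nan")
    return cov / math.sqrt(va * vb)


def pearson_matrix(states: np.ndarray) -> np.ndarray:
    n = states.shape[1]
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            out[i, j] = 1.0 if i == j else pearson(states[:, i], states[:, j])
    return out


def count_runs(column) -> int:
    count = 0
    prev = 0
    for v in column:
        if v == 1 and prev == 0:
            count += 1
        prev = v
    return count


def burst_rates(states: np.ndarray, fps: float) -> list[float]:
    minutes = states.shape[0] / fps / 60.0
    return [count_runs(states[:, j]) / minutes for j in range(states.shape[1])]


def network_spike_rate(states: np.ndarray, fps: float, interval_s: float = 1.0) -> list[float]:
    per = int(round(interval_s * fps))
    n_int = states.shape[0] // per
    out = []
    for k in range(n_int):
        active = 0
        for j in range(states.shape[1]):
            if any(states[f, j] for f in range(k * per, (k + 1) * per)):
                active += 1
        out.append(100.0 * active / states.shape[1])
    return out


def network_spike_peak(states, fps, interval_s=1.0) -> float:
    return max(network_spike_rate(states, fps, interval_s))


def network_spike_duration(states, fps, thresholds, interval_s=1.0) -> dict:
    nsr = network_spike_rate(states, fps, interval_s)
    return {t: sum(interval_s for v in nsr if v > t) for t in thresholds}


def percentile_linear(values, q) -> float:
    """Percentile with linear interpolation between order statistics."""
    s = sorted(values)
    if len(s) == 1:
        return s[0]
    pos = q / 100.0 * (len(s) - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, len(s) - 1)
    frac = pos - lo
    return s[lo] * (1 - frac) + s[hi] * frac


def pair_values(matrix: np.ndarray) -> list[float]:
    n = matrix.shape[0]
    return [matrix[i, j] for i in range(n) for j in range(i + 1, n)
            if not math.isnan(matrix[i, j])]


def network_degree(matrix: np.ndarray, thresholds) -> dict:
    n = matrix.shape[0]
    n_pairs = n * (n - 1) // 2
    out = {}
    for t in thresholds:
        hits = 0
        for i in range(n):
            for j in range(i + 1, n):
                if not math.isnan(matrix[i, j]) and matrix[i, j] > t:
                    hits += 1
        out[t] = hits / n_pairs
    return out


def connectivity(matrix: np.ndarray, threshold: float) -> list[float]:
    n = matrix.shape[0]
    out = []
    for i in range(n):
        hits = sum(1 for j in range(n)
                   if j != i and not math.isnan(matrix[i, j]) and matrix[i, j] > threshold)
        out.append(100.0 * hits / (n - 1))
    return out


def clusters_by_percentile(matrix: np.ndarray, q: float = 80.0) -> list[set[int]]:
    """Connected components of the above-percentile edge set, size >= 2."""
    vals = pair_values(matrix)
    if not vals:
        return []
    cut = percentile_linear(vals, q)
    n = matrix.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if not math.isnan(matrix[i, j]) and matrix[i, j] > cut:
                parent[find(i)] = find(j)
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return [g for g in groups.values() if len(g) >= 2]


def intra_inter_means(matrix: np.ndarray, clusters: list[set[int]]) -> tuple[list, list]:
    intra = []
    for members in clusters:
        ms = sorted(members)
        vals = [matrix[a, b] for ai, a in enumerate(ms) for b in ms[ai + 1:]
                if not math.isnan(matrix[a, b])]
        intra.append(sum(vals) / len(vals) if vals else float("nan"))
    inter = []
    clustered = {m for c in clusters for m in c}
    for members in clusters:
        for i in sorted(members):
            vals = [matrix[i, j] for j in range(matrix.shape[0])
                    if j != i and j not in members and not math.isnan(matrix[i, j])]
            inter.append(sum(vals) / len(vals) if vals else float("nan"))
    return intra, inter


def euclidean(p, q) -> float:
    return math.sqrt((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2)


def radial(points: np.ndarray, i: int, j: int) -> float:
    cx = sum(p[0] for p in points) / len(points)
    cy = sum(p[1] for p in points) / len(points)
    return abs(euclidean(points[i], (cx, cy)) - euclidean(points[j], (cx, cy)))
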