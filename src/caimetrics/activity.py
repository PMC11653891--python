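"""Per-neuron and network activation metrics from a binarized raster.

Burst rate counts each neuron's activations per minute.  Network metrics cut
the recording into fixed intervals (1 s by default) and ask, per interval,
what percentage of neurons had at least one active frame: the network spike
rate (NSR) is that per-interval percentage, the network spike peak its
maximum, and the network spike duration the total time the NSR stays above
each of a set of percentage thresholds.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .binarize import BinaryRaster, count_activations

#: Simultaneous-activity thresholds (percent of neurons) for spike duration.
NSD_THRESHOLDS = (2.5, 5.0, 10.0, 15.0, 20.0, 25.0)

#: Histogram bin width for burst rates, events/min.
BURST_BIN_WIDTH = 1.0 / 3.0

#: Histogram bin width for NSR values, percentage points.
NSR_BIN_WIDTH = 2.5


def burst_rate(raster: BinaryRaster) -> np.ndarray:
    """Activations per minute for every neuron."""
    if raster.n_frames == 0 or raster.n_neurons == 0:
        raise ValueError("burst_rate requires a nonempty raster")
    duration_min = raster.n_frames / raster.fps / 60.0
    counts = np.array([count_activations(raster.states[:, j]) for j in range(raster.n_neurons)])
    return counts / duration_min


def burst_rate_histogram(rates: Sequence[float],
                         bin_width: float = BURST_BIN_WIDTH) -> tuple[np.ndarray, np.ndarray]:
    """Percent of neurons per burst-rate bin.

    Bins are left-closed right-open, ``[k*w, (k+1)*w)`` starting at zero.
    Returns ``(bin_edges, percents)``; percents sum to 100 for nonempty
    input, and an empty rate list yields empty arrays.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    rates = np.asarray(list(rates), dtype=float)
    if rates.size == 0:
        return np.empty(0), np.empty(0)
    n_bins = int(np.floor(rates.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.floor(rates / bin_width).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    return edges, 100.0 * counts / rates.size


def _interval_active(raster: BinaryRaster, interval_s: float) -> np.ndarray:
    """(n_intervals, n_neurons) bool: neuron has >= 1 active frame in interval."""
    frames_per = int(round(interval_s * raster.fps))
    if frames_per < 1:
        raise ValueError("interval must span at least one frame")
    n_int = raster.n_frames // frames_per  # trailing partial interval dropped
    trimmed = raster.states[: n_int * frames_per]
    return trimmed.reshape(n_int, frames_per, raster.n_neurons).any(axis=1)


def network_spike_rate(raster: BinaryRaster, interval_s: float = 1.0) -> np.ndarray:
    """Percent of neurons active within each interval of the recording.

    A neuron counts as active in an interval if it has at least one active
    frame inside it; the trailing partial interval is dropped.
    """
    if raster.n_neurons == 0:
        raise ValueError("network_spike_rate requires at least one neuron")
    active = _interval_active(raster, interval_s)
    return 100.0 * active.sum(axis=1) / raster.n_neurons


def network_spike_rate_histogram(nsr: Sequence[float],
                                 bin_width: float = NSR_BIN_WIDTH) -> tuple[np.ndarray, np.ndarray]:
    """Percent of intervals per NSR bin, over fixed [0, 100] coverage.

    Left-closed right-open bins of ``bin_width`` percentage points; the last
    bin closes at 100 so a fully active interval is counted.
    """
    nsr = np.asarray(list(nsr), dtype=float)
    edges = np.arange(0.0, 100.0 + bin_width / 2, bin_width)
    if nsr.size == 0:
        return edges, np.zeros(edges.size - 1)
    counts, _ = np.histogram(nsr, bins=edges)
    return edges, 100.0 * counts / nsr.size


def network_spike_peak(raster: BinaryRaster, interval_s: float = 1.0) -> float:
    """Maximum percent of simultaneously active neurons over all intervals."""
    nsr = network_spike_rate(raster, interval_s)
    if nsr.size == 0:
        raise ValueError("recording shorter than one interval")
    return float(nsr.max())


def network_spike_duration(raster: BinaryRaster,
                           thresholds: Sequence[float] = NSD_THRESHOLDS,
                           interval_s: float = 1.0,
                           as_fraction: bool = False) -> dict[float, float]:
    """Time (seconds) the NSR exceeds each threshold (percent of neurons).

    With ``as_fraction=True`` values are returned as percent of the analyzed
    intervals instead of seconds.
    """
    for t in thresholds:
        if not 0 < t <= 100:
            raise ValueError(f"threshold must be in (0, 100], got {t}")
    nsr = network_spike_rate(raster, interval_s)
    out: dict[float, float] = {}
    for t in thresholds:
        n_above = int(np.sum(nsr > t))
        out[float(t)] = (100.0 * n_above / nsr.size if nsr.size else 0.0) if as_fraction \
            else n_above * interval_s
    return out
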