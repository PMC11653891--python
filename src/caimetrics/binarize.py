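"""Binarization of fluorescence traces into active / inactive frames.

Four rule-based methods convert a continuous calcium trace into a 0/1 vector:

``spike``
    Marks the phase of rapid fluorescence growth (the event rise) only:
    the trace is smoothed by a centred moving average, frames where the
    smoothed first difference exceeds a robust noise floor become candidate
    active frames, then short active runs (< ``cold`` frames) are deleted and
    short passive gaps (< ``warm`` frames) merge flanking runs.  Defaults
    window=10, cold=0, warm=50 frames.
``full``
    Marks the whole supra-threshold part of the trace:
    active where trace > median + k_mad * MAD (default k_mad=3).
``signal``
    Active where the standardized raw intensity exceeds ``z`` (default 2).
``diff``
    Active where the standardized first difference exceeds ``z`` (default 2);
    marks the rise phase, without smoothing or run filtering.

``active_accuracy`` measures the overlap of two binary vectors as the ratio
of the intersection to the union of their active frames (Jaccard index), and
``count_activations`` counts contiguous active runs — the per-neuron calcium
events from which the burst rate is derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .io import TraceMatrix

METHODS = ("spike", "full", "signal", "diff")

# Robust-threshold constants. The spike slope floor is expressed in units of
# the MAD-estimated noise scale of the smoothed first difference; 0 disables
# it and reduces the candidate rule to "strictly positive first difference",
# which is exact for noise-free traces.
DEFAULT_WINDOW = 10
DEFAULT_COLD = 0
DEFAULT_WARM = 50
DEFAULT_SLOPE_Z = 4.0
DEFAULT_K_MAD = 3.0
DEFAULT_Z = 2.0

_MAD_TO_SD = 1.4826  # consistency constant for Gaussian noise


class TraceTooShortError(ValueError):
    pass


@dataclass
class SpikeParams:
    """Parameters of the rise-phase (``spike``) detector, all in frames.

    ``window`` is the moving-average smoothing span; ``cold`` the minimum
    duration of an active phase (shorter runs are deleted); ``warm`` the
    minimum duration of a passive phase (shorter gaps merge flanking runs).
    ``slope_z`` scales the robust noise floor on the smoothed derivative.
    """

    window: int = DEFAULT_WINDOW
    cold: int = DEFAULT_COLD
    warm: int = DEFAULT_WARM
    slope_z: float = DEFAULT_SLOPE_Z

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.cold < 0 or self.warm < 0:
            raise ValueError("cold and warm must be >= 0")
        if self.slope_z < 0:
            raise ValueError("slope_z must be >= 0")


@dataclass
class BinaryRaster:
    """Frames x neurons active-state matrix with method provenance."""

    states: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    fps: float = 15.0
    neuron_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        if self.states.ndim != 2:
            raise ValueError("raster must be 2-D (frames x neurons)")
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("raster cells must be 0 or 1")
        self.states = self.states.astype(np.uint8)
        if not self.neuron_ids:
            self.neuron_ids = [f"n{i}" for i in range(self.states.shape[1])]

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.states.shape[1]


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge truncation (shorter window at ends)."""
    if window == 1:
        return x.astype(float)
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / den


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) spans of consecutive True values."""
    m = np.asarray(mask, dtype=bool).astype(np.int8)
    edges = np.flatnonzero(np.diff(np.r_[0, m, 0]))
    return list(zip(edges[0::2], edges[1::2]))


def _drop_short_runs(mask: np.ndarray, min_len: int) -> np.ndarray:
    if min_len <= 0:
        return mask
    out = mask.copy()
    for start, stop in _runs(mask):
        if stop - start < min_len:
            out[start:stop] = False
    return out


def _fill_short_gaps(mask: np.ndarray, min_gap: int) -> np.ndarray:
    """Merge active runs separated by passive gaps shorter than ``min_gap``."""
    if min_gap <= 0:
        return mask
    out = mask.copy()
    spans = _runs(mask)
    for (_, stop_prev), (start_next, _) in zip(spans, spans[1:]):
        if start_next - stop_prev < min_gap:
            out[stop_prev:start_next] = True
    return out


def binarize_spike(trace: np.ndarray, params: SpikeParams | None = None) -> np.ndarray:
    """Rise-phase detector: active during rapid fluorescence growth.

    Candidate frames are those where the first difference of the smoothed
    trace exceeds ``slope_z`` times a MAD-based estimate of its noise scale
    (strictly positive when the noise scale is zero).  Candidate runs shorter
    than ``cold`` frames are deleted, then passive gaps shorter than ``warm``
    frames merge the flanking runs.
    """
    p = params or SpikeParams()
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1:
        raise ValueError("binarize_spike expects a 1-D trace")
    if x.size <= p.window:
        raise TraceTooShortError(f"trace length {x.size} <= window {p.window}")
    smooth = _moving_average(x, p.window)
    d = np.diff(smooth)
    noise_scale = _MAD_TO_SD * np.median(np.abs(d - np.median(d)))
    floor = p.slope_z * noise_scale
    active = np.zeros(x.size, dtype=bool)
    active[1:] = d > max(floor, 0.0)
    active = _drop_short_runs(active, p.cold)
    active = _fill_short_gaps(active, p.warm)
    return active.astype(np.uint8)


def binarize_full(trace: np.ndarray, k_mad: float = DEFAULT_K_MAD) -> np.ndarray:
    """Supra-threshold detector: active where trace > median + k_mad * MAD.

    Degenerate fallbacks keep the rule total: when MAD is zero the threshold
    becomes mean + k_mad * SD, and when SD is also zero (constant trace)
    every frame is inactive.
    """
    x = np.asarray(trace, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad > 0:
        thr = med + k_mad * mad
    else:
        sd = x.std()
        if sd == 0:
            return np.zeros(x.size, dtype=np.uint8)
        thr = x.mean() + k_mad * sd
    return (x > thr).astype(np.uint8)


def binarize_signal(trace: np.ndarray, z: float = DEFAULT_Z) -> np.ndarray:
    """Active where the standardized raw intensity exceeds ``z``."""
    x = np.asarray(trace, dtype=float)
    sd = x.std()
    if sd == 0:
        return np.zeros(x.size, dtype=np.uint8)
    return ((x - x.mean()) / sd > z).astype(np.uint8)


def binarize_diff(trace: np.ndarray, z: float = DEFAULT_Z) -> np.ndarray:
    """Active where the standardized first difference exceeds ``z``.

    Frame t is active when (x[t] - x[t-1]) standardized exceeds ``z``;
    frame 0 is always inactive.  A constant-derivative trace (e.g. a linear
    ramp) has zero derivative variance and yields all zeros.
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 2:
        raise TraceTooShortError("binarize_diff needs at least 2 frames")
    d = np.diff(x)
    sd = d.std()
    out = np.zeros(x.size, dtype=np.uint8)
    if sd == 0:
        return out
    out[1:] = (d - d.mean()) / sd > z
    return out


_DISPATCH: dict[str, Callable] = {
    "full": binarize_full,
    "signal": binarize_signal,
    "diff": binarize_diff,
}


def binarize_trace(trace: np.ndarray, method: str = "spike", **params) -> np.ndarray:
    if method == "spike":
        return binarize_spike(trace, SpikeParams(**params) if params else None)
    try:
        fn = _DISPATCH[method]
    except KeyError:
        raise ValueError(f"unknown binarization method {method!r}; choose from {METHODS}") from None
    return fn(trace, **params)


def binarize_matrix(traces: TraceMatrix, method: str = "spike", **params) -> BinaryRaster:
    """Binarize every neuron of a trace matrix with one method."""
    cols = [binarize_trace(traces.values[:, j], method, **params) for j in range(traces.n_neurons)]
    states = np.column_stack(cols) if cols else np.zeros((traces.n_frames, 0), dtype=np.uint8)
    recorded = dict(params)
    if method == "spike" and not params:
        p = SpikeParams()
        recorded = {"window": p.window, "cold": p.cold, "warm": p.warm, "slope_z": p.slope_z}
    return BinaryRaster(states, method=method, params=recorded, fps=traces.fps,
                        neuron_ids=list(traces.neuron_ids))


def count_activations(binary: np.ndarray) -> int:
    """Number of contiguous active runs (0 -> 1 transitions; frame 0 counts)."""
    b = np.asarray(binary).astype(bool)
    if b.ndim != 1:
        raise ValueError("count_activations expects a 1-D vector")
    return int(np.sum(np.diff(np.r_[0, b.astype(np.int8)]) == 1))


def active_accuracy(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of the active frames of two binary vectors.

    Returns a value in [0, 1]; two vectors with no active frames at all
    score 0 by convention.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    union = np.sum(a | b)
    if union == 0:
        return 0.0
    return float(np.sum(a & b) / union)
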