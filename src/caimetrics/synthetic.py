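"""Synthetic miniscope recordings with known ground truth.

The generator emulates the statistical structure of extracted CA1 calcium
traces: per-neuron calcium events arrive as homogeneous Poisson processes
(events/min configurable per neuron), each event contributes a fast-rise /
slow-decay GCaMP6f-like transient, Gaussian noise is added, and neurons get
uniform 2-D positions in the imaged field.  Pairwise co-activation is
controllable: a coupled pair (i, j, f) rebuilds neuron j's event train so
that each of i's events is copied into j with probability f while each of
j's own events survives with probability 1 - f; at f = 1 the trains are
identical, at f = 0 independent.  Multi-session series emulate the
experimental timeline (baseline days, stress, 3 h, 10 days) via per-state
rate multipliers, small centroid jitter and per-session neuron dropout.

Everything is seeded: the same seed reproduces onsets, positions and traces
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .io import NeuronMap, TraceMatrix


@dataclass
class SimConfig:
    """Parameters of one simulated recording.

    Rates are in events per minute (scalar or one per neuron); kinetics in
    seconds; noise in the same arbitrary units as the unit-peak transient.
    """

    n_neurons: int = 50
    duration_s: float = 300.0
    fps: float = 15.0
    rate_per_min: float | Sequence[float] = 1.0
    rise_tau_s: float = 0.1
    decay_tau_s: float = 0.6
    noise_sd: float = 0.05
    field_size_px: tuple[float, float] = (600.0, 600.0)
    coupled_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    amplitude_sigma: float = 0.25  # log-normal sd of per-event amplitudes; 0 = identical
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 0:
            raise ValueError("n_neurons must be >= 0")
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValueError("duration_s and fps must be positive")
        if self.rise_tau_s <= 0 or self.decay_tau_s <= 0:
            raise ValueError("kinetic time constants must be positive")
        if self.rise_tau_s >= self.decay_tau_s:
            raise ValueError("rise_tau_s must be smaller than decay_tau_s")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        rates = self.rates()
        if (rates < 0).any():
            raise ValueError("event rates must be >= 0")
        for i, j, f in self.coupled_pairs:
            if not (0 <= i < self.n_neurons and 0 <= j < self.n_neurons) or i == j:
                raise ValueError(f"invalid coupled pair ({i}, {j})")
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"sharing fraction must be in [0, 1], got {f}")

    def rates(self) -> np.ndarray:
        r = np.broadcast_to(np.asarray(self.rate_per_min, dtype=float), (self.n_neurons,))
        return r.copy()

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass
class GroundTruth:
    """Truth ledger of a simulated recording (for parameter-recovery tests)."""

    event_onsets: list[np.ndarray]  # per-neuron strictly increasing onset frames
    positions: NeuronMap
    rate_per_min: np.ndarray  # realized events/min per neuron
    pair_sharing: dict[tuple[int, int], float]  # realized coincidence fractions

    def __post_init__(self) -> None:
        for onsets in self.event_onsets:
            if onsets.size and (np.diff(onsets) <= 0).any():
                raise ValueError("onset frames must be strictly increasing")


@dataclass
class SessionSeriesConfig:
    """A multi-session experiment: per-state rate multipliers over a base recording."""

    base: SimConfig = field(default_factory=SimConfig)
    state_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {
            "baseline_d1": 1.0,
            "baseline_d2": 1.0,
            "baseline_d3": 1.0,
            "baseline_d4": 1.0,
            "baseline_d5": 1.0,
            "stress": 2.0,
            "3h": 1.8,
            "10days": 1.0,
        }
    )
    centroid_jitter_px: float = 1.0
    dropout_fraction: float = 0.0
    n_mice: int = 1

    def __post_init__(self) -> None:
        if not self.state_multipliers:
            raise ValueError("state_multipliers must name at least one state")
        if any(m <= 0 for m in self.state_multipliers.values()):
            raise ValueError("rate multipliers must be > 0")
        if self.centroid_jitter_px < 0:
            raise ValueError("centroid_jitter_px must be >= 0")
        if not 0.0 <= self.dropout_fraction < 1.0:
            raise ValueError("dropout_fraction must be in [0, 1)")
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")


@dataclass
class SimulatedSession:
    """One simulated recording of a session series, with its truth ledger."""

    mouse_id: str
    state: str
    traces: TraceMatrix
    positions: NeuronMap
    truth: GroundTruth


def _poisson_onsets(rng: np.random.Generator, rate_per_min: float, n_frames: int,
                    fps: float) -> np.ndarray:
    """Homogeneous Poisson event times thinned to unique frame indices."""
    duration_min = n_frames / fps / 60.0
    n_events = rng.poisson(rate_per_min * duration_min)
    if n_events == 0:
        return np.empty(0, dtype=int)
    frames = np.unique(rng.integers(0, n_frames, size=n_events))
    return frames.astype(int)


def simulate_events(config: SimConfig, rng: np.random.Generator | None = None) -> GroundTruth:
    """Draw per-neuron Poisson event onsets, apply pair coupling, place neurons.

    Positions are uniform over the field.  Returns a :class:`GroundTruth`
    with realized rates and realized pair-coincidence fractions.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_frames = config.n_frames
    rates = config.rates()
    onsets = [_poisson_onsets(rng, rates[k], n_frames, config.fps)
              for k in range(config.n_neurons)]

    realized_sharing: dict[tuple[int, int], float] = {}
    for i, j, f in config.coupled_pairs:
        if f >= 1.0:
            onsets[j] = onsets[i].copy()
        elif f > 0.0:
            keep_own = onsets[j][rng.random(onsets[j].size) >= f]
            copied = onsets[i][rng.random(onsets[i].size) < f]
            onsets[j] = np.unique(np.concatenate([keep_own, copied])).astype(int)
        shared = np.intersect1d(onsets[i], onsets[j]).size
        realized_sharing[(i, j)] = shared / onsets[j].size if onsets[j].size else 0.0

    width, height = config.field_size_px
    xy = np.column_stack([rng.uniform(0, width, config.n_neurons),
                          rng.uniform(0, height, config.n_neurons)])
    positions = NeuronMap([f"n{k}" for k in range(config.n_neurons)], xy)
    duration_min = config.duration_s / 60.0
    realized = np.array([o.size / duration_min for o in onsets])
    return GroundTruth(onsets, positions, realized, realized_sharing)


def transient_kernel(config: SimConfig) -> np.ndarray:
    """Unit-peak difference-of-exponentials calcium transient, sampled at fps.

    k(t) = A * (exp(-t / tau_d) - exp(-t / tau_r)), normalized so the peak
    equals 1; truncated at 8 decay time constants.
    """
    tr, td = config.rise_tau_s, config.decay_tau_s
    n = max(2, int(np.ceil(8 * td * config.fps)))
    t = np.arange(n) / config.fps
    k = np.exp(-t / td) - np.exp(-t / tr)
    t_peak = tr * td / (td - tr) * np.log(td / tr)
    peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
    return k / peak


def render_traces(truth: GroundTruth, config: SimConfig,
                  rng: np.random.Generator | None = None) -> TraceMatrix:
    """Render event onsets into fluorescence traces.

    Each onset adds one transient kernel scaled by a log-normal amplitude
    (sigma ``amplitude_sigma``; all amplitudes 1 when sigma is 0); overlapping
    transients sum.  Gaussian noise with SD ``noise_sd`` is added per frame.
    """
    rng = rng if rng is not None else np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_frames = config.n_frames
    kernel = transient_kernel(config)
    values = np.zeros((n_frames, config.n_neurons))
    for k, onsets in enumerate(truth.event_onsets):
        if onsets.size and (onsets.min() < 0 or onsets.max() >= n_frames):
            raise ValueError(f"neuron {k} has onsets outside the frame range")
        for onset in onsets:
            amp = rng.lognormal(0.0, config.amplitude_sigma) if config.amplitude_sigma > 0 else 1.0
            span = min(kernel.size, n_frames - onset)
            values[onset:onset + span, k] += amp * kernel[:span]
    if config.noise_sd > 0:
        values += rng.normal(0.0, config.noise_sd, size=values.shape)
    return TraceMatrix(values, fps=config.fps,
                       neuron_ids=list(truth.positions.neuron_ids))


def simulate_recording(config: SimConfig) -> tuple[TraceMatrix, GroundTruth]:
    """Convenience: events + rendering with a single seed."""
    rng = np.random.default_rng(config.seed)
    truth = simulate_events(config, rng)
    traces = render_traces(truth, config, rng)
    return traces, truth


def simulate_session_series(config: SessionSeriesConfig) -> list[SimulatedSession]:
    """Simulate one recording per (mouse, state).

    Per mouse, base positions and base per-neuron rates are drawn once; each
    session multiplies the rates by its state multiplier, jitters centroids
    with Gaussian noise (SD ``centroid_jitter_px``) and drops each neuron
    independently with probability ``dropout_fraction``.  Neuron ids are
    stable across sessions of a mouse, so the planted cross-session identity
    is the id itself.
    """
    rng = np.random.default_rng(config.base.seed)
    sessions: list[SimulatedSession] = []
    for m in range(config.n_mice):
        mouse_id = f"mouse{m + 1}"
        base_rates = config.base.rates()
        width, height = config.base.field_size_px
        base_xy = np.column_stack([rng.uniform(0, width, config.base.n_neurons),
                                   rng.uniform(0, height, config.base.n_neurons)])
        ids = [f"n{k}" for k in range(config.base.n_neurons)]
        for state, mult in config.state_multipliers.items():
            keep = rng.random(config.base.n_neurons) >= config.dropout_fraction
            keep_idx = np.flatnonzero(keep)
            scfg = replace(config.base, n_neurons=int(keep_idx.size),
                           rate_per_min=base_rates[keep_idx] * mult,
                           coupled_pairs=_remap_pairs(config.base.coupled_pairs, keep_idx))
            truth = simulate_events(scfg, rng)
            xy = base_xy[keep_idx] + rng.normal(0.0, config.centroid_jitter_px,
                                                size=(keep_idx.size, 2))
            session_ids = [ids[k] for k in keep_idx]
            positions = NeuronMap(session_ids, xy)
            truth = GroundTruth(truth.event_onsets, positions, truth.rate_per_min,
                                truth.pair_sharing)
            traces = render_traces(truth, scfg, rng)
            sessions.append(SimulatedSession(mouse_id, state, traces, positions, truth))
    return sessions


def event_detection_scores(truth: GroundTruth, states: np.ndarray,
                           tol_frames: int = 10) -> tuple[float, float]:
    """Precision and recall of detected activations against planted onsets.

    Detected events are the starts of active runs in the binarized raster
    (frames x neurons, aligned with ``truth.event_onsets``).  Each detected
    start is greedily matched to the nearest unmatched true onset within
    ``tol_frames``.  Returns ``(precision, recall)`` pooled over neurons;
    either is 1.0 when its denominator is zero.
    """
    states = np.asarray(states)
    n_true = n_detected = n_matched = 0
    for k, onsets in enumerate(truth.event_onsets):
        col = states[:, k].astype(np.int8)
        starts = np.flatnonzero(np.diff(np.r_[0, col]) == 1)
        n_true += onsets.size
        n_detected += starts.size
        available = list(onsets)
        for s in starts:
            if not available:
                break
            gaps = [abs(int(s) - int(o)) for o in available]
            best = int(np.argmin(gaps))
            if gaps[best] <= tol_frames:
                available.pop(best)
                n_matched += 1
    precision = n_matched / n_detected if n_detected else 1.0
    recall = n_matched / n_true if n_true else 1.0
    return float(precision), float(recall)


def _remap_pairs(pairs: list[tuple[int, int, float]],
                 keep_idx: np.ndarray) -> list[tuple[int, int, float]]:
    """Re-index coupled pairs after dropout; pairs losing a member are removed."""
    new_index = {int(old): new for new, old in enumerate(keep_idx)}
    out = []
    for i, j, f in pairs:
        if i in new_index and j in new_index:
            out.append((new_index[i], new_index[j], f))
    return out
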