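"""Cross-session neuron tracking and stress-response classification.

Neurons are matched across sessions by centroid proximity: a greedy
globally-nearest matcher repeatedly links the closest unmatched pair of
centroids while their distance stays within ``max_dist`` (7 pixels by
default, the criterion used to call two ROIs the same cell).  Matched
neurons' burst rates are then normalized to a designated baseline session,
and each neuron is classified as activated (normalized rate > 1.75),
inhibited (< 0.5) or non-responsive (in between; boundary values fall in
the non-responsive band).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.spatial.distance import cdist

from .io import NeuronMap

DEFAULT_MAX_DIST_PX = 7.0
DEFAULT_UPPER = 1.75
DEFAULT_LOWER = 0.5

RESPONSE_CLASSES = ("activated", "inhibited", "non_responsive")


@dataclass
class IdentityMap:
    """One-to-one matching between the neurons of two sessions."""

    matches: dict[str, str]  # id in session A -> id in session B
    distances: dict[str, float]  # keyed by session-A id
    unmatched_a: list[str]
    unmatched_b: list[str]
    max_dist: float

    def __post_init__(self) -> None:
        if len(set(self.matches.values())) != len(self.matches):
            raise ValueError("matching is not one-to-one")
        bad = [a for a, d in self.distances.items() if d > self.max_dist]
        if bad:
            raise ValueError(f"matched distances exceed max_dist for {bad}")


@dataclass
class ResponseClassification:
    """Per-neuron stress-response label with the normalized rate behind it."""

    labels: dict[str, str]
    normalized_rate: dict[str, float]
    upper: float = DEFAULT_UPPER
    lower: float = DEFAULT_LOWER


def match_neurons(map_a: NeuronMap, map_b: NeuronMap,
                  max_dist: float = DEFAULT_MAX_DIST_PX) -> IdentityMap:
    """Greedy globally-nearest centroid matching within ``max_dist`` pixels.

    Candidate pairs are visited in order of increasing distance (ties broken
    lexicographically by (id_a, id_b)); a pair is matched when both neurons
    are still free.  Neurons with no free partner within ``max_dist`` stay
    unmatched.
    """
    if len(map_a) == 0 or len(map_b) == 0:
        raise ValueError("both maps must be nonempty")
    dist = cdist(map_a.xy, map_b.xy)
    ai, bi = np.nonzero(dist <= max_dist)
    order = sorted(range(ai.size),
                   key=lambda k: (dist[ai[k], bi[k]], map_a.neuron_ids[ai[k]],
                                  map_b.neuron_ids[bi[k]]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: dict[str, str] = {}
    distances: dict[str, float] = {}
    for k in order:
        a, b = int(ai[k]), int(bi[k])
        if a in used_a or b in used_b:
            continue
        used_a.add(a)
        used_b.add(b)
        matches[map_a.neuron_ids[a]] = map_b.neuron_ids[b]
        distances[map_a.neuron_ids[a]] = float(dist[a, b])
    unmatched_a = [nid for i, nid in enumerate(map_a.neuron_ids) if i not in used_a]
    unmatched_b = [nid for i, nid in enumerate(map_b.neuron_ids) if i not in used_b]
    return IdentityMap(matches, distances, unmatched_a, unmatched_b, max_dist)


def normalize_to_baseline(rates_by_session: Mapping[str, Mapping[str, float]],
                          baseline_session: str,
                          ) -> tuple[dict[str, dict[str, float]], int]:
    """Divide each tracked neuron's rate by its rate in the baseline session.

    ``rates_by_session`` maps session label -> {neuron id -> burst rate},
    with ids already aligned across sessions (e.g. baseline ids propagated
    through :func:`match_neurons`).  Neurons whose baseline rate is zero, or
    absent from a session, are excluded from that session's output; the
    second return value counts the exclusions.
    """
    if baseline_session not in rates_by_session:
        raise KeyError(f"baseline session {baseline_session!r} missing")
    baseline = rates_by_session[baseline_session]
    normalized: dict[str, dict[str, float]] = {}
    n_excluded = 0
    for session, rates in rates_by_session.items():
        out: dict[str, float] = {}
        for nid, rate in rates.items():
            base = baseline.get(nid)
            if base is None or base <= 0:
                n_excluded += 1
                continue
            out[nid] = rate / base
        normalized[session] = out
    return normalized, n_excluded


def classify_response(normalized: Mapping[str, float],
                      upper: float = DEFAULT_UPPER,
                      lower: float = DEFAULT_LOWER) -> ResponseClassification:
    """Three-way partition of tracked neurons by baseline-normalized rate.

    activated: rate > upper; inhibited: rate < lower; non_responsive
    otherwise (the closed interval [lower, upper]).  Exhaustive and
    exclusive for every finite input.
    """
    if lower >= upper:
        raise ValueError("lower threshold must be below upper threshold")
    labels: dict[str, str] = {}
    for nid, ratio in normalized.items():
        if ratio > upper:
            labels[nid] = "activated"
        elif ratio < lower:
            labels[nid] = "inhibited"
        else:
            labels[nid] = "non_responsive"
    return ResponseClassification(labels, dict(normalized), upper=upper, lower=lower)


def response_fractions(classification: ResponseClassification) -> dict[str, float]:
    """Percent of neurons per response class; the three values sum to 100."""
    if not classification.labels:
        raise ValueError("no classified neurons")
    n = len(classification.labels)
    counts = {c: 0 for c in RESPONSE_CLASSES}
    for lab in classification.labels.values():
        counts[lab] += 1
    return {c: 100.0 * k / n for c, k in counts.items()}


def per_mouse_normalize(metric_by_recording: Mapping[str, float],
                        recording_mouse: Mapping[str, str],
                        mouse_baseline_means: Mapping[str, float]) -> dict[str, float]:
    """Divide each recording's metric by its mouse's baseline mean."""
    out: dict[str, float] = {}
    for rec, value in metric_by_recording.items():
        mouse = recording_mouse[rec]
        base = mouse_baseline_means[mouse]
        if base <= 0:
            raise ValueError(f"non-positive baseline mean for mouse {mouse!r}")
        out[rec] = value / base
    return out
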