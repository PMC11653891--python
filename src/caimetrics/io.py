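"""Reading, writing and trimming of extracted calcium-imaging data.

The pipeline starts downstream of source extraction (CNMF): its inputs are a
fluorescence trace matrix (frames x neurons, arbitrary units) and a table of
ROI centroids (neuron id, x, y in pixels) per recording, plus a manifest
labelling recordings by mouse and experimental state.  Delimited text (comma
or tab, auto-detected) is the canonical interchange format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: Canonical experimental-state vocabulary: five consecutive baseline days,
#: the recording immediately after acute restraint stress, 3 hours after,
#: and 10 days after.  Arbitrary extra labels are allowed for custom designs.
STATE_LABELS = (
    "baseline_d1",
    "baseline_d2",
    "baseline_d3",
    "baseline_d4",
    "baseline_d5",
    "stress",
    "3h",
    "10days",
)

DEFAULT_FPS = 15.0


class TraceIOError(ValueError):
    """Raised on malformed trace / map / raster files."""


@dataclass
class TraceMatrix:
    """Fluorescence traces for one recording.

    Attributes
    ----------
    values : ndarray, shape (n_frames, n_neurons)
        Fluorescence intensity in arbitrary units, one column per neuron.
    fps : float
        Acquisition rate in frames per second.
    neuron_ids : list of str
        Stable per-neuron identifiers (column order).
    """

    values: np.ndarray
    fps: float = DEFAULT_FPS
    neuron_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise TraceIOError("trace matrix must be 2-D (frames x neurons)")
        if not np.isfinite(self.values).all():
            raise TraceIOError("trace matrix contains non-finite values")
        if self.fps <= 0:
            raise TraceIOError("fps must be positive")
        if not self.neuron_ids:
            self.neuron_ids = [f"n{i}" for i in range(self.values.shape[1])]
        if len(self.neuron_ids) != self.values.shape[1]:
            raise TraceIOError("neuron_ids length does not match column count")
        if len(set(self.neuron_ids)) != len(self.neuron_ids):
            raise TraceIOError("neuron_ids must be unique")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass
class NeuronMap:
    """ROI centroid positions (pixels) for one recording."""

    neuron_ids: list[str]
    xy: np.ndarray  # shape (n_neurons, 2)

    def __post_init__(self) -> None:
        self.neuron_ids = [str(i) for i in self.neuron_ids]
        self.xy = np.asarray(self.xy, dtype=float).reshape(len(self.neuron_ids), 2)
        if not np.isfinite(self.xy).all():
            raise TraceIOError("centroid coordinates must be finite")
        if len(set(self.neuron_ids)) != len(self.neuron_ids):
            raise TraceIOError("neuron ids in map must be unique")
        self._index = {nid: k for k, nid in enumerate(self.neuron_ids)}

    def __contains__(self, neuron_id: str) -> bool:
        return neuron_id in self._index

    def __len__(self) -> int:
        return len(self.neuron_ids)

    def position(self, neuron_id: str) -> np.ndarray:
        try:
            return self.xy[self._index[neuron_id]]
        except KeyError:
            raise KeyError(f"unknown neuron id: {neuron_id!r}") from None

    def center_of_mass(self) -> np.ndarray:
        """Unweighted centroid of all neuron positions."""
        if len(self) == 0:
            raise TraceIOError("cannot take center of mass of an empty map")
        return self.xy.mean(axis=0)

    def subset(self, neuron_ids: Sequence[str]) -> "NeuronMap":
        return NeuronMap(list(neuron_ids), np.array([self.position(i) for i in neuron_ids]))


@dataclass
class SessionRecord:
    mouse_id: str
    state: str
    trace_path: str
    map_path: str


@dataclass
class SessionSet:
    """Manifest of recordings across mice and experimental states."""

    records: list[SessionRecord]

    def by_state(self, state: str) -> list[SessionRecord]:
        return [r for r in self.records if r.state == state]

    def states(self) -> list[str]:
        seen: list[str] = []
        for r in self.records:
            if r.state not in seen:
                seen.append(r.state)
        return seen


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def load_traces(path: str | Path, fps: float = DEFAULT_FPS) -> TraceMatrix:
    """Load a frames x neurons delimited-text trace file.

    The first row holds neuron ids.  Ragged rows or non-numeric cells raise
    :class:`TraceIOError` naming the offending cell; nothing is imputed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _detect_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, header=0, dtype=str, skipinitialspace=True)
    except pd.errors.ParserError as exc:  # ragged rows
        raise TraceIOError(f"malformed trace file {path}: {exc}") from exc
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = np.argwhere(numeric.isna().to_numpy())
        r, c = bad[0]
        raise TraceIOError(
            f"non-numeric cell in {path} at data row {r}, column {df.columns[c]!r}"
        )
    return TraceMatrix(numeric.to_numpy(float), fps=fps, neuron_ids=[str(c) for c in df.columns])


def save_traces(traces: TraceMatrix, path: str | Path, sep: str = ",") -> None:
    pd.DataFrame(traces.values, columns=traces.neuron_ids).to_csv(path, sep=sep, index=False)


def load_map(path: str | Path) -> NeuronMap:
    """Load an id,x_px,y_px centroid table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    required = {"id", "x_px", "y_px"}
    if not required.issubset(df.columns):
        raise TraceIOError(f"map file {path} must have columns id,x_px,y_px")
    return NeuronMap(df["id"].astype(str).tolist(), df[["x_px", "y_px"]].to_numpy(float))


def save_map(nmap: NeuronMap, path: str | Path, sep: str = ",") -> None:
    pd.DataFrame({"id": nmap.neuron_ids, "x_px": nmap.xy[:, 0], "y_px": nmap.xy[:, 1]}).to_csv(
        path, sep=sep, index=False
    )


def save_raster(states: np.ndarray, neuron_ids: Sequence[str], path: str | Path) -> None:
    """Write a frames x neurons 0/1 raster as delimited text."""
    pd.DataFrame(np.asarray(states, dtype=int), columns=list(neuron_ids)).to_csv(path, index=False)


def load_raster(path: str | Path) -> tuple[np.ndarray, list[str]]:
    tm = load_traces(path)
    states = tm.values
    if not np.isin(states, (0, 1)).all():
        raise TraceIOError(f"raster file {path} contains values outside {{0,1}}")
    return states.astype(np.uint8), tm.neuron_ids


def load_manifest(path: str | Path) -> SessionSet:
    """Load a YAML (or JSON) session manifest.

    Expected structure::

        recordings:
          - mouse: m1
            state: baseline_d1
            traces: m1_d1_traces.csv
            map: m1_d1_map.csv

    Relative paths are resolved against the manifest's directory and must
    exist at load time.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "recordings" not in doc:
        raise TraceIOError(f"manifest {path} must contain a 'recordings' list")
    records = []
    for entry in doc["recordings"]:
        trace_path = (path.parent / entry["traces"]).resolve()
        map_path = (path.parent / entry["map"]).resolve()
        for p in (trace_path, map_path):
            if not p.exists():
                raise TraceIOError(f"manifest {path} references missing file {p}")
        records.append(
            SessionRecord(str(entry["mouse"]), str(entry["state"]), str(trace_path), str(map_path))
        )
    return SessionSet(records)


def save_manifest(sessions: SessionSet, path: str | Path) -> None:
    doc = {
        "recordings": [
            {"mouse": r.mouse_id, "state": r.state, "traces": r.trace_path, "map": r.map_path}
            for r in sessions.records
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def trim_recording(traces: TraceMatrix, head_s: float = 60.0, tail_s: float = 60.0) -> TraceMatrix:
    """Discard the first ``head_s`` and last ``tail_s`` seconds of a recording.

    With the defaults a 7-minute recording yields its middle 5 minutes, the
    fragment on which all metrics are computed.  Neuron order and ids are
    preserved.  Raises :class:`TraceIOError` if nothing would remain.
    """
    head = int(round(head_s * traces.fps))
    tail = int(round(tail_s * traces.fps))
    if head < 0 or tail < 0:
        raise TraceIOError("head_s and tail_s must be non-negative")
    stop = traces.n_frames - tail
    if stop - head <= 0:
        raise TraceIOError(
            f"trimming {head_s}+{tail_s} s leaves no frames of a "
            f"{traces.duration_s:.1f} s recording"
        )
    return TraceMatrix(traces.values[head:stop], fps=traces.fps, neuron_ids=list(traces.neuron_ids))
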