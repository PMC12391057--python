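"""Core domain types and I/O for windowed spike-train recordings.

The analysis operates on an ensemble of N simultaneously recorded neurons whose
spiking has been segmented into S equal-duration time windows (trials, stimulus
presentations, or arbitrary epochs). Spike times inside a window are stored in
seconds relative to the window start.

Supported on-disk representations:

* a long-format delimited table with columns ``neuron_id, window_id,
  spike_time_s`` (plus an optional windows sidecar table giving
  ``window_id, start_s, duration_s[, label]``),
* a JSON document ``{"duration_s": ..., "windows": [...], "neurons":
  {id: {window_id: [times]}}}``,
* continuous per-neuron spike streams on a global clock, cut into windows by
  :func:`segment_stream`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("simnets")

__all__ = [
    "SpikeTrain",
    "Window",
    "WindowTable",
    "EnsembleRecording",
    "read_long_table",
    "write_long_table",
    "read_json",
    "write_json",
    "segment_stream",
    "write_matrix",
    "read_matrix",
]

_TIME_ATOL = 1e-12


def _as_times(times: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(times) if not isinstance(times, np.ndarray) else times,
                     dtype=np.float64).ravel()
    return arr


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times of one neuron within one fixed-duration window.

    Parameters
    ----------
    times
        Spike times in seconds, relative to the window start. Must be
        non-decreasing and lie within ``[0, duration]``. Duplicate times are
        allowed (they are kept; the edit-distance metric handles multisets).
    duration
        Window length in seconds, strictly positive.
    """

    times: np.ndarray
    duration: float

    def __post_init__(self):
        object.__setattr__(self, "times", _as_times(self.times))
        if not np.isfinite(self.duration) or self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        t = self.times
        if t.size:
            if not np.all(np.isfinite(t)):
                raise ValueError("spike times must be finite")
            if np.any(np.diff(t) < 0):
                raise ValueError("spike times must be sorted (non-decreasing)")
            if t[0] < -_TIME_ATOL or t[-1] > self.duration + _TIME_ATOL:
                raise ValueError(
                    f"spike times must lie in [0, {self.duration}], "
                    f"got range [{t[0]}, {t[-1]}]"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def __len__(self) -> int:
        return self.n_spikes


@dataclass(frozen=True)
class Window:
    """One time segment: identifier, global start, duration, optional label."""

    id: str
    start_s: float = 0.0
    duration_s: float = 1.0
    label: str | None = None


class WindowTable:
    """Ordered collection of equal-duration windows."""

    def __init__(self, windows: Sequence[Window]):
        windows = list(windows)
        if not windows:
            raise ValueError("WindowTable needs at least one window")
        durations = {round(w.duration_s, 12) for w in windows}
        if len(durations) > 1:
            bad = sorted({w.id for w in windows})
            raise ValueError(
                f"all windows must share one duration; offending windows: {bad} "
                f"with durations {sorted(durations)}"
            )
        ids = [w.id for w in windows]
        if len(set(ids)) != len(ids):
            raise ValueError("window ids must be unique")
        self.windows = windows

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    @property
    def ids(self) -> list[str]:
        return [w.id for w in self.windows]

    @property
    def duration(self) -> float:
        return self.windows[0].duration_s


class EnsembleRecording:
    """N neurons x S equal-duration windows of :class:`SpikeTrain` objects.

    The train grid is complete: every (neuron, window) cell holds a train,
    possibly empty. Neuron and window order is the declaration order; no
    implicit sorting is applied.
    """

    def __init__(
        self,
        neuron_ids: Sequence[str],
        windows: Sequence[Window] | WindowTable,
        trains: Sequence[Sequence[SpikeTrain]],
    ):
        self.neuron_ids = [str(n) for n in neuron_ids]
        self.windows = list(windows.windows if isinstance(windows, WindowTable)
                            else windows)
        self.trains = [list(row) for row in trains]
        self._validate()

    def _validate(self) -> None:
        n, s = len(self.neuron_ids), len(self.windows)
        if n < 2:
            raise ValueError(f"need at least 2 neurons, got {n}")
        if s < 3:
            raise ValueError(f"need at least 3 windows, got {s}")
        if len(set(self.neuron_ids)) != n:
            raise ValueError("neuron ids must be unique")
        WindowTable(self.windows)  # equal-duration + unique-id check
        dur = self.windows[0].duration_s
        if len(self.trains) != n:
            raise ValueError("train grid row count must equal neuron count")
        for i, row in enumerate(self.trains):
            if len(row) != s:
                raise ValueError(
                    f"neuron {self.neuron_ids[i]}: expected {s} trains, got {len(row)}"
                )
            for tr in row:
                if abs(tr.duration - dur) > _TIME_ATOL:
                    raise ValueError(
                        f"neuron {self.neuron_ids[i]}: train duration {tr.duration} "
                        f"!= window duration {dur}"
                    )

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def duration(self) -> float:
        return self.windows[0].duration_s

    @property
    def window_ids(self) -> list[str]:
        return [w.id for w in self.windows]

    @property
    def window_labels(self) -> list[str | None]:
        return [w.label for w in self.windows]

    def neuron_index(self, neuron_id: str) -> int:
        try:
            return self.neuron_ids.index(neuron_id)
        except ValueError:
            raise KeyError(f"unknown neuron id: {neuron_id!r}") from None

    def trains_for(self, neuron_id: str) -> list[SpikeTrain]:
        return self.trains[self.neuron_index(neuron_id)]

    def total_spikes(self) -> int:
        return sum(tr.n_spikes for row in self.trains for tr in row)

    def reorder_windows(self, order: Sequence[int]) -> "EnsembleRecording":
        """Return a copy with windows (and all trains) re-ordered by ``order``."""
        order = list(order)
        if sorted(order) != list(range(self.n_windows)):
            raise ValueError("order must be a permutation of window indices")
        return EnsembleRecording(
            self.neuron_ids,
            [self.windows[j] for j in order],
            [[row[j] for j in order] for row in self.trains],
        )


# ---------------------------------------------------------------------------
# long-format delimited table
# ---------------------------------------------------------------------------

_REQUIRED_COLS = ("neuron_id", "window_id", "spike_time_s")


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return {"csv": ",", "tsv": "\t"}.get(dialect, dialect)
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def _read_windows_sidecar(path: str | Path, dialect: str | None = None) -> WindowTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect))
    for col in ("window_id", "duration_s"):
        if col not in df.columns:
            raise ValueError(f"windows sidecar {path} missing column {col!r}")
    durations = df["duration_s"].astype(float)
    if durations.nunique() > 1:
        bad = df.loc[durations != durations.iloc[0], "window_id"].tolist()
        raise ValueError(
            f"windows sidecar declares unequal durations; offending windows: {bad}"
        )
    windows = []
    for _, row in df.iterrows():
        windows.append(
            Window(
                id=str(row["window_id"]),
                start_s=float(row.get("start_s", 0.0)) if "start_s" in df.columns else 0.0,
                duration_s=float(row["duration_s"]),
                label=str(row["label"]) if "label" in df.columns and pd.notna(row["label"]) else None,
            )
        )
    return WindowTable(windows)


def read_long_table(
    path: str | Path,
    windows: str | Path | WindowTable | None = None,
    duration_s: float | None = None,
    dialect: str | None = None,
) -> EnsembleRecording:
    """Read a long-format spike table into an :class:`EnsembleRecording`.

    The table must have header columns ``neuron_id, window_id, spike_time_s``;
    spike times are relative to the window start. Window duration comes from
    the ``windows`` sidecar (path or :class:`WindowTable`) or from
    ``duration_s``. Neurons and windows are ordered by first appearance
    (sidecar declaration order takes precedence for windows). A (neuron,
    window) pair absent from the table yields an empty train provided the
    window is known from the sidecar or from another neuron's rows.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect))
    for col in _REQUIRED_COLS:
        if col not in df.columns:
            raise ValueError(f"{path} missing required column {col!r}")
    df = df.copy()
    df["neuron_id"] = df["neuron_id"].astype(str)
    df["window_id"] = df["window_id"].astype(str)

    if isinstance(windows, (str, Path)):
        windows = _read_windows_sidecar(windows, dialect)
    if windows is not None:
        duration = windows.duration
        window_list = list(windows.windows)
    else:
        if duration_s is None:
            raise ValueError("need a windows sidecar or an explicit duration_s")
        duration = float(duration_s)
        window_list = []
    known = {w.id for w in window_list}
    for wid in df["window_id"]:
        if wid not in known:
            window_list.append(Window(id=wid, start_s=0.0, duration_s=duration))
            known.add(wid)

    # bounds check with 1-based data row numbers (header is row 1)
    t = df["spike_time_s"].astype(float).to_numpy()
    bad = np.flatnonzero((t < -_TIME_ATOL) | (t > duration + _TIME_ATOL))
    if bad.size:
        rows = (bad[:5] + 2).tolist()
        raise ValueError(
            f"{path}: spike_time_s outside [0, {duration}] at file row(s) {rows}"
        )

    dup = df.duplicated(subset=["neuron_id", "window_id", "spike_time_s"])
    if dup.any():
        warnings.warn(
            f"{path}: {int(dup.sum())} duplicate (neuron, window, time) rows kept",
            stacklevel=2,
        )

    neuron_ids = list(dict.fromkeys(df["neuron_id"]))
    wid_index = {w.id: j for j, w in enumerate(window_list)}
    grid: list[list[list[float]]] = [
        [[] for _ in window_list] for _ in neuron_ids
    ]
    nid_index = {n: i for i, n in enumerate(neuron_ids)}
    for nid, wid, time in zip(df["neuron_id"], df["window_id"], t):
        grid[nid_index[nid]][wid_index[wid]].append(float(time))
    trains = [
        [SpikeTrain(np.sort(np.asarray(cell)), duration) for cell in row]
        for row in grid
    ]
    return EnsembleRecording(neuron_ids, window_list, trains)


def write_long_table(rec: EnsembleRecording, path: str | Path,
                     windows_path: str | Path | None = None) -> None:
    """Write a recording as a long-format table (plus optional windows sidecar)."""
    path = Path(path)
    sep = _sep_for(path, None)
    rows = []
    for nid, row in zip(rec.neuron_ids, rec.trains):
        for w, tr in zip(rec.windows, row):
            for t in tr.times:
                rows.append((nid, w.id, t))
    pd.DataFrame(rows, columns=list(_REQUIRED_COLS)).to_csv(
        path, sep=sep, index=False, float_format="%.9f"
    )
    if windows_path is not None:
        wdf = pd.DataFrame(
            {
                "window_id": [w.id for w in rec.windows],
                "start_s": [w.start_s for w in rec.windows],
                "duration_s": [w.duration_s for w in rec.windows],
                "label": [w.label for w in rec.windows],
            }
        )
        wdf.to_csv(Path(windows_path), sep=sep, index=False)


# ---------------------------------------------------------------------------
# JSON document
# ---------------------------------------------------------------------------


def read_json(path: str | Path) -> EnsembleRecording:
    """Read the structured JSON spike document."""
    with open(path) as fh:
        doc = json.load(fh)
    duration = float(doc["duration_s"])
    window_list = []
    for w in doc.get("windows", []):
        if isinstance(w, str):
            window_list.append(Window(id=w, duration_s=duration))
        else:
            window_list.append(
                Window(
                    id=str(w["id"]),
                    start_s=float(w.get("start_s", 0.0)),
                    duration_s=duration,
                    label=w.get("label"),
                )
            )
    known = {w.id for w in window_list}
    neurons = doc["neurons"]
    for per_window in neurons.values():
        for wid in per_window:
            if wid not in known:
                window_list.append(Window(id=wid, duration_s=duration))
                known.add(wid)
    neuron_ids = list(neurons)
    trains = [
        [
            SpikeTrain(np.sort(np.asarray(neurons[nid].get(w.id, []), dtype=float)),
                       duration)
            for w in window_list
        ]
        for nid in neuron_ids
    ]
    return EnsembleRecording(neuron_ids, window_list, trains)


def write_json(rec: EnsembleRecording, path: str | Path) -> None:
    doc = {
        "duration_s": rec.duration,
        "windows": [
            {"id": w.id, "start_s": w.start_s, "label": w.label}
            for w in rec.windows
        ],
        "neurons": {
            nid: {w.id: row[j].times.tolist() for j, w in enumerate(rec.windows)}
            for nid, row in zip(rec.neuron_ids, rec.trains)
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# stream segmentation
# ---------------------------------------------------------------------------


def segment_stream(
    streams: Mapping[str, Iterable[float]], windows: WindowTable | Sequence[Window]
) -> EnsembleRecording:
    """Cut continuous per-neuron spike streams into an equal-duration window grid.

    Each window takes spikes with ``start_s <= t < start_s + duration`` (half-
    open, so a spike exactly on a boundary belongs to the following window
    only), re-referenced to the window start. Overlapping windows are
    permitted — spikes are then duplicated across windows — and logged.
    """
    table = windows if isinstance(windows, WindowTable) else WindowTable(windows)
    starts = np.array([w.start_s for w in table], dtype=float)
    dur = table.duration
    order = np.argsort(starts, kind="stable")
    if np.any(starts[order][1:] < starts[order][:-1] + dur - _TIME_ATOL):
        logger.info("segment_stream: overlapping windows; spikes may be duplicated")

    neuron_ids = list(streams)
    trains = []
    for nid in neuron_ids:
        t = _as_times(streams[nid])
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError(f"stream for neuron {nid!r} is not sorted")
        row = []
        for w in table:
            lo = np.searchsorted(t, w.start_s, side="left")
            hi = np.searchsorted(t, w.start_s + dur, side="left")
            row.append(SpikeTrain(t[lo:hi] - w.start_s, dur))
        trains.append(row)
    return EnsembleRecording(neuron_ids, table, trains)


# ---------------------------------------------------------------------------
# matrix I/O
# ---------------------------------------------------------------------------


def write_matrix(matrix: np.ndarray, path: str | Path,
                 ids: Sequence[str] | None = None) -> None:
    """Write a square matrix as a delimited table with row/column headers."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {matrix.shape}")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matrix contains non-finite entries")
    if ids is None:
        ids = [str(i) for i in range(matrix.shape[0])]
    path = Path(path)
    pd.DataFrame(matrix, index=list(ids), columns=list(ids)).to_csv(
        path, sep=_sep_for(path, None), float_format="%.12g"
    )


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, None), index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]
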