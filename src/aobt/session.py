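"""Core data types and plain-text I/O for trial-structured single-unit sessions.

A session bundles one or more sorted spike trains, a trial table of stimulus
events, and a stimulus panel with a designated solvent-control stimulus
(e.g. Ringer's solution).  All times are seconds from session start, 0-based.

On disk a session is a directory of transparent text files::

    spikes.csv   cell_id, spike_time_s          (one row per spike)
    cells.csv    cell_id                        (cell index; keeps empty trains)
    trials.csv   stimulus_id, onset_s, offset_s, repeat_index
    panel.json   {"stimuli": [{"id", "label", "tag"}...], "control": id}
    meta.json    free-form metadata (seed, generator config, duration, ...)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class SessionFormatError(Exception):
    """A session directory is missing files or malformed."""


class SessionValidationError(Exception):
    """Session content violates a structural invariant."""


# Stimulus epochs in the emulated experiments last 3-5 s; sessions whose
# trial table falls outside these bounds are rejected unless overridden.
DEFAULT_DURATION_BOUNDS = (3.0, 5.0)


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times for one sorted unit.

    Parameters
    ----------
    cell_id : str
        Unit identifier, unique within a session.
    spike_times : ndarray
        Strictly increasing spike times in seconds from session start, >= 0.
    """

    cell_id: str
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        if times.ndim != 1:
            raise SessionValidationError(
                f"cell {self.cell_id}: spike_times must be 1-D"
            )
        if times.size and times[0] < 0:
            raise SessionValidationError(
                f"cell {self.cell_id}: negative spike time {times[0]}"
            )
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise SessionValidationError(
                f"cell {self.cell_id}: spike times not strictly increasing"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeTrain):
            return NotImplemented
        return self.cell_id == other.cell_id and np.array_equal(
            self.spike_times, other.spike_times
        )

    def __len__(self) -> int:
        return int(self.spike_times.size)


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus delivery: identity, epoch and repeat number."""

    stimulus_id: str
    onset: float
    offset: float
    repeat_index: int

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise SessionValidationError(
                f"event {self.stimulus_id}: offset {self.offset} <= onset {self.onset}"
            )
        if self.repeat_index < 1:
            raise SessionValidationError(
                f"event {self.stimulus_id}: repeat_index must be >= 1"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class StimulusPanel:
    """The stimulus battery: ids, labels, optional group tags, one control.

    The control is the solvent-only stimulus (Ringer's solution in the
    emulated experiments); responses to it disqualify a cell from analysis.
    """

    stimulus_ids: tuple
    control: str
    labels: Mapping[str, str] = field(default_factory=dict)
    tags: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = tuple(self.stimulus_ids)
        object.__setattr__(self, "stimulus_ids", ids)
        # normalize: every stimulus carries a label (defaulting to its id),
        # so panels compare equal across an I/O round trip
        labels = {s: self.labels.get(s, s) for s in ids}
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "tags", dict(self.tags))
        if len(set(ids)) != len(ids):
            raise SessionValidationError("duplicate stimulus ids in panel")
        if self.control not in ids:
            raise SessionValidationError(
                f"control stimulus {self.control!r} not in panel"
            )

    @property
    def test_stimulus_ids(self) -> tuple:
        """All stimulus ids except the control, in panel order."""
        return tuple(s for s in self.stimulus_ids if s != self.control)

    def label(self, stimulus_id: str) -> str:
        return self.labels.get(stimulus_id, stimulus_id)


@dataclass
class Session:
    """One recording session: spike trains + trial table + stimulus panel."""

    trains: list
    trials: list
    panel: StimulusPanel
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trains = list(self.trains)
        self.trials = list(self.trials)
        self.validate()

    # -- access helpers -------------------------------------------------
    @property
    def cell_ids(self) -> list:
        return [t.cell_id for t in self.trains]

    def train(self, cell_id: str) -> SpikeTrain:
        for t in self.trains:
            if t.cell_id == cell_id:
                return t
        raise KeyError(cell_id)

    def events_for(self, stimulus_id: str) -> list:
        return [e for e in self.trials if e.stimulus_id == stimulus_id]

    @property
    def duration(self) -> float:
        """Recorded span in seconds (from metadata, else inferred)."""
        if "duration_s" in self.metadata:
            return float(self.metadata["duration_s"])
        last_event = max((e.offset for e in self.trials), default=0.0)
        last_spike = max(
            (t.spike_times[-1] for t in self.trains if len(t)), default=0.0
        )
        return max(last_event + 15.0, last_spike)

    # -- validation ------------------------------------------------------
    def validate(self, duration_bounds=DEFAULT_DURATION_BOUNDS) -> None:
        """Check structural invariants; raise SessionValidationError."""
        seen = set()
        for t in self.trains:
            if t.cell_id in seen:
                raise SessionValidationError(f"duplicate cell id {t.cell_id!r}")
            seen.add(t.cell_id)
        lo, hi = duration_bounds
        for e in self.trials:
            if e.stimulus_id not in self.panel.stimulus_ids:
                raise SessionValidationError(
                    f"trial references unknown stimulus {e.stimulus_id!r}"
                )
            if not (lo - 1e-9 <= e.duration <= hi + 1e-9):
                raise SessionValidationError(
                    f"stimulus epoch duration {e.duration:.3f} s outside "
                    f"[{lo}, {hi}] s for {e.stimulus_id!r}"
                )

    def repeat_counts(self) -> pd.Series:
        """Number of delivered repeats per stimulus id."""
        ids = [e.stimulus_id for e in self.trials]
        return pd.Series(ids, dtype=object).value_counts().sort_index()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Session):
            return NotImplemented
        return (
            self.trains == other.trains
            and self.trials == other.trials
            and self.panel == other.panel
            and self.metadata == other.metadata
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def write_session(session: Session, path) -> None:
    """Write a session to ``path`` (a directory, created if needed).

    The representation is bit-stable given fixed float formatting: writing
    the same session twice produces byte-identical files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rows = [
        (t.cell_id, s) for t in session.trains for s in t.spike_times
    ]
    spikes = pd.DataFrame(rows, columns=["cell_id", "spike_time_s"])
    spikes.to_csv(path / "spikes.csv", index=False, float_format=_FLOAT_FMT)

    cells = pd.DataFrame({"cell_id": session.cell_ids})
    cells.to_csv(path / "cells.csv", index=False)

    trials = pd.DataFrame(
        [
            (e.stimulus_id, e.onset, e.offset, e.repeat_index)
            for e in session.trials
        ],
        columns=["stimulus_id", "onset_s", "offset_s", "repeat_index"],
    )
    trials.to_csv(path / "trials.csv", index=False, float_format=_FLOAT_FMT)

    panel = {
        "stimuli": [
            {
                "id": s,
                "label": session.panel.labels.get(s, s),
                "tag": session.panel.tags.get(s),
            }
            for s in session.panel.stimulus_ids
        ],
        "control": session.panel.control,
    }
    (path / "panel.json").write_text(
        json.dumps(panel, indent=2, sort_keys=True) + "\n"
    )
    (path / "meta.json").write_text(
        json.dumps(session.metadata, indent=2, sort_keys=True) + "\n"
    )


def read_session(path) -> Session:
    """Read and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    for fname in ("spikes.csv", "cells.csv", "trials.csv", "panel.json", "meta.json"):
        if not (path / fname).exists():
            raise SessionFormatError(f"missing {fname} in {path}")

    panel_doc = json.loads((path / "panel.json").read_text())
    if "control" not in panel_doc or panel_doc["control"] is None:
        raise SessionFormatError("panel.json does not designate a control stimulus")
    panel = StimulusPanel(
        stimulus_ids=tuple(s["id"] for s in panel_doc["stimuli"]),
        control=panel_doc["control"],
        labels={s["id"]: s.get("label", s["id"]) for s in panel_doc["stimuli"]},
        tags={
            s["id"]: s["tag"]
            for s in panel_doc["stimuli"]
            if s.get("tag") is not None
        },
    )

    cells = pd.read_csv(path / "cells.csv", dtype={"cell_id": str})
    spikes = pd.read_csv(
        path / "spikes.csv",
        dtype={"cell_id": str, "spike_time_s": float},
        float_precision="round_trip",
    )
    grouped = {k: v["spike_time_s"].to_numpy() for k, v in spikes.groupby("cell_id")}
    trains = [
        SpikeTrain(cid, grouped.get(cid, np.empty(0)))
        for cid in cells["cell_id"]
    ]

    trial_df = pd.read_csv(
        path / "trials.csv", dtype={"stimulus_id": str},
        float_precision="round_trip",
    )
    trials = [
        StimulusEvent(r.stimulus_id, r.onset_s, r.offset_s, int(r.repeat_index))
        for r in trial_df.itertuples()
    ]

    metadata = json.loads((path / "meta.json").read_text())
    return Session(trains=trains, trials=trials, panel=panel, metadata=metadata)
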