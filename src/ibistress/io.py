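"""Reading, validating, filtering and labelling inter-beat-interval (IBI) sequences.

The on-disk dialect is the Empatica E4 ``IBI.csv`` export: an optional first
line ``<session-start epoch>, IBI`` followed by two comma-separated numeric
columns — the timestamp of each detected beat (seconds since session start)
and the duration of that beat (seconds).  Plain headerless two-column CSV is
accepted too, so synthetic fixtures round-trip through the same reader.

An :class:`IBISequence` additionally carries recorded *segment boundaries*:
when several recording segments are concatenated (e.g. the public-speaking
and mental-arithmetic tasks merged into one "stressed" sequence), downstream
sliding windows must never span the join.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Default physiologic IBI range in seconds (50-100 bpm).
PHYSIO_LOW = 0.6
PHYSIO_HIGH = 1.2

#: Decimal places written by :func:`write_ibi_file`; round-trips are exact
#: at this precision.
CSV_DECIMALS = 9


class Condition(str, Enum):
    """Binary affective condition label."""

    STRESSED = "stressed"
    NON_STRESSED = "non_stressed"


class IBIFormatError(ValueError):
    """Raised when an IBI file cannot be parsed."""


class EmptyInputError(IBIFormatError):
    """Raised when an IBI file contains no data rows."""


@dataclass(frozen=True)
class IBISequence:
    """A subject's ordered beat durations with timestamps and label.

    Parameters
    ----------
    subject_id
        Opaque subject identifier.
    condition
        ``Condition.STRESSED`` or ``Condition.NON_STRESSED``.
    timestamps
        Seconds since session start, strictly increasing.
    durations
        Beat-to-beat intervals in seconds, positive, same length.
    boundaries
        Sorted start indices (into ``durations``) of segments after the
        first; windows never cross these.
    """

    subject_id: str
    condition: Condition
    timestamps: np.ndarray
    durations: np.ndarray
    boundaries: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        dur = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "durations", dur)
        object.__setattr__(self, "condition", Condition(self.condition))
        if ts.ndim != 1 or dur.ndim != 1 or ts.shape != dur.shape:
            raise ValueError("timestamps and durations must be 1-D and equal length")
        if ts.size and np.any(np.diff(ts) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(dur <= 0):
            raise ValueError("durations must all be positive")
        b = tuple(sorted(int(i) for i in self.boundaries))
        if any(i <= 0 or i >= dur.size for i in b):
            raise ValueError("boundaries must lie strictly inside the sequence")
        if len(set(b)) != len(b):
            raise ValueError("duplicate boundary indices")
        object.__setattr__(self, "boundaries", b)

    @property
    def n_beats(self) -> int:
        return int(self.durations.size)

    def segments(self) -> list[tuple[int, int]]:
        """Half-open ``(start, stop)`` index ranges of unbroken segments."""
        cuts = [0, *self.boundaries, self.n_beats]
        return [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]


def _detect_header(first_line: str) -> bool:
    """E4 files start with ``<epoch>, IBI``; any non two-numeric line is a header."""
    parts = [p.strip() for p in first_line.split(",")]
    if len(parts) != 2:
        return True
    try:
        float(parts[0]), float(parts[1])
    except ValueError:
        return True
    return False


def read_ibi_file(path: str | Path, subject_id: str, condition: Condition | str) -> IBISequence:
    """Parse an E4-dialect IBI CSV into an :class:`IBISequence`.

    A JSON sidecar written by :func:`write_ibi_file` (same stem, ``.json``)
    supplies segment boundaries when present.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    EmptyInputError
        If no data rows remain after the optional header.
    IBIFormatError
        On a non-numeric or malformed data row (the message names the line).
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise EmptyInputError(f"{path}: file contains no data")
    skip = 1 if _detect_header(lines[0]) else 0
    data_lines = lines[skip:]
    if not data_lines:
        raise EmptyInputError(f"{path}: no data rows after header")

    frame = pd.DataFrame([ln.split(",") for ln in data_lines])
    if frame.shape[1] != 2:
        bad = int((frame.notna().sum(axis=1) != 2).idxmax())
        raise IBIFormatError(
            f"{path}: line {bad + skip + 1}: expected two comma-separated columns"
        )
    ts = pd.to_numeric(frame[0].str.strip(), errors="coerce")
    dur = pd.to_numeric(frame[1].str.strip(), errors="coerce")
    bad_rows = np.flatnonzero(ts.isna().to_numpy() | dur.isna().to_numpy())
    if bad_rows.size:
        lineno = int(bad_rows[0]) + skip + 1
        raise IBIFormatError(f"{path}: line {lineno}: non-numeric value")

    boundaries: tuple[int, ...] = ()
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        boundaries = tuple(meta.get("boundaries", ()))
    return IBISequence(
        subject_id=subject_id,
        condition=Condition(condition),
        timestamps=ts.to_numpy(dtype=float),
        durations=dur.to_numpy(dtype=float),
        boundaries=boundaries,
    )


def write_ibi_file(seq: IBISequence, path: str | Path, session_start: float = 0.0) -> Path:
    """Serialize a sequence in the E4 dialect plus a JSON sidecar.

    The sidecar records subject, condition and segment boundaries so that
    :func:`read_ibi_file` reproduces the sequence exactly.
    """
    path = Path(path)
    fmt = f"%.{CSV_DECIMALS}f"
    with open(path, "w") as fh:
        fh.write(f"{session_start:.6f}, IBI\n")
        for t, d in zip(seq.timestamps, seq.durations):
            fh.write(f"{fmt % t},{fmt % d}\n")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "subject_id": seq.subject_id,
                "condition": seq.condition.value,
                "boundaries": list(seq.boundaries),
            },
            indent=0,
        )
    )
    return path


def filter_physiologic(
    seq: IBISequence, low: float = PHYSIO_LOW, high: float = PHYSIO_HIGH
) -> IBISequence:
    """Keep exactly the beats with ``low <= duration <= high``, order preserved.

    Segment boundaries are remapped to their positions in the filtered
    sequence.  Idempotent; may return an empty sequence.
    """
    if not low < high:
        raise ValueError(f"low must be < high (got {low}, {high})")
    mask = (seq.durations >= low) & (seq.durations <= high)
    kept_before = np.cumsum(mask)  # kept count up to and including i
    new_b = []
    n_kept = int(kept_before[-1]) if mask.size else 0
    for b in seq.boundaries:
        nb = int(kept_before[b - 1]) if b > 0 else 0
        if 0 < nb < n_kept:
            new_b.append(nb)
    return replace(
        seq,
        timestamps=seq.timestamps[mask],
        durations=seq.durations[mask],
        boundaries=tuple(sorted(set(new_b))),
    )


def merge_stress_segments(segments: Sequence[IBISequence]) -> IBISequence:
    """Concatenate same-subject stressed segments, recording the joins.

    Mirrors pooling the public-speaking and mental-arithmetic task recordings
    into one "stressed" sequence.  Timestamps of later segments are shifted
    so the merged timeline stays strictly increasing; a boundary index is
    recorded at every join so sliding windows never span one.
    """
    if not segments:
        raise ValueError("no segments to merge")
    subj = segments[0].subject_id
    for s in segments:
        if s.subject_id != subj:
            raise ValueError(
                f"cannot merge segments from different subjects ({s.subject_id!r} vs {subj!r})"
            )
        if s.condition is not Condition.STRESSED:
            raise ValueError("merge_stress_segments accepts only stressed segments")
    if len(segments) == 1:
        return segments[0]

    ts_parts, dur_parts, boundaries = [], [], []
    offset = 0.0
    n = 0
    for s in segments:
        shift = offset - s.timestamps[0] + s.durations[0] if n else 0.0
        ts_parts.append(s.timestamps + shift)
        dur_parts.append(s.durations)
        boundaries.extend(n + b for b in s.boundaries)
        if n:
            boundaries.append(n)
        n += s.n_beats
        offset = ts_parts[-1][-1]
    return IBISequence(
        subject_id=subj,
        condition=Condition.STRESSED,
        timestamps=np.concatenate(ts_parts),
        durations=np.concatenate(dur_parts),
        boundaries=tuple(sorted(boundaries)),
    )
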