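"""Reading and writing performances as Standard MIDI Files.

Connects the SMF codec to the in-package note-event representation.
Times are converted to seconds on read and quantised to ticks (PPQ 480,
120 BPM) on write; all channels are merged and the percussion channel
ignored, matching the single-strand piano material the measures target.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional

from melodymetrics import smf
from melodymetrics.errors import EmptyPerformanceError
from melodymetrics.events import NoteEvent, Performance, PerformanceMetadata

METADATA_COLUMNS = [
    "participant_id",
    "group",
    "session",
    "item",
    "instrument",
    "imprct",
    "repct",
    "nimptasks",
    "claimed_tasks",
    "midi_path",
]


def read_midi(
    path,
    *,
    metadata: Optional[PerformanceMetadata] = None,
    unclosed: str = "close",
) -> Performance:
    """Read an SMF type 0/1 file into a :class:`Performance`.

    The tempo map is applied so onsets/offsets are in seconds. Metadata
    fields are left unset unless a sidecar-provided ``metadata`` object
    is supplied. ``unclosed`` ("close" | "error") controls note-ons with
    no matching note-off.

    Raises
    ------
    MidiFormatError
        If the file is not parseable SMF.
    EmptyPerformanceError
        If the file contains no paired notes.
    """
    raw = smf.read_smf(path, unclosed=unclosed)
    if not raw:
        raise EmptyPerformanceError(f"{path}: no notes found")
    notes = [
        NoteEvent(n.pitch, n.onset, n.offset, max(1, n.velocity)) for n in raw
    ]
    return Performance(notes, metadata or PerformanceMetadata())


def write_midi(performance: Performance, path) -> None:
    """Write a performance as a single-track type-0 SMF.

    Fixed tempo 120 BPM, PPQ 480; onsets/offsets quantised to the
    nearest tick (sub-tick notes are stretched to one tick).

    Raises
    ------
    EmptyPerformanceError
        If the performance has no notes.
    """
    if not performance.notes:
        raise EmptyPerformanceError("refusing to write an empty performance")
    raw = [
        smf.RawNote(n.pitch, n.onset, n.offset, n.velocity, channel=0)
        for n in performance.notes
    ]
    smf.write_smf(raw, path)


def _parse_metadata_row(row: dict) -> PerformanceMetadata:
    def _int(key):
        value = row.get(key, "")
        return int(value) if value not in ("", None) else None

    tasks = row.get("claimed_tasks", "") or ""
    claimed = tuple(int(t) for t in str(tasks).split(";") if t.strip())
    return PerformanceMetadata(
        participant_id=row.get("participant_id") or None,
        group=row.get("group") or None,
        session=row.get("session") or None,
        item=_int("item"),
        instrument=row.get("instrument") or None,
        imprct=_int("imprct"),
        repct=_int("repct"),
        nimptasks=_int("nimptasks"),
        claimed_tasks=claimed,
    )


def read_metadata_csv(path) -> list[tuple[Path, PerformanceMetadata]]:
    """Read a sidecar metadata CSV; returns (midi_path, metadata) pairs.

    MIDI paths are resolved relative to the CSV's directory.
    """
    base = Path(path).parent
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            midi_path = Path(row["midi_path"])
            if not midi_path.is_absolute():
                midi_path = base / midi_path
            out.append((midi_path, _parse_metadata_row(row)))
    return out


def metadata_to_row(meta: PerformanceMetadata, midi_path="") -> dict:
    """Flatten metadata into a sidecar CSV row."""
    return {
        "participant_id": meta.participant_id or "",
        "group": meta.group or "",
        "session": meta.session or "",
        "item": "" if meta.item is None else meta.item,
        "instrument": meta.instrument or "",
        "imprct": "" if meta.imprct is None else meta.imprct,
        "repct": "" if meta.repct is None else meta.repct,
        "nimptasks": "" if meta.nimptasks is None else meta.nimptasks,
        "claimed_tasks": ";".join(str(t) for t in meta.claimed_tasks),
        "midi_path": str(midi_path),
    }
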