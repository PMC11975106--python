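"""Minimal Standard MIDI File (SMF) codec.

Reads type 0/1 files with pulses-per-quarter-note timing, applying the
tempo map to produce onsets/offsets in seconds; writes single-track
type 0 files at a fixed tempo. Only the event vocabulary the package
needs is interpreted (note on/off, set-tempo); everything else is
skipped structurally. SMPTE division and multi-port subtleties are out
of scope.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

from melodymetrics.errors import MidiFormatError

DEFAULT_TEMPO_US = 500_000  # microseconds per quarter note (120 BPM)
WRITE_PPQ = 480

_CHANNEL_DATA_LEN = {0x8: 2, 0x9: 2, 0xA: 2, 0xB: 2, 0xC: 1, 0xD: 1, 0xE: 2}
_PERCUSSION_CHANNEL = 9  # MIDI channel 10


@dataclass(frozen=True)
class RawNote:
    """A paired note with times in seconds (tempo map already applied)."""

    pitch: int
    onset: float
    offset: float
    velocity: int
    channel: int


def _read_varlen(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    for _ in range(4):
        if pos >= len(data):
            raise MidiFormatError("truncated variable-length quantity")
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos
    raise MidiFormatError("variable-length quantity exceeds 4 bytes")


def _write_varlen(value: int) -> bytes:
    if value < 0:
        raise ValueError("negative delta time")
    chunks = [value & 0x7F]
    value >>= 7
    while value:
        chunks.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(chunks))


def _parse_track(data: bytes):
    """Yield (abs_tick, status, payload) triples from one MTrk body."""
    pos = 0
    tick = 0
    running_status = None
    while pos < len(data):
        delta, pos = _read_varlen(data, pos)
        tick += delta
        if pos >= len(data):
            raise MidiFormatError("event expected after delta time")
        status = data[pos]
        if status & 0x80:
            pos += 1
            if status < 0xF0:
                running_status = status
        else:
            if running_status is None:
                raise MidiFormatError("data byte with no running status")
            status = running_status
        if status == 0xFF:  # meta
            if pos >= len(data):
                raise MidiFormatError("truncated meta event")
            meta_type = data[pos]
            length, pos = _read_varlen(data, pos + 1)
            payload = data[pos : pos + length]
            if len(payload) != length:
                raise MidiFormatError("truncated meta payload")
            pos += length
            yield tick, status, (meta_type, payload)
            if meta_type == 0x2F:  # end of track
                return
        elif status in (0xF0, 0xF7):  # sysex
            length, pos = _read_varlen(data, pos)
            pos += length
        elif status >= 0xF0:
            # system common: F1/F3 carry one data byte, F2 two, rest none
            pos += {0xF1: 1, 0xF2: 2, 0xF3: 1}.get(status, 0)
        else:
            nbytes = _CHANNEL_DATA_LEN[status >> 4]
            payload = data[pos : pos + nbytes]
            if len(payload) != nbytes:
                raise MidiFormatError("truncated channel event")
            pos += nbytes
            yield tick, status, payload


class _TempoMap:
    """Piecewise-constant tempo; converts absolute ticks to seconds."""

    def __init__(self, changes: list[tuple[int, int]], ppq: int):
        changes = sorted(changes)
        if not changes or changes[0][0] > 0:
            changes.insert(0, (0, DEFAULT_TEMPO_US))
        self._ticks = [t for t, _ in changes]
        self._seconds = [0.0]
        for (t0, us), (t1, _) in zip(changes, changes[1:]):
            self._seconds.append(
                self._seconds[-1] + (t1 - t0) * us / (ppq * 1e6)
            )
        self._tempos = [us for _, us in changes]
        self._ppq = ppq

    def to_seconds(self, tick: int) -> float:
        # linear scan is fine: tempo maps here have a handful of entries
        i = 0
        while i + 1 < len(self._ticks) and self._ticks[i + 1] <= tick:
            i += 1
        return self._seconds[i] + (tick - self._ticks[i]) * self._tempos[i] / (
            self._ppq * 1e6
        )


def read_smf(path, *, unclosed: str = "close") -> list[RawNote]:
    """Parse an SMF file into paired notes with times in seconds.

    All channels are merged; the percussion channel (10) is ignored.
    Velocity-0 note-ons are treated as note-offs. ``unclosed`` controls
    notes lacking a note-off: "close" ends them at the track's final
    tick, "error" raises.
    """
    if unclosed not in ("close", "error"):
        raise ValueError("unclosed must be 'close' or 'error'")
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < 14 or data[:4] != b"MThd":
        raise MidiFormatError("missing MThd header")
    hlen, fmt, ntrks, division = struct.unpack(">IHHH", data[4:14])
    if hlen != 6:
        raise MidiFormatError(f"unexpected MThd length {hlen}")
    if fmt not in (0, 1):
        raise MidiFormatError(f"unsupported SMF format {fmt}")
    if division & 0x8000:
        raise MidiFormatError("SMPTE time division is not supported")
    ppq = division
    if ppq == 0:
        raise MidiFormatError("zero pulses-per-quarter division")

    pos = 14
    tracks = []
    for _ in range(ntrks):
        if pos + 8 > len(data):
            raise MidiFormatError("truncated track header")
        if data[pos : pos + 4] != b"MTrk":
            raise MidiFormatError("missing MTrk chunk")
        (tlen,) = struct.unpack(">I", data[pos + 4 : pos + 8])
        body = data[pos + 8 : pos + 8 + tlen]
        if len(body) != tlen:
            raise MidiFormatError("truncated track body")
        tracks.append(list(_parse_track(body)))
        pos += 8 + tlen

    tempo_changes: list[tuple[int, int]] = []
    for track in tracks:
        for tick, status, payload in track:
            if status == 0xFF and payload[0] == 0x51:
                meta = payload[1]
                if len(meta) != 3:
                    raise MidiFormatError("malformed set-tempo event")
                tempo_changes.append((tick, int.from_bytes(meta, "big")))
    tmap = _TempoMap(tempo_changes, ppq)

    notes: list[RawNote] = []
    end_tick = max(
        (tick for track in tracks for tick, _, _ in track), default=0
    )
    open_notes: dict[tuple[int, int], list[tuple[int, int]]] = {}
    merged = sorted(
        (tick, status, payload)
        for track in tracks
        for tick, status, payload in track
        if status < 0xF0
    )
    for tick, status, payload in merged:
        kind, channel = status >> 4, status & 0x0F
        if channel == _PERCUSSION_CHANNEL:
            continue
        if kind == 0x9 and payload[1] > 0:
            open_notes.setdefault((channel, payload[0]), []).append(
                (tick, payload[1])
            )
        elif kind == 0x8 or (kind == 0x9 and payload[1] == 0):
            stack = open_notes.get((channel, payload[0]))
            if stack:
                on_tick, velocity = stack.pop(0)
                if tick > on_tick:
                    notes.append(
                        RawNote(
                            payload[0],
                            tmap.to_seconds(on_tick),
                            tmap.to_seconds(tick),
                            velocity,
                            channel,
                        )
                    )
    leftovers = [(k, v) for k, vs in open_notes.items() for v in vs]
    if leftovers:
        if unclosed == "error":
            raise MidiFormatError(
                f"{len(leftovers)} note-on event(s) lack a matching note-off"
            )
        for (channel, pitch), (on_tick, velocity) in leftovers:
            if end_tick > on_tick:
                notes.append(
                    RawNote(
                        pitch,
                        tmap.to_seconds(on_tick),
                        tmap.to_seconds(end_tick),
                        velocity,
                        channel,
                    )
                )
    notes.sort(key=lambda n: (n.onset, n.pitch))
    return notes


def write_smf(notes: list[RawNote], path) -> None:
    """Write a type-0 SMF at 120 BPM, PPQ 480; times quantised to ticks.

    A note quantised to zero length is stretched to one tick so no note
    vanishes on round trip.
    """
    ticks_per_second = WRITE_PPQ * 1e6 / DEFAULT_TEMPO_US
    events: list[tuple[int, int, bytes]] = []  # (tick, order, payload)
    for note in notes:
        on = round(note.onset * ticks_per_second)
        off = round(note.offset * ticks_per_second)
        if off <= on:
            off = on + 1
        status = 0x90 | (note.channel & 0x0F)
        events.append((on, 1, bytes([status, note.pitch, note.velocity])))
        events.append((off, 0, bytes([0x80 | (note.channel & 0x0F), note.pitch, 0])))
    events.sort(key=lambda e: (e[0], e[1]))

    body = bytearray()
    body += _write_varlen(0) + bytes([0xFF, 0x51, 0x03]) + DEFAULT_TEMPO_US.to_bytes(3, "big")
    tick = 0
    for etick, _, payload in events:
        body += _write_varlen(etick - tick) + payload
        tick = etick
    body += _write_varlen(0) + bytes([0xFF, 0x2F, 0x00])

    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 0, 1, WRITE_PPQ))
        fh.write(b"MTrk" + struct.pack(">I", len(body)) + bytes(body))
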