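"""Canonical indel-allele descriptors.

An allele observed in an amplicon is identified purely by the indel events it
carries relative to the reference sequence; substitutions are treated as
sequencing noise elsewhere and never enter the identity. The descriptor
grammar is::

    WT                          no indel events
    D:<start>:<length>          deletion of <length> reference bases at
                                0-based reference offset <start>
    I:<pos>:<bases>             insertion of <bases> before reference
                                offset <pos>

Multiple events are semicolon-joined in ascending reference position.
Because an indel inside a repeat has several equivalent placements, events
are *left-aligned* against the reference before formatting, so every
equivalent alignment maps to a single canonical descriptor.
"""

from __future__ import annotations

from typing import Iterable

WT = "WT"

# An event is ("D", start, length) or ("I", pos, bases).
Event = tuple


def left_align_deletion(ref: str, start: int, length: int) -> tuple[int, int]:
    """Shift a deletion to its leftmost equivalent placement."""
    while start > 0 and ref[start - 1] == ref[start + length - 1]:
        start -= 1
    return start, length


def left_align_insertion(ref: str, pos: int, bases: str) -> tuple[int, str]:
    """Shift an insertion to its leftmost equivalent placement.

    Rotating the inserted string while stepping left preserves the resulting
    sequence (standard VCF-style normalization).
    """
    while pos > 0 and bases and ref[pos - 1] == bases[-1]:
        bases = ref[pos - 1] + bases[:-1]
        pos -= 1
    return pos, bases


def normalize_events(ref: str, events: Iterable[Event]) -> list[Event]:
    out = []
    for ev in events:
        if ev[0] == "D":
            s, l = left_align_deletion(ref, ev[1], ev[2])
            out.append(("D", s, l))
        elif ev[0] == "I":
            p, b = left_align_insertion(ref, ev[1], ev[2])
            out.append(("I", p, b))
        else:  # pragma: no cover - guarded by construction
            raise ValueError(f"unknown event kind {ev[0]!r}")
    out.sort(key=lambda e: (e[1], e[0]))
    return out


def format_descriptor(events: Iterable[Event]) -> str:
    parts = []
    for ev in events:
        if ev[0] == "D":
            parts.append(f"D:{ev[1]}:{ev[2]}")
        else:
            parts.append(f"I:{ev[1]}:{ev[2]}")
    return ";".join(parts) if parts else WT


def parse_descriptor(descriptor: str) -> list[Event]:
    if descriptor == WT:
        return []
    events: list[Event] = []
    for part in descriptor.split(";"):
        kind, pos, payload = part.split(":")
        if kind == "D":
            events.append(("D", int(pos), int(payload)))
        elif kind == "I":
            events.append(("I", int(pos), payload))
        else:
            raise ValueError(f"bad event {part!r} in descriptor {descriptor!r}")
    return events


def apply_events(ref: str, events: Iterable[Event]) -> str:
    """Apply indel events (non-overlapping, ascending) to a reference string."""
    events = sorted(events, key=lambda e: e[1])
    out = []
    cursor = 0
    for ev in events:
        if ev[1] < cursor:
            raise ValueError("overlapping indel events")
        out.append(ref[cursor : ev[1]])
        if ev[0] == "D":
            cursor = ev[1] + ev[2]
        else:
            out.append(ev[2])
            cursor = ev[1]
    out.append(ref[cursor:])
    return "".join(out)
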