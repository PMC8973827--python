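"""Note text standardization and rule-based sentence splitting.

Raw H&P note text arrives with inconsistent whitespace, carriage
returns, and non-printing characters.  :func:`normalize_note` collapses
all of that to single spaces while preserving casing and punctuation;
:func:`split_sentences` then segments the normalized text on
sentence-final punctuation with an abbreviation guard, plus bullet
markers and ALL-CAPS section headers ("ASSESSMENT:"), which are common
sentence-like fragments in clinical notes.  The splitter is a
deterministic rule system: explicit, fixture-tested, and cheap.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "NoteDocument",
    "Sentence",
    "normalize_note",
    "split_sentences",
    "sentences_from_note",
    "read_notes_jsonl",
    "write_notes_jsonl",
]


@dataclass(frozen=True)
class NoteDocument:
    """One history-and-physical note with its position in the
    patient → encounter → note hierarchy."""

    note_id: str
    encounter_id: str
    patient_id: str
    text: str
    note_time: str = ""

    def __post_init__(self) -> None:
        for name in ("note_id", "encounter_id", "patient_id"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")


@dataclass(frozen=True)
class Sentence:
    note_id: str
    index: int
    text: str
    char_span: tuple[int, int]


# Abbreviations whose trailing period never ends a sentence.
_GUARDED = {"dr", "mr", "mrs", "ms", "prof", "st", "vs", "e.g", "i.e", "a.m", "p.m"}

_HEADER_RE = re.compile(r"\b[A-Z][A-Z /&]{1,}:(?=\s)")
_BULLET_RE = re.compile(r"\s[-•*]\s")
_TERMINAL_RE = re.compile(r"[.!?]+(?=\s|$)")


def normalize_note(raw_text: str) -> str:
    """Collapse whitespace runs to single spaces and drop non-printing
    characters; casing and punctuation are untouched (case folding
    happens inside matching/classification, never here)."""
    if not raw_text:
        return ""
    text = "".join(ch for ch in raw_text if ch.isprintable() or ch in "\t\n\r")
    text = re.sub(r"\s+", " ", text)
    return text.strip()


def _is_guarded_period(text: str, dot_pos: int, end: int) -> bool:
    """Decide whether the period at ``dot_pos`` belongs to an abbreviation."""
    before = text[:dot_pos]
    m = re.search(r"([A-Za-z][A-Za-z.]*)$", before)
    if not m:
        return False
    token = m.group(1).lower().rstrip(".")
    if token in _GUARDED:
        return True
    if len(token) == 1 and token.isalpha() and m.group(1)[0].isupper():
        return True  # personal initial, "J. Smith"
    if token == "pt":
        # "pt." ends a fragment unless it runs straight into a
        # lowercase continuation ("the pt. reports pain").
        rest = text[end:].lstrip()
        return bool(rest) and rest[0].islower()
    return False


def split_sentences(normalized_text: str, note_id: str = "") -> list[Sentence]:
    """Split already-normalized text into ordered, non-overlapping
    sentences whose spans jointly cover all non-whitespace text."""
    text = normalized_text
    if not text.strip():
        return []

    cut_points: set[int] = set()
    for m in _TERMINAL_RE.finditer(text):
        if text[m.start()] == "." and _is_guarded_period(text, m.start(), m.end()):
            continue
        cut_points.add(m.end())
    for m in _HEADER_RE.finditer(text):
        cut_points.add(m.end())
        cut_points.add(m.start())
    for m in _BULLET_RE.finditer(text):
        cut_points.add(m.start())

    sentences: list[Sentence] = []
    start = 0
    for cut in sorted(cut_points | {len(text)}):
        segment = text[start:cut]
        if segment.strip():
            lead = len(segment) - len(segment.lstrip())
            trail = len(segment) - len(segment.rstrip())
            span = (start + lead, cut - trail)
            sentences.append(
                Sentence(
                    note_id=note_id,
                    index=len(sentences),
                    text=text[span[0] : span[1]],
                    char_span=span,
                )
            )
        start = cut
    return sentences


def sentences_from_note(note: NoteDocument) -> list[Sentence]:
    """Normalize a note's text and split it into sentences."""
    return split_sentences(normalize_note(note.text), note_id=note.note_id)


def read_notes_jsonl(path: str | Path) -> Iterator[NoteDocument]:
    """Read line-delimited note records.

    Each line is a JSON object with fields ``note_id``, ``encounter_id``,
    ``patient_id``, ``text`` and optionally ``note_time``.  Malformed
    lines raise :class:`ValueError` naming the line number.
    """
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                yield NoteDocument(
                    note_id=str(rec["note_id"]),
                    encounter_id=str(rec["encounter_id"]),
                    patient_id=str(rec["patient_id"]),
                    text=rec.get("text", ""),
                    note_time=str(rec.get("note_time", "")),
                )
            except (json.JSONDecodeError, KeyError) as exc:
                raise ValueError(f"{path}: malformed note record at line {lineno}: {exc}") from exc


def write_notes_jsonl(notes: Iterable[NoteDocument], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for note in notes:
            fh.write(
                json.dumps(
                    {
                        "note_id": note.note_id,
                        "encounter_id": note.encounter_id,
                        "patient_id": note.patient_id,
                        "note_time": note.note_time,
                        "text": note.text,
                    }
                )
                + "\n"
            )
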