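"""Negative patient-descriptor lexicon and stem-based sentence matching.

The lexicon holds fifteen descriptors commonly used to characterize a
patient or their behaviour unfavourably in history-and-physical (H&P)
notes ("noncompliant", "agitated", "refused", ...).  Each descriptor is
matched by a lowercase stem so that alternative grammatical forms are
found (e.g. stem ``adher`` matches "adherent", "adhere", "adhered",
"adherence").  Matching is purely lexical; deciding whether an occurrence
is actually a negative characterization of the patient is the job of
:mod:`notelex.classify`.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "Descriptor",
    "DescriptorHit",
    "POLARITY_CLASSES",
    "build_default_lexicon",
    "load_lexicon",
    "match_descriptors",
]

POLARITY_CLASSES = ("inherent_negative", "polarity_by_negation")

#: Grammatical suffixes a stem may carry and still count as a descriptor
#: form.  A closed list (rather than "any letters") is what keeps
#: look-alike tokens such as "resistor" (resist + "or") from matching.
_SUFFIXES = (
    "",
    "e", "es", "ed", "ing", "ingly",
    "ion", "ions", "ive", "ively",
    "ely", "eness", "ness", "ly",
    "s", "t", "ts", "ce", "ces",
    "y", "ily",
    "al", "als", "ally",
    "ance", "ant", "ants", "ence", "ent",
    "ation", "ational",
)

#: Negation morphemes recognized when fused or hyphen-joined to the stem
#: ("noncompliant", "non-adherent", "uncooperative", "inadherent").
#: Free-standing negators ("not", "poorly", "denies") are cue words for
#: the context classifier, not part of lexical matching.
_NEG_PREFIXES = ("non-", "non", "un", "in-", "in")


@dataclass(frozen=True)
class Descriptor:
    """One lexicon entry."""

    term: str
    stem: str
    polarity_class: str
    variants_note: str = ""

    def __post_init__(self) -> None:
        if not self.stem or self.stem != self.stem.lower():
            raise ValueError(f"stem must be non-empty lowercase: {self.stem!r}")
        if not self.term.lower().startswith(self.stem):
            raise ValueError(
                f"stem {self.stem!r} is not a prefix of term {self.term!r}"
            )
        if self.polarity_class not in POLARITY_CLASSES:
            raise ValueError(f"unknown polarity_class {self.polarity_class!r}")


@dataclass(frozen=True)
class DescriptorHit:
    """A descriptor occurrence inside a single sentence.

    ``span`` is a 0-based half-open character interval in the original
    sentence and covers the whole matched token including any fused
    negation prefix; ``matched_surface`` is the verbatim slice.
    """

    descriptor: Descriptor
    span: tuple[int, int]
    matched_surface: str
    negation_prefix: str | None = None


def _compile(stem: str) -> re.Pattern[str]:
    suffix_alt = "|".join(
        sorted((re.escape(s) for s in _SUFFIXES), key=len, reverse=True)
    )
    neg_alt = "|".join(re.escape(p) for p in _NEG_PREFIXES)
    # Word boundary = transition from non-letter to letter; a hyphen is
    # internal only when it joins a negation prefix to the stem.
    return re.compile(
        rf"(?<![a-z])(?:(?P<neg>{neg_alt}))?(?P<body>{re.escape(stem)}(?:{suffix_alt}))(?![a-z])",
        re.IGNORECASE,
    )


_PATTERN_CACHE: dict[str, re.Pattern[str]] = {}


def _pattern_for(descriptor: Descriptor) -> re.Pattern[str]:
    pat = _PATTERN_CACHE.get(descriptor.stem)
    if pat is None:
        pat = _compile(descriptor.stem)
        _PATTERN_CACHE[descriptor.stem] = pat
    return pat


def load_lexicon(path: str | Path) -> list[Descriptor]:
    """Read a lexicon from a tab-delimited file (term, stem, polarity_class)."""
    entries: list[Descriptor] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            entries.append(
                Descriptor(
                    term=row["term"],
                    stem=row["stem"],
                    polarity_class=row["polarity_class"],
                    variants_note=row.get("variants_note", ""),
                )
            )
    return entries


def build_default_lexicon() -> list[Descriptor]:
    """Return the default fifteen-descriptor lexicon shipped with the package."""
    source = resources.files("notelex").joinpath("data/lexicon.tsv")
    with resources.as_file(source) as path:
        lexicon = load_lexicon(path)
    if len(lexicon) != 15:  # guards against a corrupted data file
        raise RuntimeError(f"default lexicon has {len(lexicon)} entries, expected 15")
    return lexicon


def match_descriptors(
    sentence_text: str, lexicon: list[Descriptor] | None = None
) -> list[DescriptorHit]:
    """Find every descriptor occurrence in a single (post-split) sentence.

    Matching is case-insensitive and word-initial: the stem, optionally
    preceded by a fused or hyphenated negation prefix, must start at a
    letter/non-letter boundary, and the token must end in one of the
    recognized grammatical suffixes.  Hits are returned ordered by span
    start (ties broken by descriptor term), so the output is
    deterministic; overlapping hits for distinct descriptors are all
    reported.
    """
    if lexicon is None:
        lexicon = build_default_lexicon()
    hits: list[DescriptorHit] = []
    if not sentence_text:
        return hits
    for descriptor in lexicon:
        for m in _pattern_for(descriptor).finditer(sentence_text):
            neg = m.group("neg")
            hits.append(
                DescriptorHit(
                    descriptor=descriptor,
                    span=(m.start(), m.end()),
                    matched_surface=m.group(0),
                    negation_prefix=neg.lower() if neg else None,
                )
            )
    hits.sort(key=lambda h: (h.span[0], h.descriptor.term))
    return hits
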