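"""Corpus containers and I/O: JSONL standoff annotations and i2b2 2014 XML.

The on-disk interchange format is JSON Lines, one narrative per line::

    {"id": "n1", "text": "seen by Dr Brown",
     "spans": [{"start": 11, "end": 16, "label": "NAME", "subtype": "doctor"}]}

Offsets are 0-based, half-open, and counted in Unicode code points — never
bytes — so they are unambiguous under multi-byte text.  Overlapping or
adjacent-with-overlap gold spans are merged on read: the task is a single
binary NAME class, so overlap carries no information.

The i2b2 2014 de-identification corpus reader extracts only the three name
subcategories (DOCTOR, PATIENT, USERNAME); every other PHI category (dates,
locations, ages, ...) is out of the task's scope and treated as NON-NAME.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from lxml import etree

__all__ = [
    "NameSubtype",
    "Span",
    "Narrative",
    "AnnotatedNarrative",
    "CorpusFormatError",
    "merge_spans",
    "read_jsonl_corpus",
    "write_jsonl_corpus",
    "read_i2b2_xml",
    "select_candidates",
    "DEFAULT_CANDIDATE_PATTERNS",
]


class CorpusFormatError(ValueError):
    """Malformed corpus file (bad JSON, bad XML, or invalid offsets)."""


class NameSubtype(Enum):
    DOCTOR = "doctor"
    PATIENT = "patient"
    USERNAME = "username"
    UNSPECIFIED = "unspecified"


@dataclass(frozen=True)
class Span:
    """Half-open character interval flagged as NAME."""

    start: int
    end: int
    label: str = "NAME"
    subtype: NameSubtype = NameSubtype.UNSPECIFIED

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span bounds: ({self.start}, {self.end})")
        if self.label != "NAME":
            raise ValueError(f"unsupported span label: {self.label!r}")

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class Narrative:
    """A raw case narrative: opaque id plus UTF-8 text."""

    id: str
    text: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("narrative id must be non-empty")


@dataclass(frozen=True)
class AnnotatedNarrative:
    narrative: Narrative
    gold_spans: Tuple[Span, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "gold_spans", tuple(self.gold_spans))
        n = len(self.narrative.text)
        for s in self.gold_spans:
            if s.end > n:
                raise ValueError(
                    f"narrative {self.narrative.id!r}: span ({s.start}, {s.end}) "
                    f"exceeds text length {n}"
                )

    @property
    def id(self) -> str:
        return self.narrative.id

    @property
    def text(self) -> str:
        return self.narrative.text


def merge_spans(spans: Iterable[Span]) -> Tuple[Span, ...]:
    """Sort spans and merge any that overlap.

    Subtypes survive only when a merged group is homogeneous; a mixed merge
    falls back to UNSPECIFIED.
    """
    ordered = sorted(spans, key=lambda s: (s.start, s.end))
    merged: List[Span] = []
    for s in ordered:
        if merged and s.start < merged[-1].end:
            prev = merged[-1]
            subtype = prev.subtype if prev.subtype == s.subtype else NameSubtype.UNSPECIFIED
            merged[-1] = Span(prev.start, max(prev.end, s.end), subtype=subtype)
        else:
            merged.append(s)
    return tuple(merged)


# ---------------------------------------------------------------------------
# JSONL standoff format
# ---------------------------------------------------------------------------

def _span_from_json(obj: dict, narrative_id: str) -> Span:
    try:
        subtype = NameSubtype(obj.get("subtype", "unspecified"))
        return Span(int(obj["start"]), int(obj["end"]), obj.get("label", "NAME"), subtype)
    except (KeyError, ValueError) as exc:
        raise CorpusFormatError(
            f"narrative {narrative_id!r}: invalid span {obj!r}: {exc}"
        ) from exc


def read_jsonl_corpus(path) -> List[AnnotatedNarrative]:
    """Read a JSONL standoff corpus, one annotated narrative per line.

    Raises :class:`CorpusFormatError` naming the line number on malformed
    JSON, and naming the narrative id when a span falls outside its text.
    """
    out: List[AnnotatedNarrative] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{path}: malformed JSON on line {lineno}: {exc}") from exc
            try:
                nid = str(obj["id"])
                narrative = Narrative(nid, str(obj["text"]))
                spans = [_span_from_json(s, nid) for s in obj.get("spans", [])]
                out.append(AnnotatedNarrative(narrative, merge_spans(spans)))
            except (KeyError, ValueError) as exc:
                raise CorpusFormatError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_jsonl_corpus(corpus: Sequence[AnnotatedNarrative], path) -> None:
    """Write a corpus in the JSONL standoff format (round-trips with the reader)."""
    with open(path, "w", encoding="utf-8") as fh:
        for ann in corpus:
            obj = {
                "id": ann.id,
                "text": ann.text,
                "spans": [
                    {"start": s.start, "end": s.end, "label": s.label,
                     "subtype": s.subtype.value}
                    for s in ann.gold_spans
                ],
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# i2b2 2014 XML dialect
# ---------------------------------------------------------------------------

_I2B2_NAME_TYPES = {
    "DOCTOR": NameSubtype.DOCTOR,
    "PATIENT": NameSubtype.PATIENT,
    "USERNAME": NameSubtype.USERNAME,
}


def read_i2b2_xml(path) -> AnnotatedNarrative:
    """Read one i2b2 2014 de-identification record.

    The record carries the document text as CDATA in a ``TEXT`` element and
    PHI annotations as children of a ``TAGS`` element with ``start``/``end``/
    ``TYPE`` attributes.  Only NAME tags of TYPE DOCTOR, PATIENT or USERNAME
    become gold spans (with the matching subtype); all other PHI categories
    are ignored.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusFormatError(f"{path}: not well-formed XML: {exc}") from exc
    root = tree.getroot()
    text_el = root.find("TEXT")
    tags_el = root.find("TAGS")
    if text_el is None or tags_el is None:
        raise CorpusFormatError(f"{path}: missing TEXT or TAGS element")
    text = text_el.text or ""
    spans: List[Span] = []
    for tag in tags_el:
        phi_type = tag.get("TYPE", "")
        if phi_type not in _I2B2_NAME_TYPES:
            continue
        try:
            start, end = int(tag.get("start")), int(tag.get("end"))
        except (TypeError, ValueError) as exc:
            raise CorpusFormatError(f"{path}: tag missing start/end: {exc}") from exc
        if not (0 <= start < end <= len(text)):
            raise CorpusFormatError(
                f"{path}: tag offsets ({start}, {end}) inconsistent with text "
                f"of length {len(text)}"
            )
        spans.append(Span(start, end, subtype=_I2B2_NAME_TYPES[phi_type]))
    record_id = Path(str(path)).stem
    return AnnotatedNarrative(Narrative(record_id, text), merge_spans(spans))


# ---------------------------------------------------------------------------
# Candidate selection for annotation
# ---------------------------------------------------------------------------

#: Context patterns used to enrich a low-prevalence corpus with narratives
#: likely to contain names before manual annotation.  A faithful-in-spirit
#: reconstruction (the original expressions are not public); editable via
#: the ``candidate_patterns.txt`` lexicon.
DEFAULT_CANDIDATE_PATTERNS = [
    r"(?i)\b(?:dr|doctor|mr|mrs|ms|miss|prof|professor|sister|nurse)\b[.\s]",
    r"(?i)\b(?:name|patient|reporter|consultant|gp)\s*:",
    r"(?i)\b(?:md|m\.d\.|phd|rn|frcp)\b",
    r"\b[A-Z]\.?\s?[A-Z]\b(?![A-Za-z])",   # initial pairs like "J.B." or "SB"
    r"(?i)\b(?:regards|signed|yours sincerely|best wishes)\b",
]


def select_candidates(
    corpus: Sequence[Narrative],
    patterns: Optional[Sequence[str]] = None,
) -> Tuple[List[Narrative], Dict[str, int]]:
    """Select narratives whose text matches ≥ 1 context pattern.

    Returns the matching sub-corpus (input order preserved) and per-pattern
    hit counts.  Deterministic; invalid regexes raise ``re.error`` up front.
    """
    raw = DEFAULT_CANDIDATE_PATTERNS if patterns is None else list(patterns)
    compiled = [(p, re.compile(p)) for p in raw]
    hits: Dict[str, int] = {p: 0 for p, _ in compiled}
    selected: List[Narrative] = []
    for narr in corpus:
        matched = False
        for p, rx in compiled:
            if rx.search(narr.text):
                hits[p] += 1
                matched = True
        if matched:
            selected.append(narr)
    return selected, hits
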