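"""Hand-engineered rule classifier for names near salutations, labels, titles.

Three rule families fire on case-insensitive trigger tokens:

* **salutation** — capture the 1–3 words *following* "dr.", "mr", "nurse", ...
* **label** — capture the 1–3 words *following* a field label ending in a
  colon ("name:", "patient:").
* **title** — capture the 1–3 words *preceding* a post-positioned credential
  ("m.d.", "rn").

Capture extent depends on capitalisation: the word adjacent to the trigger is
always captured, and the second and third words are added only while each
additional word starts with an uppercase letter.  A capture never crosses a
sentence-terminating period, question/exclamation mark, or newline, and never
exceeds three words.  Because at least one word is always captured ("the
doctor said ..." flags "said"), the rules alone have low precision but
catch obvious salutation contexts a statistical model may miss.

Triggers match whole alphanumeric tokens only, so "dr" never fires inside
"drug".  The lexicon is an editable plain-text file; see
:func:`load_ruleset` for the format.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

from .corpus_io import Span, merge_spans
from .tokenization import Token, tokenize

__all__ = ["RuleSet", "rule_classify", "load_ruleset", "default_ruleset"]

MAX_CAPTURE_WORDS = 3
_SENTENCE_TERMINATORS = frozenset(".!?\n")

_DEFAULT_SALUTATIONS = [
    "dr.", "dr", "doctor", "mr.", "mr", "mrs.", "mrs", "ms.", "ms", "miss",
    "mx", "prof.", "prof", "professor", "sister", "nurse", "sir", "madam",
]
_DEFAULT_LABELS = [
    "name:", "patient:", "reporter:", "consultant:", "gp:", "surname:",
    "forename:", "physician:", "pharmacist:",
]
_DEFAULT_TITLES = [
    "m.d.", "md", "ph.d.", "phd", "rn", "frcp", "mbbs", "b.sc.", "pharmd",
]


@dataclass(frozen=True)
class RuleSet:
    """Trigger lexicons for the three rule families; capture window fixed at 3."""

    salutations: Tuple[str, ...] = tuple(_DEFAULT_SALUTATIONS)
    labels: Tuple[str, ...] = tuple(_DEFAULT_LABELS)
    titles: Tuple[str, ...] = tuple(_DEFAULT_TITLES)
    max_window: int = MAX_CAPTURE_WORDS

    def __post_init__(self) -> None:
        if self.max_window != MAX_CAPTURE_WORDS:
            raise ValueError("capture window is fixed at 3 words")
        for family, triggers in (("salutations", self.salutations),
                                 ("labels", self.labels), ("titles", self.titles)):
            if any(not t.strip() for t in triggers):
                raise ValueError(f"empty trigger in {family}")


def default_ruleset() -> RuleSet:
    return RuleSet()


def load_ruleset(path=None) -> RuleSet:
    """Load a rule lexicon: ``[salutations]`` / ``[labels]`` / ``[titles]``
    section headers, one trigger per line, ``#`` comments ignored."""
    if path is None:
        ref = importlib.resources.files("namedeid") / "data" / "ruleset.txt"
        text = ref.read_text(encoding="utf-8")
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    sections = {"salutations": [], "labels": [], "titles": []}
    current = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1].lower()
            if current not in sections:
                raise ValueError(f"unknown lexicon section {current!r}")
            continue
        if current is None:
            raise ValueError("trigger line before any section header")
        sections[current].append(line.lower())
    return RuleSet(tuple(sections["salutations"]), tuple(sections["labels"]),
                   tuple(sections["titles"]))


def _trigger_token_texts(trigger: str) -> List[str]:
    return [t.text.lower() for t in tokenize(trigger)]


def _has_terminator(text: str, start: int, end: int) -> bool:
    return any(ch in _SENTENCE_TERMINATORS for ch in text[start:end])


def _match_trigger(text, tokens, i, trig_tokens, trigger, need_colon):
    """Try to match trigger token sequence at token index *i*.

    Returns the character offset just past the trigger (with the trigger's
    own trailing '.'/':' consumed) or None.
    """
    k = len(trig_tokens)
    if i + k > len(tokens):
        return None
    for off, want in enumerate(trig_tokens):
        if tokens[i + off].text.lower() != want:
            return None
        if off:  # multi-token triggers like "m.d.": inter-token text must match
            gap = text[tokens[i + off - 1].end:tokens[i + off].start]
            want_gap = _trigger_gap(trigger, off)
            if gap != want_gap:
                return None
    pos = tokens[i + k - 1].end
    if need_colon:
        j = pos
        while j < len(text) and text[j] in " \t":
            j += 1
        if j >= len(text) or text[j] != ":":
            return None
        return j + 1
    if trigger.endswith(".") and pos < len(text) and text[pos] == ".":
        return pos + 1
    return pos


def _trigger_gap(trigger: str, off: int) -> str:
    toks = tokenize(trigger)
    return trigger[toks[off - 1].end:toks[off].start]


def _capture_forward(text, tokens, j0, after_pos):
    """Capture 1–3 word tokens starting at index j0; returns token index range."""
    if j0 >= len(tokens) or _has_terminator(text, after_pos, tokens[j0].start):
        return None
    last = j0
    for m in range(1, MAX_CAPTURE_WORDS):
        j = j0 + m
        if j >= len(tokens):
            break
        if _has_terminator(text, tokens[j - 1].end, tokens[j].start):
            break
        if not tokens[j].text[0].isupper():
            break
        last = j
    return j0, last


def _capture_backward(text, tokens, j0, before_pos):
    if j0 < 0 or _has_terminator(text, tokens[j0].end, before_pos):
        return None
    first = j0
    for m in range(1, MAX_CAPTURE_WORDS):
        j = j0 - m
        if j < 0:
            break
        if _has_terminator(text, tokens[j].end, tokens[j + 1].start):
            break
        if not tokens[j].text[0].isupper():
            break
        first = j
    return first, j0


def rule_classify(text: str, ruleset: RuleSet | None = None) -> List[Span]:
    """Apply the three rule families; returns merged, sorted NAME spans.

    Deterministic; output spans lie on whole-token boundaries and never
    overlap.
    """
    if ruleset is None:
        ruleset = default_ruleset()
    tokens = tokenize(text)
    captures: List[Tuple[int, int]] = []

    forward_families = (
        [(t, False) for t in ruleset.salutations]
        + [(t, True) for t in ruleset.labels]
    )
    fwd = [(t.lower(), _trigger_token_texts(t), colon) for t, colon in forward_families]
    bwd = [(t.lower(), _trigger_token_texts(t)) for t in ruleset.titles]

    for i in range(len(tokens)):
        for trigger, trig_tokens, need_colon in fwd:
            if not trig_tokens:
                continue
            end_pos = _match_trigger(text, tokens, i, trig_tokens, trigger, need_colon)
            if end_pos is None:
                continue
            cap = _capture_forward(text, tokens, i + len(trig_tokens), end_pos)
            if cap:
                captures.append(cap)
        for trigger, trig_tokens in bwd:
            if not trig_tokens:
                continue
            end_pos = _match_trigger(text, tokens, i, trig_tokens, trigger, False)
            if end_pos is None:
                continue
            cap = _capture_backward(text, tokens, i - 1, tokens[i].start)
            if cap:
                captures.append(cap)

    spans = [Span(tokens[a].start, tokens[b].end) for a, b in captures]
    return list(merge_spans(spans))
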