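"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import re
from typing import List, Sequence, Tuple

import numpy as np
import pytest

from namedeid.corpus_io import AnnotatedNarrative, Narrative, Span


# ---------------------------------------------------------------------------
# Brute-force covering-mode oracle (character-level, independent of the
# implementation under test)
# ---------------------------------------------------------------------------

def brute_force_covering(text: str, gold_spans: Sequence[Tuple[int, int]],
                         pred_spans: Sequence[Tuple[int, int]]):
    """Score covering mode by explicit per-character set arithmetic.

    Returns dicts {stratum: (tp, fp, fn, tn)} with strata all/long/short.
    """
    tokens = [(m.start(), m.end()) for m in re.finditer(r"[^\W_]+", text)]

    # merge overlapping predicted intervals (overlap only, not adjacency)
    merged: List[List[int]] = []
    for s, e in sorted(pred_spans):
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    gold_chars = set()
    for s, e in gold_spans:
        gold_chars.update(range(s, e))

    def is_name(tok):
        return any(c in gold_chars for c in range(tok[0], tok[1]))

    def fully_covered_by(tok, interval):
        return all(interval[0] <= c < interval[1] for c in range(tok[0], tok[1]))

    def partially_covered(tok):
        # some span overlaps the token; full coverage by a single span is
        # handled separately, so any overlap here is partial
        chars = set(range(tok[0], tok[1]))
        return any(chars & set(range(s, e)) for s, e in merged)

    span_forgives = []
    for interval in merged:
        span_forgives.append(any(
            is_name(tok) and fully_covered_by(tok, interval) for tok in tokens))

    counts = {"all": [0, 0, 0, 0], "long": [0, 0, 0, 0], "short": [0, 0, 0, 0]}

    def bump(tok, slot):
        for key in ("all", "short" if tok[1] - tok[0] <= 3 else "long"):
            counts[key][slot] += 1

    for tok in tokens:
        cover_idx = next((i for i, iv in enumerate(merged)
                          if fully_covered_by(tok, iv)), None)
        if is_name(tok):
            bump(tok, 0 if cover_idx is not None else 2)
        elif cover_idx is not None:
            bump(tok, 3 if span_forgives[cover_idx] else 1)
        elif partially_covered(tok):
            bump(tok, 1)
        else:
            bump(tok, 3)
    return {k: tuple(v) for k, v in counts.items()}


def random_covering_instance(rng: np.random.Generator):
    """A small random text with random gold and predicted intervals."""
    n_tokens = int(rng.integers(1, 21))
    words = []
    for _ in range(n_tokens):
        length = int(rng.integers(1, 7))
        words.append("".join(rng.choice(list("abcdefgh"), size=length)))
    seps = rng.choice([" ", ", ", ". ", "-", "  "], size=n_tokens)
    text = "".join(w + s for w, s in zip(words, seps)).rstrip()

    def random_spans(k_max):
        spans = []
        for _ in range(int(rng.integers(0, k_max))):
            a = int(rng.integers(0, len(text)))
            b = int(rng.integers(a + 1, len(text) + 1))
            spans.append((a, b))
        return spans

    return text, random_spans(4), random_spans(5)


@pytest.fixture
def oracle():
    return brute_force_covering


@pytest.fixture
def make_annotated():
    def _make(text: str, spans=(), nid="n1") -> AnnotatedNarrative:
        return AnnotatedNarrative(
            Narrative(nid, text), [Span(a, b) for a, b in spans])
    return _make
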