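"""Simple alphanumeric tokenizer and token-level gold labels.

Evaluation and rule matching both operate on *alphanumeric tokens*: maximal
runs of consecutive Unicode letters or decimal digits.  Underscores and all
punctuation delimit tokens, so ``"Stevens-Johnson"`` yields two tokens.  This
is deliberately not a linguistic tokenizer — the binary NAME / NON-NAME
classification task is defined over these character runs, and the short
(≤ 3 characters, a proxy for initials) versus long distinction is measured on
their character counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, List, Sequence

__all__ = [
    "Token",
    "TokenLabel",
    "SHORT_TOKEN_MAX_LEN",
    "tokenize",
    "project_gold",
    "is_short",
]

#: Tokens of at most this many characters are "short" (initial-like).
SHORT_TOKEN_MAX_LEN = 3


def _is_alnum(ch: str) -> bool:
    # Unicode letters and digits; underscore is a delimiter.
    return ch.isalpha() or ch.isdigit()


@dataclass(frozen=True)
class Token:
    """A maximal run of alphanumeric characters with code-point offsets."""

    text: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.text) or not self.text:
            raise ValueError(f"inconsistent token offsets: {self!r}")


class TokenLabel(Enum):
    NAME = "NAME"
    NON_NAME = "NON_NAME"


def tokenize(text: str) -> List[Token]:
    """Split *text* into maximal alphanumeric runs.

    The returned tokens are ordered, non-overlapping, and their intervals
    cover exactly the alphanumeric positions of *text*.  Empty text gives an
    empty list.
    """
    tokens: List[Token] = []
    start = None
    for i, ch in enumerate(text):
        if _is_alnum(ch):
            if start is None:
                start = i
        elif start is not None:
            tokens.append(Token(text[start:i], start, i))
            start = None
    if start is not None:
        tokens.append(Token(text[start:], start, len(text)))
    return tokens


def project_gold(tokens: Sequence[Token], gold_spans: Iterable) -> List[TokenLabel]:
    """Label each token NAME iff it overlaps any gold span by ≥ 1 character.

    Partial overlap counts: a partially annotated token is still a name
    fragment, and treating it as NAME is the privacy-conservative choice.
    """
    spans = [(s.start, s.end) for s in gold_spans]
    labels = []
    for tok in tokens:
        hit = any(tok.start < e and s < tok.end for s, e in spans)
        labels.append(TokenLabel.NAME if hit else TokenLabel.NON_NAME)
    return labels


def is_short(token: Token) -> bool:
    """True iff the token has ≤ 3 characters (initial-like)."""
    return len(token.text) <= SHORT_TOKEN_MAX_LEN
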