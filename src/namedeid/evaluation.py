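"""Covering-mode token-level scoring and stratified metrics.

Scoring is a binary token-classification evaluation over alphanumeric
tokens, in *covering mode*:

* a gold NAME token is a true positive only if some predicted span
  **completely encapsulates** it; partial coverage is a false negative
  (the privacy-critical "leak");
* a gold NON-NAME token fully covered by a predicted span is forgiven (not
  a false positive) when that same span also fully covers at least one gold
  NAME token — over-extension around a true name costs nothing;
* a NON-NAME token only *partially* covered by any predicted span is always
  a false positive, as is a fully covered one whose span contains no fully
  covered NAME token (a spurious flag).

All counts are kept per stratum: all tokens, long tokens (> 3 characters)
and short tokens (≤ 3, initial-like).  Percentages are rounded half-up to
whole percent (false-positive rates to two decimals); undefined ratios
(zero denominator) are reported as ``None``, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .corpus_io import AnnotatedNarrative, Narrative, Span, merge_spans
from .tokenization import TokenLabel, is_short, project_gold, tokenize

__all__ = [
    "Cell",
    "ConfusionCounts",
    "StratumMetrics",
    "MetricsReport",
    "evaluate_covering",
    "evaluate_corpus",
    "compute_metrics",
    "narrative_recall",
    "narrative_fn_counts",
    "make_confusion_fixture",
    "metrics_report",
]

STRATA = ("all", "long", "short")


@dataclass(frozen=True)
class Cell:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "Cell") -> "Cell":
        return Cell(self.tp + other.tp, self.fp + other.fp,
                    self.fn + other.fn, self.tn + other.tn)


@dataclass(frozen=True)
class ConfusionCounts:
    """Covering-mode confusion counts per stratum (all = long + short)."""

    all: Cell = field(default_factory=Cell)
    long: Cell = field(default_factory=Cell)
    short: Cell = field(default_factory=Cell)

    def __post_init__(self) -> None:
        combined = self.long + self.short
        if combined != self.all:
            raise ValueError("stratum additivity violated: all != long + short")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.all + other.all, self.long + other.long,
                               self.short + other.short)

    def stratum(self, name: str) -> Cell:
        return getattr(self, name)


def _round_half_up(value: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    out = Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP)
    return float(out) if ndigits else int(out)


@dataclass(frozen=True)
class StratumMetrics:
    """Percent metrics for one stratum; None marks an undefined ratio."""

    precision: Optional[int]
    recall: Optional[int]
    f1: Optional[int]
    fpr: Optional[float]


@dataclass(frozen=True)
class MetricsReport:
    metrics: Dict[str, StratumMetrics]
    narrative_recall: Dict[str, Optional[int]]
    touched_narratives: int


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def evaluate_covering(gold: AnnotatedNarrative,
                      predicted: Sequence[Span]) -> ConfusionCounts:
    """Score one narrative's predicted spans against its gold annotation."""
    text = gold.text
    for s in predicted:
        if s.end > len(text):
            raise ValueError(
                f"narrative {gold.id!r}: predicted span ({s.start}, {s.end}) "
                f"out of bounds")
    spans = merge_spans(predicted)
    tokens = tokenize(text)
    labels = project_gold(tokens, gold.gold_spans)

    # Does each predicted span fully cover at least one gold NAME token?
    forgiving = []
    for p in spans:
        covers_name = any(
            lab is TokenLabel.NAME and p.start <= t.start and t.end <= p.end
            for t, lab in zip(tokens, labels))
        forgiving.append(covers_name)

    cells = {"long": [0, 0, 0, 0], "short": [0, 0, 0, 0]}  # tp fp fn tn
    for tok, lab in zip(tokens, labels):
        full = None
        partial = False
        for idx, p in enumerate(spans):
            if p.start <= tok.start and tok.end <= p.end:
                full = idx
                break
            if p.start < tok.end and tok.start < p.end:
                partial = True
        key = "short" if is_short(tok) else "long"
        if lab is TokenLabel.NAME:
            cells[key][0 if full is not None else 2] += 1
        else:
            if full is not None:
                if not forgiving[full]:
                    cells[key][1] += 1
                else:
                    cells[key][3] += 1
            elif partial:
                cells[key][1] += 1
            else:
                cells[key][3] += 1

    long_c, short_c = Cell(*cells["long"]), Cell(*cells["short"])
    return ConfusionCounts(long_c + short_c, long_c, short_c)


def evaluate_corpus(gold_corpus: Sequence[AnnotatedNarrative],
                    predictions: Mapping[str, Sequence[Span]]) -> ConfusionCounts:
    """Aggregate covering-mode counts over a corpus (missing ids = no spans)."""
    total = ConfusionCounts()
    for ann in gold_corpus:
        total = total + evaluate_covering(ann, predictions.get(ann.id, ()))
    return total


def compute_metrics(counts: ConfusionCounts) -> Dict[str, StratumMetrics]:
    """Precision / recall / F1 (whole percent) and FPR (two decimals) per stratum."""
    out: Dict[str, StratumMetrics] = {}
    for name in STRATA:
        c = counts.stratum(name)
        precision = (_round_half_up(100 * c.tp / (c.tp + c.fp), 0)
                     if c.tp + c.fp else None)
        recall = (_round_half_up(100 * c.tp / (c.tp + c.fn), 0)
                  if c.tp + c.fn else None)
        f1 = (_round_half_up(100 * 2 * c.tp / (2 * c.tp + c.fp + c.fn), 0)
              if 2 * c.tp + c.fp + c.fn else None)
        fpr = (_round_half_up(100 * c.fp / (c.fp + c.tn), 2)
               if c.fp + c.tn else None)
        out[name] = StratumMetrics(precision, recall, f1, fpr)
    return out


# ---------------------------------------------------------------------------
# Narrative-level recall
# ---------------------------------------------------------------------------

def narrative_fn_counts(gold: AnnotatedNarrative,
                        predicted: Sequence[Span]) -> Dict[str, Tuple[int, int]]:
    """Per stratum: (gold NAME token count, leaked/fn token count)."""
    counts = evaluate_covering(gold, predicted)
    return {name: (counts.stratum(name).tp + counts.stratum(name).fn,
                   counts.stratum(name).fn) for name in STRATA}


def narrative_recall(gold_corpus: Sequence[AnnotatedNarrative],
                     predictions: Mapping[str, Sequence[Span]],
                     stratum: str = "all") -> Optional[int]:
    """Percent of name-bearing narratives with zero leaked tokens of *stratum*.

    Denominator: narratives containing ≥ 1 gold NAME token of the stratum;
    numerator: those in which every such token was fully covered.  Undefined
    (None) when no narrative bears a token of the stratum.
    """
    den = num = 0
    for ann in gold_corpus:
        gold_n, fn = narrative_fn_counts(ann, predictions.get(ann.id, ()))[stratum]
        if gold_n:
            den += 1
            if fn == 0:
                num += 1
    return _round_half_up(100 * num / den, 0) if den else None


def metrics_report(gold_corpus: Sequence[AnnotatedNarrative],
                   predictions: Mapping[str, Sequence[Span]]) -> MetricsReport:
    """Full stratified report plus narrative-level recall and touch count."""
    counts = evaluate_corpus(gold_corpus, predictions)
    touched = sum(1 for ann in gold_corpus if predictions.get(ann.id))
    return MetricsReport(
        metrics=compute_metrics(counts),
        narrative_recall={s: narrative_recall(gold_corpus, predictions, s)
                          for s in STRATA},
        touched_narratives=touched,
    )


# ---------------------------------------------------------------------------
# Exact-confusion fixtures
# ---------------------------------------------------------------------------

_FIXTURE_WORDS = {
    # (stratum, role) -> word; name words differ from filler words so the
    # construction is easy to eyeball.
    ("long", "name"): "Abcd",
    ("long", "filler"): "wxyz",
    ("short", "name"): "Ab",
    ("short", "filler"): "qq",
}


def make_confusion_fixture(
    target: ConfusionCounts,
) -> Tuple[List[AnnotatedNarrative], Dict[str, List[Span]]]:
    """Construct a corpus + predictions that score exactly to *target*.

    One narrative per stratum: tp words carry both a gold span and an exactly
    matching predicted span; fn words carry only a gold span; fp words carry
    only a predicted span; tn words carry neither.  Scoring the result with
    :func:`evaluate_covering` reproduces the target cell-for-cell.
    """
    corpus: List[AnnotatedNarrative] = []
    predictions: Dict[str, List[Span]] = {}
    for stratum in ("long", "short"):
        c = target.stratum(stratum)
        words: List[Tuple[str, str]] = (
            [("name", "tp")] * c.tp + [("name", "fn")] * c.fn
            + [("filler", "fp")] * c.fp + [("filler", "tn")] * c.tn)
        parts: List[str] = []
        gold: List[Span] = []
        pred: List[Span] = []
        pos = 0
        for role, outcome in words:
            w = _FIXTURE_WORDS[(stratum, role)]
            if parts:
                parts.append(" ")
                pos += 1
            start, end = pos, pos + len(w)
            parts.append(w)
            pos = end
            if outcome in ("tp", "fn"):
                gold.append(Span(start, end))
            if outcome in ("tp", "fp"):
                pred.append(Span(start, end))
        nid = f"fixture-{stratum}"
        corpus.append(AnnotatedNarrative(Narrative(nid, "".join(parts)), gold))
        predictions[nid] = pred
    return corpus, predictions
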