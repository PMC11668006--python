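"""End-to-end de-identification: ensemble, redaction, review queue, probes.

The final label for each token is the OR of the neural classifier and the
rule classifier: a token is redacted if *either* arm flags it.  The OR can
only add flags, so ensemble recall and false-positive rate are both at least
each arm's.  Rules always see the original-cased text — capitalisation is
their signal — even when the neural backend lowercases internally.

Redaction replaces each merged flagged span with a fixed placeholder
(default "NAME"), preserving every character outside the spans.  Narratives
with at least one flag are queued for human review, ordered by flagged-token
count descending (triage order; most-flagged first).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .corpus_io import AnnotatedNarrative, Narrative, Span, merge_spans
from .neural import Classifier, ModelConfig, labels_to_spans, predict_tokens
from .rules import RuleSet, rule_classify
from .tokenization import TokenLabel, project_gold, tokenize

__all__ = [
    "PipelineConfig",
    "ensemble_or",
    "redact",
    "flag_for_review",
    "inject_name",
    "predict_narrative",
    "deidentify_corpus",
    "sensitivity_probe",
]


@dataclass(frozen=True)
class PipelineConfig:
    use_rules: bool = True
    placeholder: str = "NAME"
    review_mode: bool = True
    model_path: Optional[str] = None
    ruleset_path: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.placeholder:
            raise ValueError("placeholder must be non-empty")


def ensemble_or(labels_a: Sequence[TokenLabel],
                labels_b: Sequence[TokenLabel]) -> List[TokenLabel]:
    """Token-wise OR: NAME iff NAME in either input."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences differ in length")
    return [TokenLabel.NAME
            if TokenLabel.NAME in (a, b) else TokenLabel.NON_NAME
            for a, b in zip(labels_a, labels_b)]


def redact(text: str, spans: Sequence[Span], placeholder: str = "NAME") -> str:
    """Replace each span with *placeholder*; everything else is untouched.

    Spans must be non-overlapping (merge upstream); no character of a
    flagged span survives into the output.
    """
    ordered = sorted(spans, key=lambda s: s.start)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start < prev.end:
            raise ValueError("overlapping spans; merge before redacting")
    out: List[str] = []
    pos = 0
    for s in ordered:
        if s.end > len(text):
            raise ValueError(f"span ({s.start}, {s.end}) out of bounds")
        out.append(text[pos:s.start])
        out.append(placeholder)
        pos = s.end
    out.append(text[pos:])
    return "".join(out)


def flag_for_review(predictions: Mapping[str, Sequence[Span]],
                    texts: Optional[Mapping[str, str]] = None) -> List[str]:
    """Narrative ids with ≥ 1 predicted span, most flagged tokens first.

    Flagged-token counts need the narrative texts; without them the tie-break
    falls back to span count.  Ties are broken by id for determinism.
    """
    def burden(nid: str) -> int:
        spans = predictions[nid]
        if texts is not None and nid in texts:
            labels = project_gold(tokenize(texts[nid]), spans)
            return sum(1 for lab in labels if lab is TokenLabel.NAME)
        return len(spans)

    flagged = [nid for nid, spans in predictions.items() if spans]
    return sorted(flagged, key=lambda nid: (-burden(nid), nid))


def inject_name(annotated: AnnotatedNarrative, replacement_name: str,
                target_span: Span) -> AnnotatedNarrative:
    """Replace one gold name with a surrogate, shifting later spans.

    *target_span* must be one of the narrative's gold spans.  The replacement
    becomes the new gold span at that position; downstream offsets shift by
    the length difference.
    """
    if target_span not in annotated.gold_spans:
        raise ValueError("target_span is not a gold span of this narrative")
    old_text = annotated.text
    delta = len(replacement_name) - (target_span.end - target_span.start)
    new_text = (old_text[:target_span.start] + replacement_name
                + old_text[target_span.end:])
    new_spans: List[Span] = []
    for s in annotated.gold_spans:
        if s == target_span:
            new_spans.append(Span(s.start, s.start + len(replacement_name),
                                  subtype=s.subtype))
        elif s.start >= target_span.end:
            new_spans.append(Span(s.start + delta, s.end + delta,
                                  subtype=s.subtype))
        else:
            new_spans.append(s)
    return AnnotatedNarrative(Narrative(annotated.id, new_text), new_spans)


# ---------------------------------------------------------------------------
# End-to-end prediction
# ---------------------------------------------------------------------------

def predict_narrative(text: str, classifier: Classifier,
                      ruleset: Optional[RuleSet] = None,
                      use_rules: bool = True,
                      config: Optional[ModelConfig] = None) -> List[Span]:
    """Predicted NAME spans for one narrative (neural, optionally OR rules)."""
    tokens = tokenize(text)
    labels = predict_tokens(text, classifier, config)
    if use_rules:
        rule_labels = project_gold(tokens, rule_classify(text, ruleset))
        labels = ensemble_or(labels, rule_labels)
    return labels_to_spans(tokens, labels)


def deidentify_corpus(
    corpus: Sequence[AnnotatedNarrative],
    classifier: Classifier,
    pipeline_config: PipelineConfig = PipelineConfig(),
    ruleset: Optional[RuleSet] = None,
) -> Tuple[List[AnnotatedNarrative], Dict[str, List[Span]], List[str]]:
    """Redact a corpus; returns (redacted corpus, predictions, review queue).

    Deterministic for fixed inputs and model weights.  The redacted corpus
    carries no gold spans (they no longer align with the rewritten text).
    """
    predictions: Dict[str, List[Span]] = {}
    redacted: List[AnnotatedNarrative] = []
    for ann in corpus:
        spans = predict_narrative(ann.text, classifier, ruleset,
                                  pipeline_config.use_rules)
        predictions[ann.id] = spans
        new_text = redact(ann.text, spans, pipeline_config.placeholder)
        redacted.append(AnnotatedNarrative(Narrative(ann.id, new_text), ()))
    texts = {ann.id: ann.text for ann in corpus}
    queue = flag_for_review(predictions, texts) if pipeline_config.review_mode else []
    return redacted, predictions, queue


def sensitivity_probe(annotated: AnnotatedNarrative, target_span: Span,
                      surrogate_names: Sequence[str], classifier: Classifier,
                      ruleset: Optional[RuleSet] = None,
                      use_rules: bool = True) -> Dict[str, bool]:
    """Swap surrogate names into one gold slot and re-run prediction.

    For each surrogate, reports True iff every alphanumeric token of the
    injected name is fully covered by a predicted span — the name-injection
    sensitivity protocol for probing whether recall depends on the name
    itself rather than its context.
    """
    results: Dict[str, bool] = {}
    for name in surrogate_names:
        probe = inject_name(annotated, name, target_span)
        new_span = Span(target_span.start, target_span.start + len(name))
        predicted = predict_narrative(probe.text, classifier, ruleset, use_rules)
        merged = merge_spans(predicted)
        name_tokens = [t for t in tokenize(probe.text)
                       if new_span.start <= t.start and t.end <= new_span.end]
        results[name] = all(
            any(p.start <= t.start and t.end <= p.end for p in merged)
            for t in name_tokens)
    return results
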