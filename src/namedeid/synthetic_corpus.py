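"""Synthetic adverse-event narratives with gold name annotations.

The real narratives this package targets (spontaneous adverse-event reports)
are confidential, so development and testing run on generated stand-ins that
emulate the *structural* characteristics of that data: very low name
prevalence (about 71 name-bearing narratives per 5,042, with 179 NAME tokens
against ~263k NON-NAME tokens in the reference test conditions), a mix of
multi-token full names and ≤3-character initials, salutation/label/title
contexts around names, signature blocks, and medical-eponym distractors
("Stevens-Johnson syndrome") that punish naive capitalisation rules.  No
attempt is made at stylistic fidelity to real reports.

Counts are realised *exactly*, not in expectation: the number of name-bearing
narratives, the total NAME-token count and the short-token share are fixed by
partitioning before sampling, so evaluation denominators are known a priori.
Drug names and dates are emitted as placeholder tokens (DRUG1, DATE1, ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .corpus_io import AnnotatedNarrative, Narrative, Span

__all__ = [
    "SyntheticConfig",
    "generate_corpus",
    "test_set_conditions",
    "training_conditions",
    "FIRST_NAMES",
    "LAST_NAMES",
    "SHORT_SINGLE",
    "SHORT_PAIR",
    "name_inventory",
]

CONTEXTS = ("salutation", "label", "title", "bare", "signature")

# Name lexicons mix origins so fairness probes (e.g. South Asian vs common
# English names) are expressible.  All entries tokenize to >3-character
# tokens; the short lexicons hold initial-like mentions of 1 or 2 short
# (≤3-character) tokens respectively.
FIRST_NAMES = [
    "Ramesh", "Priya", "Hanna", "John", "Jane", "Deirdre", "Kwame", "Amara",
    "Fatima", "Ingrid", "Carlos", "Aisha", "Mateo", "Keiko", "Olusegun",
    "Sanjay", "Meiling", "Dmitri", "Sofia", "Tariq",
]
LAST_NAMES = [
    "Patel", "Smith", "Rosling", "Kaveson", "Johnson", "Brown", "Okafor",
    "Nakamura", "Singh", "Svensson", "Garcia", "Osei", "Kumar", "Jones",
    "Petrov", "Haddad", "Nguyen", "Larsson", "Mbeki", "Carter",
]
SHORT_SINGLE = ["SB", "JB", "Li", "Raj", "Ali", "Mo", "Ed", "KT", "DH", "Ng"]
SHORT_PAIR = ["J.B.", "A.K.", "R. P.", "M.K.", "D. H.", "S. N."]

DISTRACTORS = [
    "The patient was diagnosed with Stevens-Johnson syndrome.",
    "Symptoms were consistent with Bell's palsy.",
    "Parkinson's disease was ruled out on examination.",
    "History of Hodgkin lymphoma in remission.",
    "Crohn's disease noted in past medical history.",
    "Person A reported the event on behalf of the patient.",
    "Addison's disease considered in the differential.",
    "Graves' disease previously treated with DRUG2.",
]

BODY_SENTENCES = [
    "Patient commenced DRUG1 on DATE1.",
    "Developed nausea and dizziness after two doses.",
    "Rash appeared on the trunk and spread to the limbs.",
    "DRUG1 was withdrawn on DATE2 and symptoms resolved.",
    "No concurrent medication apart from DRUG2.",
    "Reports severe headache and fatigue since DATE1.",
    "Admitted for observation overnight and discharged the next day.",
    "Symptoms recurred on rechallenge with DRUG1.",
    "Blood tests on DATE2 were unremarkable.",
    "The reaction was considered possibly related to DRUG1.",
]

_CONTEXT_TEMPLATES = {
    "salutation": ["Seen by dr. {NAME} at the surgery.",
                   "Discussed with Mr {NAME} by telephone.",
                   "Reviewed by doctor {NAME} on DATE2."],
    "label": ["Reporter: {NAME}. Further details awaited.",
              "Patient: {NAME}. Consent for follow-up given."],
    "title": ["Assessed by {NAME} m.d. following the reaction.",
              "Report countersigned by {NAME} MD."],
    "bare": ["{NAME} experienced swelling of the lips.",
             "According to {NAME} the symptoms began overnight.",
             "The reaction was first noticed by {NAME} at home."],
    "signature": ["Kind regards, {NAME}", "Yours sincerely, {NAME}"],
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters.

    Defaults reproduce the reference held-out test conditions: 5,042
    narratives of which exactly 71 bear names, 179 NAME tokens in total, a
    71/179 short-token share, and a mixed context distribution.
    """

    n_narratives: int = 5042
    frac_with_names: float = 71 / 5042
    total_name_tokens: Optional[int] = 179
    names_per_narrative: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.4, 2: 0.35, 3: 0.15, 4: 0.1})
    frac_initials: float = 71 / 179
    context_mix: Mapping[str, float] = field(
        default_factory=lambda: {"salutation": 0.30, "label": 0.10,
                                 "title": 0.10, "bare": 0.35,
                                 "signature": 0.15})
    distractor_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_narratives < 0:
            raise ValueError("n_narratives must be >= 0")
        for name, frac in (("frac_with_names", self.frac_with_names),
                           ("frac_initials", self.frac_initials)):
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.distractor_rate < 0:
            raise ValueError("distractor_rate must be >= 0")
        total_w = sum(self.context_mix.values())
        if abs(total_w - 1.0) > 1e-9:
            raise ValueError("context_mix weights must sum to 1")
        if any(k not in CONTEXTS for k in self.context_mix):
            raise ValueError(f"context_mix keys must be among {CONTEXTS}")


def test_set_conditions(seed: int = 0) -> SyntheticConfig:
    """Reference test-set structure (5,042 narratives, 71 bearing, 179 tokens)."""
    return SyntheticConfig(seed=seed)


def training_conditions(n_narratives: int = 500, seed: int = 0) -> SyntheticConfig:
    """Enriched, training-like structure: ~64% of narratives bear names
    (as after machine-assisted candidate selection), ~2.3 NAME tokens per
    bearing narrative, short share ~25% (267/1080)."""
    frac = 299 / 467
    n_with = round(frac * n_narratives)
    total = round(n_with * 1080 / 299)
    return SyntheticConfig(
        n_narratives=n_narratives, frac_with_names=frac,
        total_name_tokens=total, frac_initials=267 / 1080, seed=seed)


def name_inventory() -> Dict[str, List[str]]:
    """The lexicons mentions are drawn from (for audits and fairness probes)."""
    return {"first": list(FIRST_NAMES), "last": list(LAST_NAMES),
            "short_single": list(SHORT_SINGLE), "short_pair": list(SHORT_PAIR)}


def _exact_round(value: float, what: str) -> int:
    n = round(value)
    if abs(value - n) > 1e-9:
        warnings.warn(f"{what} = {value} is not integral; rounded to {n}")
    return int(n)


def _partition_tokens(n_with: int, total: int,
                      rng: np.random.Generator) -> List[int]:
    """Split *total* tokens over *n_with* narratives, each getting >= 1."""
    if total < n_with:
        raise ValueError("total_name_tokens must be >= name-bearing narratives")
    counts = np.ones(n_with, dtype=int)
    extra = total - n_with
    if extra:
        idx = rng.integers(0, n_with, size=extra)
        np.add.at(counts, idx, 1)
    return counts.tolist()


def _allocate_short(budgets: Sequence[int], n_short: int,
                    rng: np.random.Generator) -> List[int]:
    """Choose exactly *n_short* short slots across narratives' token budgets."""
    slots = [i for i, k in enumerate(budgets) for _ in range(k)]
    chosen = rng.choice(len(slots), size=n_short, replace=False)
    short = [0] * len(budgets)
    for c in chosen:
        short[slots[int(c)]] += 1
    return short


def _mentions_for(n_long: int, n_short: int,
                  rng: np.random.Generator) -> List[Tuple[str, int]]:
    """Assemble name mentions consuming exactly the given slot counts.

    Returns (mention_text, token_count) pairs: full names (2 long tokens),
    single surnames (1 long), initial pairs (2 short) and single initials.
    """
    mentions: List[Tuple[str, int]] = []
    while n_long >= 2 and rng.random() < 0.7:
        first = FIRST_NAMES[int(rng.integers(len(FIRST_NAMES)))]
        last = LAST_NAMES[int(rng.integers(len(LAST_NAMES)))]
        # hyphenated first names contribute 2 tokens on their own
        k = 2 + first.count("-")
        if k > n_long:
            break
        mentions.append((f"{first} {last}", k))
        n_long -= k
    while n_long > 0:
        mentions.append((LAST_NAMES[int(rng.integers(len(LAST_NAMES)))], 1))
        n_long -= 1
    while n_short >= 2 and rng.random() < 0.5:
        mentions.append((SHORT_PAIR[int(rng.integers(len(SHORT_PAIR)))], 2))
        n_short -= 2
    while n_short > 0:
        mentions.append((SHORT_SINGLE[int(rng.integers(len(SHORT_SINGLE)))], 1))
        n_short -= 1
    order = rng.permutation(len(mentions))
    return [mentions[int(i)] for i in order]


def _render(sentences: List[str], mentions: List[Tuple[str, int]],
            config: SyntheticConfig,
            rng: np.random.Generator) -> Tuple[str, List[Span]]:
    """Interleave body sentences with name-bearing context sentences."""
    ctx_names = list(config.context_mix)
    ctx_weights = np.array([config.context_mix[c] for c in ctx_names])
    pieces: List[str] = []
    spans: List[Span] = []
    pos = 0

    def emit(sentence: str, name: Optional[str] = None) -> None:
        nonlocal pos
        if pieces:
            pieces.append(" ")
            pos += 1
        if name is None:
            pieces.append(sentence)
            pos += len(sentence)
            return
        before, after = sentence.split("{NAME}")
        pieces.append(before)
        pos += len(before)
        spans.append(Span(pos, pos + len(name)))
        pieces.append(name)
        pos += len(name)
        pieces.append(after)
        pos += len(after)

    body = list(sentences)
    name_sentences = []
    for mention, _k in mentions:
        ctx = ctx_names[int(rng.choice(len(ctx_names), p=ctx_weights))]
        tpl = _CONTEXT_TEMPLATES[ctx][int(rng.integers(len(_CONTEXT_TEMPLATES[ctx])))]
        name_sentences.append((ctx, tpl, mention))

    # Non-signature name sentences are spliced at random body positions;
    # a signature, if any, goes last.
    inner = [(t, m) for c, t, m in name_sentences if c != "signature"]
    sigs = [(t, m) for c, t, m in name_sentences if c == "signature"]
    positions = sorted(int(rng.integers(0, len(body) + 1)) for _ in inner)
    out: List[Tuple[str, Optional[str]]] = []
    bi = 0
    for p, (tpl, mention) in zip(positions, inner):
        while bi < p:
            out.append((body[bi], None))
            bi += 1
        out.append((tpl, mention))
    out.extend((s, None) for s in body[bi:])
    out.extend(sigs)

    for sentence, mention in out:
        emit(sentence, mention)
    return "".join(pieces), spans


def generate_corpus(config: SyntheticConfig) -> List[AnnotatedNarrative]:
    """Generate an annotated corpus; deterministic for a fixed seed.

    Exactly ``round(frac_with_names * n)`` narratives bear names; when
    ``total_name_tokens`` is set the corpus holds exactly that many NAME
    tokens, of which exactly ``round(frac_initials * total)`` are short.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_narratives
    n_with = _exact_round(config.frac_with_names * n, "frac_with_names * n")

    if n_with:
        if config.total_name_tokens is not None:
            budgets = _partition_tokens(n_with, config.total_name_tokens, rng)
        else:
            ks = sorted(config.names_per_narrative)
            ws = np.array([config.names_per_narrative[k] for k in ks], float)
            ws /= ws.sum()
            budgets = [int(ks[int(rng.choice(len(ks), p=ws))])
                       for _ in range(n_with)]
        total = sum(budgets)
        n_short = _exact_round(config.frac_initials * total,
                               "frac_initials * total NAME tokens")
        shorts = _allocate_short(budgets, n_short, rng)
    else:
        budgets, shorts = [], []

    bearing = set(rng.choice(n, size=n_with, replace=False).tolist()) if n_with else set()
    bearing_order = sorted(bearing)
    budget_of = {idx: (budgets[j], shorts[j])
                 for j, idx in enumerate(bearing_order)}

    corpus: List[AnnotatedNarrative] = []
    for i in range(n):
        n_sent = int(rng.integers(3, 7))
        sent_idx = rng.integers(0, len(BODY_SENTENCES), size=n_sent)
        sentences = [BODY_SENTENCES[int(j)] for j in sent_idx]
        n_distr = int(rng.poisson(config.distractor_rate))
        for _ in range(n_distr):
            d = DISTRACTORS[int(rng.integers(len(DISTRACTORS)))]
            sentences.insert(int(rng.integers(0, len(sentences) + 1)), d)
        if i in bearing:
            k, s = budget_of[i]
            mentions = _mentions_for(k - s, s, rng)
        else:
            mentions = []
        text, spans = _render(sentences, mentions, config, rng)
        corpus.append(AnnotatedNarrative(Narrative(f"syn-{i:05d}", text), spans))
    return corpus
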