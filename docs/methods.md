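# Methods

## Task and model

De-identification is cast as binary token classification: every maximal run
of alphanumeric characters (Unicode letters and decimal digits; underscores
and all punctuation delimit) is labelled NAME or NON-NAME.  Character spans
are derived from label runs, and redaction replaces each span with a fixed
placeholder.  Two detectors are combined by OR:

1. **Neural arm.**  A transformer encoder with a two-class token head.
   Words are mapped to subword units (hashed character trigrams over a
   2,048-slot vocabulary in the test backend), sequences longer than the
   budget are cut into independent chunks of at most `max_sequence_length`
   units including the two sentinel positions — never splitting a word's
   subword group — and each chunk is scored independently with no context
   stitching.  Per subword the head produces a softmax pair; a *word* is
   NON-NAME only if **every** one of its subwords has
   P(NON-NAME) > τ (strict inequality; default τ = 0.9).  Both choices —
   any-subword aggregation and ties flagging — err toward redaction, since
   a missed name is the costly error.  Training minimises categorical cross
   entropy with Adam (default 5 epochs, learning rate 1e-5, no class
   weighting), shuffling chunk order each epoch with a seeded generator;
   retraining with the same seed, corpus and backend is bit-reproducible.

2. **Rule arm.**  Case-insensitive whole-token triggers in three families:
   salutations capture the 1–3 *following* words, labels ("name:",
   "reporter:") likewise after their colon, titles ("m.d.") the 1–3
   *preceding* words.  The adjacent word is always captured; the second and
   third only while each added word starts with an uppercase letter; no
   capture crosses a sentence-terminating `.`, `!`, `?` or newline.
   Because one word is always captured ("the doctor **said**"), the rules
   have high reach but low precision by construction; their value is
   catching salutation-adjacent names that are obvious to a reader.  The
   exact published trigger inventories are not available, so the shipped
   lexicon (`data/ruleset.txt`) is a reconstruction consistent with the
   documented behaviour; it is a plain editable text file.
   Rules always run on original-cased text, as capitalisation is their
   signal.

The neural forward and backward passes (embeddings, post-LN encoder blocks
with multi-head attention and ReLU feed-forward, linear head) are written
directly in numpy; analytic gradients are verified against central finite
differences in the test suite.  The `tiny_test_transformer` backend
(d_model 32, 2 heads, 1 layer, FFN 64, init std 0.02) is the default and
needs no network access; `pretrained_uncased_transformer` describes the
same graph at full size and must be populated from a local weights
directory — no weights ship with the package.

## Evaluation: covering mode

Scoring is per gold token, stratified into all / long (> 3 chars) / short
(≤ 3 chars, initial-like):

* gold NAME token — true positive iff some predicted span **fully
  encapsulates** it; partial coverage is a false negative (a *leak*);
* gold NON-NAME token fully covered by a span that also fully covers at
  least one gold NAME token — forgiven (true negative): over-extension
  around a real name is harmless;
* gold NON-NAME token partially covered, or fully covered by a span with no
  fully covered NAME token — false positive.

Where a span fully covers one NAME token but only partially covers a
second, the forgiveness rule still applies to its fully covered NON-NAME
tokens (the rule requires ≥ 1 fully covered NAME token in the same span).
Overlapping predicted spans are merged before scoring (overlap, not mere
adjacency).  Precision, recall and F1 are rounded half-up to whole
percentage points, the false-positive rate to two decimals; a zero
denominator yields "undefined", never 0.  The FPR denominator is the gold
NON-NAME token count of the stratum.  Narrative-level recall divides the
name-bearing narratives with zero leaked tokens of a stratum by all
narratives bearing ≥ 1 gold NAME token of that stratum.

A consequence of forgiveness worth knowing: covering-mode FPR is *not*
monotone under the OR ensemble.  An added rule flag can complete the
coverage of a name token and thereby convert a neighbouring neural false
positive into a forgiven true negative.  Monotonicity ("OR only adds
flags") is exact on the flagged-token sets and on plain token-label
counts, and that is where the test suite asserts it; covering recall is
monotone either way.

`make_confusion_fixture` inverts the evaluator: given any internally
consistent per-stratum confusion table it constructs a corpus and
prediction set that score to exactly that table, which is how printed
result tables are reproduced from their printed counts without access to
the confidential evaluation data.

## Synthetic data

The generator targets structural, not stylistic, fidelity.  Narratives are
3–6 sentences of adverse-event boilerplate with DRUG/DATE placeholder
tokens, optionally carrying medical-eponym and pseudo-identifier
distractors ("Stevens-Johnson syndrome", "Person A") at a configurable
Poisson rate (default 0.2/narrative).  Name mentions are injected through
five context families — salutation, label, title, bare, signature — with
default weights 0.30/0.10/0.10/0.35/0.15 (chosen so that roughly half of
mentions carry an explicit cue, the rest are bare or signature-context).
The name lexicons mix origins (South Asian, East Asian, African, European)
so fairness probes are expressible; short mentions are drawn from
initial-style lexicons (1 or 2 tokens of ≤ 3 characters).

Counts are realised exactly by partitioning before sampling: the number of
name-bearing narratives is `round(frac_with_names · n)`, the NAME-token
total is partitioned over bearing narratives (each ≥ 1), and exactly
`round(frac_initials · total)` token slots are short.  Two presets exist:
`test_set_conditions()` (5,042 narratives, 71 bearing, 179 NAME tokens,
71 short — the low-prevalence held-out profile) and
`training_conditions(n)` (64% bearing, ~2.3 NAME tokens per bearing
narrative, 25% short — the enriched profile produced by machine-assisted
candidate selection).  What passing tests on this data shows is that the
machinery — labelling, chunking, threshold, ensemble, scoring — behaves
correctly and that the contexts are learnable; it does not show
performance on real clinical language, whose lexical variety, typos and
ambiguity the generator deliberately does not model.

## Scaled learning experiment

The full-size recipe (pretrained encoder, 5 epochs, lr 1e-5, τ = 0.9) is
run at desk scale with the tiny backend: 500 synthetic training narratives
(enriched profile), 200 held-out, fixed seeds.  In this regime the model is
deliberately under-confident: 2,500 Adam steps at lr 1e-5 move parameters
far enough to make common context words confidently NON-NAME but rarely
push name tokens past τ = 0.9, so held-out token recall is high (≥ 93%
across seeds tried; the acceptance bar is 80%) while precision is poor.
That is the intended reading: the threshold design makes recall the robust
quantity, and precision is what pretraining buys.  That the architecture
genuinely learns is checked separately: with a unique marker token before
every name and a generous regime (lr 1e-3, 15 epochs) the tiny model
reaches perfect recall with precision > 0.8.

The name-injection sensitivity protocol swaps ten surrogate full names
(mixed origins, paired from the shipped lexicons) into a salutation-context
gold slot of a fixed narrative and asks whether every token of the injected
name is flagged; the acceptance bar is 9 of 10.

## Numerical and design notes

* Offsets are 0-based, half-open, in Unicode code points.  Overlapping gold
  spans merge on read; the task is a single binary class.
* Gold projection is any-overlap (≥ 1 character): a partially annotated
  token is still a name fragment.
* The 512-unit sequence budget counts the two sentinels; a single word
  whose subwords exceed the budget is tail-truncated with a warning.
* i2b2 2014 records: only DOCTOR/PATIENT/USERNAME tags become gold spans
  (subtype retained, collapsed to NAME for modelling and scoring); all
  other PHI categories are out of scope and treated as NON-NAME.  There is
  no i2b2 writer.
* The review queue is ordered by flagged-token count descending — a triage
  choice, not a correctness requirement.
* `epochs=0` returns the initialised backend unchanged; an all-one-class
  training corpus warns (degenerate fit); empty corpus is an error.
* Training loss is logged per epoch and must stay finite; a NaN raises
  rather than silently corrupting weights.

## Known limitations

* The tiny backend's hashed-trigram vocabulary can collide name and
  non-name pieces; at 2,048 slots this is negligible on the synthetic
  lexicons but would not be acceptable at realistic vocabulary sizes.
* Rules have no part-of-speech awareness; "the doctor said" flags "said"
  by design, which is why rules-alone precision is low.
* No surrogate-name replacement mode: redaction uses placeholders only.
* Scores are calibrated only implicitly by cross entropy; τ = 0.9 is a
  decision threshold, not a calibrated probability guarantee.
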