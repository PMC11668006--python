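"""Transformer token classifier with a NON-NAME decision threshold.

The classifier assigns each alphanumeric token a probability pair
(NAME, NON-NAME) and labels it NON-NAME only when the NON-NAME score is
*strictly above* a confidence threshold (default 0.9); otherwise the token
is flagged as a NAME.  Requiring high confidence to withhold a flag is the
privacy-conservative direction: ties and uncertainty favour redaction.

Architecture: token + learned position embeddings, one (or more) post-LN
encoder blocks (multi-head self-attention, ReLU feed-forward), and a linear
two-class head.  Training minimises categorical cross entropy with Adam.
The forward and backward passes are written directly in numpy; a finite-
difference check in the test suite guards the gradients.

Backends
--------
``tiny_test_transformer``
    A small randomly initialised network over a hashed character-n-gram
    subword vocabulary.  Self-contained: no downloads, fast on one CPU.
``pretrained_uncased_transformer``
    The same computation graph at larger dimensions, populated from a local
    weights directory via :meth:`Classifier.load`.  No pretrained weights
    ship with the package, so constructing this backend without a weights
    directory raises an informative error.

Words longer than the sequence budget never have their subword group split
across chunks: narratives are cut into independent, non-overlapping chunks
of at most ``max_sequence_length`` units including the two sentinel
positions, and inference runs on each chunk independently.
"""

from __future__ import annotations

import json
import logging
import warnings
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .corpus_io import AnnotatedNarrative, Span
from .tokenization import Token, TokenLabel, project_gold, tokenize

__all__ = [
    "ModelConfig",
    "Classifier",
    "split_sequences",
    "train",
    "predict_scores",
    "predict_tokens",
    "predict_spans",
    "labels_to_spans",
]

logger = logging.getLogger(__name__)

BACKENDS = ("pretrained_uncased_transformer", "tiny_test_transformer")

_CLS_ID, _SEP_ID = 0, 1
_N_SPECIAL = 2
_PIECE_LEN = 3  # subword pieces are character n-grams of up to this length


@dataclass(frozen=True)
class ModelConfig:
    """Training and decision hyperparameters.

    Defaults follow the reference fine-tuning recipe: 5 epochs, learning
    rate 1e-5 with Adam, NON-NAME decision threshold 0.9, sequences capped
    at 512 subword units (sentinels included).
    """

    epochs: int = 5
    learning_rate: float = 1e-5
    non_name_threshold: float = 0.9
    max_sequence_length: int = 512
    seed: int = 0
    backend: str = "tiny_test_transformer"

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.learning_rate <= 0:
            raise ValueError("epochs must be >= 0 and learning_rate > 0")
        if not 0 < self.non_name_threshold <= 1:
            raise ValueError("non_name_threshold must be in (0, 1]")
        if self.max_sequence_length < 3:
            raise ValueError("max_sequence_length must leave room for sentinels")
        if self.backend not in BACKENDS:
            raise ValueError(f"unknown backend {self.backend!r}")


_TINY_ARCH = dict(vocab_size=2048, d_model=32, n_heads=2, n_layers=1, d_ff=64)
_BASE_ARCH = dict(vocab_size=30522, d_model=768, n_heads=12, n_layers=12, d_ff=3072)


# ---------------------------------------------------------------------------
# Subword vocabulary (hashed character n-grams)
# ---------------------------------------------------------------------------

def word_to_subwords(word: str, vocab_size: int) -> List[int]:
    """Deterministically map a lowercased word to ≥ 1 hashed subword ids."""
    w = word.lower()
    pieces = [w[i:i + _PIECE_LEN] for i in range(0, len(w), _PIECE_LEN)]
    span = vocab_size - _N_SPECIAL
    return [_N_SPECIAL + zlib.crc32(p.encode("utf-8")) % span for p in pieces]


# ---------------------------------------------------------------------------
# Sequence chunking
# ---------------------------------------------------------------------------

def split_sequences(groups: Sequence[Sequence[int]],
                    max_len: int) -> List[List[List[int]]]:
    """Chunk per-word subword groups so each chunk fits the sequence budget.

    *groups* is one list of subword ids per word.  Chunks are non-overlapping
    and order-preserving; each holds at most ``max_len - 2`` content units
    (two positions are reserved for the begin/end sentinels) and never splits
    a word's group.  A single word whose group alone exceeds the budget has
    its tail subwords truncated, with a warning.
    """
    if max_len < 3:
        raise ValueError("max_len must be >= 3")
    capacity = max_len - 2
    chunks: List[List[List[int]]] = []
    current: List[List[int]] = []
    used = 0
    for g in groups:
        g = list(g)
        if len(g) > capacity:
            warnings.warn(
                f"word with {len(g)} subword units exceeds the sequence "
                f"budget of {capacity}; truncating its tail")
            g = g[:capacity]
        if used + len(g) > capacity and current:
            chunks.append(current)
            current, used = [], 0
        current.append(g)
        used += len(g)
    if current or not chunks:
        chunks.append(current)
    return chunks


# ---------------------------------------------------------------------------
# Parameters and forward/backward
# ---------------------------------------------------------------------------

def _init_params(arch: Dict[str, int], max_pos: int,
                 rng: np.random.Generator) -> Dict[str, np.ndarray]:
    d, f = arch["d_model"], arch["d_ff"]
    std = 0.02

    def N(*shape):
        return rng.normal(0.0, std, size=shape)

    params: Dict[str, np.ndarray] = {
        "E": N(arch["vocab_size"], d),
        "P": N(max_pos, d),
        "Wc": N(d, 2), "bc": np.zeros(2),
    }
    for l in range(arch["n_layers"]):
        params.update({
            f"{l}.Wq": N(d, d), f"{l}.bq": np.zeros(d),
            f"{l}.Wk": N(d, d), f"{l}.bk": np.zeros(d),
            f"{l}.Wv": N(d, d), f"{l}.bv": np.zeros(d),
            f"{l}.Wo": N(d, d), f"{l}.bo": np.zeros(d),
            f"{l}.ln1_g": np.ones(d), f"{l}.ln1_b": np.zeros(d),
            f"{l}.W1": N(d, f), f"{l}.b1": np.zeros(f),
            f"{l}.W2": N(f, d), f"{l}.b2": np.zeros(d),
            f"{l}.ln2_g": np.ones(d), f"{l}.ln2_b": np.zeros(d),
        })
    return params


_LN_EPS = 1e-5


def _layernorm_fwd(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return xhat * g + b, (xhat, inv, g)


def _layernorm_bwd(dy, cache):
    xhat, inv, g = cache
    d = xhat.shape[-1]
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (dxhat - dxhat.mean(axis=-1, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True))
    return dx, dg, db


def _softmax(x):
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _forward(params, arch, ids):
    """Run the encoder; returns per-position logits and a backward cache."""
    d, h = arch["d_model"], arch["n_heads"]
    dh = d // h
    L = len(ids)
    X = params["E"][ids] + params["P"][:L]
    cache = {"ids": ids, "L": L, "layers": []}
    for l in range(arch["n_layers"]):
        p = {k.split(".", 1)[1]: v for k, v in params.items()
             if k.startswith(f"{l}.")}
        Q = X @ p["Wq"] + p["bq"]
        K = X @ p["Wk"] + p["bk"]
        V = X @ p["Wv"] + p["bv"]
        Qh = Q.reshape(L, h, dh).transpose(1, 0, 2)
        Kh = K.reshape(L, h, dh).transpose(1, 0, 2)
        Vh = V.reshape(L, h, dh).transpose(1, 0, 2)
        S = Qh @ Kh.transpose(0, 2, 1) / np.sqrt(dh)
        A = _softmax(S)
        Hh = A @ Vh                                   # (h, L, dh)
        Hcat = Hh.transpose(1, 0, 2).reshape(L, d)
        M = Hcat @ p["Wo"] + p["bo"]
        X1, ln1c = _layernorm_fwd(X + M, p["ln1_g"], p["ln1_b"])
        Z = X1 @ p["W1"] + p["b1"]
        R = np.maximum(Z, 0.0)
        F = R @ p["W2"] + p["b2"]
        X2, ln2c = _layernorm_fwd(X1 + F, p["ln2_g"], p["ln2_b"])
        cache["layers"].append(dict(X=X, Q=Q, K=K, V=V, A=A, Hcat=Hcat,
                                    X1=X1, Z=Z, R=R, ln1c=ln1c, ln2c=ln2c))
        X = X2
    logits = X @ params["Wc"] + params["bc"]
    cache["Xout"] = X
    return logits, cache


def _backward(params, arch, cache, dlogits):
    d, h = arch["d_model"], arch["n_heads"]
    dh = d // h
    L = cache["L"]
    grads: Dict[str, np.ndarray] = {}
    grads["Wc"] = cache["Xout"].T @ dlogits
    grads["bc"] = dlogits.sum(axis=0)
    dX = dlogits @ params["Wc"].T
    for l in reversed(range(arch["n_layers"])):
        c = cache["layers"][l]
        p = {k.split(".", 1)[1]: v for k, v in params.items()
             if k.startswith(f"{l}.")}
        dx12, dg2, db2 = _layernorm_bwd(dX, c["ln2c"])
        grads[f"{l}.ln2_g"], grads[f"{l}.ln2_b"] = dg2, db2
        # FFN branch
        dF = dx12
        grads[f"{l}.W2"] = c["R"].T @ dF
        grads[f"{l}.b2"] = dF.sum(axis=0)
        dR = dF @ p["W2"].T
        dZ = dR * (c["Z"] > 0)
        grads[f"{l}.W1"] = c["X1"].T @ dZ
        grads[f"{l}.b1"] = dZ.sum(axis=0)
        dX1 = dx12 + dZ @ p["W1"].T
        dx11, dg1, db1 = _layernorm_bwd(dX1, c["ln1c"])
        grads[f"{l}.ln1_g"], grads[f"{l}.ln1_b"] = dg1, db1
        # attention branch
        dM = dx11
        grads[f"{l}.Wo"] = c["Hcat"].T @ dM
        grads[f"{l}.bo"] = dM.sum(axis=0)
        dHcat = dM @ p["Wo"].T
        dHh = dHcat.reshape(L, h, dh).transpose(1, 0, 2)
        Vh = c["V"].reshape(L, h, dh).transpose(1, 0, 2)
        Qh = c["Q"].reshape(L, h, dh).transpose(1, 0, 2)
        Kh = c["K"].reshape(L, h, dh).transpose(1, 0, 2)
        A = c["A"]
        dVh = A.transpose(0, 2, 1) @ dHh
        dA = dHh @ Vh.transpose(0, 2, 1)
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dS /= np.sqrt(dh)
        dQh = dS @ Kh
        dKh = dS.transpose(0, 2, 1) @ Qh
        dQ = dQh.transpose(1, 0, 2).reshape(L, d)
        dK = dKh.transpose(1, 0, 2).reshape(L, d)
        dV = dVh.transpose(1, 0, 2).reshape(L, d)
        X = c["X"]
        grads[f"{l}.Wq"] = X.T @ dQ
        grads[f"{l}.bq"] = dQ.sum(axis=0)
        grads[f"{l}.Wk"] = X.T @ dK
        grads[f"{l}.bk"] = dK.sum(axis=0)
        grads[f"{l}.Wv"] = X.T @ dV
        grads[f"{l}.bv"] = dV.sum(axis=0)
        dX = dx11 + dQ @ p["Wq"].T + dK @ p["Wk"].T + dV @ p["Wv"].T
    grads["E"] = np.zeros_like(params["E"])
    np.add.at(grads["E"], cache["ids"], dX)
    grads["P"] = np.zeros_like(params["P"])
    grads["P"][:L] = dX
    return grads


def loss_and_grads(params, arch, ids, labels_mask):
    """Cross-entropy loss and gradients for one chunk.

    *labels_mask* is a pair (y, mask): target class indices (0 = NAME,
    1 = NON-NAME) and a 0/1 mask selecting positions that contribute to the
    loss (sentinels are masked out).
    """
    y, mask = labels_mask
    logits, cache = _forward(params, arch, ids)
    probs = _softmax(logits)
    n = max(int(mask.sum()), 1)
    eps = 1e-12
    loss = -(mask * np.log(probs[np.arange(len(y)), y] + eps)).sum() / n
    dlogits = probs.copy()
    dlogits[np.arange(len(y)), y] -= 1.0
    dlogits *= (mask / n)[:, None]
    return loss, _backward(params, arch, cache, dlogits)


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

@dataclass
class Classifier:
    """A (possibly trained) transformer token classifier."""

    config: ModelConfig
    arch: Dict[str, int]
    params: Dict[str, np.ndarray]

    @classmethod
    def initialize(cls, config: ModelConfig) -> "Classifier":
        if config.backend == "tiny_test_transformer":
            arch = dict(_TINY_ARCH)
        else:
            raise ValueError(
                "the pretrained backend has no bundled weights; load it "
                "from a local weights directory with Classifier.load()")
        rng = np.random.default_rng(config.seed)
        params = _init_params(arch, config.max_sequence_length, rng)
        return cls(config, arch, params)

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Save as a directory: config manifest (JSON) + weights (npz)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {"config": asdict(self.config), "arch": self.arch}
        (path / "config.json").write_text(json.dumps(manifest, indent=2))
        np.savez(path / "weights.npz", **self.params)

    @classmethod
    def load(cls, path) -> "Classifier":
        path = Path(path)
        manifest = json.loads((path / "config.json").read_text())
        config = ModelConfig(**manifest["config"])
        with np.load(path / "weights.npz") as npz:
            params = {k: npz[k] for k in npz.files}
        return cls(config, manifest["arch"], params)

    # -- inference --------------------------------------------------------
    def _narrative_groups(self, tokens: Sequence[Token]) -> List[List[int]]:
        v = self.arch["vocab_size"]
        return [word_to_subwords(t.text, v) for t in tokens]

    def subword_probs(self, tokens: Sequence[Token]) -> List[np.ndarray]:
        """Per word: array of (p_name, p_non_name) rows, one per subword."""
        groups = self._narrative_groups(tokens)
        out: List[np.ndarray] = [None] * len(groups)  # type: ignore
        idx = 0
        for chunk in split_sequences(groups, self.config.max_sequence_length):
            if not chunk:
                continue
            ids = np.array([_CLS_ID] + [u for g in chunk for u in g] + [_SEP_ID])
            logits, _ = _forward(self.params, self.arch, ids)
            probs = _softmax(logits)[1:-1]  # drop sentinels
            pos = 0
            for g in chunk:
                out[idx] = probs[pos:pos + len(g)]
                pos += len(g)
                idx += 1
        return out


def train(corpus: Sequence[AnnotatedNarrative], config: ModelConfig,
          classifier: Optional[Classifier] = None) -> Classifier:
    """Fine-tune a token classifier on an annotated corpus.

    Reproducible: the same seed, backend and corpus give identical weights.
    With ``epochs == 0`` the returned classifier is the initialised backend,
    untouched.  Per-epoch mean loss is logged.
    """
    if not corpus:
        raise ValueError("training corpus is empty")
    clf = classifier if classifier is not None else Classifier.initialize(config)

    examples = []  # (ids, y, mask) per chunk
    seen_labels = set()
    for ann in corpus:
        tokens = tokenize(ann.text)
        labels = project_gold(tokens, ann.gold_spans)
        seen_labels.update(labels)
        groups = [word_to_subwords(t.text, clf.arch["vocab_size"]) for t in tokens]
        y_groups = [[0 if lab is TokenLabel.NAME else 1] * len(g)
                    for g, lab in zip(groups, labels)]
        gi = 0
        for chunk in split_sequences(groups, config.max_sequence_length):
            if not chunk:
                continue
            flat, yflat = [], []
            for g in chunk:
                flat.extend(g)
                yflat.extend(y_groups[gi][:len(g)])
                gi += 1
            ids = np.array([_CLS_ID] + flat + [_SEP_ID])
            y = np.array([1] + yflat + [1])
            mask = np.ones(len(ids))
            mask[0] = mask[-1] = 0.0
            examples.append((ids, y, mask))
    if len(seen_labels) < 2:
        warnings.warn("training corpus contains a single class; the "
                      "fitted model is degenerate")

    rng = np.random.default_rng(config.seed + 1)
    m = {k: np.zeros_like(v) for k, v in clf.params.items()}
    v = {k: np.zeros_like(p) for k, p in clf.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    t = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(examples))
        total = 0.0
        for i in order:
            ids, y, mask = examples[i]
            loss, grads = loss_and_grads(clf.params, clf.arch, ids, (y, mask))
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite training loss")
            total += loss
            t += 1
            for k, g in grads.items():
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mhat = m[k] / (1 - b1 ** t)
                vhat = v[k] / (1 - b2 ** t)
                clf.params[k] = clf.params[k] - config.learning_rate * mhat / (
                    np.sqrt(vhat) + eps)
        logger.info("epoch %d/%d: mean loss %.4f", epoch + 1, config.epochs,
                    total / len(examples))
    return clf


# ---------------------------------------------------------------------------
# Decision rule and span assembly
# ---------------------------------------------------------------------------

def predict_scores(text: str, classifier: Classifier) -> List[Tuple[float, float]]:
    """Per alphanumeric token: (p_name, p_non_name), summing to 1.

    A token's pair comes from its most name-like subword (the one with the
    lowest NON-NAME score), matching the any-subword decision rule.
    """
    tokens = tokenize(text)
    out = []
    for probs in classifier.subword_probs(tokens):
        row = probs[int(np.argmin(probs[:, 1]))]
        out.append((float(row[0]), float(row[1])))
    return out


def predict_tokens(text: str, classifier: Classifier,
                   config: Optional[ModelConfig] = None) -> List[TokenLabel]:
    """Label each token: NON-NAME iff its NON-NAME score is strictly above
    the threshold on *every* subword; otherwise NAME (ties flag)."""
    thr = (config or classifier.config).non_name_threshold
    labels = []
    for _, p_nn in predict_scores(text, classifier):
        labels.append(TokenLabel.NON_NAME if p_nn > thr else TokenLabel.NAME)
    return labels


def labels_to_spans(tokens: Sequence[Token],
                    labels: Sequence[TokenLabel]) -> List[Span]:
    """Merge maximal runs of NAME tokens into character spans.

    A run's span stretches from the first token's start to the last token's
    end, covering intervening punctuation/whitespace.
    """
    if len(tokens) != len(labels):
        raise ValueError("tokens and labels differ in length")
    spans: List[Span] = []
    run_start = None
    for i, (tok, lab) in enumerate(zip(tokens, labels)):
        if lab is TokenLabel.NAME:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            spans.append(Span(tokens[run_start].start, tokens[i - 1].end))
            run_start = None
    if run_start is not None:
        spans.append(Span(tokens[run_start].start, tokens[-1].end))
    return spans


def predict_spans(text: str, classifier: Classifier,
                  config: Optional[ModelConfig] = None) -> List[Span]:
    tokens = tokenize(text)
    return labels_to_spans(tokens, predict_tokens(text, classifier, config))
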