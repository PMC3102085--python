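"""Maximum-entropy Markov model chemical-entity recogniser.

Each position carries a multinomial logistic (maximum-entropy) distribution
P(label_i | label_{i-1}, context_i) over the BIO labels {O, B-CM, I-CM},
with the previous label entering as conjoined context features and the
observation entering through character n-grams, token shape, affixes and
neighbouring words.  Decoding is Viterbi; per-entity confidence is the exact
probability mass, under the model's sequence distribution, of all label
sequences realising that entity — computed by a constrained forward pass, so
it is a genuine probability in [0, 1] suitable for threshold filtering.

Training maximises the L2-penalised conditional log-likelihood of the gold
BIO sequences with L-BFGS from zero initialisation; given a fixed corpus
order the whole procedure is deterministic.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.special import logsumexp

from .annotations import AnnotatedDocument, EntitySpan, Token, from_bio, to_bio
from .tokeniser import tokenise

__all__ = [
    "LABELS",
    "START",
    "TrainingConfig",
    "MEMMModel",
    "extract_features",
    "train",
    "viterbi",
    "entity_confidence",
    "tag",
    "save_model",
    "load_model",
]

LABELS = ("O", "B-CM", "I-CM")
START = "<START>"  # previous-label sentinel at position 0

FEATURE_TEMPLATE_VERSION = "1"

_GREEK = re.compile(r"[Ͱ-Ͽ]")


def token_shape(surface: str) -> str:
    """Collapsed character-class pattern: A/a letters, d digits, g Greek, p other."""
    out: list[str] = []
    for ch in surface:
        if ch.isdigit():
            c = "d"
        elif _GREEK.match(ch):
            c = "g"
        elif ch.isalpha():
            c = "A" if ch.isupper() else "a"
        else:
            c = "p"
        if not out or out[-1] != c:
            out.append(c)
    return "".join(out)


def _surfaces(tokens) -> list[str]:
    return [t.surface if isinstance(t, Token) else t for t in tokens]


def extract_features(tokens, i: int, prev_label: str,
                     ngram_orders: tuple[int, ...] = (1, 2, 3, 4)) -> list[str]:
    """Binary feature names for position ``i`` given the previous label.

    Includes character n-grams of the current token for each configured order
    (with ``^``/``$`` word-boundary sentinels), token shape, 3-character
    prefix/suffix, lowercased neighbour surfaces (edge sentinels), the
    previous label, and a previous-label/shape conjunction.  Deterministic in
    its arguments; duplicates are removed preserving first occurrence.
    """
    surfaces = _surfaces(tokens)
    if not (0 <= i < len(surfaces)):
        raise IndexError(f"position {i} out of range for {len(surfaces)} tokens")
    w = surfaces[i]
    shape = token_shape(w)
    feats = [
        "bias",
        f"shape={shape}",
        f"pre3={w[:3]}",
        f"suf3={w[-3:]}",
        f"prev_w={surfaces[i - 1].lower() if i > 0 else '<s>'}",
        f"next_w={surfaces[i + 1].lower() if i + 1 < len(surfaces) else '</s>'}",
        f"prev_label={prev_label}",
        f"prev_label|shape={prev_label}|{shape}",
    ]
    padded = "^" + w + "$"
    for n in ngram_orders:
        for j in range(len(padded) - n + 1):
            feats.append(f"ng{n}={padded[j:j + n]}")
    return list(dict.fromkeys(feats))


@dataclass(frozen=True)
class TrainingConfig:
    l2_strength: float = 1.0
    max_iterations: int = 300
    convergence_tol: float = 1e-8
    ngram_orders: tuple[int, ...] = (1, 2, 3, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.l2_strength <= 0:
            raise ValueError("l2_strength must be positive")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")


@dataclass
class MEMMModel:
    """Trained weights plus the feature template needed to reapply them."""

    feature_index: dict[str, int]
    weights: np.ndarray  # shape (n_features, n_labels)
    labels: tuple[str, ...] = LABELS
    ngram_orders: tuple[int, ...] = (1, 2, 3, 4)
    feature_template_version: str = FEATURE_TEMPLATE_VERSION
    training_meta: dict = field(default_factory=dict)

    def scores(self, tokens, i: int, prev_label: str) -> np.ndarray:
        """Unnormalised label scores; unknown features contribute zero."""
        s = np.zeros(len(self.labels))
        for f in extract_features(tokens, i, prev_label, self.ngram_orders):
            j = self.feature_index.get(f)
            if j is not None:
                s += self.weights[j]
        return s

    def log_probs(self, tokens, i: int, prev_label: str) -> np.ndarray:
        s = self.scores(tokens, i, prev_label)
        return s - logsumexp(s)


def _log_lattice(model: MEMMModel, tokens) -> list[np.ndarray]:
    """Per-position conditional log-distributions.

    Element 0 has shape (L,) — conditioned on the START sentinel; element i>0
    has shape (L, L) with rows indexed by the previous label.
    """
    n = len(tokens)
    L = len(model.labels)
    lattice: list[np.ndarray] = []
    if n == 0:
        return lattice
    lattice.append(model.log_probs(tokens, 0, START))
    for i in range(1, n):
        mat = np.empty((L, L))
        for p, prev in enumerate(model.labels):
            mat[p] = model.log_probs(tokens, i, prev)
        lattice.append(mat)
    return lattice


def train(corpus: list[AnnotatedDocument], tokeniser=None,
          config: TrainingConfig | None = None) -> MEMMModel:
    """Fit an MEMM on gold-annotated documents.

    ``tokeniser`` is any callable SourceDocument -> list[Token] (default: the
    chemistry-aware tokeniser).  Gold entities whose boundaries fall inside a
    token are dropped with diagnostics; a corpus with zero boundary-aligned
    entities is refused because the resulting single-class model would be
    silently useless.
    """
    cfg = config or TrainingConfig()
    tok_fn = tokeniser or tokenise
    if not corpus:
        raise ValueError("empty training corpus")

    sequences: list[tuple[list[Token], list[str]]] = []
    n_dropped = 0
    n_entities = 0
    for adoc in corpus:
        tokens = tok_fn(adoc.document)
        labels, dropped = to_bio(tokens, adoc.entities)
        n_dropped += len(dropped)
        n_entities += len(adoc.entities) - len(dropped)
        sequences.append((tokens, labels))
    if n_entities == 0:
        raise ValueError(
            "no boundary-aligned entities in training corpus "
            f"({n_dropped} dropped as boundary mismatches)")

    label_idx = {lab: k for k, lab in enumerate(LABELS)}
    feature_index: dict[str, int] = {}
    rows: list[list[int]] = []
    y: list[int] = []
    for tokens, labels in sequences:
        prev = START
        for i, lab in enumerate(labels):
            cols = []
            for f in extract_features(tokens, i, prev, cfg.ngram_orders):
                j = feature_index.setdefault(f, len(feature_index))
                cols.append(j)
            rows.append(cols)
            y.append(label_idx[lab])
            prev = lab

    n_inst = len(rows)
    n_feat = len(feature_index)
    L = len(LABELS)
    indptr = np.zeros(n_inst + 1, dtype=np.int64)
    for i, cols in enumerate(rows):
        indptr[i + 1] = indptr[i] + len(cols)
    indices = np.fromiter((j for cols in rows for j in cols), dtype=np.int64,
                          count=indptr[-1])
    data = np.ones(indptr[-1])
    X = sp.csr_matrix((data, indices, indptr), shape=(n_inst, n_feat))
    y_arr = np.asarray(y)
    onehot_rows = np.arange(n_inst)
    l2 = cfg.l2_strength

    def objective(wflat: np.ndarray):
        W = wflat.reshape(n_feat, L)
        S = X @ W
        logZ = logsumexp(S, axis=1)
        ll = S[onehot_rows, y_arr] - logZ
        P = np.exp(S - logZ[:, None])
        P[onehot_rows, y_arr] -= 1.0
        grad = X.T @ P + l2 * W
        f = -ll.sum() + 0.5 * l2 * (W * W).sum()
        return f, grad.ravel()

    res = minimize(objective, np.zeros(n_feat * L), jac=True, method="L-BFGS-B",
                   options={"maxiter": cfg.max_iterations,
                            "ftol": cfg.convergence_tol,
                            "gtol": 1e-8})
    W = res.x.reshape(n_feat, L)
    meta = {
        "n_documents": len(corpus),
        "n_instances": n_inst,
        "n_features": n_feat,
        "n_entities": n_entities,
        "n_boundary_mismatches": n_dropped,
        "l2_strength": cfg.l2_strength,
        "max_iterations": cfg.max_iterations,
        "convergence_tol": cfg.convergence_tol,
        "seed": cfg.seed,
        "converged": bool(res.success),
        "final_objective": float(res.fun),
    }
    return MEMMModel(feature_index=feature_index, weights=W,
                     ngram_orders=tuple(cfg.ngram_orders), training_meta=meta)


def viterbi(model: MEMMModel, tokens) -> tuple[list[str], float]:
    """Most probable label sequence and its joint log-probability.

    Ties break by label order O < B-CM < I-CM (argmax-first); empty input
    yields ``([], 0.0)``.
    """
    n = len(tokens)
    if n == 0:
        return [], 0.0
    lattice = _log_lattice(model, tokens)
    L = len(model.labels)
    delta = lattice[0].copy()
    back = np.zeros((n, L), dtype=np.int64)
    for i in range(1, n):
        cand = delta[:, None] + lattice[i]  # (prev, label)
        back[i] = np.argmax(cand, axis=0)
        delta = cand[back[i], np.arange(L)]
    best = int(np.argmax(delta))
    logp = float(delta[best])
    path = [best]
    for i in range(n - 1, 0, -1):
        path.append(int(back[i][path[-1]]))
    return [model.labels[k] for k in path[::-1]], logp


def _span_to_token_range(tokens, start: int, end: int) -> tuple[int, int]:
    first = last = None
    for i, t in enumerate(tokens):
        if t.start == start:
            first = i
        if t.end == end:
            last = i
    if first is None or last is None or last < first:
        raise ValueError(
            f"span [{start}, {end}) is not aligned to token boundaries")
    return first, last


def _constrained_forward(lattice: list[np.ndarray], labels: tuple[str, ...],
                         first: int, last: int) -> float:
    """Mass of all sequences realising exactly the entity on tokens [first, last]."""
    n = len(lattice)
    L = len(labels)
    O, B, I = (labels.index(l) for l in ("O", "B-CM", "I-CM"))
    masks = np.ones((n, L), dtype=bool)
    masks[first] = False
    masks[first, B] = True
    for k in range(first + 1, last + 1):
        masks[k] = False
        masks[k, I] = True
    if last + 1 < n:
        masks[last + 1, I] = False  # entity must end: no continuation
    neg = -np.inf
    alpha = np.where(masks[0], lattice[0], neg)
    for i in range(1, n):
        cand = alpha[:, None] + lattice[i]
        alpha = logsumexp(cand, axis=0)
        alpha = np.where(masks[i], alpha, neg)
    total = logsumexp(alpha)
    return float(min(1.0, max(0.0, np.exp(total))))


def entity_confidence(model: MEMMModel, tokens, span: EntitySpan) -> float:
    """Probability that the model's label-sequence distribution realises ``span``.

    The event: B-CM at the span's first token, I-CM through its last, and the
    following token (if any) not I-CM; all other positions are free.  Summed
    exactly by a constrained forward pass.
    """
    first, last = _span_to_token_range(tokens, span.start, span.end)
    lattice = _log_lattice(model, tokens)
    return _constrained_forward(lattice, model.labels, first, last)


def tag(model: MEMMModel, tokens, threshold: float = 0.3,
        text: str | None = None) -> list[EntitySpan]:
    """Decode, attach per-entity confidence, and filter below ``threshold``.

    The default threshold of 0.3 is the conventional operating point for
    MEMM-based chemical NER; sweep it with :mod:`chemner.evaluation` to pick
    a corpus-specific operating point.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    labels, _ = viterbi(model, tokens)
    entities, _repairs = from_bio(tokens, labels, text=text)
    if not entities:
        return []
    lattice = _log_lattice(model, tokens)
    kept: list[EntitySpan] = []
    for ent in entities:
        first, last = _span_to_token_range(tokens, ent.start, ent.end)
        ent.confidence = _constrained_forward(lattice, model.labels, first, last)
        if ent.confidence >= threshold:
            kept.append(ent)
    return kept


def save_model(model: MEMMModel, path: str | Path) -> None:
    """Serialise to a versioned JSON archive; weights round-trip bit-exactly."""
    features = sorted(model.feature_index, key=model.feature_index.get)
    payload = {
        "format": "chemner-memm",
        "feature_template_version": model.feature_template_version,
        "labels": list(model.labels),
        "ngram_orders": list(model.ngram_orders),
        "features": features,
        "weights": model.weights.tolist(),
        "training_meta": model.training_meta,
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_model(path: str | Path) -> MEMMModel:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("format") != "chemner-memm":
        raise ValueError(f"{path}: not a chemner MEMM model file")
    if payload["feature_template_version"] != FEATURE_TEMPLATE_VERSION:
        raise ValueError(
            f"{path}: feature template version "
            f"{payload['feature_template_version']!r} does not match this "
            f"build ({FEATURE_TEMPLATE_VERSION!r})")
    return MEMMModel(
        feature_index={f: i for i, f in enumerate(payload["features"])},
        weights=np.asarray(payload["weights"]),
        labels=tuple(payload["labels"]),
        ngram_orders=tuple(payload["ngram_orders"]),
        feature_template_version=payload["feature_template_version"],
        training_meta=payload["training_meta"],
    )
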