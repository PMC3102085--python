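"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's lattice/forward/Viterbi code paths:
conditional distributions are recomputed directly from features and weights,
and sequence-level quantities come from exhaustive enumeration over all
3^n label sequences.
"""

from __future__ import annotations

import itertools

import numpy as np

from chemner.memm import LABELS, START, MEMMModel, extract_features


def make_random_model(rng: np.random.Generator, surfaces: list[str],
                      ngram_orders=(1, 2)) -> MEMMModel:
    """A model whose feature space covers every feature the inputs can fire."""
    feats: dict[str, int] = {}
    for i in range(len(surfaces)):
        for prev in (START,) + LABELS:
            for f in extract_features(surfaces, i, prev, ngram_orders):
                feats.setdefault(f, len(feats))
    weights = rng.normal(scale=1.5, size=(len(feats), len(LABELS)))
    return MEMMModel(feature_index=feats, weights=weights,
                     ngram_orders=ngram_orders)


def cond_probs(model: MEMMModel, surfaces: list[str], i: int,
               prev: str) -> np.ndarray:
    """Softmax over labels computed directly from summed feature weights."""
    s = np.zeros(len(LABELS))
    for f in extract_features(surfaces, i, prev, model.ngram_orders):
        j = model.feature_index.get(f)
        if j is not None:
            s += model.weights[j]
    e = np.exp(s - s.max())
    return e / e.sum()


def sequence_prob(model: MEMMModel, surfaces: list[str],
                  labels: tuple[str, ...]) -> float:
    p = 1.0
    prev = START
    for i, lab in enumerate(labels):
        p *= cond_probs(model, surfaces, i, prev)[LABELS.index(lab)]
        prev = lab
    return p


def enumerate_best(model: MEMMModel, surfaces: list[str]
                   ) -> tuple[list[str], float]:
    """Argmax over all 3^n sequences; ties broken by label order."""
    best_seq, best_p = None, -1.0
    for seq in itertools.product(LABELS, repeat=len(surfaces)):
        p = sequence_prob(model, surfaces, seq)
        if p > best_p:
            best_seq, best_p = seq, p
    return list(best_seq), float(np.log(best_p))


def enumerate_confidence(model: MEMMModel, surfaces: list[str],
                         first: int, last: int) -> float:
    """Mass of sequences realising exactly the entity on tokens [first, last]."""
    total = 0.0
    for seq in itertools.product(LABELS, repeat=len(surfaces)):
        if seq[first] != "B-CM":
            continue
        if any(seq[k] != "I-CM" for k in range(first + 1, last + 1)):
            continue
        if last + 1 < len(seq) and seq[last + 1] == "I-CM":
            continue
        total += sequence_prob(model, surfaces, seq)
    return total


def brute_force_counts(gold, pred) -> tuple[int, int, int]:
    """Set-intersection scoring on (start, end, label) triples."""
    g = {(s.start, s.end, s.label) for s in gold}
    p = {(s.start, s.end, s.label) for s in pred}
    tp = sum(1 for k in p if k in g)
    return tp, len(p) - tp, len(g) - tp
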