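"""Exact-span scoring, confidence-threshold sweeps, operating-point selection.

Matching is exact on (start, end, label): a partial overlap counts as one
false positive plus one false negative, so a system that returns
"ruthenium(ii)" where the gold mention is "ruthenium (ii) diimine" is
penalised twice — the partial-entity failure mode that better tokenisation
removes.  The "ROC" of threshold tuning is realised as a P/R/F sweep: NER
has no negative-instance denominator, so a true false-positive *rate* is
undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotations import EntitySpan

__all__ = ["EvalResult", "ThresholdSweep", "evaluate", "sweep",
           "select_threshold"]


def _keys(spans) -> set[tuple[int, int, str]]:
    out = set()
    for s in spans:
        if isinstance(s, EntitySpan):
            out.add(s.key())
        else:
            start, end, label = s
            out.add((start, end, label))
    return out


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 1.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 1.0

    @property
    def f_score(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def __add__(self, other: "EvalResult") -> "EvalResult":
        return EvalResult(self.tp + other.tp, self.fp + other.fp,
                          self.fn + other.fn)


def _as_doc_lists(spans):
    """Normalise input to a list of per-document span lists."""
    spans = list(spans)
    if spans and isinstance(spans[0], (list, tuple)) and not (
            isinstance(spans[0], tuple) and len(spans[0]) == 3
            and isinstance(spans[0][0], int)):
        return [list(d) for d in spans]
    return [spans]


def evaluate(gold, predicted) -> EvalResult:
    """Exact span+label scoring.

    ``gold`` and ``predicted`` are span collections for one document, or
    lists of per-document collections (counts are summed across documents).
    Spans are :class:`EntitySpan` or plain ``(start, end, label)`` tuples.
    """
    gold_docs = _as_doc_lists(gold)
    pred_docs = _as_doc_lists(predicted)
    if len(gold_docs) != len(pred_docs):
        raise ValueError(f"{len(gold_docs)} gold documents vs "
                         f"{len(pred_docs)} predicted")
    total = EvalResult(0, 0, 0)
    for g, p in zip(gold_docs, pred_docs):
        gk, pk = _keys(g), _keys(p)
        tp = len(gk & pk)
        total = total + EvalResult(tp, len(pk) - tp, len(gk) - tp)
    return total


@dataclass
class ThresholdSweep:
    points: list[tuple[float, EvalResult]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ts = [t for t, _ in self.points]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("thresholds must be strictly increasing")

    @property
    def thresholds(self) -> list[float]:
        return [t for t, _ in self.points]


def sweep(gold, predictions, thresholds=None,
          provenance: dict | None = None) -> ThresholdSweep:
    """Evaluate at every confidence threshold.

    Every prediction must carry a confidence (deterministic recognisers like
    the pattern recogniser have none — use :func:`evaluate` directly).  The
    default grid is the set of distinct prediction confidences plus {0, 1}.
    """
    pred_docs = _as_doc_lists(predictions)
    gold_docs = _as_doc_lists(gold)
    flat = [e for doc in pred_docs for e in doc]
    for e in flat:
        if not isinstance(e, EntitySpan) or e.confidence is None:
            raise ValueError(
                "every prediction in a sweep needs a confidence; for "
                "confidence-free output use evaluate() at a single point")
    if thresholds is None:
        thresholds = sorted({0.0, 1.0} | {e.confidence for e in flat})
    else:
        thresholds = sorted(set(thresholds))
        if thresholds and not (0 <= thresholds[0] and thresholds[-1] <= 1):
            raise ValueError("thresholds must lie in [0, 1]")
    points = []
    for t in thresholds:
        filtered = [[e for e in doc if e.confidence >= t] for doc in pred_docs]
        points.append((t, evaluate(gold_docs, filtered)))
    return ThresholdSweep(points=points, provenance=provenance or {})


def select_threshold(sw: ThresholdSweep, criterion: str = "max_f") -> float:
    """Operating point selection: threshold of the max-F row (ties: smallest)."""
    if not sw.points:
        raise ValueError("empty sweep")
    if criterion != "max_f":
        raise ValueError(f"unknown criterion {criterion!r}")
    best_t, best_f = sw.points[0][0], sw.points[0][1].f_score
    for t, res in sw.points[1:]:
        if res.f_score > best_f:
            best_t, best_f = t, res.f_score
    return best_t
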