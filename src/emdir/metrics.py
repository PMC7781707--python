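"""Classification and retrieval performance measures.

Classification is scored with macro-averaged precision (AP), recall (AR)
and their harmonic mean F1 from a confusion matrix; retrieval with average
precision per query and its mean over queries (mAP), plus the three vector
measures used for nearest-neighbour search: Euclidean distance, Manhattan
distance and cosine similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

MEASURES = ("euclidean", "manhattan", "cosine")
#: measures for which larger scores mean more similar
SIMILARITY_MEASURES = frozenset({"cosine"})


@dataclass
class RankedRetrieval:
    """One query's ranked result list.

    ``entries`` are ``(record_id, score, relevant)`` ordered best-first:
    descending score for similarity measures, ascending for distances.
    """

    query_id: str
    entries: list[tuple]
    measure: str = "cosine"

    def __post_init__(self) -> None:
        scores = [e[1] for e in self.entries]
        if self.measure in SIMILARITY_MEASURES:
            ordered = all(a >= b for a, b in zip(scores, scores[1:]))
        else:
            ordered = all(a <= b for a, b in zip(scores, scores[1:]))
        if not ordered:
            raise ValueError(
                f"entries are not sorted for measure {self.measure!r}"
            )

    @property
    def relevance(self) -> list[bool]:
        return [bool(e[2]) for e in self.entries]


@dataclass
class EvaluationReport:
    """Bundle of classification and retrieval scores for one evaluation run."""

    total_irma_error: float
    per_image_errors: list[float]
    map_score: float
    per_query_ap: list[float]
    ap: float | None = None
    ar: float | None = None
    f1: float | None = None
    classification_irma_error: float | None = None
    precision_recall_curve: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out = {"total_irma_error": self.total_irma_error, "mAP": self.map_score}
        if self.ap is not None:
            out.update(
                {
                    "AP": self.ap,
                    "AR": self.ar,
                    "F1": self.f1,
                    "classification_irma_error": self.classification_irma_error,
                }
            )
        return out


def classification_metrics(confusion) -> tuple[float, float, float]:
    """Macro precision, recall and F1 from a square confusion matrix.

    ``confusion[i, j]`` counts images of true class ``i`` predicted as
    class ``j``.  Classes with an empty denominator (never predicted, or
    absent from the truth) contribute 0 and are logged.
    """
    mat = np.asarray(confusion)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"confusion matrix must be square, got shape {mat.shape}")
    if np.any(mat < 0) or not np.allclose(mat, np.round(mat)):
        raise ValueError("confusion matrix must hold non-negative integer counts")
    m = mat.shape[0]
    tp = np.diag(mat).astype(float)
    predicted = mat.sum(axis=0).astype(float)  # tp + fp per class
    actual = mat.sum(axis=1).astype(float)  # tp + fn per class
    precisions = np.zeros(m)
    recalls = np.zeros(m)
    for k in range(m):
        if predicted[k] > 0:
            precisions[k] = tp[k] / predicted[k]
        else:
            logger.warning("class %d was never predicted; precision set to 0", k)
        if actual[k] > 0:
            recalls[k] = tp[k] / actual[k]
        else:
            logger.warning("class %d has no true instances; recall set to 0", k)
    ap = float(precisions.mean())
    ar = float(recalls.mean())
    f1 = 0.0 if ap + ar == 0 else 2.0 * ap * ar / (ap + ar)
    return ap, ar, float(f1)


def average_precision(ranked: RankedRetrieval) -> float:
    """Mean of precision-at-rank over the ranks of the relevant items.

    Zero when no relevant item appears anywhere in the ranking.
    """
    rel = ranked.relevance
    if not rel:
        raise ValueError("cannot score an empty ranking")
    precisions = []
    hits = 0
    for rank, is_rel in enumerate(rel, start=1):
        if is_rel:
            hits += 1
            precisions.append(hits / rank)
    if not precisions:
        return 0.0
    return float(sum(precisions) / len(precisions))


def mean_average_precision(rankings) -> float:
    """Arithmetic mean of per-query average precision."""
    rankings = list(rankings)
    if not rankings:
        raise ValueError("cannot average over an empty query set")
    return float(np.mean([average_precision(r) for r in rankings]))


def precision_at_recall_curve(rankings, recall_levels=None) -> dict:
    """Interpolated mean precision at fixed recall levels over all queries.

    For each query, precision at recall level r is the maximum precision
    attained at any rank whose recall is >= r (standard PR interpolation);
    queries with no relevant item contribute 0 at every level.
    """
    if recall_levels is None:
        recall_levels = np.linspace(0.1, 1.0, 10)
    recall_levels = np.asarray(recall_levels, dtype=float)
    rankings = list(rankings)
    per_level = np.zeros((len(rankings), len(recall_levels)))
    for qi, ranked in enumerate(rankings):
        rel = ranked.relevance
        n_rel = sum(rel)
        if n_rel == 0:
            continue
        hits = 0
        prec, rec = [], []
        for rank, is_rel in enumerate(rel, start=1):
            if is_rel:
                hits += 1
                prec.append(hits / rank)
                rec.append(hits / n_rel)
        prec = np.asarray(prec)
        rec = np.asarray(rec)
        for li, level in enumerate(recall_levels):
            mask = rec >= level - 1e-12
            per_level[qi, li] = prec[mask].max() if mask.any() else 0.0
    return {
        "recall": recall_levels.tolist(),
        "precision": per_level.mean(axis=0).tolist(),
    }


def pairwise_measure(a, b, measure: str = "cosine") -> float:
    """Euclidean distance, Manhattan distance, or cosine similarity of two vectors."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"vector length mismatch: {a.shape} vs {b.shape}")
    if measure == "euclidean":
        return float(np.sqrt(np.sum((a - b) ** 2)))
    if measure == "manhattan":
        return float(np.sum(np.abs(a - b)))
    if measure == "cosine":
        na = float(np.linalg.norm(a))
        nb = float(np.linalg.norm(b))
        if na == 0.0 or nb == 0.0:
            raise ValueError("cosine similarity is undefined for a zero vector")
        return float(np.dot(a, b) / (na * nb))
    raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
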