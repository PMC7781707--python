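"""Nearest-neighbour retrieval over learned embeddings, plus evaluation.

The index is an exhaustive linear scan: at 32 dimensions and desk scale,
approximate structures buy nothing, and the exact scan keeps the ranking
deterministic (ties broken by record id).  Evaluation follows the two
protocols used for hierarchical radiograph retrieval: the total IRMA error
under the 1-NN rule, and mean average precision over full-depth rankings
with exact class identity as relevance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np

from .irma import CodeScheme, IRMACode, irma_error, parse_irma_code, total_irma_error
from .metrics import (
    MEASURES,
    SIMILARITY_MEASURES,
    EvaluationReport,
    RankedRetrieval,
    average_precision,
    classification_metrics,
    mean_average_precision,
    precision_at_recall_curve,
)

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingRecord:
    """One indexed image: id, 32-d embedding, hierarchical code, class label."""

    record_id: str
    embedding: np.ndarray
    code: IRMACode
    class_label: int

    def __post_init__(self) -> None:
        self.embedding = np.asarray(self.embedding, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.embedding)):
            raise ValueError(f"record {self.record_id}: embedding is not finite")


@dataclass
class FeatureIndex:
    """Searchable embedding collection with a fixed similarity measure."""

    records: list[EmbeddingRecord]
    measure: str = "cosine"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("cannot build an empty index")
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("record ids must be unique")
        dims = {r.embedding.shape[0] for r in self.records}
        if len(dims) != 1:
            raise ValueError(f"ragged embedding lengths: {sorted(dims)}")
        self._matrix = np.stack([r.embedding for r in self.records])

    def __len__(self) -> int:
        return len(self.records)

    @property
    def dim(self) -> int:
        return self._matrix.shape[1]


def build_index(records, measure: str = "cosine", provenance: dict | None = None) -> FeatureIndex:
    return FeatureIndex(records=list(records), measure=measure, provenance=provenance or {})


def _scores(index: FeatureIndex, probe: np.ndarray) -> np.ndarray:
    mat = index._matrix
    if index.measure == "euclidean":
        return np.sqrt(np.sum((mat - probe) ** 2, axis=1))
    if index.measure == "manhattan":
        return np.sum(np.abs(mat - probe), axis=1)
    norms = np.linalg.norm(mat, axis=1)
    pn = np.linalg.norm(probe)
    if pn == 0.0 or np.any(norms == 0.0):
        raise ValueError("cosine similarity is undefined for a zero vector")
    return (mat @ probe) / (norms * pn)


def query(index: FeatureIndex, probe, k: int, *,
          exclude_id: str | None = None, query_id: str = "query",
          relevant_class: int | None = None) -> RankedRetrieval:
    """Top-k records, best first, ties broken by ascending record id."""
    probe = np.asarray(probe, dtype=np.float64).ravel()
    if probe.shape[0] != index.dim:
        raise ValueError(f"probe length {probe.shape[0]} != index dimension {index.dim}")
    pool = index.records if exclude_id is None else [
        r for r in index.records if r.record_id != exclude_id
    ]
    if not 1 <= k <= len(pool):
        raise ValueError(f"k={k} out of range for index of size {len(pool)}")
    scores = _scores(index, probe)
    if exclude_id is not None:
        keep = [i for i, r in enumerate(index.records) if r.record_id != exclude_id]
    else:
        keep = range(len(index.records))
    reverse = index.measure in SIMILARITY_MEASURES
    ranked = sorted(
        ((float(scores[i]), index.records[i]) for i in keep),
        key=lambda t: (-t[0] if reverse else t[0], t[1].record_id),
    )[:k]
    entries = [
        (
            rec.record_id,
            score,
            (rec.class_label == relevant_class) if relevant_class is not None else False,
        )
        for score, rec in ranked
    ]
    return RankedRetrieval(query_id=query_id, entries=entries, measure=index.measure)


def nn_classify(index: FeatureIndex, probe, *, exclude_id: str | None = None):
    """1-NN rule: the query inherits the code and class of its best match."""
    top = query(index, probe, k=1, exclude_id=exclude_id)
    best_id = top.entries[0][0]
    rec = next(r for r in index.records if r.record_id == best_id)
    return rec.code, rec.class_label


def evaluate(index: FeatureIndex, queries, scheme: CodeScheme = CodeScheme(), *,
             predictions=None, drop_self: bool = False,
             rank_cutoff: int | None = None) -> EvaluationReport:
    """Score retrieval (1-NN IRMA error, mAP) and optionally classification.

    ``queries`` is a list of ``(record_id, probe, true_code, true_class)``.
    Relevance is exact class identity; rankings run to full index depth
    unless ``rank_cutoff`` is given.  ``predictions`` may supply per-query
    predicted class labels (e.g. softmax argmax) together with a mapping
    class -> code, as ``(labels, class_to_code)``; classification AP/AR/F1
    and IRMA error are then reported as well.  ``drop_self`` excludes the
    query's own record id from its ranking (leave-one-out protocol).
    """
    queries = list(queries)
    if not queries:
        raise ValueError("cannot evaluate an empty query set")
    rankings = []
    pairs = []
    for qid, probe, true_code, true_class in queries:
        exclude = qid if drop_self else None
        depth = len(index) - (1 if drop_self else 0)
        if rank_cutoff is not None:
            depth = min(depth, rank_cutoff)
        ranked = query(
            index, probe, k=depth, exclude_id=exclude,
            query_id=qid, relevant_class=true_class,
        )
        rankings.append(ranked)
        code, _ = nn_classify(index, probe, exclude_id=exclude)
        pairs.append((true_code, code))
    per_image = [irma_error(c, p, scheme) for c, p in pairs]
    total = float(sum(per_image))
    map_score = mean_average_precision(rankings)
    per_query_ap = [average_precision(r) for r in rankings]
    report = EvaluationReport(
        total_irma_error=total,
        per_image_errors=per_image,
        map_score=map_score,
        per_query_ap=per_query_ap,
        precision_recall_curve=precision_at_recall_curve(rankings),
    )
    if predictions is not None:
        labels, class_to_code = predictions
        labels = np.asarray(labels)
        true_classes = np.asarray([q[3] for q in queries])
        classes = np.unique(np.concatenate([true_classes, labels]))
        lut = {c: i for i, c in enumerate(classes)}
        confusion = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(true_classes, labels):
            confusion[lut[t], lut[p]] += 1
        ap, ar, f1 = classification_metrics(confusion)
        cls_pairs = [
            (q[2], class_to_code[p]) for q, p in zip(queries, labels)
        ]
        report.ap, report.ar, report.f1 = ap, ar, f1
        report.classification_irma_error = total_irma_error(cls_pairs, scheme)
    return report


def compare_indexes(index_a: FeatureIndex, index_b: FeatureIndex, queries_a, queries_b,
                    scheme: CodeScheme = CodeScheme(), labels=("with_emd", "without_emd")):
    """Side-by-side evaluation rows for two feature pipelines."""
    rows = {}
    for label, index, qs in zip(labels, (index_a, index_b), (queries_a, queries_b)):
        report = evaluate(index, qs, scheme)
        rows[label] = {"total_irma_error": report.total_irma_error, "mAP": report.map_score}
    return rows


def save_index(index: FeatureIndex, path) -> None:
    """Persist the index as HDF5 (embeddings, ids, codes, labels, attrs)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("embeddings", data=index._matrix)
        str_dt = h5py.string_dtype(encoding="utf-8")
        fh.create_dataset(
            "record_ids", data=[r.record_id for r in index.records], dtype=str_dt
        )
        fh.create_dataset(
            "codes", data=[str(r.code) for r in index.records], dtype=str_dt
        )
        fh.create_dataset(
            "class_labels", data=[r.class_label for r in index.records], dtype="i8"
        )
        fh.attrs["measure"] = index.measure
        for key, value in index.provenance.items():
            fh.attrs[f"provenance_{key}"] = value


def load_index(path) -> FeatureIndex:
    with h5py.File(path, "r") as fh:
        embeddings = fh["embeddings"][...]
        ids = [s.decode() if isinstance(s, bytes) else s for s in fh["record_ids"][...]]
        codes = [s.decode() if isinstance(s, bytes) else s for s in fh["codes"][...]]
        labels = fh["class_labels"][...]
        measure = fh.attrs["measure"]
        provenance = {
            key[len("provenance_"):]: fh.attrs[key]
            for key in fh.attrs
            if key.startswith("provenance_")
        }
    records = [
        EmbeddingRecord(
            record_id=i, embedding=e, code=parse_irma_code(c), class_label=int(l)
        )
        for i, e, c, l in zip(ids, embeddings, codes, labels)
    ]
    return build_index(records, measure=measure, provenance=provenance)
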