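"""Feature index, nearest-neighbour queries, and the evaluation harness."""

import numpy as np
import pytest

from emdir.irma import CodeScheme, irma_error, parse_irma_code, total_irma_error
from emdir.metrics import average_precision, pairwise_measure
from emdir.retrieval import (
    EmbeddingRecord,
    build_index,
    evaluate,
    load_index,
    nn_classify,
    query,
    save_index,
)

CODES = [
    "1121-127-700-500",
    "1121-127-700-400",
    "2221-227-800-600",
    "3331-327-900-700",
]


def make_records(rng, n=20, dim=8, clustered=False):
    centroids = rng.normal(size=(4, dim)) * 3.0
    records = []
    for i in range(n):
        cls = int(i % 4)
        emb = centroids[cls] + 0.01 * rng.normal(size=dim) if clustered else rng.normal(size=dim)
        records.append(
            EmbeddingRecord(
                record_id=f"rec{i:03d}",
                embedding=emb,
                code=parse_irma_code(CODES[cls]),
                class_label=cls,
            )
        )
    return records


class TestBuildIndex:
    def test_size_and_dim(self, rng):
        index = build_index(make_records(rng), measure="cosine")
        assert len(index) == 20
        assert index.dim == 8

    def test_duplicate_ids_rejected(self, rng):
        records = make_records(rng)
        records[1].record_id = records[0].record_id
        with pytest.raises(ValueError, match="unique"):
            build_index(records)

    def test_ragged_embeddings_rejected(self, rng):
        records = make_records(rng)
        records[2].embedding = rng.normal(size=5)
        with pytest.raises(ValueError, match="ragged"):
            build_index(records)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_index([])


class TestQuery:
    @pytest.mark.parametrize("measure", ["euclidean", "manhattan", "cosine"])
    def test_matches_exhaustive_pairwise_sort(self, rng, measure):
        records = make_records(rng, n=50)
        index = build_index(records, measure=measure)
        probe = rng.normal(size=8)
        ranked = query(index, probe, k=50)
        expected = sorted(
            ((pairwise_measure(probe, r.embedding, measure), r.record_id) for r in records),
            key=lambda t: (-t[0], t[1]) if measure == "cosine" else (t[0], t[1]),
        )
        assert [e[0] for e in ranked.entries] == [rid for _, rid in expected]
        assert [e[1] for e in ranked.entries] == pytest.approx([s for s, _ in expected])

    def test_stored_embedding_ranks_first_under_cosine(self, rng):
        records = make_records(rng)
        index = build_index(records, measure="cosine")
        ranked = query(index, records[7].embedding, k=3)
        assert ranked.entries[0][0] == records[7].record_id
        assert ranked.entries[0][1] == pytest.approx(1.0)

    def test_k_equal_to_index_size_is_a_permutation(self, rng):
        records = make_records(rng)
        ranked = query(build_index(records), rng.normal(size=8), k=len(records))
        assert sorted(e[0] for e in ranked.entries) == sorted(r.record_id for r in records)

    def test_dimension_and_k_validation(self, rng):
        index = build_index(make_records(rng))
        with pytest.raises(ValueError, match="probe length"):
            query(index, np.zeros(5), k=1)
        with pytest.raises(ValueError, match="out of range"):
            query(index, np.zeros(8), k=21)

    def test_insertion_order_invariance(self, rng):
        records = make_records(rng)
        probe = rng.normal(size=8)
        a = query(build_index(records), probe, k=10)
        shuffled = [records[i] for i in rng.permutation(len(records))]
        b = query(build_index(shuffled), probe, k=10)
        assert [e[0] for e in a.entries] == [e[0] for e in b.entries]

    def test_cosine_ranking_invariant_to_probe_rescaling(self, rng):
        index = build_index(make_records(rng), measure="cosine")
        probe = rng.normal(size=8)
        a = query(index, probe, k=10)
        b = query(index, 37.5 * probe, k=10)
        assert [e[0] for e in a.entries] == [e[0] for e in b.entries]


class TestNNClassify:
    def test_stored_embedding_returns_own_code(self, rng):
        records = make_records(rng)
        index = build_index(records, measure="cosine")
        code, cls = nn_classify(index, records[5].embedding)
        assert str(code) == str(records[5].code)
        assert cls == records[5].class_label

    def test_equidistant_tie_broken_by_record_id(self):
        shared = np.array([1.0, 0.0])
        records = [
            EmbeddingRecord("b", shared, parse_irma_code(CODES[0]), 0),
            EmbeddingRecord("a", shared, parse_irma_code(CODES[2]), 2),
        ]
        index = build_index(records, measure="euclidean")
        code, cls = nn_classify(index, shared)
        assert cls == 2  # record "a" sorts first

    def test_agrees_with_exhaustive_scan(self, rng):
        records = make_records(rng, n=30)
        index = build_index(records, measure="euclidean")
        for _ in range(10):
            probe = rng.normal(size=8)
            _, cls = nn_classify(index, probe)
            dists = [
                (pairwise_measure(probe, r.embedding, "euclidean"), r.record_id, r.class_label)
                for r in records
            ]
            assert cls == min(dists)[2]


class TestEvaluate:
    def test_self_queries_are_perfect(self, rng):
        # class-clustered embeddings, as a trained model produces
        records = make_records(rng, clustered=True)
        index = build_index(records, measure="cosine")
        queries = [
            (r.record_id, r.embedding, r.code, r.class_label) for r in records
        ]
        report = evaluate(index, queries)
        assert report.total_irma_error == pytest.approx(0.0)
        assert report.map_score == pytest.approx(1.0)

    def test_class_without_indexed_members_has_zero_ap(self, rng):
        records = make_records(rng, n=8)
        index = build_index(records)
        probe = rng.normal(size=8)
        report = evaluate(
            index, [("q0", probe, parse_irma_code("9999-999-999-999"), 99)]
        )
        assert report.per_query_ap == [0.0]

    def test_report_matches_first_principles_recomputation(self, rng):
        records = make_records(rng, n=40)
        index = build_index(records, measure="cosine")
        scheme = CodeScheme()
        queries = []
        for i in range(15):
            cls = int(i % 4)
            queries.append(
                (f"q{i}", rng.normal(size=8), parse_irma_code(CODES[cls]), cls)
            )
        report = evaluate(index, queries, scheme)

        expected_aps, expected_pairs = [], []
        for qid, probe, code, cls in queries:
            sims = sorted(
                (
                    (pairwise_measure(probe, r.embedding, "cosine"), r.record_id, r)
                    for r in records
                ),
                key=lambda t: (-t[0], t[1]),
            )
            rel = [r.class_label == cls for _, _, r in sims]
            hits, precs = 0, []
            for rank, flag in enumerate(rel, 1):
                if flag:
                    hits += 1
                    precs.append(hits / rank)
            expected_aps.append(sum(precs) / len(precs) if precs else 0.0)
            expected_pairs.append((code, sims[0][2].code))
        assert report.per_query_ap == pytest.approx(expected_aps)
        assert report.map_score == pytest.approx(np.mean(expected_aps))
        assert report.total_irma_error == pytest.approx(
            total_irma_error(expected_pairs, scheme)
        )

    def test_total_error_consistent_with_metrics_module(self, rng):
        records = make_records(rng, n=16)
        index = build_index(records, measure="euclidean")
        queries = [
            (f"q{i}", rng.normal(size=8), parse_irma_code(CODES[i % 4]), i % 4)
            for i in range(10)
        ]
        report = evaluate(index, queries)
        pairs = [
            (q[2], nn_classify(index, q[1])[0]) for q in queries
        ]
        assert report.total_irma_error == pytest.approx(total_irma_error(pairs))
        assert report.per_image_errors == pytest.approx(
            [irma_error(c, p) for c, p in pairs]
        )

    def test_drop_self_excludes_own_record(self, rng):
        records = make_records(rng, n=8)
        index = build_index(records, measure="cosine")
        r = records[0]
        ranked = query(index, r.embedding, k=7, exclude_id=r.record_id)
        assert r.record_id not in [e[0] for e in ranked.entries]

    def test_classification_predictions_reported(self, rng):
        records = make_records(rng, n=16)
        index = build_index(records)
        queries = [
            (f"q{i}", rng.normal(size=8), parse_irma_code(CODES[i % 4]), i % 4)
            for i in range(8)
        ]
        labels = [q[3] for q in queries]  # perfect classifier
        class_to_code = {i: parse_irma_code(CODES[i]) for i in range(4)}
        report = evaluate(index, queries, predictions=(labels, class_to_code))
        assert report.ap == report.ar == report.f1 == 1.0
        assert report.classification_irma_error == pytest.approx(0.0)

    def test_empty_queries_rejected(self, rng):
        index = build_index(make_records(rng))
        with pytest.raises(ValueError, match="empty"):
            evaluate(index, [])


def test_hdf5_round_trip(tmp_path, rng):
    records = make_records(rng)
    index = build_index(records, measure="manhattan", provenance={"model": "abc123"})
    path = tmp_path / "index.h5"
    save_index(index, path)
    loaded = load_index(path)
    assert loaded.measure == "manhattan"
    assert loaded.provenance["model"] == "abc123"
    assert len(loaded) == len(index)
    for a, b in zip(index.records, loaded.records):
        assert a.record_id == b.record_id
        np.testing.assert_array_equal(a.embedding, b.embedding)
        assert str(a.code) == str(b.code)
        assert a.class_label == b.class_label
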