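import itertools

import numpy as np
import pytest

from orientq.corpus import AuditCorpus, AuditRecord
from orientq.errors import ConfigError, StatementError
from orientq.statements import (
    ClusterAssignment,
    SentencePool,
    build_sentence_pool,
    cluster,
    extract_statements,
    reduce_dimensions,
    segment_sentences,
    select_k,
)
from tests.conftest import dense_embedding


def corpus_of(*texts):
    return AuditCorpus(
        [AuditRecord("i", f"r{k}", t) for k, t in enumerate(texts)]
    )


class TestSegmentation:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("A one. B two! C three?", ["A one", "B two", "C three"]),
            ("A one.. B two.", ["A one", "B two"]),
            ("光线充足。走廊安全。", ["光线充足", "走廊安全"]),
            ("first; second; third", ["first", "second", "third"]),
        ],
    )
    def test_terminal_punctuation_split(self, text, expected):
        out = segment_sentences(corpus_of(text))
        assert [s for s, _, _ in out] == expected

    def test_exact_duplicates_removed_within_record_only(self):
        out = segment_sentences(corpus_of("Same thing. Same thing.", "Same thing."))
        assert [s for s, _, _ in out] == ["Same thing", "Same thing"]
        assert [(i, r) for _, i, r in out] == [("i", "r0"), ("i", "r1")]

    def test_record_without_sentences_dropped_with_warning(self, caplog):
        corpus = AuditCorpus(
            [
                AuditRecord("i", "r0", "Real sentence."),
                AuditRecord("i", "r1", "... ; !"),
            ]
        )
        with caplog.at_level("WARNING"):
            out = segment_sentences(corpus)
        assert len(out) == 1
        assert "r1" in caplog.text


class TestPCA:
    def test_full_variance_target_keeps_rank_and_distances(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 4))
        red = reduce_dimensions(X, variance_target=1.0)
        assert red.n_components == 4
        d_orig = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        d_red = np.linalg.norm(red.X[:, None] - red.X[None, :], axis=2)
        assert np.allclose(d_orig, d_red, atol=1e-9)

    def test_collinear_points_need_one_component(self):
        direction = np.ones(5)
        X = np.outer([0.0, 1.0, 2.0], direction)
        red = reduce_dimensions(X, variance_target=0.9)
        assert red.n_components == 1

    def test_components_match_covariance_eigendecomposition(self):
        """Brute-force oracle: component variances equal covariance
        eigenvalues of a hand-entered 4-point set."""
        X = np.array([[2.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 3.0, 2.0], [3.0, 2.0, 1.0]])
        red = reduce_dimensions(X, variance_target=1.0)
        eig = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
        assert np.allclose(red.X.var(axis=0, ddof=1), eig[: red.n_components], atol=1e-9)

    def test_rank_zero_input_rejected(self):
        with pytest.raises(StatementError, match="rank-0"):
            reduce_dimensions(np.ones((5, 3)), variance_target=0.9)

    def test_sparse_and_dense_paths_agree(self):
        import scipy.sparse as sp

        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 6))
        X[:, [1, 4]] = 0.0  # zero columns are dropped on the sparse path
        a = reduce_dimensions(X, variance_target=0.95)
        b = reduce_dimensions(sp.csr_matrix(X), variance_target=0.95)
        assert a.n_components == b.n_components
        assert np.allclose(np.abs(a.X), np.abs(b.X), atol=1e-9)


class TestSelectK:
    def test_three_separated_gaussians_recovered(self):
        rng = np.random.default_rng(42)
        X = np.vstack([c + 0.05 * rng.normal(size=(30, 3)) for c in np.eye(3)])
        sel = select_k(X, range(2, 9), seed=0)
        assert sel.chosen_k == 3

    def test_duplicated_distinct_points(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        sel = select_k(X, [2, 3], seed=0)
        assert sel.chosen_k == 2
        assert sel.silhouette[0] == pytest.approx(1.0)
        assert sel.rank_table.valid.tolist() == [True, False]

    def test_chosen_k_is_first_minimum_of_joint_rank(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 2))
        sel = select_k(X, range(2, 7), seed=0)
        table = sel.rank_table.dropna(subset=["joint_rank"])
        best = table.loc[table.joint_rank.idxmin(), "K"]  # idxmin -> first min
        assert sel.chosen_k == best

    def test_grid_validation(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ConfigError):
            select_k(X, [3, 2], seed=0)
        with pytest.raises(ConfigError):
            select_k(X, [2, 10], seed=0)


class TestCluster:
    def test_k_equals_n_rows_zero_inertia(self):
        X = np.arange(12.0).reshape(6, 2)
        asg = cluster(X, 6, seed=0)
        assert len(set(asg.labels.tolist())) == 6
        d = np.linalg.norm(X - asg.centroids[asg.labels], axis=1)
        assert np.allclose(d, 0.0)

    def test_two_far_clusters_match_minimal_inertia_partition(self):
        """Brute-force oracle: enumerate all 2-partitions of 8 points."""
        rng = np.random.default_rng(5)
        X = np.vstack(
            [rng.normal(0, 0.2, size=(4, 2)), rng.normal(8, 0.2, size=(4, 2))]
        )
        best_inertia, best_split = np.inf, None
        for mask_bits in itertools.product([0, 1], repeat=8):
            mask = np.array(mask_bits, dtype=bool)
            if not mask.any() or mask.all():
                continue
            inertia = sum(
                np.sum((X[m] - X[m].mean(axis=0)) ** 2) for m in (mask, ~mask)
            )
            if inertia < best_inertia:
                best_inertia, best_split = inertia, mask
        asg = cluster(X, 2, seed=0)
        got = asg.labels == asg.labels[0]
        assert np.array_equal(got, best_split) or np.array_equal(got, ~best_split)

    def test_same_seed_identical_labels(self):
        X = np.random.default_rng(2).normal(size=(30, 3))
        a = cluster(X, 4, seed=9)
        b = cluster(X, 4, seed=9)
        assert np.array_equal(a.labels, b.labels)

    def test_k_above_n_rows_rejected(self):
        with pytest.raises(ConfigError):
            cluster(np.zeros((3, 2)), 4, seed=0)


def make_pool(texts, vectors):
    return SentencePool(
        sentences=[(t, "inst", f"r{k}") for k, t in enumerate(texts)],
        embedding=dense_embedding(vectors),
    )


class TestExtractStatements:
    def test_single_cluster_takes_closest_to_mean(self):
        """Brute-force oracle: distances to the centroid sorted by hand."""
        X = np.array([[0.0], [1.0], [2.0], [3.0], [10.0]])
        centroid = X.mean(axis=0, keepdims=True)  # 3.2
        order = np.argsort(np.abs(X[:, 0] - centroid[0, 0]), kind="stable")
        asg = ClusterAssignment(
            labels=np.zeros(5, dtype=int), centroids=centroid, K=1, X=X
        )
        pool = make_pool([f"s{i}" for i in range(5)], np.eye(5))  # all orthogonal
        out = extract_statements(asg, pool, per_cluster=3, dedup_threshold=0.99)
        assert [s.text for s in out.statements] == [f"s{i}" for i in order[:3]]

    def test_near_duplicates_keep_closer_to_centroid(self):
        X = np.array([[0.0], [0.1], [0.2], [0.9], [1.5]])
        asg = ClusterAssignment(
            labels=np.zeros(5, dtype=int), centroids=X.mean(0, keepdims=True), K=1, X=X
        )
        vectors = np.array(
            [[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [1.0, -1.0]]
        )
        pool = make_pool(["d1", "d2", "u1", "u2", "u3"], vectors)
        out = extract_statements(asg, pool, per_cluster=3, dedup_threshold=0.99)
        texts = [s.text for s in out.statements]
        # centroid is 0.54: ranking is u1 (0.34), u2 (0.36), d2 (0.44), d1, u3;
        # d1 duplicates d2 but sits farther from the centroid, so it drops
        assert texts == ["u1", "u2", "d2"]

    def test_zero_margin_point_excluded(self):
        # two clusters at -1 and +1; the point at 0 is exactly equidistant
        X = np.array([[-1.2], [-1.0], [-0.8], [0.0], [0.8], [1.0], [1.2]])
        labels = np.array([0, 0, 0, 0, 1, 1, 1])
        centroids = np.array([[-1.0], [1.0]])
        asg = ClusterAssignment(labels=labels, centroids=centroids, K=2, X=X)
        pool = make_pool([f"s{i}" for i in range(7)], np.eye(7))
        out = extract_statements(asg, pool, per_cluster=3, dedup_threshold=0.99)
        assert "s3" not in [s.text for s in out.statements]

    def test_exhausted_cluster_error_names_cluster(self):
        X = np.array([[0.0], [0.0], [5.0], [5.1], [5.2]])
        labels = np.array([0, 0, 1, 1, 1])
        centroids = np.array([[0.0], [5.1]])
        asg = ClusterAssignment(labels=labels, centroids=centroids, K=2, X=X)
        pool = make_pool(["a", "b", "c", "d", "e"], np.eye(5))
        with pytest.raises(StatementError, match="cluster 0"):
            extract_statements(asg, pool, per_cluster=3, dedup_threshold=0.99)

    def test_output_size_is_k_times_per_cluster(self):
        rng = np.random.default_rng(0)
        X = np.vstack([c + 0.1 * rng.normal(size=(10, 2)) for c in 5 * np.eye(2)[: 2]])
        X = np.vstack([X, 10 + 0.1 * rng.normal(size=(10, 2))])
        asg = cluster(X, 3, seed=0)
        pool = make_pool(
            [f"s{i}" for i in range(30)], rng.normal(size=(30, 8))
        )
        out = extract_statements(asg, pool, per_cluster=3, dedup_threshold=0.99)
        assert len(out) == 9


def test_reduce_then_cluster_equals_cluster_on_raw_full_rank():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(40, 3))
    red = reduce_dimensions(X, variance_target=1.0)
    a = cluster(red.X, 4, seed=0)
    b = cluster(X, 4, seed=0)
    # same partition up to label permutation
    relabel = {}
    for la, lb in zip(a.labels, b.labels):
        relabel.setdefault(la, lb)
        assert relabel[la] == lb


def test_build_sentence_pool_alignment(small_corpus):
    pool = build_sentence_pool(small_corpus)
    assert pool.embedding.n_units == len(pool.sentences)
    assert all(t for t, _, _ in pool.sentences)
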