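"""Term-document matrix, truncated SVD space, fold-in and ranking."""

import numpy as np
import pytest
import scipy.sparse as sp

import literank as lr
from literank.engine import load_model, save_model


def _dict(words):
    return lr.Dictionary(words=tuple(sorted(words)))


def _mini_collection(doc_texts_by_factor):
    factors, docs = [], {}
    for name, texts in doc_texts_by_factor.items():
        factors.append(lr.FactorSpec(name=name, query_terms=(name,)))
        docs[name] = [
            lr.CitationRecord(pmid=f"{name}{i}", title=t)
            for i, t in enumerate(texts)
        ]
    return lr.DocumentCollection(factors=factors, documents_of=docs)


class TestCountTerms:
    def test_basic_counts(self):
        d = _dict(["risk", "stroke"])
        counts = lr.count_terms("stroke stroke risk", d)
        assert counts[d.index_of["stroke"]] == 2
        assert counts[d.index_of["risk"]] == 1

    def test_out_of_dictionary_ignored(self):
        d = _dict(["stroke"])
        assert lr.count_terms("completely unrelated words", d).sum() == 0

    def test_matches_naive_scan_oracle(self):
        rng = np.random.default_rng(3)
        words = [f"w{i:02d}" for i in range(20)]
        d = _dict(words)
        text = " ".join(rng.choice(words + ["zzz"], size=200))
        counts = lr.count_terms(text, d)
        naive = {w: 0 for w in words}
        for tok in text.split():
            if tok in naive:
                naive[tok] += 1
        for w in words:
            assert counts[d.index_of[w]] == naive[w]


class TestBuildMatrix:
    def test_identity_weighting_is_raw_counts(self):
        coll = _mini_collection({"f1": ["aaa"], "f2": ["bbb bbb"]})
        d = _dict(["aaa", "bbb"])
        m = lr.build_matrix(coll, d, weighting="none")
        assert np.allclose(m.values.toarray(), [[1, 0], [0, 2]])

    def test_log_entropy_matches_hand_computation(self):
        # counts: term aaa in doc1 only (c=1); term bbb in doc2 only (c=2)
        coll = _mini_collection({"f1": ["aaa"], "f2": ["bbb bbb"]})
        d = _dict(["aaa", "bbb"])
        m = lr.build_matrix(coll, d, weighting="log-entropy")
        # each term occurs in one doc: p=1, entropy term 0, g = 1 + 0 = 1
        expected = np.array([[np.log(2), 0], [0, np.log(3)]])
        assert np.allclose(m.values.toarray(), expected)

    def test_log_entropy_split_term(self):
        # term aaa occurs once in each of two docs: p=1/2 each,
        # g = 1 + 2*(0.5*ln 0.5)/ln 2 = 0
        coll = _mini_collection({"f1": ["aaa"], "f2": ["aaa bbb"]})
        d = _dict(["aaa", "bbb"])
        m = lr.build_matrix(coll, d, weighting="log-entropy")
        assert np.allclose(m.values.toarray()[d.index_of["aaa"]], [0, 0])

    def test_nonzero_pattern_matches_count_oracle(self, small_space):
        collection, _, dictionary, matrix, _ = small_space
        col = 0
        for factor in collection.factors:
            for rec in collection.documents_of[factor.name]:
                counts = lr.count_terms(lr.document_text(rec), dictionary)
                observed = matrix.values[:, col].toarray().ravel()
                assert np.array_equal(observed != 0, counts != 0)
                col += 1

    def test_disjoint_vocabulary_rejected(self):
        coll = _mini_collection({"f1": ["xxx"]})
        with pytest.raises(lr.InputError):
            lr.build_matrix(coll, _dict(["unrelated"]), weighting="none")


def _space_from_dense(dense, weighting="none", k=None):
    n_terms, n_docs = dense.shape
    words = tuple(f"w{i:03d}" for i in range(n_terms))
    matrix = lr.TermDocMatrix(
        dictionary=lr.Dictionary(words=words),
        doc_ids=[("f", j) for j in range(n_docs)],
        values=sp.csr_matrix(dense.astype(float)),
        weighting=weighting,
        global_weights=np.ones(n_terms),
    )
    return matrix, lr.decompose(matrix, k=k)


class TestDecompose:
    def test_diagonal_singular_values(self):
        _, space = _space_from_dense(np.diag([3.0, 1.0]), k=2)
        assert np.allclose(space.singular_values, [3.0, 1.0])

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(5)
        A = rng.random((8, 6))
        _, space = _space_from_dense(A, k=6)
        recon = space.term_basis @ np.diag(space.singular_values) @ (
            space.doc_vectors / space.singular_values
        ).T
        assert np.linalg.norm(recon - A) / np.linalg.norm(A) < 1e-8

    def test_truncation_error_matches_dense_oracle(self):
        rng = np.random.default_rng(7)
        A = rng.random((20, 30))
        _, space = _space_from_dense(A, k=5)
        recon = space.term_basis @ (space.doc_vectors.T)
        # oracle: dense full SVD truncated to 5
        U, s, Vt = np.linalg.svd(A)
        oracle = (U[:, :5] * s[:5]) @ Vt[:5]
        assert np.linalg.norm(recon - A) == pytest.approx(
            np.linalg.norm(oracle - A), rel=1e-10
        )

    def test_orthonormal_basis_and_sorted_values(self):
        rng = np.random.default_rng(9)
        _, space = _space_from_dense(rng.random((15, 10)), k=7)
        gram = space.term_basis.T @ space.term_basis
        assert np.allclose(gram, np.eye(7), atol=1e-8)
        assert np.all(np.diff(space.singular_values) <= 1e-12)
        assert np.all(space.singular_values > 0)

    def test_k_above_rank_rejected_with_maximum(self):
        A = np.outer([1.0, 2.0, 3.0], [1.0, 1.0])  # rank 1
        with pytest.raises(lr.InputError, match="rank 1"):
            _space_from_dense(A, k=2)

    def test_auto_k_fraction(self):
        _, space = _space_from_dense(np.diag([10.0, 1.0, 1.0]))
        # 10^2/(10^2+1+1) > 0.8 already
        assert space.k == 1


class TestFoldIn:
    def test_document_text_reproduces_coordinates_at_full_rank(self, small_space):
        collection, _, dictionary, matrix, _ = small_space
        rank = np.linalg.matrix_rank(matrix.values.toarray())
        full = lr.decompose(matrix, k=rank)
        rec = collection.documents_of[collection.factor_names[0]][0]
        q = lr.fold_in(lr.document_text(rec), dictionary, full)
        assert np.allclose(q, full.doc_vectors[0], atol=1e-6)

    def test_single_word_query_proportional_to_basis_row(self, small_space):
        _, _, dictionary, _, space = small_space
        word = space.dictionary.words[0]
        q = lr.fold_in(word, dictionary, space)
        row = space.term_basis[space.dictionary.index_of[word]]
        # weighting scales the whole vector; direction matches the basis row
        cosim = np.dot(q, row) / (np.linalg.norm(q) * np.linalg.norm(row))
        assert cosim == pytest.approx(1.0, abs=1e-10)

    def test_linearity_over_weighted_counts(self, small_space):
        """Multiword fold-in equals the weighted-count sum of word fold-ins."""
        _, _, dictionary, _, space = small_space
        w1, w2 = space.dictionary.words[0], space.dictionary.words[1]
        q = lr.fold_in(f"{w1} {w2} {w2}", dictionary, space)
        from literank.engine import count_terms, _weight_query_counts

        weighted = _weight_query_counts(
            count_terms(f"{w1} {w2} {w2}", dictionary), space
        )
        oracle = space.term_basis.T @ weighted
        assert np.allclose(q, oracle, atol=1e-12)

    def test_unrecognized_query_rejected_with_tokens(self, small_space):
        _, _, dictionary, _, space = small_space
        with pytest.raises(lr.QueryError) as err:
            lr.fold_in("xyzzy plugh", dictionary, space)
        assert "xyzzy" in err.value.unrecognized


class TestCosine:
    def test_self_similarity(self):
        v = np.array([0.3, -1.2, 4.0])
        assert lr.cosine(v, v) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert lr.cosine(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_closed_form(self):
        assert lr.cosine(np.array([1.0, 1.0]), np.array([1.0, 0.0])) == pytest.approx(
            np.sqrt(2) / 2, abs=1e-4
        )

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        u, v = rng.normal(size=5), rng.normal(size=5)
        assert lr.cosine(3.5 * u, 0.2 * v) == pytest.approx(lr.cosine(u, v))

    def test_zero_vector_undefined(self):
        with pytest.raises(lr.UndefinedScoreError):
            lr.cosine(np.zeros(3), np.ones(3))


class TestRankFactors:
    def test_planted_topic_factor_ranks_first(self, small_space):
        _, truth, dictionary, _, space = small_space
        topic_words = truth["topic_words"][0]
        result = lr.rank_factors(" ".join(topic_words[:3]), space, dictionary)
        top = result.scores[0][0]
        assert truth["topic_of_factor"][top] == 0

    def test_covers_all_factors_once_descending(self, small_space):
        collection, _, dictionary, _, space = small_space
        result = lr.rank_factors("t00w00", space, dictionary)
        assert sorted(result.factor_names) == sorted(collection.factor_names)
        scores = [s for _, s in result.scores]
        assert scores == sorted(scores, reverse=True)

    def test_matches_brute_force_cosine_loop(self, small_space):
        _, _, dictionary, _, space = small_space
        result = lr.rank_factors("t01w02 t01w03", space, dictionary)
        q = lr.fold_in("t01w02 t01w03", dictionary, space)
        for name, score in result.scores:
            v = space.factor_vectors[name]
            expected = float(np.dot(q, v) / (np.linalg.norm(q) * np.linalg.norm(v)))
            assert score == pytest.approx(expected, abs=1e-12)

    def test_document_order_permutation_invariance(self, small_config):
        collection, _ = lr.generate_planted_corpus(small_config)
        headings = lr.generate_mesh_fixture(30, seed=1, config=small_config)
        dictionary = lr.filter_vocabulary(lr.build_vocabulary(headings))

        def scores(coll):
            matrix = lr.build_matrix(coll, dictionary, weighting="log-entropy")
            space = lr.decompose(matrix, k=10)
            return dict(lr.rank_factors("t00w00 t00w01", space).scores)

        shuffled = lr.DocumentCollection(
            factors=list(reversed(collection.factors)),
            documents_of={
                name: list(reversed(docs))
                for name, docs in collection.documents_of.items()
            },
        )
        s1, s2 = scores(collection), scores(shuffled)
        for name in s1:
            assert s1[name] == pytest.approx(s2[name], abs=1e-10)


class TestFullRankEquivalence:
    def test_reduces_to_vector_space_model(self):
        """At k=rank with identity weighting, eigen-space cosine equals raw
        cosine for in-span queries, on random small corpora."""
        rng = np.random.default_rng(42)
        for trial in range(5):
            n_terms = int(rng.integers(10, 30))
            n_factors = int(rng.integers(3, 6))
            words = [f"w{i:02d}" for i in range(n_terms)]
            texts = {
                f"f{j}": [
                    " ".join(rng.choice(words, size=15))
                    for _ in range(int(rng.integers(2, 5)))
                ]
                for j in range(n_factors)
            }
            coll = _mini_collection(texts)
            d = _dict(words)
            matrix = lr.build_matrix(coll, d, weighting="none")
            rank = np.linalg.matrix_rank(matrix.values.toarray())
            space = lr.decompose(matrix, k=rank)
            # query = one document's raw text (guaranteed in-span)
            query = texts["f0"][0]
            result = lr.rank_factors(query, space, d)
            # raw vector-space oracle: normalized centroid of raw doc columns
            qv = lr.count_terms(query, d)
            dense = matrix.values.toarray()
            col = 0
            for name in coll.factor_names:
                cols = []
                for _ in coll.documents_of[name]:
                    cols.append(col)
                    col += 1
                centroid = dense[:, cols].mean(axis=1)
                expected = float(
                    np.dot(qv, centroid)
                    / (np.linalg.norm(qv) * np.linalg.norm(centroid))
                )
                assert result.score_of(name) == pytest.approx(expected, abs=1e-8)


def test_model_bundle_round_trip(tmp_path, small_space):
    _, _, dictionary, _, space = small_space
    save_model(space, tmp_path / "model")
    again = load_model(tmp_path / "model")
    assert again.k == space.k
    assert np.allclose(again.doc_vectors, space.doc_vectors)
    r1 = lr.rank_factors("t00w00", space, dictionary)
    r2 = lr.rank_factors("t00w00", again, dictionary)
    assert r1.factor_names == r2.factor_names
    assert [s for _, s in r1.scores] == pytest.approx(
        [s for _, s in r2.scores], abs=1e-9
    )
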