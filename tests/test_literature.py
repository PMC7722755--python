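"""Co-mention counting, Jaccard scoring, thresholding, TF-IDF."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msea.errors import EmptyCorpusError, NoValidThresholdError, UnknownEntityError
from msea.literature import (
    AssociationMatrix,
    MentionCorpus,
    associations_to_library,
    count_cooccurrence,
    jaccard_index,
    jaccard_matrix,
    select_threshold_by_taxonomy,
    tfidf_normalize,
    threshold_by_top_fraction,
)
from msea.simulate import PlantedCorpusSpec, make_mention_corpus, make_toy_taxonomy


def corpus_of(docs):
    corpus = MentionCorpus()
    for i, (microbes, genes) in enumerate(docs):
        corpus.add_document(f"d{i}", microbes, genes)
    return corpus


class TestCountCooccurrence:
    def test_single_document(self):
        mat = count_cooccurrence(corpus_of([({"m1"}, {"g1"})]))
        assert mat.co_counts[mat.microbe_idx("m1"), mat.gene_idx("G1")] == 1
        assert mat.microbe_doc_counts.tolist() == [1]
        assert mat.gene_doc_counts.tolist() == [1]

    def test_microbe_only_document_counts_toward_marginal(self):
        mat = count_cooccurrence(corpus_of([({"m1"}, {"g1"}), ({"m1"}, set())]))
        assert mat.co_counts[0, 0] == 1
        assert mat.microbe_doc_counts[mat.microbe_idx("m1")] == 2

    def test_empty_corpus_raises(self):
        with pytest.raises(EmptyCorpusError):
            count_cooccurrence(corpus_of([({"m1"}, set()), (set(), {"g1"})]))

    def test_matches_brute_force_double_loop(self):
        spec = PlantedCorpusSpec(
            n_docs=50, n_microbes=6, n_genes=5, background_rate=0.25,
            planted_pairs=((0, 0, 0.4),), seed=11,
        )
        corpus = make_mention_corpus(spec)
        mat = count_cooccurrence(corpus)
        for i, microbe in enumerate(mat.microbes):
            docs_m = {d for d, (ms, _) in corpus.documents.items() if microbe in ms}
            assert mat.microbe_doc_counts[i] == len(docs_m)
            for j, gene in enumerate(mat.genes):
                docs_g = {d for d, (_, gs) in corpus.documents.items() if gene in gs}
                assert mat.gene_doc_counts[j] == len(docs_g)
                assert mat.co_counts[i, j] == len(docs_m & docs_g)


def matrix_of(co, m_counts, g_counts, microbes=None, genes=None):
    co = np.asarray(co)
    microbes = microbes or [f"m{i}" for i in range(co.shape[0])]
    genes = genes or [f"g{j}" for j in range(co.shape[1])]
    return AssociationMatrix(microbes, genes, co, np.asarray(m_counts), np.asarray(g_counts))


class TestJaccard:
    def test_printed_ratio(self):
        mat = matrix_of([[2]], [4], [3])
        assert jaccard_index(mat, "m0", "g0") == pytest.approx(2 / 5)

    def test_identical_document_sets_score_one(self):
        mat = matrix_of([[7]], [7], [7])
        assert jaccard_index(mat, "m0", "g0") == 1.0

    def test_zero_overlap_and_zero_marginals(self):
        mat = matrix_of([[0, 0]], [5], [3, 0])
        assert jaccard_index(mat, "m0", "g0") == 0.0
        mat0 = matrix_of([[0]], [0], [0])
        assert jaccard_index(mat0, "m0", "g0") == 0.0

    def test_unknown_entity(self):
        mat = matrix_of([[1]], [1], [1])
        with pytest.raises(UnknownEntityError):
            jaccard_index(mat, "nope", "g0")

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_bounded_and_symmetric(self, co, extra_m, extra_g):
        m, g = co + extra_m, co + extra_g
        mat = matrix_of([[co]], [m], [g])
        mat_t = matrix_of([[co]], [g], [m])
        score = jaccard_index(mat, "m0", "g0")
        assert 0.0 <= score <= 1.0
        assert score == jaccard_index(mat_t, "m0", "g0")
        assert (score == 1.0) == (co == m == g and co > 0)


class TestThreshold:
    def test_top_pair_of_thousand(self):
        rng = np.random.default_rng(5)
        co = rng.permutation(1000).reshape(40, 25)
        mat = matrix_of(co, [1000] * 40, [1000] * 25)
        assoc = threshold_by_top_fraction(mat, 0.001)
        assert len(assoc.pairs) == 1
        i, j = np.unravel_index(co.argmax(), co.shape)
        assert assoc.pairs == {(f"m{i}", f"g{j}")}
        assert assoc.threshold == pytest.approx(jaccard_matrix(mat).max())

    def test_fraction_one_keeps_all_positive_pairs(self):
        mat = matrix_of([[3, 0], [0, 2]], [5, 5], [5, 5])
        assoc = threshold_by_top_fraction(mat, 1.0)
        assert assoc.pairs == {("m0", "g0"), ("m1", "g1")}

    def test_ties_at_cut_all_retained(self):
        mat = matrix_of([[5, 5, 1, 0]], [10], [10, 10, 10, 10])
        assoc = threshold_by_top_fraction(mat, 0.25)  # nominally 1 pair
        assert assoc.pairs == {("m0", "g0"), ("m0", "g1")}

    @pytest.mark.parametrize("fraction", [0, -0.1, 1.5])
    def test_invalid_fraction(self, fraction):
        mat = matrix_of([[1]], [1], [1])
        with pytest.raises(ValueError):
            threshold_by_top_fraction(mat, fraction)

    def test_monotone_in_fraction(self):
        rng = np.random.default_rng(3)
        co = rng.integers(0, 20, size=(8, 9))
        mat = matrix_of(co, [40] * 8, [40] * 9)
        previous = frozenset()
        for fraction in (0.05, 0.2, 0.5, 1.0):
            pairs = threshold_by_top_fraction(mat, fraction).pairs
            assert previous <= pairs
            previous = pairs


class TestAssociationsToLibrary:
    def test_shared_gene_groups_microbes(self):
        mat = matrix_of([[3], [2]], [5, 5], [5])
        assoc = threshold_by_top_fraction(mat, 1.0)
        lib = associations_to_library(assoc)
        assert lib["g0"].members == {"m0", "m1"}

    def test_per_gene_singletons(self):
        mat = matrix_of([[3, 2]], [5], [5, 5])
        lib = associations_to_library(threshold_by_top_fraction(mat, 1.0))
        assert len(lib) == 2
        assert all(len(ms) == 1 for ms in lib)

    def test_member_pairs_bijective_with_associations(self):
        rng = np.random.default_rng(9)
        co = rng.integers(0, 10, size=(6, 7))
        mat = matrix_of(co, [30] * 6, [30] * 7)
        assoc = threshold_by_top_fraction(mat, 0.3)
        lib = associations_to_library(assoc)
        rebuilt = {
            (m, gene) for gene, ms in lib.sets.items() for m in ms.members
        }
        assert rebuilt == set(assoc.pairs)


class TestTfidf:
    def test_hand_computed_3x2(self):
        mat = matrix_of([[2, 0], [1, 1], [0, 3]], [4, 4, 4], [4, 4])
        w = tfidf_normalize(mat)
        idf0 = np.log(3 / 2)  # gene g0 present in 2 of 3 microbes
        idf1 = np.log(3 / 2)
        expected = np.array(
            [[1.0 * idf0, 0.0], [0.5 * idf0, 0.5 * idf1], [0.0, 1.0 * idf1]]
        )
        np.testing.assert_allclose(w.to_numpy(), expected)

    def test_ubiquitous_gene_column_zero(self):
        mat = matrix_of([[1, 2], [3, 1]], [5, 5], [5, 5])
        w = tfidf_normalize(mat)
        assert (w["g0"] == 0).all()  # present in every microbe row

    def test_rare_gene_idf_log_n(self):
        mat = matrix_of([[1, 1], [0, 1], [0, 1]], [3, 3, 3], [3, 3])
        w = tfidf_normalize(mat)
        assert w.loc["m0", "g0"] == pytest.approx(0.5 * np.log(3))

    def test_identical_profiles_identical_rows(self):
        mat = matrix_of([[2, 4, 0], [2, 4, 0], [1, 0, 3]], [9, 9, 9], [9, 9, 9])
        w = tfidf_normalize(mat)
        np.testing.assert_allclose(w.iloc[0], w.iloc[1])

    def test_zero_row_stays_zero(self):
        mat = matrix_of([[0, 0], [1, 2]], [0, 5], [5, 5])
        assert (tfidf_normalize(mat).iloc[0] == 0).all()


class TestThresholdSelection:
    @staticmethod
    def genus_structured_inputs(seed=0):
        """Corpus whose co-mentions are planted only within genera."""
        tree = make_toy_taxonomy(n_phyla=2, genera_per_phylum=3, species_per_genus=3)
        leaves = sorted(tree.nodes[n].name for n in tree.leaves)
        corpus = MentionCorpus()
        rng = np.random.default_rng(seed)
        genes = [f"GENE{k}" for k in range(6)]
        # gene k is co-mentioned with every species of genus k, plus noise
        genus_of = {name: name.split(" ")[0] for name in leaves}
        genera = sorted({g for g in genus_of.values()})
        doc = 0
        for d in range(300):
            microbes, mentioned = set(), set()
            for k, genus in enumerate(genera):
                if rng.random() < 0.3:
                    members = [n for n in leaves if genus_of[n] == genus]
                    microbes.add(str(rng.choice(members)))
                    mentioned.add(genes[k])
            if rng.random() < 0.05:
                microbes.add(str(rng.choice(leaves)))
                mentioned.add(str(rng.choice(genes)))
            corpus.add_document(f"d{doc}", microbes, mentioned)
            doc += 1
        return corpus, tree

    def test_planted_fraction_maximizes_statistic(self):
        corpus, tree = self.genus_structured_inputs()
        matrix = count_cooccurrence(corpus)
        # 18 planted pairs (6 genes x 3 species) out of 18 x 6 = 108
        best, stats = select_threshold_by_taxonomy(
            matrix, tree, candidates=[18 / 108, 0.5, 1.0]
        )
        assert best == pytest.approx(18 / 108)
        assert stats[best] > stats[0.5]
        # at fraction 1.0 every microbe keeps every gene: degenerate, skipped
        assert np.isnan(stats[1.0])

    def test_selection_is_deterministic(self):
        corpus, tree = self.genus_structured_inputs()
        matrix = count_cooccurrence(corpus)
        best1, stats1 = select_threshold_by_taxonomy(matrix, tree, candidates=[0.2, 0.5])
        best2, stats2 = select_threshold_by_taxonomy(matrix, tree, candidates=[0.2, 0.5])
        assert best1 == best2
        assert stats1 == stats2

    def test_noise_corpus_statistic_near_zero(self):
        tree = make_toy_taxonomy(n_phyla=4, genera_per_phylum=3, species_per_genus=3)
        leaves = sorted(tree.nodes[n].name for n in tree.leaves)  # 36 -> 630 pairs
        rng = np.random.default_rng(21)
        corpus = MentionCorpus()
        genes = [f"GENE{k}" for k in range(20)]
        for d in range(400):
            microbes = {m for m in leaves if rng.random() < 0.05}
            mentioned = {g for g in genes if rng.random() < 0.05}
            corpus.add_document(f"d{d}", microbes, mentioned)
        matrix = count_cooccurrence(corpus)
        _, stats = select_threshold_by_taxonomy(matrix, tree, candidates=[0.5, 1.0])
        rho = stats[1.0]
        assert np.isfinite(rho) and abs(rho) < 0.1

    def test_all_degenerate_raises(self):
        mat = matrix_of([[0, 0], [0, 0]], [3, 3], [3, 3],
                        microbes=["Lactobacillus reuteri", "Clostridium difficile"])
        tree = make_toy_taxonomy(1, 2, 2)
        with pytest.raises(NoValidThresholdError):
            select_threshold_by_taxonomy(mat, tree, candidates=[0.5, 1.0])


def test_planted_pair_exceeds_null_percentile_over_seeds():
    """A pair co-mentioned in 20% of docs beats the 99th percentile of
    off-pair Jaccard scores in >= 95 of 100 seeds (200 docs, 10x10 grid,
    1% background)."""
    successes = 0
    for seed in range(100):
        spec = PlantedCorpusSpec(
            n_docs=200, n_microbes=10, n_genes=10, background_rate=0.01,
            planted_pairs=((0, 0, 0.2),), seed=seed,
        )
        corpus = make_mention_corpus(spec)
        try:
            mat = count_cooccurrence(corpus)
        except EmptyCorpusError:
            continue
        J = jaccard_matrix(mat)
        try:
            i = mat.microbe_idx("M0001")
            j = mat.gene_idx("G0001")
        except UnknownEntityError:
            continue
        planted_score = J[i, j]
        off = np.delete(J.ravel(), i * J.shape[1] + j)
        if planted_score > np.percentile(off, 99):
            successes += 1
    assert successes >= 95
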