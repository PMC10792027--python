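"""Heterogeneous graph construction, edge weights, node features, sampling."""

import math

import numpy as np
import pytest

from conftest import (
    brute_force_counts,
    brute_force_pmi,
    brute_force_tfidf,
    random_corpus,
)

from motifms.hetero_graph import (
    MOL,
    MOTIF,
    CooccurrenceCounts,
    SamplerConfig,
    build_hetero_graph,
    count_occurrences,
    node_features,
    pmi,
    sample_subgraph,
    tfidf,
)
from motifms.molio import parse_smiles
from motifms.motif_vocab import MotifVocabulary, build_vocabulary


@pytest.fixture(scope="module")
def toy_vocab(worked_corpus):
    return build_vocabulary(worked_corpus, K=2)  # ["CC", "CCO"]


def _manual_counts(M, N, N_pair, C):
    return CooccurrenceCounts(M=M, N=N, N_pair=N_pair, C=C)


class TestCountOccurrences:
    def test_worked_example(self, toy_vocab):
        corpus = [parse_smiles("CCO"), parse_smiles("CCC")]
        counts = count_occurrences(corpus, toy_vocab)
        assert counts.M == 2
        assert counts.N == {"CCO": 1, "CC": 1}
        assert counts.C == {("CCO", 0): 1, ("CC", 1): 1}

    def test_motif_in_all_molecules(self, toy_vocab):
        corpus = [parse_smiles("CCO")] * 3
        counts = count_occurrences(corpus, toy_vocab)
        assert counts.N["CCO"] == counts.M == 3

    def test_empty_corpus_rejected(self, toy_vocab):
        with pytest.raises(ValueError):
            count_occurrences([], toy_vocab)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_recount(self, seed):
        rng = np.random.default_rng(seed)
        corpus = random_corpus(rng, 20)
        vocab = build_vocabulary(corpus, K=8)
        counts = count_occurrences(corpus, vocab)
        M, N, N_pair, C = brute_force_counts(corpus, vocab)
        assert counts.M == M
        assert counts.N == N
        assert counts.N_pair == N_pair
        assert counts.C == C


class TestPMI:
    def setup_method(self):
        self.vocab = MotifVocabulary(motifs=["CC", "CCO"],
                                     counts={"CC": 1, "CCO": 1}, K=2)

    def test_independent_motifs_give_no_edge(self):
        counts = _manual_counts(4, {"CC": 2, "CCO": 2}, {("CC", "CCO"): 1}, {})
        assert pmi("CC", "CCO", counts, self.vocab) == 0.0

    def test_positive_association(self):
        counts = _manual_counts(4, {"CC": 2, "CCO": 2}, {("CC", "CCO"): 2}, {})
        assert pmi("CC", "CCO", counts, self.vocab) == pytest.approx(math.log(2))

    def test_no_cooccurrence_no_edge(self):
        counts = _manual_counts(4, {"CC": 2, "CCO": 2}, {}, {})
        assert pmi("CC", "CCO", counts, self.vocab) == 0.0

    def test_unknown_motif_rejected(self):
        counts = _manual_counts(4, {"CC": 2}, {}, {})
        with pytest.raises(KeyError):
            pmi("CC", "NN", counts, self.vocab)


class TestTFIDF:
    def test_worked_value(self):
        counts = _manual_counts(4, {"CC": 2}, {}, {("CC", 0): 2})
        assert tfidf("CC", 0, counts) == pytest.approx(2 * (math.log(5 / 3) + 1), abs=1e-10)

    def test_ubiquitous_motif(self):
        counts = _manual_counts(4, {"CC": 4}, {}, {("CC", 0): 1})
        assert tfidf("CC", 0, counts) == pytest.approx(1.0)

    def test_monotone_in_count(self):
        values = [
            tfidf("CC", 0, _manual_counts(4, {"CC": 2}, {}, {("CC", 0): c}))
            for c in (1, 2, 3)
        ]
        assert values[0] < values[1] < values[2]

    def test_absent_motif_no_edge(self):
        counts = _manual_counts(4, {"CC": 2}, {}, {})
        assert tfidf("CC", 0, counts) == 0.0


class TestBruteForceFormulaOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_pmi_tfidf_match_independent_recount(self, seed):
        """Both weight formulas agree with a from-scratch recount plus
        direct formula evaluation to 1e-12."""
        rng = np.random.default_rng(1000 + seed)
        corpus = random_corpus(rng, int(rng.integers(4, 20)))
        vocab = build_vocabulary(corpus, K=8)
        counts = count_occurrences(corpus, vocab)
        M, N, N_pair, C = brute_force_counts(corpus, vocab)
        for i in vocab.motifs:
            for j in vocab.motifs:
                if i < j:
                    assert pmi(i, j, counts, vocab) == pytest.approx(
                        brute_force_pmi(i, j, M, N, N_pair), abs=1e-12)
            for jm in range(len(corpus)):
                assert tfidf(i, jm, counts) == pytest.approx(
                    brute_force_tfidf(i, jm, M, N, C), abs=1e-12)


class TestBuildGraph:
    @pytest.fixture()
    def graph(self, toy_vocab):
        corpus = [parse_smiles("CCO"), parse_smiles("CCC")]
        counts = count_occurrences(corpus, toy_vocab)
        return build_hetero_graph(corpus, toy_vocab, counts)

    def test_no_molecule_molecule_edges(self, graph):
        for node, nbrs in graph.adj.items():
            for nbr, _ in nbrs:
                assert not (node[0] == MOL and nbr[0] == MOL)

    def test_node_count(self, graph, toy_vocab):
        assert graph.num_nodes == 2 + len(toy_vocab)

    def test_edges_match_exhaustive_enumeration(self, graph, toy_vocab):
        corpus = [parse_smiles("CCO"), parse_smiles("CCC")]
        counts = count_occurrences(corpus, toy_vocab)
        expected = set()
        for a in range(len(toy_vocab)):
            for b in range(a + 1, len(toy_vocab)):
                w = pmi(toy_vocab.motifs[a], toy_vocab.motifs[b], counts, toy_vocab)
                if w > 0:
                    expected.add(((MOTIF, a), (MOTIF, b), round(w, 12)))
        for rank, label in enumerate(toy_vocab.motifs):
            for j in range(2):
                w = tfidf(label, j, counts)
                if w > 0:
                    expected.add(((MOTIF, rank), (MOL, j), round(w, 12)))
        actual = set()
        for node, nbrs in graph.adj.items():
            for nbr, w in nbrs:
                a, b = sorted((node, nbr))
                actual.add((a, b, round(w, 12)))
        # expected uses (motif, mol) orientation; normalize the same way
        expected = {(min(a, b), max(a, b), w) for a, b, w in expected}
        assert actual == expected

    def test_all_weights_positive(self, graph):
        for node, nbrs in graph.adj.items():
            for _, w in nbrs:
                assert w > 0

    def test_motif_motif_weights_symmetric(self):
        rng = np.random.default_rng(5)
        corpus = random_corpus(rng, 12)
        vocab = build_vocabulary(corpus, K=6)
        counts = count_occurrences(corpus, vocab)
        graph = build_hetero_graph(corpus, vocab, counts)
        w = {}
        for node, nbrs in graph.adj.items():
            for nbr, weight in nbrs:
                w[(node, nbr)] = weight
        for (a, b), weight in w.items():
            assert w[(b, a)] == weight


class TestNodeFeatures:
    def test_molecule_occurrence_vector(self, toy_vocab):
        corpus = [parse_smiles("CCO"), parse_smiles("CCC")]
        counts = count_occurrences(corpus, toy_vocab)
        v = node_features((MOL, 0), counts, toy_vocab, molecule=corpus[0])
        assert len(v) == len(toy_vocab) + 1
        assert v[toy_vocab.rank("CCO")] == 1
        assert v[toy_vocab.rank("CC")] == 0
        assert v[-1] == pytest.approx(corpus[0].exact_mass)

    def test_motif_weight_positive_even_when_isolated(self, toy_vocab):
        counts = _manual_counts(2, {"CC": 1, "CCO": 1}, {}, {})
        v = node_features((MOTIF, 0), counts, toy_vocab)
        assert v[-1] > 0
        # no co-occurrence with the other motif
        assert v[toy_vocab.rank("CCO")] == 0


@pytest.fixture(scope="module")
def sampler_graph():
    rng = np.random.default_rng(9)
    corpus = random_corpus(rng, 15)
    vocab = build_vocabulary(corpus, K=8)
    counts = count_occurrences(corpus, vocab)
    return build_hetero_graph(corpus, vocab, counts)


class TestSampler:
    @pytest.fixture()
    def graph(self, sampler_graph):
        return sampler_graph

    def test_budget_one_per_hop(self, graph):
        sub = sample_subgraph(graph, [(MOL, 0)], SamplerConfig(1, 1, 1), rng_seed=0)
        assert len(sub.nodes) <= 4
        assert (MOL, 0) in sub.nodes

    def test_first_hop_is_motif_only(self, graph):
        cfg = SamplerConfig(100, 100, 100)
        for j in range(5):
            seed_node = (MOL, j)
            first_hop = {n for n, _ in graph.neighbors(seed_node)}
            assert all(n[0] == MOTIF for n in first_hop)

    def test_seed_reproducibility(self, graph):
        cfg = SamplerConfig(2, 2, 2)
        a = sample_subgraph(graph, [(MOL, 1)], cfg, rng_seed=42)
        b = sample_subgraph(graph, [(MOL, 1)], cfg, rng_seed=42)
        assert a.nodes == b.nodes
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.X, b.X)

    def test_large_budget_recovers_full_3hop_neighborhood(self, graph):
        """With per-hop budgets above the max degree, sampling equals an
        unrestricted BFS truncated at 3 hops."""
        cfg = SamplerConfig(10**6, 10**6, 10**6)
        sub = sample_subgraph(graph, [(MOL, 2)], cfg, rng_seed=0)
        # independent oracle: plain BFS
        frontier, seen = {(MOL, 2)}, {(MOL, 2)}
        for _ in range(3):
            frontier = {n for f in frontier for n, _ in graph.neighbors(f)} - seen
            seen |= frontier
        assert set(sub.nodes) == seen

    def test_isolated_seed_yields_singleton(self, toy_vocab):
        corpus = [parse_smiles("CCO"), parse_smiles("c1ccncc1")]
        counts = count_occurrences(corpus, toy_vocab)
        graph = build_hetero_graph(corpus, toy_vocab, counts)
        sub = sample_subgraph(graph, [(MOL, 1)], SamplerConfig(4, 4, 4), rng_seed=0)
        assert sub.nodes == [(MOL, 1)]

    def test_non_molecule_seed_rejected(self, graph):
        with pytest.raises(ValueError):
            sample_subgraph(graph, [(MOTIF, 0)], SamplerConfig(1, 1, 1), rng_seed=0)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            SamplerConfig(0, 1, 1)
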