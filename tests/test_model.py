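"""Encoder and prediction-head behavior: invariances, determinism, shapes."""

import dataclasses

import numpy as np
import pytest

from conftest import random_corpus

from motifms.hetero_graph import (
    SamplerConfig,
    build_hetero_graph,
    count_occurrences,
    sample_subgraph,
)
from motifms.model import (
    ModelConfig,
    count_parameters,
    encode_molecule,
    encode_motif_graph,
    init_params,
    load_checkpoint,
    motif_spectrum_feature,
    predict_spectrum,
    save_checkpoint,
)
from motifms.molio import ATOM_FEATURE_DIM, MoleculeGraph, featurize_molecule, parse_smiles
from motifms.molio import FeaturizationConfig
from motifms.motif_vocab import build_vocabulary

CFG = ModelConfig(vocab_size=5, d_hidden=16, fingerprint_bits=64, m_max=120,
                  sampler=SamplerConfig(2, 2, 2))


@pytest.fixture(scope="module")
def params():
    return init_params(CFG, rng_seed=0)


def _graph(smiles):
    return featurize_molecule(parse_smiles(smiles), FeaturizationConfig(64))


def _permute(g: MoleculeGraph, perm):
    inv = np.argsort(perm)
    return MoleculeGraph(
        node_features=g.node_features[perm],
        edge_index=np.array([[inv[i], inv[j]] for i, j in g.edge_index]),
        edge_features=g.edge_features,
        fingerprint=g.fingerprint,
    )


class TestEncodeMolecule:
    def test_permutation_invariance(self, params):
        g = _graph("CC(N)C(=O)O")
        perm = np.random.default_rng(3).permutation(g.node_features.shape[0])
        a = encode_molecule(g, params, CFG).data
        b = encode_molecule(_permute(g, perm), params, CFG).data
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_single_atom_molecule(self, params):
        out = encode_molecule(_graph("C"), params, CFG).data
        assert out.shape == (CFG.d_hidden,)
        assert np.all(np.isfinite(out))

    def test_different_molecules_differ(self, params):
        a = encode_molecule(_graph("CCO"), params, CFG).data
        b = encode_molecule(_graph("c1ccccc1"), params, CFG).data
        assert not np.allclose(a, b)


@pytest.fixture(scope="module")
def hetero_setup():
    rng = np.random.default_rng(21)
    corpus = random_corpus(rng, 12)
    vocab = build_vocabulary(corpus, K=5)
    counts = count_occurrences(corpus, vocab)
    graph = build_hetero_graph(corpus, vocab, counts)
    cfg = dataclasses.replace(CFG, vocab_size=len(vocab))
    return corpus, vocab, graph, cfg, init_params(cfg, rng_seed=0)


class TestEncodeMotifGraph:
    def test_deterministic(self, hetero_setup):
        _, _, graph, cfg, params = hetero_setup
        sub = sample_subgraph(graph, [("mol", 0)], cfg.sampler, rng_seed=7)
        a = encode_motif_graph(sub, params, cfg).data
        b = encode_motif_graph(sub, params, cfg).data
        np.testing.assert_array_equal(a, b)

    def test_edge_weights_are_used(self, hetero_setup):
        _, _, graph, cfg, params = hetero_setup
        sub = sample_subgraph(graph, [("mol", 0)], cfg.sampler, rng_seed=7)
        a = encode_motif_graph(sub, params, cfg).data
        doubled = dataclasses.replace(sub, W=2.0 * sub.W)
        b = encode_motif_graph(doubled, params, cfg).data
        assert not np.allclose(a, b)

    def test_isolated_seed_uses_self_features(self, hetero_setup):
        _, _, graph, cfg, params = hetero_setup
        sub = sample_subgraph(graph, [("mol", 0)], cfg.sampler, rng_seed=7)
        lone = dataclasses.replace(sub, nodes=[sub.nodes[sub.seed_positions[0]]],
                                   X=sub.X[sub.seed_positions[0]][None, :],
                                   W=np.zeros((1, 1)), seed_positions=[0])
        out = encode_motif_graph(lone, params, cfg).data
        assert out.shape == (cfg.d_hidden,)
        assert np.all(np.isfinite(out))

    def test_missing_seed_rejected(self, hetero_setup):
        _, _, graph, cfg, params = hetero_setup
        sub = sample_subgraph(graph, [("mol", 0)], cfg.sampler, rng_seed=7)
        with pytest.raises(ValueError):
            encode_motif_graph(sub, params, cfg, seed_position=len(sub.nodes))


class TestPredictSpectrum:
    @pytest.fixture()
    def forward_args(self, hetero_setup):
        corpus, vocab, graph, cfg, params = hetero_setup
        sub = sample_subgraph(graph, [("mol", 0)], cfg.sampler, rng_seed=7)
        spec_feat = np.zeros(cfg.m_max)
        spec_feat[10] = 1.0
        return (_graph(corpus[0].smiles), sub, spec_feat), cfg, params

    def test_output_is_positive_and_sized(self, forward_args):
        args, cfg, params = forward_args
        out = predict_spectrum(*args, params, cfg).data
        assert out.shape == (cfg.m_max,)
        assert np.all(out > 0)  # softplus head

    def test_deterministic(self, forward_args):
        args, cfg, params = forward_args
        a = predict_spectrum(*args, params, cfg).data
        b = predict_spectrum(*args, params, cfg).data
        np.testing.assert_array_equal(a, b)

    def test_ablating_motif_spectra_changes_prediction(self, forward_args):
        args, cfg, params = forward_args
        full = predict_spectrum(*args, params, cfg).data
        ablated_cfg = dataclasses.replace(cfg, use_motif_spectra=False)
        ablated = predict_spectrum(*args, params, ablated_cfg).data
        assert not np.allclose(full, ablated)


class TestMotifSpectrumFeature:
    def test_weighted_sum_and_unit_norm(self):
        mat = np.array([[1.0, 0.0, 0.0], [0.0, 2.0, 0.0]])
        occ = np.array([2.0, 1.0])
        v = motif_spectrum_feature(occ, mat)
        np.testing.assert_allclose(v, np.array([2.0, 2.0, 0.0]) / np.sqrt(8))

    def test_no_motifs_gives_zero_profile(self):
        v = motif_spectrum_feature(np.zeros(2), np.ones((2, 4)))
        np.testing.assert_array_equal(v, np.zeros(4))


class TestParams:
    def test_same_seed_identical(self):
        a, b = init_params(CFG, 5), init_params(CFG, 5)
        for k in a.tensors:
            np.testing.assert_array_equal(a[k].data, b[k].data)

    def test_different_seeds_differ(self):
        a, b = init_params(CFG, 5), init_params(CFG, 6)
        assert any(not np.array_equal(a[k].data, b[k].data) for k in a.tensors)

    def test_count_constant_across_seeds(self):
        assert count_parameters(init_params(CFG, 1)) == count_parameters(init_params(CFG, 2))

    def test_count_monotone_in_width(self):
        wide = dataclasses.replace(CFG, d_hidden=32)
        assert count_parameters(init_params(wide, 0)) > count_parameters(init_params(CFG, 0))

    def test_count_matches_hand_arithmetic(self):
        """Tiny config: sum every declared layer shape by hand."""
        cfg = ModelConfig(vocab_size=3, d_hidden=4, fingerprint_bits=64, m_max=50)
        d, F, V, M = 4, 64, 3, 50
        expected = 0
        expected += (ATOM_FEATURE_DIM * d + d) + 2 * (d * d + d)  # 3 GCN layers
        expected += F * d + d  # fingerprint projection
        expected += (2 * d) * d + d  # molecule readout
        expected += (V + 1) * d + d + d * d + d  # 2-layer input MLP
        expected += 3 * 2 * (d * d + d)  # 3 GIN layers, 2 linears each
        expected += M * d + d  # motif-spectrum projection
        expected += 1  # motif-spectrum output-skip gate
        expected += (3 * d) * (2 * d) + 2 * d  # head layer 0
        expected += (2 * d) * (2 * d) + 2 * d  # head layer 1
        expected += (2 * d) * M + M  # output layer
        assert count_parameters(init_params(cfg, 0)) == expected


class TestCheckpoint:
    def test_round_trip(self, tmp_path, params):
        motifs = ["CC", "CCO", "CO", "CN", "CCC"]
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, params, CFG, motifs)
        loaded, cfg = load_checkpoint(path, motifs)
        assert cfg == CFG
        for k in params.tensors:
            np.testing.assert_array_equal(loaded[k].data, params[k].data)

    def test_vocab_mismatch_refused(self, tmp_path, params):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, params, CFG, ["CC", "CCO"])
        with pytest.raises(ValueError, match="vocabulary"):
            load_checkpoint(path, ["CC", "OO"])
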