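"""The two-encoder spectrum predictor.

A molecule is encoded twice: (i) a 3-layer graph convolutional network over
its atom graph (degree-normalized neighbor averaging, learned linear
transforms), mean-pooled and fused with a projected topological fingerprint;
(ii) a 3-layer graph isomorphism network over a sampled neighborhood of the
heterogeneous molecule-motif graph (sum aggregation, messages scaled by the
PMI / TF-IDF edge weights, 2-layer MLP input embedding).  Both embeddings
are concatenated together with a projection of the molecule's
occurrence-weighted motif-spectrum profile, and a 2-hidden-layer MLP head
emits the binned intensity vector through a softplus rectification (strictly
positive, so the cosine objective is always defined).  Because the
motif-spectrum profile already lives on the output m/z grid, it also enters
the output layer directly through a learned scalar gate; the output bias
starts low so the softplus baseline is near zero for the sparse spectra.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor
from .hetero_graph import SampledSubgraph, SamplerConfig
from .molio import ATOM_FEATURE_DIM, DEFAULT_M_MAX, MoleculeGraph

#: fixed divisor applied to the molecular-weight feature column so it is
#: commensurate with the occurrence counts
_WEIGHT_SCALE = 100.0


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Layer counts default to the 3 + 3 encoder depths and the 2-layer input
    embedding; ``vocab_size`` must match the vocabulary the heterogeneous
    graph was built with.
    """

    vocab_size: int
    d_hidden: int = 256
    n_layers_mol: int = 3
    n_layers_motif: int = 3
    head_hidden_layers: int = 2
    input_mlp_layers: int = 2
    m_max: int = DEFAULT_M_MAX
    fingerprint_bits: int = 2048
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    dropout: float = 0.0
    use_motif_spectra: bool = True

    def __post_init__(self):
        if min(self.d_hidden, self.vocab_size, self.m_max) < 1:
            raise ValueError("all dimensions must be >= 1")


class ModelParams:
    """All trainable tensors, keyed by name."""

    def __init__(self, tensors: dict):
        self.tensors = tensors

    def __getitem__(self, name: str) -> Tensor:
        return self.tensors[name]

    def values(self):
        return self.tensors.values()

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.tensors.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, v in state.items():
            self.tensors[k].data = np.asarray(v, dtype=float)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(cfg: ModelConfig, rng_seed: int = 0) -> ModelParams:
    """Fan-in-scaled (Glorot) initialization, reproducible per seed."""
    rng = np.random.default_rng(rng_seed)
    d = cfg.d_hidden
    t: dict = {}

    def linear(name, fan_in, fan_out):
        t[f"{name}.W"] = Tensor(_glorot(rng, fan_in, fan_out), requires_grad=True)
        t[f"{name}.b"] = Tensor(np.zeros(fan_out), requires_grad=True)

    for layer in range(cfg.n_layers_mol):
        linear(f"gcn{layer}", ATOM_FEATURE_DIM if layer == 0 else d, d)
    linear("fp_proj", cfg.fingerprint_bits, d)
    linear("mol_readout", 2 * d, d)

    dims = [cfg.vocab_size + 1] + [d] * cfg.input_mlp_layers
    for layer in range(cfg.input_mlp_layers):
        linear(f"motif_in{layer}", dims[layer], dims[layer + 1])
    for layer in range(cfg.n_layers_motif):
        linear(f"gin{layer}a", d, d)
        linear(f"gin{layer}b", d, d)

    linear("spec_proj", cfg.m_max, d)
    # gated skip of the motif-spectrum profile into the output layer
    t["spec_skip.g"] = Tensor(np.array(4.0), requires_grad=True)

    head_dims = [3 * d] + [2 * d] * cfg.head_hidden_layers + [cfg.m_max]
    for layer in range(len(head_dims) - 1):
        linear(f"head{layer}", head_dims[layer], head_dims[layer + 1])
    # spectra are sparse: start the output bias low so the softplus baseline
    # is near zero instead of log(2) in every bin
    t[f"head{len(head_dims) - 2}.b"].data[:] = -4.0
    return ModelParams(t)


def count_parameters(params: ModelParams) -> int:
    """Exact number of trainable scalars."""
    return int(sum(p.data.size for p in params.values()))


def _dropout(h: Tensor, rate: float, rng) -> Tensor:
    if rng is None or rate <= 0.0:
        return h
    mask = (rng.random(h.shape) >= rate) / (1.0 - rate)
    return h * Tensor(mask)


def _normalized_adjacency(g: MoleculeGraph) -> np.ndarray:
    """Symmetric-normalized adjacency with self-loops, D^-1/2 (A+I) D^-1/2."""
    n = g.node_features.shape[0]
    a = np.eye(n)
    for i, j in g.edge_index:
        a[i, j] = 1.0
    deg = a.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    return a * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def encode_molecule(g: MoleculeGraph, params: ModelParams, cfg: ModelConfig,
                    dropout_rng=None) -> Tensor:
    """Molecule-graph embedding: 3 GCN rounds, mean pool, fingerprint fuse.

    Exactly permutation-invariant: every step is a function of the
    (normalized) adjacency and commutes with atom relabeling.
    """
    a_hat = Tensor(_normalized_adjacency(g))
    h = Tensor(g.node_features)
    for layer in range(cfg.n_layers_mol):
        h = (a_hat @ (h @ params[f"gcn{layer}.W"]) + params[f"gcn{layer}.b"]).relu()
        h = _dropout(h, cfg.dropout, dropout_rng)
    pooled = h.mean(axis=0)
    fp = (Tensor(g.fingerprint.astype(float)) @ params["fp_proj.W"]
          + params["fp_proj.b"]).relu()
    fused = Tensor.concat([pooled, fp])
    return (fused @ params["mol_readout.W"] + params["mol_readout.b"]).relu()


def encode_motif_graph(sub: SampledSubgraph, params: ModelParams, cfg: ModelConfig,
                       seed_position: int | None = None,
                       dropout_rng=None) -> Tensor:
    """Embedding of a seed molecule node within its sampled neighborhood.

    Node features pass through the 2-layer input MLP; then 3 isomorphism-
    network rounds of edge-weight-scaled sum aggregation (with self-loop),
    each followed by a 2-layer MLP update.  An isolated seed reduces to a
    transform of its own features.
    """
    if seed_position is None:
        if len(sub.seed_positions) != 1:
            raise ValueError("seed_position required for multi-seed subgraphs")
        seed_position = sub.seed_positions[0]
    if not 0 <= seed_position < len(sub.nodes):
        raise ValueError("seed missing from subgraph")
    x = sub.X.copy()
    x[:, -1] = x[:, -1] / _WEIGHT_SCALE
    h = Tensor(x)
    for layer in range(cfg.input_mlp_layers):
        h = (h @ params[f"motif_in{layer}.W"] + params[f"motif_in{layer}.b"]).relu()
    agg = Tensor(sub.W + np.eye(len(sub.nodes)))
    for layer in range(cfg.n_layers_motif):
        m = agg @ h
        m = (m @ params[f"gin{layer}a.W"] + params[f"gin{layer}a.b"]).relu()
        h = (m @ params[f"gin{layer}b.W"] + params[f"gin{layer}b.b"]).relu()
        h = _dropout(h, cfg.dropout, dropout_rng)
    return h.pick_row(seed_position)


def motif_spectrum_feature(occurrences: np.ndarray,
                           motif_spectra_matrix: np.ndarray) -> np.ndarray:
    """Occurrence-weighted sum of the molecule's motif spectra, unit norm.

    ``occurrences`` is the |V|-length count vector; the matrix stacks one
    binned motif spectrum per vocabulary rank.  All-zero occurrence vectors
    give the zero profile.
    """
    v = occurrences @ motif_spectra_matrix
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def predict_spectrum(mol_graph: MoleculeGraph, sub: SampledSubgraph,
                     spec_feature: np.ndarray, params: ModelParams,
                     cfg: ModelConfig, dropout_rng=None) -> Tensor:
    """Full forward pass; returns the positive intensity vector (m_max,)."""
    h_mol = encode_molecule(mol_graph, params, cfg, dropout_rng)
    h_motif = encode_motif_graph(sub, params, cfg, dropout_rng=dropout_rng)
    if cfg.use_motif_spectra:
        h_spec = (Tensor(spec_feature) @ params["spec_proj.W"]
                  + params["spec_proj.b"]).relu()
    else:
        h_spec = Tensor(np.zeros(cfg.d_hidden))
    z = Tensor.concat([h_mol, h_motif, h_spec])
    n_head = cfg.head_hidden_layers + 1
    for layer in range(n_head - 1):
        z = (z @ params[f"head{layer}.W"] + params[f"head{layer}.b"]).relu()
        z = _dropout(z, cfg.dropout, dropout_rng)
    out = z @ params[f"head{n_head - 1}.W"] + params[f"head{n_head - 1}.b"]
    if cfg.use_motif_spectra:
        # the profile lives on the output grid already; a learned gate lets
        # the head lean on it directly rather than decode it from a
        # projection alone
        out = out + Tensor(spec_feature) * params["spec_skip.g"]
    return out.softplus()


# ---------------------------------------------------------------------------
# Checkpointing

def vocab_hash(motifs) -> str:
    return hashlib.sha256("\n".join(motifs).encode()).hexdigest()


def save_checkpoint(path, params: ModelParams, cfg: ModelConfig, motifs) -> None:
    """Single-archive checkpoint: weights + config + vocabulary hash."""
    cfg_dict = dataclasses.asdict(cfg)
    np.savez(path,
             __config__=json.dumps(cfg_dict),
             __vocab_hash__=vocab_hash(motifs),
             **params.state_dict())


def load_checkpoint(path, motifs) -> tuple:
    """Load (params, cfg); refuses to load against a different vocabulary."""
    blob = np.load(path, allow_pickle=False)
    stored = str(blob["__vocab_hash__"])
    if stored != vocab_hash(motifs):
        raise ValueError("checkpoint was trained against a different motif vocabulary")
    cfg_dict = json.loads(str(blob["__config__"]))
    cfg_dict["sampler"] = SamplerConfig(**cfg_dict["sampler"])
    cfg = ModelConfig(**cfg_dict)
    params = init_params(cfg, rng_seed=0)
    params.load_state_dict({k: blob[k] for k in blob.files if not k.startswith("__")})
    return params, cfg
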