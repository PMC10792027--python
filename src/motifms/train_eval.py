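"""Training and evaluation: cosine objective, scaffold splitting, ranking.

The loss is the cosine distance between the true and predicted binned
spectra,

    CD(I, Ihat) = 1 - <I, Ihat> / (||I||_2 ||Ihat||_2),

and the evaluation metric is the matching cosine similarity of the
unit-normalized vectors.  Splits are scaffold-disjoint: molecules sharing a
Murcko scaffold always land in the same partition.  The identification task
ranks a reference library against each query spectrum and scores the
fraction of queries whose true candidate lands in the top 5% of the ranking.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from rdkit.Chem.Scaffolds import MurckoScaffold

from ._autodiff import Adam, Tensor
from .hetero_graph import (
    HeteroMotifGraph,
    build_hetero_graph,
    count_occurrences,
    sample_subgraph,
)
from .model import (
    ModelConfig,
    ModelParams,
    count_parameters,
    init_params,
    motif_spectrum_feature,
    predict_spectrum,
)
from .molio import FeaturizationConfig, Molecule, Spectrum, featurize_molecule
from .motif_spectra import MotifSpectrumConfig, build_motif_spectra
from .motif_vocab import OUT_OF_VOCAB, MotifVocabulary, build_vocabulary, decompose

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Metrics

def cosine_distance(a: Spectrum | np.ndarray, b: Spectrum | np.ndarray) -> float:
    """1 - cosine similarity; in [0, 1] for non-negative spectra."""
    return 1.0 - cosine_similarity(a, b)

def cosine_similarity(a: Spectrum | np.ndarray, b: Spectrum | np.ndarray) -> float:
    x = a.intensities if isinstance(a, Spectrum) else np.asarray(a, dtype=float)
    y = b.intensities if isinstance(b, Spectrum) else np.asarray(b, dtype=float)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("cosine similarity undefined for a zero spectrum")
    return float(np.dot(x, y) / (nx * ny))


# ---------------------------------------------------------------------------
# Scaffold splitting

PARTITIONS = ("train", "val", "test")


@dataclass
class SplitAssignment:
    assignment: dict  # molecule index -> partition name
    ratios: tuple
    rng_seed: int

    def indices(self, partition: str) -> list:
        return sorted(i for i, p in self.assignment.items() if p == partition)


def murcko_scaffold(mol: Molecule) -> str:
    """Murcko scaffold SMILES; acyclic molecules share the empty scaffold."""
    return MurckoScaffold.MurckoScaffoldSmiles(mol.smiles)


def scaffold_split(corpus, ratios=(0.7, 0.2, 0.1), rng_seed: int = 0) -> SplitAssignment:
    """Greedy scaffold-disjoint split.

    Scaffold groups are assigned largest-first to whichever partition is
    furthest below its target count; equal-size groups are ordered by a
    seed-shuffled permutation, so the split is deterministic per seed.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    groups: dict = {}
    for i, mol in enumerate(corpus):
        groups.setdefault(murcko_scaffold(mol), []).append(i)
    rng = np.random.default_rng(rng_seed)
    keys = sorted(groups)
    keys = [keys[i] for i in rng.permutation(len(keys))]
    keys.sort(key=lambda k: -len(groups[k]))  # stable: keeps shuffled tie order
    targets = {p: r * len(corpus) for p, r in zip(PARTITIONS, ratios)}
    filled = {p: 0 for p in PARTITIONS}
    assignment = {}
    for key in keys:
        part = max(PARTITIONS, key=lambda p: targets[p] - filled[p])
        for i in groups[key]:
            assignment[i] = part
        filled[part] += len(groups[key])
    return SplitAssignment(assignment=assignment, ratios=tuple(ratios), rng_seed=rng_seed)


# ---------------------------------------------------------------------------
# Dataset bundle

def _on_grid(s: Spectrum, m_max: int) -> Spectrum:
    """Align a binned spectrum to an ``m_max``-bin grid (truncate drops
    out-of-range bins, zero-pad extends)."""
    if s.m_max == m_max:
        return s
    out = np.zeros(m_max)
    n = min(s.m_max, m_max)
    out[:n] = s.intensities[:n]
    if s.m_max > m_max and np.any(s.intensities[m_max:]):
        logger.warning("spectrum truncated to %d bins (nonzero intensity dropped)", m_max)
    return Spectrum(intensities=out, metadata=dict(s.metadata))

@dataclass
class SpectrumDataset:
    """Everything the trainer needs, precomputed once.

    The vocabulary, co-occurrence statistics and heterogeneous graph are
    built from the training partition only; validation and test molecules
    are attached to the fixed motif-node set inductively through their own
    TF-IDF edges under the training statistics.
    """

    molecules: list
    spectra: list
    split: SplitAssignment
    vocab: MotifVocabulary
    graph: HeteroMotifGraph
    mol_graphs: list
    occurrence_vectors: np.ndarray  # (n_molecules, |V|)
    spec_features: np.ndarray  # (n_molecules, m_max)
    m_max: int

    @classmethod
    def build(cls, molecules, spectra, split: SplitAssignment,
              vocab: MotifVocabulary | None = None, K: int = 300,
              m_max: int = 1000, fingerprint_bits: int = 2048,
              motif_spectra_cfg: MotifSpectrumConfig | None = None) -> "SpectrumDataset":
        if len(molecules) != len(spectra):
            raise ValueError("molecules and spectra must align")
        spectra = [_on_grid(s, m_max) for s in spectra]
        train_idx = split.indices("train")
        if not train_idx:
            raise ValueError("empty training partition")
        if vocab is None:
            vocab = build_vocabulary([molecules[i] for i in train_idx], K=K)
        decomps = [decompose(m, vocab) for m in molecules]
        counts = count_occurrences([molecules[i] for i in train_idx], vocab,
                                   decompositions=[decomps[i] for i in train_idx])
        # graph over training molecules, keyed by global index
        graph = HeteroMotifGraph(vocab=vocab, counts=counts)
        from .hetero_graph import MOTIF, node_features, pmi

        for rank in range(len(vocab)):
            node = (MOTIF, rank)
            graph.adj[node] = []
            graph.features[node] = node_features(node, counts, vocab)
        for a in range(len(vocab)):
            for b in range(a + 1, len(vocab)):
                w = pmi(vocab.motifs[a], vocab.motifs[b], counts, vocab)
                if w > 0:
                    graph._add_edge((MOTIF, a), (MOTIF, b), w)
        occ_vectors = np.zeros((len(molecules), len(vocab)))
        for i, mol in enumerate(molecules):
            occ = Counter(lab for lab, _ in decomps[i] if lab != OUT_OF_VOCAB)
            graph.add_molecule(mol, occ, key=i)
            for rank, label in enumerate(vocab.motifs):
                occ_vectors[i, rank] = occ.get(label, 0)
        table = build_motif_spectra(
            vocab, motif_spectra_cfg or MotifSpectrumConfig(m_max=m_max))
        spectra_matrix = table.matrix(vocab, m_max)
        spec_features = np.stack([
            motif_spectrum_feature(occ_vectors[i], spectra_matrix)
            for i in range(len(molecules))
        ]) if len(molecules) else np.zeros((0, m_max))
        mol_graphs = [featurize_molecule(m, FeaturizationConfig(fingerprint_bits))
                      for m in molecules]
        return cls(molecules=molecules, spectra=spectra, split=split, vocab=vocab,
                   graph=graph, mol_graphs=mol_graphs, occurrence_vectors=occ_vectors,
                   spec_features=spec_features, m_max=m_max)

    def forward(self, index: int, params: ModelParams, cfg: ModelConfig,
                sampler_seed: int, dropout_rng=None) -> Tensor:
        sub = sample_subgraph(self.graph, [("mol", index)], cfg.sampler, sampler_seed)
        return predict_spectrum(self.mol_graphs[index], sub,
                                self.spec_features[index], params, cfg,
                                dropout_rng=dropout_rng)

    def predict(self, index: int, params: ModelParams, cfg: ModelConfig,
                sampler_seed: int = 0) -> Spectrum:
        pred = self.forward(index, params, cfg, sampler_seed)
        return Spectrum(intensities=pred.data.copy(),
                        metadata={"index": str(index)})


# ---------------------------------------------------------------------------
# Training

@dataclass
class TrainLog:
    epochs: list = field(default_factory=list)  # (epoch, mean train loss, val sim)
    best_epoch: int = -1
    best_val_similarity: float = -np.inf
    n_parameters: int = 0

    def record(self, epoch: int, loss: float, val_sim: float) -> None:
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
        self.epochs.append((epoch, loss, val_sim))


def _cosine_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    t = target / np.linalg.norm(target)
    return 1.0 - pred.dot(Tensor(t)) / pred.norm()


def train(dataset: SpectrumDataset, cfg: ModelConfig, rng_seed: int = 0,
          n_epochs: int = 200, batch_size: int = 16, lr: float = 1e-3,
          patience: int = 10, min_epochs: int = 1, restore_best: bool = True):
    """Mini-batch Adam on the mean cosine distance.

    Keeps the checkpoint with the best validation cosine similarity and
    stops early after ``patience`` epochs without improvement.  Returns
    ``(params, TrainLog)``; by default the best-validation weights are
    restored (set ``restore_best=False`` to keep the final ones, e.g. for
    capacity/overfit diagnostics).
    """
    train_idx = dataset.split.indices("train")
    val_idx = dataset.split.indices("val")
    if not train_idx:
        raise ValueError("empty training partition")
    params = init_params(cfg, rng_seed=rng_seed)
    opt = Adam(list(params.values()), lr=lr)
    rng = np.random.default_rng(rng_seed)
    log = TrainLog(n_parameters=count_parameters(params))
    best_state = params.state_dict()
    stale = 0
    for epoch in range(n_epochs):
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), batch_size):
            batch = order[start:start + batch_size]
            opt.zero_grad()
            total = None
            for i in batch:
                sampler_seed = int((rng_seed * 1_000_003 + epoch * 9973 + int(i)) % (2**31))
                pred = dataset.forward(int(i), params, cfg, sampler_seed,
                                       dropout_rng=rng if cfg.dropout > 0 else None)
                loss = _cosine_loss(pred, dataset.spectra[int(i)].intensities)
                total = loss if total is None else total + loss
            total = total * (1.0 / len(batch))
            total.backward()
            opt.step()
            losses.append(float(total.data))
        val_sim = (evaluate_similarity(dataset, params, cfg, val_idx).mean
                   if val_idx else -float(np.mean(losses)))
        log.record(epoch, float(np.mean(losses)), float(val_sim))
        if val_sim > log.best_val_similarity:
            log.best_val_similarity = float(val_sim)
            log.best_epoch = epoch
            best_state = params.state_dict()
            stale = 0
        else:
            stale += 1
            if epoch + 1 >= min_epochs and stale > patience:
                logger.info("early stop at epoch %d (best %d)", epoch, log.best_epoch)
                break
    if restore_best:
        params.load_state_dict(best_state)
    return params, log


# ---------------------------------------------------------------------------
# Evaluation

@dataclass
class SimilarityReport:
    per_molecule: list
    mean: float
    std: float


def evaluate_similarity(dataset: SpectrumDataset, params: ModelParams,
                        cfg: ModelConfig, indices, sampler_seed: int = 0) -> SimilarityReport:
    """Cosine similarity of normalized true vs predicted spectra."""
    indices = list(indices)
    if not indices:
        raise ValueError("empty evaluation set")
    sims = []
    for i in indices:
        pred = dataset.predict(int(i), params, cfg, sampler_seed=sampler_seed)
        sims.append(cosine_similarity(dataset.spectra[int(i)], pred))
    return SimilarityReport(per_molecule=sims, mean=float(np.mean(sims)),
                            std=float(np.std(sims)))


@dataclass
class RankingResult:
    ranks: list  # (query id, rank of true candidate, n_candidates)
    top5_score: float


def rank_candidates(queries, reference) -> RankingResult:
    """Library-identification ranking.

    ``queries``: (query_id, Spectrum, true_candidate_id) triples —
    typically real test-set spectra whose true candidate is the *predicted*
    spectrum of the same molecule.  ``reference``: (candidate_id, Spectrum)
    pairs.  Candidates are ordered by cosine similarity (descending), ties
    by candidate id; a query scores when its true candidate's rank is within
    the top 5% quota max(1, floor(0.05 n)).
    """
    ref = sorted(reference, key=lambda r: r[0])
    ref_ids = [r[0] for r in ref]
    ref_mat = np.stack([r[1].intensities for r in ref])
    norms = np.linalg.norm(ref_mat, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero spectrum in reference set")
    ref_unit = ref_mat / norms[:, None]
    n = len(ref)
    quota = max(1, int(np.floor(0.05 * n)))
    ranks, hits = [], 0
    for qid, spec, true_id in queries:
        if true_id not in ref_ids:
            raise ValueError(f"query {qid!r}: true candidate {true_id!r} missing from reference")
        q = spec.intensities / np.linalg.norm(spec.intensities)
        sims = ref_unit @ q
        order = sorted(range(n), key=lambda k: (-sims[k], ref_ids[k]))
        rank = order.index(ref_ids.index(true_id)) + 1
        ranks.append((qid, rank, n))
        if rank <= quota:
            hits += 1
    if not ranks:
        raise ValueError("no queries")
    return RankingResult(ranks=ranks, top5_score=hits / len(ranks))
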