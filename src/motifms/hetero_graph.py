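"""Heterogeneous molecule-motif graph with PMI / TF-IDF edge weights.

Nodes are the corpus molecules plus the vocabulary motifs.  Motif-motif edges
carry point-wise mutual information computed from per-molecule co-occurrence,

    PMI(i, j) = log( N(i,j) * M / (N(i) * N(j)) ),

kept only when positive; molecule-motif edges carry the term-frequency /
inverse-document-frequency weight

    TFIDF(i, j) = C(i)_j * ( log( (1+M) / (1+N(i)) ) + 1 ),

and molecule-molecule edges never exist.  Logs are natural.  ``M`` is the
number of molecules, ``N(i)`` the number containing motif ``i``, ``N(i,j)``
the number containing both, and ``C(i)_j`` the occurrence count of motif
``i`` inside molecule ``j``.

Because the molecule set can be large, encoders consume per-hop sampled BFS
subgraphs rather than the full graph; the first hop out of a molecule node
can only reach motif nodes, by construction.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .molio import Molecule
from .motif_vocab import MotifVocabulary, OUT_OF_VOCAB, decompose


@dataclass
class CooccurrenceCounts:
    """Per-molecule motif occurrence statistics over a corpus.

    ``C[(label, j)]`` counts occurrences of a motif inside molecule ``j``
    (multiplicity); ``N[label]`` and ``N_pair[(a, b)]`` are binary
    per-molecule document counts.
    """

    M: int
    N: dict
    N_pair: dict
    C: dict

    def occurrences(self, j: int, vocab: MotifVocabulary) -> np.ndarray:
        """Occurrence-count vector of length |V| for molecule ``j``."""
        v = np.zeros(len(vocab), dtype=float)
        for rank, label in enumerate(vocab.motifs):
            v[rank] = self.C.get((label, j), 0)
        return v


def count_occurrences(corpus, vocab: MotifVocabulary,
                      decompositions=None) -> CooccurrenceCounts:
    """Count motif occurrences/co-occurrences by replaying decompositions."""
    if not corpus:
        raise ValueError("corpus must be non-empty")
    if decompositions is None:
        decompositions = [decompose(m, vocab) for m in corpus]
    N: dict = {}
    N_pair: dict = {}
    C: dict = {}
    for j, frags in enumerate(decompositions):
        labels = [lab for lab, _ in frags if lab != OUT_OF_VOCAB]
        for lab, n in Counter(labels).items():
            C[(lab, j)] = n
        present = sorted(set(labels))
        for lab in present:
            N[lab] = N.get(lab, 0) + 1
        for a_idx in range(len(present)):
            for b_idx in range(a_idx + 1, len(present)):
                key = (present[a_idx], present[b_idx])
                N_pair[key] = N_pair.get(key, 0) + 1
    return CooccurrenceCounts(M=len(corpus), N=N, N_pair=N_pair, C=C)


def pmi(i: str, j: str, counts: CooccurrenceCounts, vocab: MotifVocabulary) -> float:
    """PMI edge weight between motifs ``i`` and ``j``; 0 means "no edge"
    (absent co-occurrence or non-positive PMI)."""
    for lab in (i, j):
        if lab not in vocab:
            raise KeyError(f"motif {lab!r} not in vocabulary")
    n_i, n_j = counts.N.get(i, 0), counts.N.get(j, 0)
    if n_i == 0 or n_j == 0:
        return 0.0
    n_ij = counts.N_pair.get((i, j) if i <= j else (j, i), 0)
    if n_ij == 0:
        return 0.0
    value = math.log(n_ij * counts.M / (n_i * n_j))
    return value if value > 0 else 0.0


def tfidf(i: str, j: int, counts: CooccurrenceCounts) -> float:
    """TF-IDF edge weight between motif ``i`` and molecule index ``j``;
    0 when the motif does not occur in the molecule."""
    c = counts.C.get((i, j), 0)
    if c == 0:
        return 0.0
    return c * (math.log((1 + counts.M) / (1 + counts.N.get(i, 0))) + 1.0)


def motif_molecular_weight(label: str) -> float:
    """Monoisotopic mass of the hydrogen-capped motif structure."""
    return Descriptors.ExactMolWt(Chem.MolFromSmiles(label))


MOTIF = "motif"
MOL = "mol"


@dataclass
class HeteroMotifGraph:
    """Weighted undirected heterogeneous graph plus node features.

    Node keys are ``("motif", rank)`` and ``("mol", index)``.  Every node
    carries a feature vector of length |V| + 1: motif-occurrence counts (for
    molecule nodes) or motif co-occurrence document counts (for motif nodes,
    diagonal = the motif's own document count), with the node's molecular
    weight appended.
    """

    vocab: MotifVocabulary
    counts: CooccurrenceCounts
    adj: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)

    @property
    def num_nodes(self) -> int:
        return len(self.adj)

    def node_type(self, node) -> str:
        return node[0]

    def neighbors(self, node):
        return self.adj[node]

    def _add_edge(self, a, b, w: float) -> None:
        self.adj[a].append((b, w))
        self.adj[b].append((a, w))

    def add_molecule(self, mol: Molecule, occurrences: Counter, key=None) -> tuple:
        """Attach a molecule node using this graph's (training) statistics.

        Used both at build time and inductively for unseen molecules: edges
        are the molecule's own TF-IDF weights under the stored ``M``/``N``.
        """
        node = (MOL, key if key is not None else self.num_nodes)
        if node in self.adj:
            raise KeyError(f"duplicate molecule node {node}")
        self.adj[node] = []
        v = np.zeros(len(self.vocab) + 1)
        for rank, label in enumerate(self.vocab.motifs):
            c = occurrences.get(label, 0)
            if c == 0:
                continue
            v[rank] = c
            w = c * (math.log((1 + self.counts.M) / (1 + self.counts.N.get(label, 0))) + 1.0)
            self._add_edge(node, (MOTIF, rank), w)
        v[-1] = mol.exact_mass
        self.features[node] = v
        return node


def node_features(node, counts: CooccurrenceCounts, vocab: MotifVocabulary,
                  molecule: Molecule | None = None) -> np.ndarray:
    """Feature vector (length |V| + 1) for a motif or molecule node."""
    v = np.zeros(len(vocab) + 1)
    kind, ident = node
    if kind == MOTIF:
        label = vocab.motifs[ident]
        for rank, other in enumerate(vocab.motifs):
            if other == label:
                v[rank] = counts.N.get(label, 0)
            else:
                key = (label, other) if label <= other else (other, label)
                v[rank] = counts.N_pair.get(key, 0)
        v[-1] = motif_molecular_weight(label)
    elif kind == MOL:
        v[: len(vocab)] = counts.occurrences(ident, vocab)
        if molecule is None:
            raise ValueError("molecule required for molecule-node features")
        v[-1] = molecule.exact_mass
    else:
        raise ValueError(f"unknown node type {kind!r}")
    return v


def build_hetero_graph(corpus, vocab: MotifVocabulary,
                       counts: CooccurrenceCounts,
                       decompositions=None) -> HeteroMotifGraph:
    """Assemble the full graph: motif nodes first, then one node per corpus
    molecule; no molecule-molecule edges exist."""
    graph = HeteroMotifGraph(vocab=vocab, counts=counts)
    for rank in range(len(vocab)):
        node = (MOTIF, rank)
        graph.adj[node] = []
        graph.features[node] = node_features(node, counts, vocab)
    for a in range(len(vocab)):
        for b in range(a + 1, len(vocab)):
            w = pmi(vocab.motifs[a], vocab.motifs[b], counts, vocab)
            if w > 0:
                graph._add_edge((MOTIF, a), (MOTIF, b), w)
    if decompositions is None:
        decompositions = [decompose(m, vocab) for m in corpus]
    for j, mol in enumerate(corpus):
        occ = Counter(lab for lab, _ in decompositions[j] if lab != OUT_OF_VOCAB)
        graph.add_molecule(mol, occ, key=j)
    return graph


@dataclass(frozen=True)
class SamplerConfig:
    """Per-hop BFS sample sizes [s1, s2, s3]."""

    s1: int = 8
    s2: int = 8
    s3: int = 8

    def __post_init__(self):
        if min(self.s1, self.s2, self.s3) < 1:
            raise ValueError("sample sizes must be >= 1")

    @property
    def sizes(self) -> tuple:
        return (self.s1, self.s2, self.s3)


@dataclass
class SampledSubgraph:
    """Node-induced subgraph ready for the motif-graph encoder."""

    nodes: list  # sorted node keys, seeds included
    X: np.ndarray  # (n_nodes, |V| + 1) features
    W: np.ndarray  # (n_nodes, n_nodes) symmetric weighted adjacency
    seed_positions: list  # row indices of the seed nodes


def sample_subgraph(graph: HeteroMotifGraph, seeds, cfg: SamplerConfig,
                    rng_seed: int) -> SampledSubgraph:
    """Hop-by-hop BFS sampling from molecule seed nodes.

    At hop ``h`` each frontier node contributes at most ``s_h`` of its
    neighbors, drawn uniformly without replacement with the given seed.  An
    isolated seed (no in-vocabulary motif) yields the seed alone.
    """
    for s in seeds:
        if graph.node_type(s) != MOL:
            raise ValueError(f"seed {s} is not a molecule node")
    rng = np.random.default_rng(rng_seed)
    selected = set(seeds)
    frontier = sorted(seeds)
    for s_h in cfg.sizes:
        nxt = set()
        for node in frontier:
            nbrs = sorted(n for n, _ in graph.neighbors(node))
            if len(nbrs) > s_h:
                idx = rng.choice(len(nbrs), size=s_h, replace=False)
                nbrs = [nbrs[i] for i in sorted(idx)]
            nxt.update(n for n in nbrs if n not in selected)
        selected.update(nxt)
        frontier = sorted(nxt)
        if not frontier:
            break
    nodes = sorted(selected)
    pos = {n: i for i, n in enumerate(nodes)}
    X = np.stack([graph.features[n] for n in nodes])
    W = np.zeros((len(nodes), len(nodes)))
    for n in nodes:
        for nbr, w in graph.neighbors(n):
            if nbr in pos:
                W[pos[n], pos[nbr]] = w
    return SampledSubgraph(nodes=nodes, X=X, W=W,
                           seed_positions=[pos[s] for s in seeds])


def export_edge_list(graph: HeteroMotifGraph, path) -> None:
    """Edge list TSV: src_type, src_id, dst_type, dst_id, weight."""
    with open(path, "w") as fh:
        fh.write("src_type\tsrc_id\tdst_type\tdst_id\tweight\n")
        seen = set()
        for node in sorted(graph.adj):
            for nbr, w in graph.neighbors(node):
                key = tuple(sorted((node, nbr)))
                if key in seen:
                    continue
                seen.add(key)
                fh.write(f"{node[0]}\t{node[1]}\t{nbr[0]}\t{nbr[1]}\t{w:.10g}\n")
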