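"""Motif vocabulary mining by iterative merge-and-update.

The miner is the byte-pair-encoding idea lifted onto molecular graphs: every
atom starts as its own fragment, and at each iteration the corpus-wide most
frequent pair of *adjacent* fragments (keyed by their canonical-SMILES labels)
is merged at every occurrence.  A merged fragment whose hydrogen-capped
structure sanitizes is admitted to the vocabulary; invalid intermediates (for
example half-built aromatic rings) are still merged so that rings can close in
later iterations, but are never vocabulary entries.

Determinism does not depend on corpus order: pair counts are aggregated over
the corpus as a multiset, ties are broken by the lexicographically smallest
label pair, and overlapping occurrences inside one molecule are resolved
greedily by lowest atom index.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field

from rdkit import Chem

from .molio import Molecule

logger = logging.getLogger(__name__)

#: reserved label for leftover fragments not in the vocabulary
OUT_OF_VOCAB = "*"


def fragment_label(rdmol: Chem.Mol, atom_ids) -> str:
    """Canonical SMILES of the subgraph induced by ``atom_ids``."""
    return Chem.MolFragmentToSmiles(rdmol, atomsToUse=sorted(atom_ids), canonical=True)


def is_valid_motif(label: str) -> bool:
    """A merged fragment is valid when its hydrogen-capped structure
    sanitizes as a standalone molecule."""
    return Chem.MolFromSmiles(label) is not None


class _MolState:
    """Fragment partition of a single molecule during mining/replay."""

    __slots__ = ("rdmol", "bonds", "fragments", "labels", "frag_of")

    def __init__(self, mol: Molecule):
        self.rdmol = mol.to_rdkit()
        self.bonds = [(i, j) for i, j, _ in mol.bonds]
        self.fragments: dict = {}
        self.labels: dict = {}
        self.frag_of: list = []
        for idx in range(mol.num_atoms):
            self.fragments[idx] = {idx}
            self.labels[idx] = fragment_label(self.rdmol, [idx])
            self.frag_of.append(idx)

    def adjacent_pairs(self) -> list:
        """Unordered adjacent fragment-id pairs, one entry per pair even if
        several bonds connect the two fragments."""
        seen = set()
        out = []
        for i, j in self.bonds:
            fi, fj = self.frag_of[i], self.frag_of[j]
            if fi == fj:
                continue
            key = (fi, fj) if fi < fj else (fj, fi)
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def pair_label_counts(self) -> Counter:
        c: Counter = Counter()
        for fi, fj in self.adjacent_pairs():
            c[_label_key(self.labels[fi], self.labels[fj])] += 1
        return c

    def merge_pair_everywhere(self, label_pair) -> list:
        """Merge every adjacent fragment pair carrying ``label_pair``,
        greedily by lowest atom index; returns the new fragments' labels."""
        merged_labels = []
        while True:
            candidates = [
                (fi, fj)
                for fi, fj in self.adjacent_pairs()
                if _label_key(self.labels[fi], self.labels[fj]) == label_pair
            ]
            if not candidates:
                return merged_labels
            fi, fj = min(candidates, key=lambda p: min(self.fragments[p[0]] | self.fragments[p[1]]))
            atoms = self.fragments[fi] | self.fragments[fj]
            new_id = min(atoms)
            for f in (fi, fj):
                del self.fragments[f]
                del self.labels[f]
            self.fragments[new_id] = atoms
            self.labels[new_id] = fragment_label(self.rdmol, atoms)
            for a in atoms:
                self.frag_of[a] = new_id
            merged_labels.append(self.labels[new_id])

    def final_fragments(self) -> list:
        """(label, frozenset of atom indices), sorted by lowest atom."""
        return [
            (self.labels[fid], frozenset(self.fragments[fid]))
            for fid in sorted(self.fragments, key=lambda f: min(self.fragments[f]))
        ]


def _label_key(a: str, b: str) -> tuple:
    return (a, b) if a <= b else (b, a)


@dataclass
class MergeState:
    """Corpus-wide mining state: per-molecule partitions plus the adjacent
    label-pair counter (kept incrementally, molecule-granular updates)."""

    mols: list
    pair_counts: Counter
    per_mol_counts: list
    iteration: int = 0

    @property
    def exhausted(self) -> bool:
        return not self.pair_counts


def init_merge_state(corpus) -> MergeState:
    """Every atom a singleton fragment; counter over adjacent label pairs."""
    if not corpus:
        raise ValueError("corpus must be non-empty")
    mols = [_MolState(m) for m in corpus]
    per_mol = [m.pair_label_counts() for m in mols]
    total: Counter = Counter()
    for c in per_mol:
        total.update(c)
    return MergeState(mols=mols, pair_counts=total, per_mol_counts=per_mol)


def merge_step(state: MergeState):
    """One merge-and-update iteration.

    Merges the most frequent adjacent label pair at every occurrence and
    returns ``(selected_pair, selected_count, motif_label_or_None)``; the
    motif label is the most frequent *valid* merged structure produced by the
    merge (ties lexicographic).  Returns ``(None, 0, None)`` on exhaustion.
    """
    if state.exhausted:
        return None, 0, None
    best_count = max(state.pair_counts.values())
    pair = min(k for k, v in state.pair_counts.items() if v == best_count)
    produced: Counter = Counter()
    for idx, mstate in enumerate(state.mols):
        if state.per_mol_counts[idx].get(pair, 0) == 0:
            continue
        state.pair_counts.subtract(state.per_mol_counts[idx])
        produced.update(mstate.merge_pair_everywhere(pair))
        state.per_mol_counts[idx] = mstate.pair_label_counts()
        state.pair_counts.update(state.per_mol_counts[idx])
    state.pair_counts = +state.pair_counts  # drop zero/negative entries
    state.iteration += 1
    valid = {lab: n for lab, n in produced.items() if is_valid_motif(lab)}
    if not valid:
        return pair, best_count, None
    top = max(valid.values())
    label = min(lab for lab, n in valid.items() if n == top)
    return pair, best_count, label


@dataclass
class MotifVocabulary:
    """Ordered mined motifs plus the merge trace needed to replay
    decompositions on unseen molecules."""

    motifs: list
    counts: dict
    K: int
    merge_trace: list = field(default_factory=list)

    def __contains__(self, label: str) -> bool:
        return label in self.counts

    def __len__(self) -> int:
        return len(self.motifs)

    def rank(self, label: str) -> int:
        return self.motifs.index(label)

    def save(self, tsv_path, trace_path=None) -> None:
        with open(tsv_path, "w") as fh:
            fh.write("rank\tcanonical_smiles\tcount\tn_atoms\n")
            for r, lab in enumerate(self.motifs):
                n_atoms = Chem.MolFromSmiles(lab).GetNumAtoms()
                fh.write(f"{r}\t{lab}\t{self.counts[lab]}\t{n_atoms}\n")
        if trace_path is not None:
            with open(trace_path, "w") as fh:
                json.dump({"K": self.K, "merge_trace": self.merge_trace}, fh)

    @classmethod
    def load(cls, tsv_path, trace_path) -> "MotifVocabulary":
        motifs, counts = [], {}
        with open(tsv_path) as fh:
            next(fh)
            for line in fh:
                _, lab, count, _ = line.rstrip("\n").split("\t")
                motifs.append(lab)
                counts[lab] = int(count)
        with open(trace_path) as fh:
            blob = json.load(fh)
        return cls(motifs=motifs, counts=counts, K=blob["K"],
                   merge_trace=[tuple(p) for p in blob["merge_trace"]])


def build_vocabulary(corpus, K: int = 300) -> MotifVocabulary:
    """Mine the top-``K`` motif vocabulary from a molecule corpus.

    Runs ``K`` merge iterations (or until no adjacent pair remains); each
    iteration records its merged pair in the trace and admits at most one new
    vocabulary label.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    state = init_merge_state(corpus)
    vocab = MotifVocabulary(motifs=[], counts={}, K=K)
    for _ in range(K):
        pair, count, label = merge_step(state)
        if pair is None:
            logger.warning(
                "corpus exhausted after %d iterations (%d motifs)",
                state.iteration, len(vocab.motifs),
            )
            break
        vocab.merge_trace.append(pair)
        if label is not None and label not in vocab.counts:
            vocab.motifs.append(label)
            vocab.counts[label] = count
    return vocab


def decompose(mol: Molecule, vocab: MotifVocabulary) -> list:
    """Replay the vocabulary's merge trace on one molecule.

    Returns ``(label, atom_index_frozenset)`` per final fragment; fragments
    whose label is not a vocabulary motif carry the reserved
    :data:`OUT_OF_VOCAB` label (their true label is kept in no way — they are
    not motifs).
    """
    state = _MolState(mol)
    for pair in vocab.merge_trace:
        state.merge_pair_everywhere(tuple(pair))
    return [
        (lab if lab in vocab else OUT_OF_VOCAB, atoms)
        for lab, atoms in state.final_fragments()
    ]
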