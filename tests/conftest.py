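"""Shared fixtures and independent brute-force oracles.

The oracle functions here recompute quantities from scratch, independent of
the package's incremental/optimized code paths, so tests can compare the two.
"""

from collections import Counter

import pytest

from motifms.molio import parse_smiles
from motifms.motif_vocab import OUT_OF_VOCAB, decompose


# A pool of small, diverse, valid SMILES used to assemble random corpora.
SMILES_POOL = [
    "CCO", "CCC", "CCN", "CCCl", "CC(C)O", "CCOC", "CCCO", "CC(=O)O",
    "c1ccccc1", "Cc1ccccc1", "CCc1ccccc1", "OCC(O)CO", "CNC", "CCS",
    "CC(C)C", "CCCCC", "NCCO", "ClCCCl", "CC(N)C(=O)O", "c1ccncc1",
]


@pytest.fixture(scope="session")
def worked_corpus():
    """The three-molecule corpus whose merge trace is known by hand."""
    return [parse_smiles(s) for s in ["CCO", "CCO", "CCC"]]


def random_corpus(rng, n_molecules, pool=SMILES_POOL):
    """A random multiset of molecules from the pool."""
    return [parse_smiles(pool[i]) for i in rng.integers(0, len(pool), n_molecules)]


# ---------------------------------------------------------------------------
# Oracles

def recount_pairs(state):
    """From-scratch adjacent label-pair counter over a MergeState, reading
    only the molecules' bond lists and current fragment partitions."""
    total = Counter()
    for mstate in state.mols:
        seen = set()
        for i, j in mstate.bonds:
            fi, fj = mstate.frag_of[i], mstate.frag_of[j]
            if fi == fj:
                continue
            key = (fi, fj) if fi < fj else (fj, fi)
            if key in seen:
                continue
            seen.add(key)
            a, b = mstate.labels[fi], mstate.labels[fj]
            total[(a, b) if a <= b else (b, a)] += 1
    return total


def brute_force_counts(corpus, vocab):
    """Independent recount of M, N(i), N(i,j), C(i)_j from decompositions."""
    M = len(corpus)
    N, N_pair, C = Counter(), Counter(), {}
    for j, mol in enumerate(corpus):
        labels = [lab for lab, _ in decompose(mol, vocab) if lab != OUT_OF_VOCAB]
        for lab, c in Counter(labels).items():
            C[(lab, j)] = c
        present = sorted(set(labels))
        for lab in present:
            N[lab] += 1
        for x in range(len(present)):
            for y in range(x + 1, len(present)):
                N_pair[(present[x], present[y])] += 1
    return M, dict(N), dict(N_pair), C


def brute_force_pmi(i, j, M, N, N_pair):
    import math

    n_ij = N_pair.get((i, j) if i <= j else (j, i), 0)
    if n_ij == 0 or N.get(i, 0) == 0 or N.get(j, 0) == 0:
        return 0.0
    v = math.log((n_ij / M) / ((N[i] / M) * (N[j] / M)))
    return v if v > 0 else 0.0


def brute_force_tfidf(i, j, M, N, C):
    import math

    c = C.get((i, j), 0)
    if c == 0:
        return 0.0
    return c * (math.log((1 + M) / (1 + N.get(i, 0))) + 1.0)
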