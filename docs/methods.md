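# Methods

`motifms` predicts an electron/collision-fragmentation mass spectrum — a
vector of intensities on a 1 Da m/z grid — from a molecular structure, by
exploiting mined substructure ("motif") statistics of a molecule corpus.
This note records the model, its assumptions, the numerical choices, and
what the synthetic benchmark does and does not demonstrate.

## Motif vocabulary by merge-and-update

Every atom of every corpus molecule starts as a singleton fragment.  Each
iteration counts, over the whole corpus, unordered pairs of *adjacent*
fragments keyed by the canonical SMILES of their induced subgraphs, merges
the most frequent pair at every occurrence, and admits the merged structure
to the vocabulary if its hydrogen-capped form sanitizes.  `K` iterations
yield at most `K` motifs (default `K = 300`).  Decomposition of any
molecule — including unseen ones — replays the recorded merge trace, so a
molecule's motif occurrences are exactly reproducible.

Choices the procedure leaves open, fixed here:

- **Tie-breaking**: ties on frequency go to the lexicographically smallest
  label pair; within one molecule overlapping occurrences merge greedily by
  lowest atom index.  Both rules make mining a function of the corpus
  *multiset* — input order cannot matter, which the suite checks.
- **Validity**: invalid intermediates (e.g. fragments of an aromatic ring)
  are still merged, just not admitted; rings therefore enter the vocabulary
  exactly when their closing merge happens, because fragment labels are
  induced subgraphs (the closing bond appears automatically).
- **One label per step**: a single label pair can merge into different
  structures at different sites (different attachment atoms).  The step
  admits the most frequent valid merged label (tie lexicographic).
- Selection-time frequencies are *not* guaranteed monotone along the
  vocabulary: merging (A, B) inside an X–A–B–X arrangement leaves the new
  fragment adjacent to two X's, so a successor pair can outnumber the pair
  just selected.  The suite documents this with a regression test.
- Leftover fragments outside the vocabulary carry a reserved
  out-of-vocabulary label and are excluded from all occurrence statistics.

## Heterogeneous molecule–motif graph

Nodes are the training molecules plus the motifs.  Motif–motif edges carry
point-wise mutual information over per-molecule document counts,
`PMI(i,j) = log( N(i,j)·M / (N(i)·N(j)) )`, kept only when positive;
molecule–motif edges carry `TFIDF(i,j) = C(i)_j · (log((1+M)/(1+N(i))) + 1)`
with `C(i)_j` the occurrence multiplicity.  Logs are natural.  There are no
molecule–molecule edges.  "Two motifs co-occur" is read as same-molecule
co-occurrence: replayed decompositions are atom-disjoint, so a literal
shared-atom criterion would produce an empty motif graph.

Node features have length `|V| + 1`: occurrence counts (molecules) or
co-occurrence document counts with the motif's own document count on the
diagonal (motifs), plus the monoisotopic weight of the node's structure
(hydrogen-capped for motifs).  The weight column is divided by a fixed 100
inside the encoder so it is commensurate with the counts.

Encoders never see the full graph: a breadth-first sampler takes at most
`[s1, s2, s3]` neighbors per frontier node per hop (default `[8, 8, 8]`,
uniform without replacement, seeded).  The first hop out of a molecule node
reaches only motif nodes by construction.  Held-out molecules attach
inductively: their own TF-IDF edges under the *training* `M` and `N(i)`,
against the fixed motif node set.

## Motif spectra

Each motif gets a synthetic reference spectrum: the isotope envelope of its
hydrogen-capped molecular ion (exact polynomial convolution of per-element
isotope distributions, aggregated at nominal mass, truncated below 1e-3
relative abundance) plus one peak per single-cleavage fragment at a fixed
0.2 relative intensity (every acyclic single bond broken once, both sides
hydrogen-capped, deduplicated by formula, the 6 heaviest kept).  Real
electron-impact library spectra, where available in MSP form, override the
computed entry for structurally matching motifs (canonical-SMILES match).

## Predictor

Two encoders feed one head:

- **Molecule encoder** — 3 rounds of symmetric-normalized graph
  convolution (`D^-1/2 (A+I) D^-1/2`, learned linear + ReLU each round)
  over one-hot atom descriptors, mean-pooled, fused with a projected
  2048-bit topological path fingerprint.  Exactly permutation-invariant.
- **Motif-graph encoder** — node features through a 2-layer MLP, then 3
  isomorphism-network rounds: sum aggregation with self-loop, messages
  scaled by the PMI/TF-IDF edge weights, 2-layer MLP update; the seed
  molecule node's representation is read out.
- **Head** — the two embeddings concatenate with a projection of the
  molecule's motif-spectrum profile (occurrence-weighted sum of its motifs'
  spectra, unit L2 norm); two hidden layers of width `2·d_hidden`, then a
  softplus output over the `M_max = 1000` bins.

Two design points the open literature on sparse spectral outputs motivates,
adopted here after the hidden-space concatenation alone showed no held-out
effect: (i) the motif-spectrum profile also enters the output layer through
a learned scalar gate — it already lives on the m/z grid, so the head can
lean on it directly instead of decoding a random projection; (ii) the
output bias initializes at −4 so the softplus baseline starts near zero.
With zero bias every bin carries a log 2 background whose 1000-bin mass
dominates the cosine objective and swamps the actual peaks.  Softplus
(rather than a hard ReLU) keeps the output strictly positive, so the cosine
loss is always defined.

Training minimizes the mean cosine distance
`1 − ⟨I, Î⟩ / (‖I‖₂‖Î‖₂)` with Adam (lr 1e-3), mini-batches of 16,
early stopping on validation cosine similarity (patience 10 by default),
best-validation weights restored.  Subgraph samples are redrawn each epoch
from a seed derived deterministically from (run seed, epoch, molecule).
All computation runs on a small reverse-mode autodiff engine over NumPy
written for this package and validated against central finite differences
in the test suite.

## Evaluation protocols

- **Spectrum similarity**: cosine similarity of unit-normalized true and
  predicted spectra, mean ± std over molecules; the multi-seed harness
  refits per seed and reports mean ± std across seeds.
- **Splitting**: Murcko-scaffold-disjoint 70/20/10.  Groups assign greedily,
  largest first, to the partition furthest below target; acyclic molecules
  share the empty scaffold and travel together.  Partition sizes are
  therefore only accurate up to scaffold-group granularity.
- **Identification**: each real test spectrum queries a reference library
  of predicted test spectra plus real train/val spectra, ranked by cosine
  similarity (ties by candidate id).  A query scores when its own predicted
  spectrum ranks within `max(1, floor(0.05·n))` — the max(1,·) keeps tiny
  candidate sets from having a zero quota.  The top-5% score is the scoring
  fraction.

## Synthetic benchmark

Licensed spectral libraries cannot ship with the package, so the study
conditions are synthetic.  The generator concatenates building blocks —
`CC`, `CCC`, `CO`, `CN`, benzene, pyridine, thiophene, optional terminal
halides — into 2–5-block molecules (≤ 20 heavy atoms), which plants known
frequent substructures for the miner to recover.  Three aromatic ring types
are included deliberately: with a single ring type almost the whole corpus
shares two Murcko scaffolds and a scaffold-disjoint split degenerates;
aromatic (not aliphatic) rings keep ring closure during mining distinct
from alkyl-chain merges.  Spectra are the molecular-ion isotope envelope
plus single-cleavage fragment peaks decaying as `exp(−0.3 · d)` with `d`
the cleaved bond's distance to the nearest chain terminus, times
multiplicative Gaussian noise (σ = 0.05, clipped at zero).  Defaults:
300 molecules, seeded and fully deterministic.

The simulation is deliberately naive chemistry: no rearrangements, radical
cations, adducts, collision-energy dependence or profile-mode peaks.
Passing tests therefore demonstrate that the pipeline mines, assembles,
trains and evaluates correctly and that the motif machinery carries signal
for a fragmentation-like structure-to-spectrum map — not that the model
reaches any particular accuracy on real tandem-MS libraries.

Problem sizes used by the checks: the learning tests train width-64
encoders on a corpus whose training partition holds ~50 molecules for up to
200 epochs (capacity: training-set similarity > 0.9; ablating the
motif-spectrum feature lowers best validation similarity in ≥ 3 of 5
seeds).  The acceptance script runs the full pipeline at n = 300 / K = 300
/ width 64 with early stopping and reports test similarity, the top-5%
identification score and planted-motif recovery.

## Known limitations

- The merge-and-update validity rule (sanitizable hydrogen-capped
  structure) and the overlap policy are explicit substitutes for choices
  the method's description leaves open.
- Motif–motif adjacency by same-molecule co-occurrence is a declared
  relaxation (see above).
- Hidden width, head depth and sampler sizes of the original-scale model
  are not recoverable from public information; defaults here are desk
  scale, and reported numbers are synthetic-benchmark quantities, not
  library-scale ones.
- Single-charge, single-adduct, unit-resolution spectra only.
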