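# motifms

Predicting tandem-MS fragmentation spectra from molecular structure, for
computational mass spectrometrists and cheminformaticians who need to
augment spectral libraries or rank candidate structures against measured
spectra.

## The method

A mass spectrum is represented as a vector of intensities **I** over 1 Da
m/z bins (1..M_max, default 1000).  The predictor combines three sources of
structural information:

1. **A mined motif vocabulary.**  Byte-pair-encoding lifted to molecular
   graphs: starting from single-atom fragments, the corpus-wide most
   frequent pair of adjacent fragments is merged each iteration; valid
   merged structures enter the vocabulary (top *K* = 300 by default).
   Frequent motifs — `CC`, `CO`, benzene rings — correspond to functional
   groups and recurring fragment ions.
2. **A heterogeneous molecule–motif graph** over the |N| corpus molecules
   and |V| motifs, weighted by

   ```
            ⎧ PMI(i,j)     i, j motifs        PMI(i,j)   = log( N(i,j)·M / (N(i)·N(j)) )
   A_ij  =  ⎨ TFIDF(i,j)   i or j a motif     TFIDF(i,j) = C(i)_j · ( log((1+M)/(1+N(i))) + 1 )
            ⎩ 0            otherwise
   ```

   with M molecules, N(i) the motif's document count, N(i,j) the pair
   document count and C(i)_j the occurrence multiplicity.  Motif
   relationships are modeled at the (sub)graph level, which sidesteps the
   long-range-dependency / oversmoothing limits of deep node-level message
   passing.
3. **Motif mass spectra**: each motif's molecular-ion isotope envelope plus
   a few generated single-cleavage fragments (optionally replaced by real
   electron-impact library spectra).

A 3-layer graph convolutional network encodes the molecule graph (with an
RDKit topological fingerprint at readout); a 3-layer graph isomorphism
network encodes a BFS-sampled `[s1,s2,s3]` neighborhood of the molecule's
node in the heterogeneous graph; both embeddings, plus the molecule's
occurrence-weighted motif-spectrum profile, feed an MLP head that emits the
binned spectrum Î.  Training minimizes the cosine distance

```
CD(I, Î) = 1 − ⟨I, Î⟩ / (‖I‖₂ ‖Î‖₂)
```

on a Murcko-scaffold-disjoint 70/20/10 split; evaluation reports the cosine
similarity of normalized spectra and the top-5% library-identification
score.  See `docs/methods.md` for assumptions, parameter defaults and
limitations.

Licensed spectral libraries cannot ship with the package, so a synthetic
module generates corpora with planted substructures and simulated
fragmentation spectra (isotope satellites, cleavage-fragment peaks,
intensity noise); everything is testable offline end to end.

## Worked example

```python
from motifms import SpectrumModel, SynthConfig, make_dataset

data = make_dataset(SynthConfig(n_molecules=100, rng_seed=7))
model = SpectrumModel(data.molecules, data.spectra, split=data.split,
                      vocab_size=100, d_hidden=64)
res = model.fit(seed=0, n_epochs=60, patience=15)
print(res.summary())

rep = res.evaluate(partition="test")
print(f"test cosine similarity: {rep.mean:.3f} +/- {rep.std:.3f}")
rank = res.rank()
print(f"top-5% identification score: {rank.top5_score:.3f}")
```

prints

```
Motif-graph spectrum predictor
==============================================
Molecules                                  100
  train / val / test              70 / 20 / 10
Motif vocabulary |V|                        86
m/z bins (M_max)                          1000
Hidden width                                64
Trainable parameters                    418537
Epochs run                                  28
Final train cosine loss                 0.0947
Best val cosine similarity              0.3047
Best epoch                                  11
==============================================
test cosine similarity: 0.339 +/- 0.126
top-5% identification score: 0.300
```

Mining the 100-molecule corpus gave an 86-motif vocabulary (the corpus
exhausted before the K = 100 budget).  Training stopped after 28 epochs;
the best validation cosine similarity (0.30) came at epoch 11 and those
weights were restored.  On the 10 held-out-scaffold test molecules the
predicted spectra reach a mean cosine similarity of 0.34 against the true
spectra, and 3 of the 10 test queries rank their own predicted spectrum
within the top 5% of a 100-spectrum reference library (a random predictor
scores ≈ 0.05).

The same pipeline is scriptable from the shell:

```sh
motifms make-synthetic --n 300 --seed 7 --out data/
motifms build-vocab --smiles data/corpus.smi --k 300 --out vocab.tsv
motifms build-graph --smiles data/corpus.smi --vocab vocab.tsv --out graph/
motifms rank --query q.msp --reference r.msp --report rank.json
```

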