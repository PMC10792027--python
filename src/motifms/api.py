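"""Model / Results front end.

:class:`SpectrumModel` bundles a corpus, its spectra and the derived motif
machinery (vocabulary, heterogeneous graph, motif spectra); ``fit`` trains
the predictor and returns a :class:`SpectrumResults` carrying the weights,
the training log and evaluation / ranking / summary methods.
"""

from __future__ import annotations

import numpy as np

from .hetero_graph import SamplerConfig
from .model import ModelConfig, count_parameters
from .molio import Spectrum, bin_spectrum, parse_smiles, read_msp, read_smiles_file
from .train_eval import (
    SpectrumDataset,
    evaluate_similarity,
    rank_candidates,
    scaffold_split,
    train,
)


class SpectrumModel:
    """A mass-spectrum predictor specified by a corpus and its spectra.

    Building the model mines the motif vocabulary from the training
    partition, constructs the heterogeneous molecule-motif graph and the
    motif spectrum table; ``fit`` then trains the two-encoder network.

    Parameters
    ----------
    molecules, spectra : aligned lists of :class:`Molecule` / :class:`Spectrum`.
    split : optional precomputed scaffold split; derived from ``split_seed``
        with 70/20/10 ratios when omitted.
    vocab_size : motif vocabulary budget K (mining iterations).
    d_hidden : embedding width of the default config.
    config : optional :class:`ModelConfig`; a default one (matching the
        vocabulary actually mined) is created when omitted.
    """

    def __init__(self, molecules, spectra, split=None, vocab_size: int = 300,
                 m_max: int = 1000, d_hidden: int = 256,
                 config: ModelConfig | None = None,
                 split_seed: int = 0, split_ratios=(0.7, 0.2, 0.1)):
        if split is None:
            split = scaffold_split(molecules, ratios=split_ratios, rng_seed=split_seed)
        fingerprint_bits = config.fingerprint_bits if config else 2048
        self.dataset = SpectrumDataset.build(
            molecules, spectra, split, K=vocab_size, m_max=m_max,
            fingerprint_bits=fingerprint_bits)
        if config is None:
            config = ModelConfig(vocab_size=len(self.dataset.vocab), m_max=m_max,
                                 d_hidden=d_hidden,
                                 fingerprint_bits=fingerprint_bits)
        elif config.vocab_size != len(self.dataset.vocab):
            raise ValueError(
                f"config.vocab_size={config.vocab_size} but vocabulary has "
                f"{len(self.dataset.vocab)} motifs")
        self.config = config

    @classmethod
    def from_files(cls, smiles_path, msp_path, **kwargs) -> "SpectrumModel":
        """Build from a .smi corpus and an MSP library matched by record id."""
        mols = read_smiles_file(smiles_path)
        records = {name: peaks for name, peaks, _ in read_msp(msp_path)}
        molecules, spectra = [], []
        m_max = kwargs.get("m_max", 1000)
        for mol_id, mol in mols:
            if mol_id not in records:
                raise KeyError(f"no spectrum for molecule {mol_id!r}")
            molecules.append(mol)
            spectra.append(bin_spectrum(records[mol_id], m_max=m_max))
        return cls(molecules, spectra, **kwargs)

    def fit(self, seed: int = 0, n_epochs: int = 200, batch_size: int = 16,
            lr: float = 1e-3, patience: int = 10,
            restore_best: bool = True) -> "SpectrumResults":
        params, log = train(self.dataset, self.config, rng_seed=seed,
                            n_epochs=n_epochs, batch_size=batch_size, lr=lr,
                            patience=patience, restore_best=restore_best)
        return SpectrumResults(self, params, log, seed=seed)


class SpectrumResults:
    """Fitted predictor: weights, training log, evaluation utilities."""

    def __init__(self, model: SpectrumModel, params, log, seed: int = 0):
        self.model = model
        self.params = params
        self.log = log
        self.seed = seed

    @property
    def n_parameters(self) -> int:
        return count_parameters(self.params)

    def predict(self, indices=None, partition: str = "test") -> list:
        """Predicted spectra for molecule indices (default: a partition)."""
        ds = self.model.dataset
        if indices is None:
            indices = ds.split.indices(partition)
        return [ds.predict(int(i), self.params, self.model.config,
                           sampler_seed=self.seed) for i in indices]

    def evaluate(self, partition: str = "test"):
        ds = self.model.dataset
        return evaluate_similarity(ds, self.params, self.model.config,
                                   ds.split.indices(partition),
                                   sampler_seed=self.seed)

    def rank(self, partition: str = "test"):
        """Identification task: real spectra of ``partition`` as queries;
        reference = predicted spectra of that partition plus the real
        train/val spectra."""
        ds = self.model.dataset
        test_idx = ds.split.indices(partition)
        preds = self.predict(indices=test_idx)
        reference = [(f"pred_{i}", preds[k]) for k, i in enumerate(test_idx)]
        for part in ("train", "val"):
            reference += [(f"real_{i}", ds.spectra[int(i)])
                          for i in ds.split.indices(part)]
        queries = [(f"query_{i}", ds.spectra[int(i)], f"pred_{i}")
                   for i in test_idx]
        return rank_candidates(queries, reference)

    def summary(self) -> str:
        ds = self.model.dataset
        cfg = self.model.config
        n_epochs = len(self.log.epochs)
        final_loss = self.log.epochs[-1][1] if n_epochs else float("nan")
        lines = [
            "Motif-graph spectrum predictor",
            "=" * 46,
            f"{'Molecules':<30}{len(ds.molecules):>16}",
            f"{'  train / val / test':<30}"
            f"{'%d / %d / %d' % tuple(len(ds.split.indices(p)) for p in ('train', 'val', 'test')):>16}",
            f"{'Motif vocabulary |V|':<30}{len(ds.vocab):>16}",
            f"{'m/z bins (M_max)':<30}{ds.m_max:>16}",
            f"{'Hidden width':<30}{cfg.d_hidden:>16}",
            f"{'Trainable parameters':<30}{self.n_parameters:>16}",
            f"{'Epochs run':<30}{n_epochs:>16}",
            f"{'Final train cosine loss':<30}{final_loss:>16.4f}",
            f"{'Best val cosine similarity':<30}{self.log.best_val_similarity:>16.4f}",
            f"{'Best epoch':<30}{self.log.best_epoch:>16}",
            "=" * 46,
        ]
        return "\n".join(lines)


def multi_seed_evaluate(model: SpectrumModel, seeds, partition: str = "test",
                        **fit_kwargs):
    """Table-style protocol: refit per seed, report mean +/- std of the
    partition's mean cosine similarity across seeds."""
    means = []
    for seed in seeds:
        res = model.fit(seed=seed, **fit_kwargs)
        means.append(res.evaluate(partition=partition).mean)
    return float(np.mean(means)), float(np.std(means))
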