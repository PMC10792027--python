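"""Synthetic molecule corpora and simulated fragmentation spectra.

Real tandem-MS training libraries are license-restricted, so every pipeline
stage is exercised on generated data instead.  Molecules are assembled by
concatenating building blocks from a small alphabet (alkyl chains, ether /
amine linkers, aromatic rings, terminal halides), which plants known
frequent substructures for the miner to recover and gives the corpus enough
ring-system diversity for scaffold-disjoint splitting to be meaningful.  Spectra follow the
coarse statistical shape the model assumes: a molecular-ion peak with its
isotope satellites, one peak per single-cleavage fragment whose intensity
decays exponentially with the cleaved bond's distance from the nearest
chain terminus, and multiplicative intensity noise.  The simulation is
deliberately naive chemistry — its purpose is a learnable structure-to-
spectrum mapping, not fragmentation physics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .molio import (
    DEFAULT_M_MAX,
    Molecule,
    Spectrum,
    bin_spectrum,
    parse_smiles,
    write_msp,
    write_smiles_file,
)
from .motif_spectra import (
    _capped_formula,
    _formula_monoisotopic_mass,
    isotope_pattern,
)
from .train_eval import scaffold_split

#: chainable blocks (left) concatenate by SMILES juxtaposition; terminal
#: blocks (right) may only end a molecule
DEFAULT_ALPHABET = ("CC", "CCC", "CO", "CN", "c1ccccc1", "c1ccncc1", "c1ccsc1")
DEFAULT_TERMINALS = ("Cl", "F", "")


@dataclass(frozen=True)
class SynthConfig:
    n_molecules: int = 300
    rng_seed: int = 0
    alphabet: tuple = DEFAULT_ALPHABET
    terminals: tuple = DEFAULT_TERMINALS
    max_heavy_atoms: int = 20
    min_blocks: int = 2
    max_blocks: int = 5
    noise_sigma: float = 0.05
    fragment_decay: float = 0.3
    m_max: int = DEFAULT_M_MAX

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def generate_corpus(cfg: SynthConfig) -> list:
    """Deterministic per-seed corpus of valid molecules.

    Each molecule is a random chain of alphabet blocks (optionally ending in
    a terminal halide); invalid or oversized draws are rejected and redrawn,
    so every returned molecule parses and sanitizes.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    corpus, seen = [], set()
    while len(corpus) < cfg.n_molecules:
        n_blocks = int(rng.integers(cfg.min_blocks, cfg.max_blocks + 1))
        smiles = "".join(rng.choice(cfg.alphabet) for _ in range(n_blocks))
        smiles += rng.choice(cfg.terminals)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None or mol.GetNumAtoms() > cfg.max_heavy_atoms:
            continue
        parsed = parse_smiles(smiles)
        # duplicates are allowed only until enough distinct structures exist
        if parsed.smiles in seen and len(seen) < cfg.n_molecules // 2:
            continue
        seen.add(parsed.smiles)
        corpus.append(parsed)
    return corpus


def _bond_terminal_distance(rd: Chem.Mol, bond) -> int:
    """Graph distance (in bonds) from the cleaved bond to the nearest
    degree-1 heavy atom; 0 when the bond touches a terminus."""
    terminals = [a.GetIdx() for a in rd.GetAtoms() if a.GetDegree() == 1]
    if not terminals:
        return 0
    dmat = Chem.GetDistanceMatrix(rd)
    ends = (bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
    return int(min(dmat[e, t] for e in ends for t in terminals))


def simulate_spectrum(mol: Molecule, cfg: SynthConfig,
                      rng: np.random.Generator) -> Spectrum:
    """Simulated fragmentation spectrum on the binned grid.

    Molecular-ion isotope envelope at base intensity 1, single-cleavage
    fragment peaks at intensity exp(-lambda * distance-to-terminal), then
    multiplicative Gaussian noise (sigma), clipped at zero.  With sigma = 0
    the spectrum is a pure function of structure.
    """
    pattern = isotope_pattern(mol.formula, monoisotopic_mass=mol.exact_mass)
    peaks = list(pattern.peaks)
    rd = mol.to_rdkit()
    for bond in rd.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        dist = _bond_terminal_distance(rd, bond)
        inten = float(np.exp(-cfg.fragment_decay * dist))
        frag = Chem.FragmentOnBonds(rd, [bond.GetIdx()], addDummies=False)
        for atom_ids in Chem.GetMolFrags(frag):
            mass = _formula_monoisotopic_mass(_capped_formula(frag, atom_ids))
            peaks.append((mass, inten))
    spectrum = bin_spectrum(peaks, m_max=cfg.m_max, metadata={"SMILES": mol.smiles})
    if cfg.noise_sigma > 0:
        noise = 1.0 + cfg.noise_sigma * rng.standard_normal(cfg.m_max)
        spectrum.intensities = np.clip(spectrum.intensities * noise, 0.0, None)
    return spectrum


@dataclass
class SyntheticDataset:
    molecules: list
    spectra: list
    split: "object"
    ids: list = field(default_factory=list)


def make_dataset(cfg: SynthConfig, out_dir=None,
                 split_ratios=(0.7, 0.2, 0.1)) -> SyntheticDataset:
    """Corpus + spectra + scaffold split; optionally written to ``out_dir``
    as corpus.smi, spectra.msp and split.json."""
    corpus = generate_corpus(cfg)
    rng = np.random.default_rng(cfg.rng_seed + 1)
    spectra = [simulate_spectrum(m, cfg, rng) for m in corpus]
    split = scaffold_split(corpus, ratios=split_ratios, rng_seed=cfg.rng_seed)
    ids = [f"mol_{i:04d}" for i in range(len(corpus))]
    ds = SyntheticDataset(molecules=corpus, spectra=spectra, split=split, ids=ids)
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        write_smiles_file(zip(ids, corpus), os.path.join(out_dir, "corpus.smi"))
        write_msp(
            [(ids[i], spectra[i].to_peaks(), {"SMILES": corpus[i].smiles})
             for i in range(len(corpus))],
            os.path.join(out_dir, "spectra.msp"),
        )
        with open(os.path.join(out_dir, "split.json"), "w") as fh:
            json.dump({ids[i]: split.assignment[i] for i in range(len(corpus))}, fh,
                      indent=0)
    return ds
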