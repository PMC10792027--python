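"""Reference mass spectra for motifs.

Each vocabulary motif gets a synthetic spectrum built from first principles:
the isotope envelope of its (hydrogen-capped) molecular ion, computed by
exact polynomial convolution of per-element isotope distributions aggregated
at nominal mass, plus a peak for every single-cleavage fragment at a fixed
relative intensity.  Where a real electron-impact library spectrum for the
same structure is available it replaces the computed one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .molio import (
    DEFAULT_M_MAX,
    Molecule,
    Spectrum,
    bin_spectrum,
    parse_smiles,
    read_msp,
)
from .motif_vocab import MotifVocabulary

logger = logging.getLogger(__name__)

# (mass-number offset from the lightest isotope, abundance); IUPAC 2021
# representative values.
ISOTOPES = {
    "H": [(0, 0.999885), (1, 0.000115)],
    "C": [(0, 0.9893), (1, 0.0107)],
    "N": [(0, 0.99636), (1, 0.00364)],
    "O": [(0, 0.99757), (1, 0.00038), (2, 0.00205)],
    "S": [(0, 0.9499), (1, 0.0075), (2, 0.0425), (4, 0.0001)],
    "P": [(0, 1.0)],
    "F": [(0, 1.0)],
    "Cl": [(0, 0.7576), (2, 0.2424)],
    "Br": [(0, 0.5069), (2, 0.4931)],
    "I": [(0, 1.0)],
}

#: mean mass spacing between adjacent nominal isotope peaks, Da
_NEUTRON_SPACING = 1.0033


@dataclass(frozen=True)
class IsotopePattern:
    """Nominal-mass isotope envelope; abundances relative to the base peak
    (max = 1), masses strictly increasing."""

    peaks: tuple  # ((mass_da, rel_abundance), ...)

    @property
    def masses(self) -> tuple:
        return tuple(m for m, _ in self.peaks)

    @property
    def abundances(self) -> tuple:
        return tuple(a for _, a in self.peaks)


def _element_distribution(element: str, count: int) -> np.ndarray:
    """Isotopologue distribution of ``count`` atoms over nominal-mass
    offsets, by repeated polynomial convolution (exponentiation by
    squaring)."""
    iso = ISOTOPES[element]
    base = np.zeros(max(off for off, _ in iso) + 1)
    for off, ab in iso:
        base[off] = ab
    result = np.array([1.0])
    power = base
    n = count
    while n:
        if n & 1:
            result = np.convolve(result, power)
        n >>= 1
        if n:
            power = np.convolve(power, power)
    return result


def isotope_pattern(formula: dict, min_abundance: float = 1e-3,
                    monoisotopic_mass: float | None = None) -> IsotopePattern:
    """Exact isotope envelope of a molecular formula at nominal-mass
    resolution.

    Raises on elements outside the supported set
    {C, H, N, O, S, P, F, Cl, Br, I}.
    """
    if not formula:
        raise ValueError("formula must be non-empty")
    for el in formula:
        if el not in ISOTOPES:
            raise ValueError(f"unsupported element {el!r} in formula")
    dist = np.array([1.0])
    for el, n in sorted(formula.items()):
        dist = np.convolve(dist, _element_distribution(el, n))
    dist = dist / dist.max()
    if monoisotopic_mass is None:
        monoisotopic_mass = _formula_monoisotopic_mass(formula)
    peaks = tuple(
        (monoisotopic_mass + off * _NEUTRON_SPACING, float(ab))
        for off, ab in enumerate(dist)
        if ab >= min_abundance
    )
    return IsotopePattern(peaks=peaks)


_MONO_MASS = {
    "H": 1.0078250319, "C": 12.0, "N": 14.0030740052, "O": 15.9949146221,
    "S": 31.97207069, "P": 30.97376151, "F": 18.9984032, "Cl": 34.96885271,
    "Br": 78.9183376, "I": 126.904468,
}


def _formula_monoisotopic_mass(formula: dict) -> float:
    return sum(_MONO_MASS[el] * n for el, n in formula.items())


def generate_fragments(motif: Molecule, max_fragments: int = 6) -> list:
    """Single-cleavage fragment formulas of a motif.

    Every acyclic single bond is broken once; both hydrogen-capped sides are
    collected, deduplicated by formula, and the ``max_fragments`` heaviest
    are kept.  All-ring structures (e.g. benzene) yield no fragments.
    """
    rd = motif.to_rdkit()
    if rd.GetNumAtoms() < 2:
        return []
    formulas: dict = {}
    for bond in rd.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        frag = Chem.FragmentOnBonds(rd, [bond.GetIdx()], addDummies=False)
        for atom_ids in Chem.GetMolFrags(frag):
            piece = _capped_formula(frag, atom_ids)
            formulas[tuple(sorted(piece.items()))] = piece
    pieces = sorted(formulas.values(), key=_formula_monoisotopic_mass, reverse=True)
    return pieces[:max_fragments]


def _capped_formula(rdmol: Chem.Mol, atom_ids) -> dict:
    """Formula of a fragment with broken bonds hydrogen-capped."""
    counts: dict = {}
    h = 0
    for idx in atom_ids:
        atom = rdmol.GetAtomWithIdx(idx)
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        # implicit Hs plus one cap per valence freed by the cleavage
        h += atom.GetTotalNumHs() + atom.GetNumRadicalElectrons()
    if h:
        counts["H"] = counts.get("H", 0) + h
    return counts


@dataclass(frozen=True)
class MotifSpectrumConfig:
    m_max: int = DEFAULT_M_MAX
    min_abundance: float = 1e-3
    fragment_intensity: float = 0.2
    max_fragments: int = 6


def motif_spectrum(motif: Molecule, cfg: MotifSpectrumConfig | None = None) -> Spectrum:
    """Binned synthetic spectrum of a motif: molecular-ion isotope envelope
    (base peak 1.0) plus one peak per generated fragment at the configured
    relative intensity."""
    cfg = cfg or MotifSpectrumConfig()
    pattern = isotope_pattern(motif.formula, cfg.min_abundance,
                              monoisotopic_mass=motif.exact_mass)
    peaks = list(pattern.peaks)
    for formula in generate_fragments(motif, cfg.max_fragments):
        peaks.append((_formula_monoisotopic_mass(formula), cfg.fragment_intensity))
    return bin_spectrum(peaks, m_max=cfg.m_max, metadata={"source": "computed"})


@dataclass
class MotifSpectrumTable:
    """One spectrum per vocabulary motif with its provenance flag
    (``computed`` or ``reference``)."""

    spectra: dict  # label -> Spectrum
    sources: dict  # label -> "computed" | "reference"

    def matrix(self, vocab: MotifVocabulary, m_max: int) -> np.ndarray:
        """(|V|, m_max) stacked intensity rows in vocabulary rank order."""
        return np.stack([self.spectra[lab].intensities[:m_max]
                         for lab in vocab.motifs]) if len(vocab) else np.zeros((0, m_max))


def build_motif_spectra(vocab: MotifVocabulary,
                        cfg: MotifSpectrumConfig | None = None) -> MotifSpectrumTable:
    cfg = cfg or MotifSpectrumConfig()
    spectra, sources = {}, {}
    for label in vocab.motifs:
        spectra[label] = motif_spectrum(parse_smiles(label), cfg)
        sources[label] = "computed"
    return MotifSpectrumTable(spectra=spectra, sources=sources)


def load_reference_spectra(msp_path, vocab: MotifVocabulary,
                           table: MotifSpectrumTable,
                           m_max: int = DEFAULT_M_MAX) -> int:
    """Override computed motif spectra with matching real library records.

    Records are matched to motifs by the canonical SMILES of the
    hydrogen-capped motif (from the record's ``SMILES`` metadata field);
    the first match wins, duplicates warn.  Returns the override count.
    """
    canon = {}
    for label in vocab.motifs:
        canon[parse_smiles(label).smiles] = label
    n_overridden = 0
    for name, peaks, meta in read_msp(msp_path):
        smiles = meta.get("SMILES") or meta.get("Smiles") or meta.get("smiles")
        if not smiles:
            continue
        try:
            key = parse_smiles(smiles).smiles
        except ValueError:
            continue
        label = canon.get(key)
        if label is None:
            continue
        if table.sources.get(label) == "reference":
            logger.warning("duplicate reference spectrum for motif %r (record %r); keeping first",
                           label, name)
            continue
        table.spectra[label] = bin_spectrum(peaks, m_max=m_max,
                                            metadata={"source": "reference", "record": name})
        table.sources[label] = "reference"
        n_overridden += 1
    return n_overridden


def save_motif_spectra(table: MotifSpectrumTable, vocab: MotifVocabulary, path) -> None:
    """Persist the table as one MSP record per motif, keyed by rank."""
    records = []
    for rank, label in enumerate(vocab.motifs):
        s = table.spectra[label]
        records.append((f"motif_{rank}", s.to_peaks(),
                        {"SMILES": label, "Source": table.sources[label]}))
    from .molio import write_msp

    write_msp(records, path)
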