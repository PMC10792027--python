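"""Molecule parsing, graph featurization and binned mass-spectrum I/O.

Molecules are heavy-atom graphs (hydrogens implicit, kept as atom-level
counts).  Spectra live on a fixed integer m/z grid: bin ``k`` collects every
peak whose m/z rounds to ``k`` (half-up), 1-based up to ``M_max``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdmolops
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: default m/z grid: 1 Da bins, 1-based, up to 1000 Da
DEFAULT_M_MAX = 1000
DEFAULT_BIN_WIDTH = 1.0


class ParseError(ValueError):
    """Raised when a SMILES string cannot be parsed and sanitized."""


@dataclass(frozen=True)
class Molecule:
    """A sanitized molecule with canonical identity.

    ``atoms`` holds per-atom tuples ``(symbol, formal_charge, aromatic,
    degree, num_H)``; ``bonds`` holds ``(i, j, order)`` with ``i < j`` and
    ``order`` one of ``single|double|triple|aromatic``.
    """

    smiles: str
    atoms: tuple
    bonds: tuple
    exact_mass: float
    formula: dict

    @property
    def num_atoms(self) -> int:
        return len(self.atoms)

    def to_rdkit(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


_BOND_ORDER = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


def _formula_counts(mol: Chem.Mol) -> dict:
    counts: dict = {}
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        h = atom.GetTotalNumHs()
        if h:
            counts["H"] = counts.get("H", 0) + h
    return counts


def parse_smiles(text: str) -> Molecule:
    """Parse a SMILES string into a sanitized :class:`Molecule`.

    Raises :class:`ParseError` naming the offending input on unparseable or
    valence-violating SMILES.
    """
    if not text or not text.strip():
        raise ParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(text.strip())
    if mol is None:
        raise ParseError(f"cannot parse SMILES {text.strip()!r}")
    canonical = Chem.MolToSmiles(mol)
    mol = Chem.MolFromSmiles(canonical)  # re-parse so atom order is canonical
    atoms = tuple(
        (
            a.GetSymbol(),
            a.GetFormalCharge(),
            a.GetIsAromatic(),
            a.GetDegree(),
            a.GetTotalNumHs(),
        )
        for a in mol.GetAtoms()
    )
    bonds = tuple(
        sorted(
            (
                min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                _BOND_ORDER[b.GetBondType()],
            )
            for b in mol.GetBonds()
        )
    )
    return Molecule(
        smiles=canonical,
        atoms=atoms,
        bonds=bonds,
        exact_mass=Descriptors.ExactMolWt(mol),
        formula=_formula_counts(mol),
    )


# ---------------------------------------------------------------------------
# Graph featurization

_ELEMENTS = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")  # + "other"
_MAX_DEGREE = 5
_CHARGES = (-2, -1, 0, 1, 2)
_MAX_H = 4
_BOND_CATS = ("single", "double", "triple", "aromatic")

ATOM_FEATURE_DIM = len(_ELEMENTS) + 1 + (_MAX_DEGREE + 1) + len(_CHARGES) + 1 + (_MAX_H + 1)
BOND_FEATURE_DIM = len(_BOND_CATS) + 2


@dataclass(frozen=True)
class FeaturizationConfig:
    fingerprint_bits: int = 2048


@dataclass(frozen=True)
class MoleculeGraph:
    node_features: np.ndarray  # (n_atoms, ATOM_FEATURE_DIM)
    edge_index: np.ndarray  # (n_directed_edges, 2)
    edge_features: np.ndarray  # (n_directed_edges, BOND_FEATURE_DIM)
    fingerprint: np.ndarray  # (F,) uint8 in {0, 1}


def _one_hot(value, choices) -> list:
    return [1.0 if value == c else 0.0 for c in choices]


def featurize_molecule(mol: Molecule, cfg: FeaturizationConfig | None = None) -> MoleculeGraph:
    """Build the per-atom / per-bond feature graph for a molecule.

    Both directions of every bond are materialized.  A single-atom molecule
    yields one node and no edges.
    """
    cfg = cfg or FeaturizationConfig()
    rd = mol.to_rdkit()
    rows = []
    for atom in rd.GetAtoms():
        sym = atom.GetSymbol()
        row = _one_hot(sym if sym in _ELEMENTS else "other", _ELEMENTS + ("other",))
        row += _one_hot(min(atom.GetDegree(), _MAX_DEGREE), range(_MAX_DEGREE + 1))
        row += _one_hot(atom.GetFormalCharge(), _CHARGES)
        row += [1.0 if atom.GetIsAromatic() else 0.0]
        row += _one_hot(min(atom.GetTotalNumHs(), _MAX_H), range(_MAX_H + 1))
        rows.append(row)
    edges, efeat = [], []
    for bond in rd.GetBonds():
        cat = _BOND_ORDER[bond.GetBondType()]
        feat = _one_hot(cat, _BOND_CATS)
        feat += [1.0 if bond.IsInRing() else 0.0, 1.0 if bond.GetIsConjugated() else 0.0]
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges += [(i, j), (j, i)]
        efeat += [feat, feat]
    return MoleculeGraph(
        node_features=np.asarray(rows, dtype=float),
        edge_index=np.asarray(edges, dtype=int).reshape(-1, 2),
        edge_features=np.asarray(efeat, dtype=float).reshape(-1, BOND_FEATURE_DIM),
        fingerprint=compute_fingerprint(mol, cfg.fingerprint_bits),
    )


def compute_fingerprint(mol: Molecule, F: int = 2048) -> np.ndarray:
    """Topological path-based binary fingerprint of length ``F`` (F >= 64)."""
    if F < 64:
        raise ValueError(f"fingerprint length must be >= 64, got {F}")
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=F)
    bv = gen.GetFingerprint(mol.to_rdkit())
    arr = np.zeros(F, dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return arr


# ---------------------------------------------------------------------------
# Spectra

@dataclass
class Spectrum:
    """A binned mass spectrum: ``intensities[k - 1]`` is the intensity in the
    1-based integer m/z bin ``k``."""

    intensities: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def m_max(self) -> int:
        return len(self.intensities)

    def intensity_at(self, mz_bin: int) -> float:
        """Intensity of the 1-based integer bin ``mz_bin``."""
        return float(self.intensities[mz_bin - 1])

    def to_peaks(self) -> list:
        """Non-zero bins as (m/z, intensity) pairs."""
        idx = np.nonzero(self.intensities)[0]
        return [(float(k + 1), float(self.intensities[k])) for k in idx]


def bin_spectrum(peaks, m_max: int = DEFAULT_M_MAX, bin_width: float = DEFAULT_BIN_WIDTH,
                 metadata: dict | None = None) -> Spectrum:
    """Aggregate (m/z, intensity) peaks onto the integer bin grid.

    Bin assignment is half-up rounding of ``mz / bin_width``; peaks landing
    outside ``1..m_max`` are dropped (count logged).  Total in-range intensity
    is conserved exactly.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not peaks:
        raise ValueError("peaks must be non-empty")
    out = np.zeros(m_max, dtype=float)
    dropped = 0
    for mz, inten in peaks:
        k = int(math.floor(mz / bin_width + 0.5))
        if 1 <= k <= m_max:
            out[k - 1] += inten
        else:
            dropped += 1
    if dropped:
        logger.warning("bin_spectrum: dropped %d peak(s) outside 1..%d", dropped, m_max)
    return Spectrum(intensities=out, metadata=dict(metadata or {}))


def normalize_spectrum(s: Spectrum) -> Spectrum:
    """Scale to unit Euclidean norm; errors on an all-zero spectrum."""
    norm = float(np.linalg.norm(s.intensities))
    if norm == 0.0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return Spectrum(intensities=s.intensities / norm, metadata=dict(s.metadata))


# ---------------------------------------------------------------------------
# MSP spectral-library I/O
#
# MSP is a line-oriented "Key: value" block format terminated by a peak table
# announced with "Num Peaks: n".  The format is trivial enough that parsing it
# directly lets malformed blocks be rejected by record name, which library
# readers silently tolerate.

class MSPFormatError(ValueError):
    pass


def read_msp(path) -> list:
    """Read an MSP library: list of ``(name, peaks, metadata)`` records.

    ``peaks`` is a list of (m/z, intensity) floats.  A record whose peak table
    does not match its declared ``Num Peaks`` raises :class:`MSPFormatError`
    naming the record.
    """
    records = []
    name, meta, peaks, expected = None, {}, [], None

    def flush():
        nonlocal name, meta, peaks, expected
        if name is None and not meta and not peaks:
            return
        if expected is None or len(peaks) != expected:
            raise MSPFormatError(
                f"record {name!r}: declared {expected} peaks, found {len(peaks)}"
            )
        records.append((name, peaks, meta))
        name, meta, peaks, expected = None, {}, [], None

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                if expected is not None:
                    flush()
                continue
            if expected is not None and expected > len(peaks):
                parts = line.replace(";", " ").split()
                try:
                    mz, inten = float(parts[0]), float(parts[1])
                except (IndexError, ValueError) as exc:
                    raise MSPFormatError(
                        f"record {name!r}: bad peak line {line!r}"
                    ) from exc
                peaks.append((mz, inten))
                continue
            if ":" in line:
                key, _, value = line.partition(":")
                key, value = key.strip(), value.strip()
                if key.lower() == "name":
                    name = value
                elif key.lower() == "num peaks":
                    expected = int(value)
                else:
                    meta[key] = value
            else:
                raise MSPFormatError(f"record {name!r}: unexpected line {line!r}")
    flush()
    return records


def write_msp(records, path) -> None:
    """Write ``(name, peaks, metadata)`` records to an MSP file.

    Inverse of :func:`read_msp`; peak values are written with 4 decimals.
    """
    with open(path, "w") as fh:
        for name, peaks, meta in records:
            fh.write(f"Name: {name}\n")
            for key, value in meta.items():
                fh.write(f"{key}: {value}\n")
            fh.write(f"Num Peaks: {len(peaks)}\n")
            for mz, inten in peaks:
                fh.write(f"{mz:.4f} {inten:.4f}\n")
            fh.write("\n")


def read_smiles_file(path) -> list:
    """Read a .smi file: one SMILES (+ optional tab-separated id) per line.

    Returns a list of ``(id, Molecule)``; ids default to the line number.
    """
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            mol_id = parts[1].strip() if len(parts) > 1 else str(lineno)
            out.append((mol_id, parse_smiles(smiles)))
    return out


def write_smiles_file(records, path) -> None:
    """Write ``(id, Molecule)`` pairs as SMILES<TAB>id lines."""
    with open(path, "w") as fh:
        for mol_id, mol in records:
            fh.write(f"{mol.smiles}\t{mol_id}\n")
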