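"""Molecular graph data model, SMILES/SDF I/O, atom featurisation, Morgan fingerprints.

Molecules are represented as lightweight :class:`MoleculeGraph` objects wrapping a
sanitised RDKit ``Mol``. Every downstream stage (enumeration, scoring, dataset
assembly, the GNN models) consumes this type, so atom ordering is fixed here once:
it equals the order of atoms in the input SMILES/SDF record.

Atom features follow the six-attribute scheme used for node regression on
molecular graphs: element type, implicit-hydrogen count, heavy-neighbour count,
formal charge, ring membership, and aromaticity, concatenated into a fixed
42-dimensional vector (see :data:`FEATURE_LENGTH` and the block layout below).
Bond features are deliberately not encoded; the graph connectivity enters the
models only through the (unweighted) adjacency.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "AtomRecord",
    "MoleculeGraph",
    "SmilesParseError",
    "ELEMENT_VOCABULARY",
    "FEATURE_LENGTH",
    "FINGERPRINT_BITS",
    "FINGERPRINT_RADIUS",
    "parse_smiles",
    "canonical_smiles",
    "featurize_atom",
    "featurize_molecule",
    "morgan_fingerprint",
    "read_smiles_file",
    "read_csv_file",
    "read_sdf_file",
    "read_molecules",
    "write_smiles_csv",
]

#: Element one-hot vocabulary: 27 named elements (organic subset, halogens, common
#: hetero/metal atoms) plus one trailing "other" slot = 28 entries. The vocabulary
#: is a configuration constant; together with the count blocks below it pins the
#: atom representation at exactly 42 dimensions.
ELEMENT_VOCABULARY: tuple[str, ...] = (
    "B", "C", "N", "O", "F", "Na", "Mg", "Al", "Si", "P", "S", "Cl",
    "K", "Ca", "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "As", "Se", "Br",
    "Sn", "I", "Pt", "Li",
)

_IMPLICIT_H_SLOTS = 5   # one-hot over {0, 1, 2, 3, 4}, clipped to top slot
_HEAVY_DEGREE_SLOTS = 6  # one-hot over {0, ..., 5}, clipped to top slot

#: Total atom feature length: 28 (element) + 5 (implicit H) + 6 (heavy degree)
#: + 1 (formal charge, clipped to [-1, 1]) + 1 (ring flag) + 1 (aromatic flag).
FEATURE_LENGTH = len(ELEMENT_VOCABULARY) + 1 + _IMPLICIT_H_SLOTS + _HEAVY_DEGREE_SLOTS + 3

FINGERPRINT_RADIUS = 2
FINGERPRINT_BITS = 1024

_morgan_generator = rdFingerprintGenerator.GetMorganGenerator(
    radius=FINGERPRINT_RADIUS, fpSize=FINGERPRINT_BITS
)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed/sanitised."""

    def __init__(self, smiles: str, reason: str = "unparsable SMILES"):
        self.smiles = smiles
        super().__init__(f"{reason}: {smiles!r}")


@dataclass(frozen=True)
class AtomRecord:
    """Chemical attributes of one heavy atom, in graph order."""

    element: str
    implicit_h: int
    heavy_degree: int
    formal_charge: int
    in_ring: bool
    aromatic: bool
    index: int


@dataclass
class MoleculeGraph:
    """A sanitised molecular graph with stable atom ordering.

    ``bonds`` holds ``(i, j, order)`` with ``i < j`` and order one of
    ``"single" | "double" | "triple" | "aromatic"``.
    """

    id: str
    rdkit_mol: Chem.Mol
    smiles: str = field(default="")

    def __post_init__(self) -> None:
        if not self.smiles:
            self.smiles = Chem.MolToSmiles(self.rdkit_mol)

    @property
    def n_atoms(self) -> int:
        return self.rdkit_mol.GetNumAtoms()

    @property
    def atoms(self) -> list[AtomRecord]:
        return [_atom_record(a) for a in self.rdkit_mol.GetAtoms()]

    @property
    def bonds(self) -> list[tuple[int, int, str]]:
        out = []
        for b in self.rdkit_mol.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            if i > j:
                i, j = j, i
            out.append((i, j, _BOND_NAMES.get(b.GetBondType(), "single")))
        return sorted(out)

    def adjacency(self) -> np.ndarray:
        """Unweighted symmetric adjacency matrix (no self loops)."""
        n = self.n_atoms
        adj = np.zeros((n, n), dtype=np.float64)
        for i, j, _ in self.bonds:
            adj[i, j] = adj[j, i] = 1.0
        return adj

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MoleculeGraph(id={self.id!r}, smiles={self.smiles!r})"


_BOND_NAMES = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


def _atom_record(atom: Chem.Atom) -> AtomRecord:
    return AtomRecord(
        element=atom.GetSymbol(),
        implicit_h=atom.GetTotalNumHs(),
        heavy_degree=atom.GetDegree(),
        formal_charge=atom.GetFormalCharge(),
        in_ring=atom.IsInRing(),
        aromatic=atom.GetIsAromatic(),
        index=atom.GetIdx(),
    )


def parse_smiles(smiles: str, mol_id: str | None = None) -> MoleculeGraph:
    """Parse and sanitise a SMILES string into a :class:`MoleculeGraph`.

    Atom ordering equals the order of atoms in the input string. Aromaticity
    and ring membership are perceived by RDKit sanitisation.

    Raises
    ------
    SmilesParseError
        If the string cannot be parsed or sanitised.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError(str(smiles), "empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return MoleculeGraph(id=mol_id if mol_id is not None else smiles, rdkit_mol=mol)


def from_rdkit(mol: Chem.Mol, mol_id: str) -> MoleculeGraph:
    """Wrap an already-sanitised RDKit Mol."""
    return MoleculeGraph(id=mol_id, rdkit_mol=mol)


def canonical_smiles(mol: MoleculeGraph | Chem.Mol | str) -> str:
    """Canonical SMILES; equal for isomorphic inputs."""
    if isinstance(mol, str):
        mol = parse_smiles(mol)
    rd = mol.rdkit_mol if isinstance(mol, MoleculeGraph) else mol
    return Chem.MolToSmiles(rd)


def featurize_atom(atom: AtomRecord | Chem.Atom) -> np.ndarray:
    """42-dimensional feature vector for one atom.

    Layout: element one-hot (28, last slot = out-of-vocabulary), implicit-H
    one-hot (5, counts >4 clip to the top slot), heavy-degree one-hot (6,
    clipped), formal charge clipped to [-1, 1] (1), ring flag (1), aromatic
    flag (1). A pure function of these six attributes.
    """
    if isinstance(atom, Chem.Atom):
        atom = _atom_record(atom)
    vec = np.zeros(FEATURE_LENGTH, dtype=np.float64)
    try:
        vec[ELEMENT_VOCABULARY.index(atom.element)] = 1.0
    except ValueError:
        vec[len(ELEMENT_VOCABULARY)] = 1.0  # "other"
    off = len(ELEMENT_VOCABULARY) + 1
    vec[off + min(atom.implicit_h, _IMPLICIT_H_SLOTS - 1)] = 1.0
    off += _IMPLICIT_H_SLOTS
    vec[off + min(atom.heavy_degree, _HEAVY_DEGREE_SLOTS - 1)] = 1.0
    off += _HEAVY_DEGREE_SLOTS
    vec[off] = float(np.clip(atom.formal_charge, -1, 1))
    vec[off + 1] = 1.0 if atom.in_ring else 0.0
    vec[off + 2] = 1.0 if atom.aromatic else 0.0
    return vec


def featurize_molecule(mol: MoleculeGraph) -> np.ndarray:
    """``n_atoms x 42`` feature matrix, rows in atom order."""
    return np.stack([featurize_atom(a) for a in mol.rdkit_mol.GetAtoms()])


def morgan_fingerprint(mol: MoleculeGraph | str) -> np.ndarray:
    """Hashed circular (Morgan) fingerprint, radius 2, folded to 1024 bits."""
    if isinstance(mol, str):
        mol = parse_smiles(mol)
    if mol.n_atoms == 0:
        raise ValueError("cannot fingerprint an empty molecule")
    fp = _morgan_generator.GetFingerprintAsNumPy(mol.rdkit_mol)
    return fp.astype(np.uint8)


# ---------------------------------------------------------------------------
# File I/O: SMILES lists, CSV, SDF
# ---------------------------------------------------------------------------

def read_smiles_file(path: str | Path) -> list[MoleculeGraph]:
    """Read a ``.smi`` file: one record per line, ``smiles[<tab>id]``."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        smiles = parts[0]
        mol_id = parts[1] if len(parts) > 1 else f"mol_{lineno}"
        out.append(parse_smiles(smiles, mol_id))
    return out


def read_csv_file(path: str | Path) -> list[MoleculeGraph]:
    """Read a CSV with at least ``id`` and ``smiles`` columns."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"id", "smiles"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: CSV must have 'id' and 'smiles' columns")
        for row in reader:
            out.append(parse_smiles(row["smiles"], row["id"]))
    return out


def read_sdf_file(path: str | Path) -> list[MoleculeGraph]:
    out = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol_{i}"
        out.append(from_rdkit(mol, name))
    return out


def read_molecules(path: str | Path) -> list[MoleculeGraph]:
    """Dispatch on file extension (.smi/.txt, .csv, .sdf)."""
    suffix = Path(path).suffix.lower()
    if suffix in (".smi", ".txt"):
        return read_smiles_file(path)
    if suffix == ".csv":
        return read_csv_file(path)
    if suffix == ".sdf":
        return read_sdf_file(path)
    raise ValueError(f"unsupported molecule file format: {path}")


def write_smiles_csv(mols: Iterable[MoleculeGraph], path: str | Path) -> None:
    """Write ``id,smiles`` rows with canonical SMILES."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles"])
        for m in mols:
            writer.writerow([m.id, m.smiles])
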