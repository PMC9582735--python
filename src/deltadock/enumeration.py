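"""Mono- and di-substituted derivative generation with a fixed fragment library.

Derivatives are formed by replacing one implicit hydrogen of a ring atom with a
single bond to the first atom of a fragment SMILES. The fragment library order is
fixed and defines the positions of the per-atom label vectors used downstream:
position ``s`` of every node label always refers to fragment ``s`` of the library.

Chemically infeasible combinations (sanitisation/valence failure) are kept in the
output as records with ``feasible=False`` and ``product_smiles=None`` so the label
matrices can mark them as missing rather than silently dropping them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
from rdkit import Chem

from .chem import MoleculeGraph, from_rdkit, parse_smiles

__all__ = [
    "DEFAULT_FRAGMENTS",
    "SubstituentLibrary",
    "DerivativeRecord",
    "DiDerivativeRecord",
    "substitutable_positions",
    "attach_substituent",
    "enumerate_mono",
    "enumerate_di",
]

#: The default substituent set, in the order that defines label-vector positions.
DEFAULT_FRAGMENTS: tuple[str, ...] = (
    "F", "Cl", "Br", "I", "C", "C(C)C", "CC", "C(=O)O",
    "O", "OC", "COC", "CO", "C(=O)C", "N", "S",
)


@dataclass(frozen=True)
class SubstituentLibrary:
    """Ordered fragment library; order is part of the data contract."""

    fragments: tuple[str, ...] = DEFAULT_FRAGMENTS

    def __post_init__(self) -> None:
        for frag in self.fragments:
            if Chem.MolFromSmiles(frag) is None:
                raise ValueError(f"fragment does not parse: {frag!r}")

    def __len__(self) -> int:
        return len(self.fragments)

    def __getitem__(self, idx: int) -> str:
        return self.fragments[idx]

    def __iter__(self):
        return iter(self.fragments)

    def heavy_atoms(self, idx: int) -> int:
        return Chem.MolFromSmiles(self.fragments[idx]).GetNumAtoms()

    @classmethod
    def from_file(cls, path) -> "SubstituentLibrary":
        lines = [ln.strip() for ln in open(path) if ln.strip() and not ln.startswith("#")]
        return cls(tuple(lines))


@dataclass(frozen=True)
class DerivativeRecord:
    """One enumerated single-point modification of a parent molecule."""

    parent_id: str
    atom_index: int
    substituent_index: int
    substituent_smiles: str
    product_smiles: str | None
    feasible: bool


@dataclass(frozen=True)
class DiDerivativeRecord:
    """One enumerated two-point modification; positions sorted by atom index."""

    parent_id: str
    positions: tuple[tuple[int, int], tuple[int, int]]  # ((atom, sub), (atom, sub))
    product_smiles: str | None
    feasible: bool


def substitutable_positions(mol: MoleculeGraph) -> list[int]:
    """Ring atoms carrying at least one implicit hydrogen, ascending order.

    Only these positions can accept a substituent: the new bond replaces one
    hydrogen, and substitution is defined over ring atoms of the scaffold.
    A molecule without rings yields an empty list.
    """
    return [
        a.GetIdx()
        for a in mol.rdkit_mol.GetAtoms()
        if a.IsInRing() and a.GetTotalNumHs() >= 1
    ]


def attach_substituent(
    mol: MoleculeGraph, atom_index: int, fragment_smiles: str
) -> MoleculeGraph | None:
    """Attach a fragment to ``atom_index`` via a single bond to the fragment's
    first atom. Returns the sanitised product, or ``None`` when the combination
    is chemically infeasible (valence/sanitisation failure).

    Attachment at the *first* atom of the fragment SMILES disambiguates the
    printed fragment strings: ``OC`` is methoxy (attached through oxygen) while
    ``CO`` is hydroxymethyl (attached through carbon).

    Raises
    ------
    ValueError
        If ``atom_index`` is not a substitutable position of ``mol`` — this is
        a caller error, distinct from chemical infeasibility.
    """
    if atom_index not in substitutable_positions(mol):
        raise ValueError(
            f"atom {atom_index} of {mol.id!r} is not substitutable "
            "(must be a ring atom with >=1 implicit H)"
        )
    frag = Chem.MolFromSmiles(fragment_smiles)
    if frag is None:
        raise ValueError(f"fragment does not parse: {fragment_smiles!r}")
    combined = Chem.RWMol(Chem.CombineMols(mol.rdkit_mol, frag))
    combined.AddBond(atom_index, mol.n_atoms, Chem.BondType.SINGLE)
    target = combined.GetAtomWithIdx(atom_index)
    target.SetNumExplicitHs(max(target.GetTotalNumHs() - 1, 0))
    target.SetNoImplicit(False)
    try:
        product = combined.GetMol()
        Chem.SanitizeMol(product)
    except Exception:
        return None
    # keep combined atom order (parent atoms first) so parent indices stay valid
    return from_rdkit(product, f"{mol.id}|a{atom_index}+{fragment_smiles}")


def enumerate_mono(
    mol: MoleculeGraph, library: SubstituentLibrary | None = None
) -> list[DerivativeRecord]:
    """All (substitutable atom x library fragment) derivatives of ``mol``.

    One record per combination in (atom, fragment) lexicographic order;
    infeasible combinations are present with ``feasible=False``.
    """
    library = library or SubstituentLibrary()
    records = []
    for atom_index in substitutable_positions(mol):
        for sub_index, frag in enumerate(library):
            prod = attach_substituent(mol, atom_index, frag)
            records.append(
                DerivativeRecord(
                    parent_id=mol.id,
                    atom_index=atom_index,
                    substituent_index=sub_index,
                    substituent_smiles=frag,
                    product_smiles=prod.smiles if prod is not None else None,
                    feasible=prod is not None,
                )
            )
    return records


def _attach_pair(
    mol: MoleculeGraph,
    positions: tuple[tuple[int, int], tuple[int, int]],
    library: SubstituentLibrary,
) -> MoleculeGraph | None:
    (a1, s1), (a2, s2) = positions
    first = attach_substituent(mol, a1, library[s1])
    if first is None:
        return None
    # atom indices of the parent are preserved by CombineMols, so the second
    # parent atom index is still valid in the intermediate product
    if a2 not in substitutable_positions(first):
        return None
    return attach_substituent(first, a2, library[s2])


def enumerate_di(
    mol: MoleculeGraph,
    library: SubstituentLibrary | None = None,
    max_records: int | None = None,
    seed: int = 0,
) -> list[DiDerivativeRecord]:
    """Derivatives modified at two *distinct* substitutable atoms.

    Enumerates unordered atom pairs crossed with fragment pairs. When the full
    count exceeds ``max_records``, a uniform seeded sample (without replacement)
    of combinations is evaluated instead; the sample is deterministic for a
    fixed seed.
    """
    library = library or SubstituentLibrary()
    atoms = substitutable_positions(mol)
    combos = [
        ((a1, s1), (a2, s2))
        for a1, a2 in combinations(atoms, 2)
        for s1, s2 in product(range(len(library)), repeat=2)
    ]
    if max_records is not None and len(combos) > max_records:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(combos), size=max_records, replace=False)
        combos = [combos[i] for i in sorted(idx)]
    records = []
    for positions in combos:
        prod = _attach_pair(mol, positions, library)
        records.append(
            DiDerivativeRecord(
                parent_id=mol.id,
                positions=positions,
                product_smiles=prod.smiles if prod is not None else None,
                feasible=prod is not None,
            )
        )
    return records
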