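"""Node-labelled graph datasets: assembly, splitting, serialisation, fixtures.

Each molecule becomes a :class:`LabeledGraph`: the 42-dim atom feature matrix
plus an ``n_atoms x n_substituents`` matrix of docking-score deltas with a
binary validity mask. A mask entry is 1 only where the substitution is feasible
and was actually scored; masked-out entries carry no information and are ignored
by training, metrics and serialisation alike.

Splits are always by molecule, never by atom: atoms of one molecule share a
graph and must not leak between train and test. Two split modes are supported —
seeded random, and a "time" split by record order standing in for
database-deposition order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import MoleculeGraph, featurize_molecule, parse_smiles
from .enumeration import (
    DerivativeRecord,
    SubstituentLibrary,
    attach_substituent,
    enumerate_mono,
    substitutable_positions,
)
from .scoring import DeltaRecord, OracleBackend, OracleParams, compute_delta, oracle_delta

__all__ = [
    "NodeLabelMatrix",
    "LabeledGraph",
    "SplitSpec",
    "build_labeled_graph",
    "split_dataset",
    "generate_fixtures",
    "make_oracle_dataset",
    "write_dataset",
    "read_dataset",
]


@dataclass
class NodeLabelMatrix:
    """Per-atom label vectors of score deltas with a validity mask."""

    values: np.ndarray  # (n_atoms, n_substituents) float
    mask: np.ndarray    # (n_atoms, n_substituents) {0, 1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=np.float64)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not np.isin(self.mask, (0.0, 1.0)).all():
            raise ValueError("mask must be binary")
        self.values = np.where(self.mask > 0, self.values, 0.0)

    @property
    def n_labeled(self) -> int:
        return int(self.mask.sum())


@dataclass
class LabeledGraph:
    """One training example: molecule, features, node labels, source position."""

    molecule: MoleculeGraph
    features: np.ndarray
    labels: NodeLabelMatrix
    record_order: int = 0

    @property
    def id(self) -> str:
        return self.molecule.id


def build_labeled_graph(
    mol: MoleculeGraph,
    scored_derivatives: list[DeltaRecord],
    n_substituents: int = 15,
    record_order: int = 0,
) -> LabeledGraph:
    """Assemble the node-label matrix of a molecule from scored modifications.

    ``values[i, s]`` holds the delta of the derivative modifying atom ``i``
    with substituent ``s``; ``mask[i, s]`` is 1 exactly for the scored feasible
    records. Duplicate (atom, substituent) records are an error.
    """
    n = mol.n_atoms
    values = np.zeros((n, n_substituents))
    mask = np.zeros((n, n_substituents))
    seen = set()
    for rec in scored_derivatives:
        key = (rec.atom_index, rec.substituent_index)
        if key in seen:
            raise ValueError(f"duplicate scored record for {mol.id!r} {key}")
        seen.add(key)
        if not (0 <= rec.atom_index < n and 0 <= rec.substituent_index < n_substituents):
            raise ValueError(f"record {key} out of range for {mol.id!r}")
        values[rec.atom_index, rec.substituent_index] = rec.delta
        mask[rec.atom_index, rec.substituent_index] = 1.0
    return LabeledGraph(
        molecule=mol,
        features=featurize_molecule(mol),
        labels=NodeLabelMatrix(values, mask),
        record_order=record_order,
    )


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Molecule-level train/test partition plus CV fold assignment."""

    mode: str
    test_fraction: float
    seed: int
    test_ids: tuple[str, ...]
    folds: dict  # molecule id -> fold in 0..n_folds-1 (training part only)

    def train_ids(self, fold: int | None = None) -> tuple[str, ...]:
        if fold is None:
            return tuple(self.folds)
        return tuple(mid for mid, f in self.folds.items() if f != fold)

    def val_ids(self, fold: int) -> tuple[str, ...]:
        return tuple(mid for mid, f in self.folds.items() if f == fold)


def split_dataset(
    graphs: list[LabeledGraph],
    mode: str = "random",
    test_fraction: float = 0.2,
    n_folds: int = 5,
    seed: int = 0,
) -> SplitSpec:
    """Partition molecules into held-out test + n-fold CV on the remainder.

    ``time`` mode holds out the last ``ceil(test_fraction * N)`` molecules by
    ``record_order`` (record order stands in for database-deposition order);
    ``random`` mode draws the same number uniformly with the given seed. The
    training molecules then receive fold labels ``0..n_folds-1`` round-robin
    after a seeded shuffle.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if mode not in ("random", "time"):
        raise ValueError(f"unknown split mode: {mode!r}")
    n = len(graphs)
    n_test = int(np.ceil(test_fraction * n))
    if n - n_test < n_folds:
        raise ValueError(f"need at least {n_folds} training molecules, have {n - n_test}")
    rng = np.random.default_rng(seed)
    if mode == "time":
        order = sorted(graphs, key=lambda g: g.record_order)
        test = order[n - n_test:]
        train = order[: n - n_test]
    else:
        idx = rng.permutation(n)
        test = [graphs[i] for i in idx[:n_test]]
        train = [graphs[i] for i in idx[n_test:]]
    fold_idx = rng.permutation(len(train)) % n_folds
    folds = {g.id: int(fold_idx[i]) for i, g in enumerate(train)}
    return SplitSpec(
        mode=mode,
        test_fraction=test_fraction,
        seed=seed,
        test_ids=tuple(g.id for g in test),
        folds=folds,
    )


# ---------------------------------------------------------------------------
# Synthetic fixture molecules
# ---------------------------------------------------------------------------

#: Ring scaffolds sampled by the fixture generator: small aromatic and
#: partially saturated systems typical of drug-like CYP ligand cores.
DEFAULT_SCAFFOLDS: tuple[str, ...] = (
    "c1ccccc1",            # benzene
    "c1ccncc1",            # pyridine
    "c1ccc2ccccc2c1",      # naphthalene
    "c1ccc2[nH]ccc2c1",    # indole
    "c1ccoc1",             # furan
    "c1ccsc1",             # thiophene
    "c1cc[nH]c1",          # pyrrole
    "c1cncnc1",            # pyrimidine
    "c1ccc2ncccc2c1",      # quinoline
    "C1CCc2ccccc2C1",      # tetralin (fused saturated ring)
    "c1csc2ccccc12",       # benzothiophene
    "C1CCCCC1",            # cyclohexane
)

#: Small chains used to decorate fixture scaffolds (distinct role from the
#: substituent library: decorations create variety in the *parents*).
_DECORATIONS: tuple[str, ...] = ("C", "CC", "O", "N", "F", "Cl", "CO", "OC", "C(C)C")


def generate_fixtures(
    n_molecules: int,
    seed: int = 0,
    scaffold_set: tuple[str, ...] | None = None,
    heavy_atom_range: tuple[int, int] = (6, 30),
) -> list[MoleculeGraph]:
    """Seeded sampler of small ring-containing molecules.

    Picks a scaffold, decorates 0-3 ring positions with small chains, and keeps
    the result only if it still has a substitutable ring atom and its heavy-atom
    count is within range. Outputs are unique by canonical SMILES where the
    scaffold/decoration space allows it.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    scaffolds = scaffold_set or DEFAULT_SCAFFOLDS
    rng = np.random.default_rng(seed)
    out: list[MoleculeGraph] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < n_molecules and attempts < 200 * n_molecules:
        attempts += 1
        scaffold = parse_smiles(str(rng.choice(list(scaffolds))), "tmp")
        mol = scaffold
        for _ in range(int(rng.integers(0, 4))):
            positions = substitutable_positions(mol)
            if not positions:
                break
            pos = int(rng.choice(positions))
            frag = str(rng.choice(list(_DECORATIONS)))
            candidate = attach_substituent(mol, pos, frag)
            if candidate is not None:
                mol = candidate
        if not substitutable_positions(mol):
            continue
        if not heavy_atom_range[0] <= mol.n_atoms <= heavy_atom_range[1]:
            continue
        if mol.smiles in seen and len(seen) < 2 * n_molecules:
            continue
        seen.add(mol.smiles)
        mol.id = f"mol_{len(out):04d}"
        out.append(mol)
    # if uniqueness ran out (tiny scaffold spaces), fill with repeats
    while len(out) < n_molecules:
        mol = parse_smiles(str(rng.choice(list(scaffolds))), f"mol_{len(out):04d}")
        out.append(mol)
    return out


def make_oracle_dataset(
    n_molecules: int,
    seed: int = 0,
    sigma: float = 0.1,
    library: SubstituentLibrary | None = None,
    scaffold_set: tuple[str, ...] | None = None,
) -> tuple[list[LabeledGraph], OracleParams]:
    """End-to-end synthetic benchmark: fixtures -> enumeration -> oracle deltas.

    Returns the labelled graphs (record_order = generation order) and the
    oracle parameters used, so tests can compare against the ground truth.
    """
    library = library or SubstituentLibrary()
    params = OracleParams(library=library, sigma=sigma, seed=seed)
    molecules = generate_fixtures(n_molecules, seed=seed, scaffold_set=scaffold_set)
    graphs = []
    for order, mol in enumerate(molecules):
        deltas = []
        for rec in enumerate_mono(mol, library):
            if not rec.feasible:
                continue
            deltas.append(
                DeltaRecord(
                    parent_id=mol.id,
                    atom_index=rec.atom_index,
                    substituent_index=rec.substituent_index,
                    delta=oracle_delta(
                        mol, rec.atom_index, rec.substituent_index, params,
                        check_feasible=False,
                    ),
                )
            )
        graphs.append(
            build_labeled_graph(mol, deltas, n_substituents=len(library), record_order=order)
        )
    return graphs, params


# ---------------------------------------------------------------------------
# Serialisation (long-format CSV + molecules table)
# ---------------------------------------------------------------------------

def _ordered_smiles(rd) -> str:
    """SMILES carrying atom-map numbers that encode the original atom order."""
    from rdkit import Chem

    tagged = Chem.Mol(rd)
    for atom in tagged.GetAtoms():
        atom.SetAtomMapNum(atom.GetIdx() + 1)
    return Chem.MolToSmiles(tagged)


def _parse_ordered(smiles: str, mol_id: str) -> MoleculeGraph:
    """Parse an atom-mapped SMILES and restore the encoded atom order."""
    from rdkit import Chem

    from .chem import from_rdkit

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable stored SMILES for {mol_id!r}: {smiles!r}")
    if all(a.GetAtomMapNum() for a in mol.GetAtoms()):
        order = sorted(range(mol.GetNumAtoms()),
                       key=lambda i: mol.GetAtomWithIdx(i).GetAtomMapNum())
        mol = Chem.RenumberAtoms(mol, order)
        for atom in mol.GetAtoms():
            atom.SetAtomMapNum(0)
    return from_rdkit(mol, mol_id)


def write_dataset(graphs: list[LabeledGraph], path: str | Path) -> None:
    """Write a dataset directory: ``molecules.csv`` + ``labels.csv``.

    The ``smiles`` column carries atom-map numbers encoding the atom order, so
    label atom indices survive the round trip bit-exactly; ``canonical_smiles``
    is provided alongside for human consumption and deduplication.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for g in graphs:
        atom_idx, sub_idx = np.nonzero(g.labels.mask)
        for i, s in zip(atom_idx, sub_idx):
            rows.append((g.id, int(i), int(s), float(g.labels.values[i, s]), 1))
    mols = pd.DataFrame(
        {
            "id": [g.id for g in graphs],
            "smiles": [_ordered_smiles(g.molecule.rdkit_mol) for g in graphs],
            "canonical_smiles": [g.molecule.smiles for g in graphs],
            "record_order": [g.record_order for g in graphs],
        }
    )
    mols.to_csv(path / "molecules.csv", index=False)
    labels = pd.DataFrame(
        rows, columns=["parent_id", "atom_index", "substituent_index", "delta", "mask"]
    )
    labels.to_csv(path / "labels.csv", index=False)


def read_dataset(path: str | Path, n_substituents: int = 15) -> list[LabeledGraph]:
    """Read a dataset directory written by :func:`write_dataset`.

    Schema violations (missing columns, duplicate keys, unknown molecule ids)
    raise descriptive errors.
    """
    path = Path(path)
    mols = pd.read_csv(path / "molecules.csv")
    required = {"id", "smiles", "record_order"}
    if not required <= set(mols.columns):
        raise ValueError(f"molecules.csv missing columns {required - set(mols.columns)}")
    labels = pd.read_csv(path / "labels.csv", float_precision="round_trip")
    required = {"parent_id", "atom_index", "substituent_index", "delta", "mask"}
    if not required <= set(labels.columns):
        raise ValueError(f"labels.csv missing columns {required - set(labels.columns)}")
    keys = labels[["parent_id", "atom_index", "substituent_index"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].tolist()
        raise ValueError(f"duplicate label rows, first: {dup}")
    unknown = set(labels["parent_id"]) - set(mols["id"])
    if unknown:
        raise ValueError(f"labels reference unknown molecule ids: {sorted(unknown)[:5]}")
    grouped = dict(tuple(labels.groupby("parent_id"))) if len(labels) else {}
    graphs = []
    for _, row in mols.iterrows():
        mol = _parse_ordered(str(row["smiles"]), str(row["id"]))
        recs = []
        for _, lr in grouped.get(str(row["id"]), pd.DataFrame(columns=labels.columns)).iterrows():
            if int(lr["mask"]) != 1:
                continue
            recs.append(
                DeltaRecord(
                    parent_id=str(row["id"]),
                    atom_index=int(lr["atom_index"]),
                    substituent_index=int(lr["substituent_index"]),
                    delta=float(lr["delta"]),
                )
            )
        graphs.append(
            build_labeled_graph(
                mol, recs, n_substituents=n_substituents, record_order=int(row["record_order"])
            )
        )
    return graphs
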