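"""Docking scores via pluggable backends, and per-modification score deltas.

Two backends are provided behind one interface:

* :class:`OracleBackend` — a deterministic synthetic scorer. The absolute score
  of a molecule is a linear function of its heavy-atom count plus seeded Gaussian
  noise; the delta caused by attaching fragment ``f`` at a target atom is

      alpha_f + beta_f * [atom is aromatic] + gamma_f * (heavy_degree(atom) - 2) + noise

  so the learnable ground truth is a deterministic function of the substituent
  identity and the local atom environment. Absolute scores of derivatives are
  defined as parent score + delta, which makes ``compute_delta`` recover the
  delta exactly at any noise level.

* :class:`SminaBackend` — a wrapper around an external Smina/AutoDock-Vina-style
  command-line binary: embeds one seeded 3D conformer, runs the binary with
  default settings, parses the pose affinity table and reports the best
  (minimum) affinity.

All per-item randomness is derived deterministically from a stable hash of the
item identity combined with the backend seed, so scores are reproducible across
runs and processes.
"""

from __future__ import annotations

import re
import shutil
import subprocess
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import MoleculeGraph, canonical_smiles
from .enumeration import SubstituentLibrary, attach_substituent

__all__ = [
    "OracleParams",
    "OracleBackend",
    "SminaBackend",
    "BackendUnavailableError",
    "DockingError",
    "DeltaRecord",
    "compute_delta",
    "oracle_base_score",
    "oracle_delta",
    "score_batch",
]


class BackendUnavailableError(RuntimeError):
    """The external docking binary is not available on PATH."""


class DockingError(RuntimeError):
    """The external docking run failed or produced unparsable output."""


@dataclass(frozen=True)
class DeltaRecord:
    """Docking-score change of one modification: score(modified) - score(original).

    Negative delta means the modification improved (lowered) the score.
    """

    parent_id: str
    atom_index: int
    substituent_index: int
    delta: float


def compute_delta(ds_mod: float, ds_orig: float) -> float:
    """Docking-score difference of a modified compound vs its original."""
    if not (np.isfinite(ds_mod) and np.isfinite(ds_orig)):
        raise ValueError(f"non-finite docking score: mod={ds_mod}, orig={ds_orig}")
    return float(ds_mod) - float(ds_orig)


# ---------------------------------------------------------------------------
# Synthetic oracle
# ---------------------------------------------------------------------------

#: Per-fragment intercepts of the synthetic oracle, chosen so that halogen
#: substitution (F, Cl) improves the score while S, OC and COC worsen it, and
#: so that most |delta| stay below 1 — the qualitative behaviour observed for
#: real CYP docking campaigns.
DEFAULT_ALPHAS: dict[str, float] = {
    "F": -0.4, "Cl": -0.3, "Br": 0.1, "I": 0.2, "C": -0.1, "C(C)C": 0.0,
    "CC": -0.05, "C(=O)O": -0.1, "O": -0.2, "OC": 0.3, "COC": 0.35,
    "CO": -0.15, "C(=O)C": -0.05, "N": -0.2, "S": 0.25,
}


def _stable_seed(*parts, base_seed: int) -> int:
    """Deterministic per-item seed (< 2**31) from string parts and a base seed."""
    key = "|".join(str(p) for p in parts)
    return (zlib.crc32(key.encode()) ^ (base_seed * 2654435761)) % (2**31 - 1)


@dataclass(frozen=True)
class OracleParams:
    """Parameters of the synthetic scoring oracle.

    ``alpha`` is the per-fragment intercept of the delta; ``beta`` scales an
    aromatic-atom effect and ``gamma`` a degree effect, both per fragment and
    drawn once from seeded uniform ranges when not given explicitly. ``sigma``
    is the s.d. of the Gaussian noise added to base scores and deltas.
    """

    library: SubstituentLibrary = field(default_factory=SubstituentLibrary)
    alpha: tuple[float, ...] = ()
    beta: tuple[float, ...] = ()
    gamma: tuple[float, ...] = ()
    base_slope: float = -0.2
    base_intercept: float = -6.0
    sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.library)
        if not self.alpha:
            object.__setattr__(
                self,
                "alpha",
                tuple(DEFAULT_ALPHAS.get(f, 0.0) for f in self.library),
            )
        rng = np.random.default_rng(_stable_seed("oracle-effects", base_seed=self.seed))
        if not self.beta:
            object.__setattr__(self, "beta", tuple(rng.uniform(-0.1, 0.1, size=n)))
        if not self.gamma:
            object.__setattr__(self, "gamma", tuple(rng.uniform(-0.05, 0.05, size=n)))
        if len(self.alpha) != n or len(self.beta) != n or len(self.gamma) != n:
            raise ValueError("alpha/beta/gamma must have one entry per library fragment")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def oracle_base_score(mol: MoleculeGraph, params: OracleParams) -> float:
    """Synthetic absolute score: slope * n_heavy + intercept + seeded noise."""
    value = params.base_slope * mol.n_atoms + params.base_intercept
    if params.sigma > 0:
        rng = np.random.default_rng(
            _stable_seed("base", canonical_smiles(mol), base_seed=params.seed)
        )
        value += params.sigma * rng.standard_normal()
    return float(value)


def oracle_delta(
    parent: MoleculeGraph,
    atom_index: int,
    substituent_index: int,
    params: OracleParams,
    check_feasible: bool = True,
) -> float:
    """Ground-truth score change for one (atom, substituent) modification.

    Raises ``ValueError`` for an infeasible substitution. ``check_feasible``
    may be disabled by callers that already hold the enumeration result.
    """
    if check_feasible:
        try:
            product = attach_substituent(parent, atom_index, params.library[substituent_index])
        except ValueError:
            product = None
    else:
        product = True
    if product is None:
        raise ValueError(
            f"infeasible substitution: {parent.id!r} atom {atom_index} "
            f"+ {params.library[substituent_index]!r}"
        )
    atom = parent.rdkit_mol.GetAtomWithIdx(atom_index)
    value = (
        params.alpha[substituent_index]
        + params.beta[substituent_index] * float(atom.GetIsAromatic())
        + params.gamma[substituent_index] * (atom.GetDegree() - 2)
    )
    if params.sigma > 0:
        rng = np.random.default_rng(
            _stable_seed(
                "delta",
                canonical_smiles(parent),
                atom_index,
                substituent_index,
                base_seed=params.seed,
            )
        )
        value += params.sigma * rng.standard_normal()
    return float(value)


class OracleBackend:
    """Synthetic docking backend with the :class:`OracleParams` model.

    ``score`` on a plain molecule returns the base score; scoring a derivative
    through :meth:`score_derivative` returns parent base score + oracle delta.
    """

    backend_id = "oracle"

    def __init__(self, params: OracleParams | None = None):
        self.params = params or OracleParams()
        self.n_calls = 0

    def score(self, mol: MoleculeGraph) -> float:
        self.n_calls += 1
        return oracle_base_score(mol, self.params)

    def score_derivative(
        self, parent: MoleculeGraph, atom_index: int, substituent_index: int
    ) -> float:
        self.n_calls += 1
        return oracle_base_score(parent, self.params) + oracle_delta(
            parent, atom_index, substituent_index, self.params
        )


# ---------------------------------------------------------------------------
# External docking backend
# ---------------------------------------------------------------------------

_AFFINITY_TABLE = re.compile(r"^\s*(\d+)\s+(-?\d+(?:\.\d+)?)", re.MULTILINE)


class SminaBackend:
    """Wrapper around a Smina/Vina-style docking binary with default settings.

    The receptor PDB must already be prepared (all non-protein atoms removed,
    except the heme cofactor for cytochromes) — receptor preparation is a
    documented manual prerequisite, not performed here.
    """

    backend_id = "smina"

    def __init__(
        self,
        receptor_path: str | Path,
        binary: str = "smina",
        workdir: str | Path = ".",
        extra_args: tuple[str, ...] = (),
        conformer_seed: int = 0,
    ):
        self.receptor_path = Path(receptor_path)
        self.binary = binary
        self.workdir = Path(workdir)
        self.extra_args = tuple(extra_args)
        self.conformer_seed = conformer_seed
        self.n_calls = 0

    def _check_available(self) -> str:
        path = shutil.which(self.binary)
        if path is None:
            raise BackendUnavailableError(
                f"docking backend unavailable: {self.binary!r} not found on PATH"
            )
        return path

    def _embed_ligand(self, mol: MoleculeGraph, out_path: Path) -> None:
        """Write one seeded lowest-energy 3D conformer as SDF."""
        rd = Chem.AddHs(Chem.Mol(mol.rdkit_mol))
        params = AllChem.ETKDGv3()
        params.randomSeed = self.conformer_seed
        if AllChem.EmbedMolecule(rd, params) != 0:
            raise DockingError(f"conformer embedding failed for {mol.id!r}")
        AllChem.MMFFOptimizeMolecule(rd)
        writer = Chem.SDWriter(str(out_path))
        writer.write(rd)
        writer.close()

    def score(self, mol: MoleculeGraph) -> float:
        binary = self._check_available()
        self.n_calls += 1
        self.workdir.mkdir(parents=True, exist_ok=True)
        ligand = self.workdir / f"{_safe_name(mol.id)}.sdf"
        pose = self.workdir / f"{_safe_name(mol.id)}_poses.sdf"
        self._embed_ligand(mol, ligand)
        cmd = [
            binary,
            "--receptor", str(self.receptor_path),
            "--ligand", str(ligand),
            "--out", str(pose),
            "--seed", str(self.conformer_seed),
            *self.extra_args,
        ]
        result = subprocess.run(cmd, capture_output=True, text=True)
        if result.returncode != 0:
            raise DockingError(
                f"docking failed for {mol.id!r} (exit {result.returncode}): "
                f"{result.stderr.strip()[:500]}"
            )
        affinities = [float(m.group(2)) for m in _AFFINITY_TABLE.finditer(result.stdout)]
        if not affinities:
            raise DockingError(f"no affinity table in docking output for {mol.id!r}")
        return min(affinities)  # best pose = minimum affinity

    def score_derivative(
        self, parent: MoleculeGraph, atom_index: int, substituent_index: int,
        library: SubstituentLibrary | None = None,
    ) -> float:
        library = library or SubstituentLibrary()
        product = attach_substituent(parent, atom_index, library[substituent_index])
        if product is None:
            raise ValueError("infeasible substitution")
        return self.score(product)


def _safe_name(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]", "_", name)


# ---------------------------------------------------------------------------
# Batch scoring with a resumable cache
# ---------------------------------------------------------------------------

def score_batch(
    backend,
    molecules,
    cache: dict | None = None,
    receptor_id: str = "",
) -> list[float | None]:
    """Score molecules in order; failures become ``None`` (with logged reason).

    Results are cached by ``(backend id, canonical SMILES, receptor id, seed)``
    so interrupted enumerations can resume without re-docking. Pass the same
    ``cache`` dict across calls to reuse results; a cache hit never touches
    the backend.
    """
    if cache is None:
        cache = {}
    seed = getattr(getattr(backend, "params", None), "seed", None)
    if seed is None:
        seed = getattr(backend, "conformer_seed", 0)
    out: list[float | None] = []
    for mol in molecules:
        key = (backend.backend_id, canonical_smiles(mol), receptor_id, seed)
        if key in cache:
            out.append(cache[key])
            continue
        try:
            value = backend.score(mol)
        except (DockingError, BackendUnavailableError):
            out.append(None)
            continue
        cache[key] = value
        out.append(value)
    return out
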