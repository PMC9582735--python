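"""Metrics, saliency-map explanations, and aggregate substitution-effect analyses.

Metrics
    Sign accuracy (direction of the score change, with an optional margin that
    discards examples whose true |delta| is small), masked MSE as a ranking
    metric, and the sum of ranking differences (SRD) for comparing model
    rankings against a reference.

Saliency maps
    Per-atom attributions of one (atom, substituent) prediction, computed from
    the gradient of that output w.r.t. the input feature matrix. The classical
    map is the per-atom Euclidean norm of the positive part of the gradient,
    ``||ReLU(dy/dx)||``; the negative map uses ``ReLU(-dy/dx)``; the
    positive-negative map is their elementwise difference. Because message
    passing only reaches ``n_conv`` hops, atoms outside that receptive field
    receive exactly zero attribution (unless a dummy node shortcuts the graph).

Summaries
    Per-substituent distributions of score changes and the magnitude histogram
    in bins [0,1), [1,2), [2,4), [4,inf), plus the mono- vs di-substitution
    comparison of mean changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._autodiff import Tensor
from ._graph_batch import collate, prepare_graph
from .chem import MoleculeGraph
from .data import LabeledGraph, build_labeled_graph
from .enumeration import DiDerivativeRecord, SubstituentLibrary, attach_substituent
from .models import GNNNodeRegressor, masked_mse
from .scoring import DeltaRecord, compute_delta

__all__ = [
    "MetricReport",
    "SaliencyMap",
    "sign_accuracy",
    "mse_ranking",
    "srd",
    "saliency",
    "saliency_from_gradient",
    "substituent_effect_summary",
    "mono_vs_di_summary",
    "export_viewer_payload",
]

MAGNITUDE_BINS = (0.0, 1.0, 2.0, 4.0, np.inf)


@dataclass(frozen=True)
class MetricReport:
    """Sign accuracy + MSE over the entries surviving mask and margin filters."""

    sign_accuracy: float  # NaN when nothing survives
    mse: float
    n_evaluated: int
    margin: float

    @property
    def defined(self) -> bool:
        return self.n_evaluated > 0


def sign_accuracy(
    pred_deltas: np.ndarray,
    true_deltas: np.ndarray,
    mask: np.ndarray,
    margin: float = 0.0,
) -> MetricReport:
    """Fraction of correctly predicted change directions.

    Evaluates only entries with ``mask == 1`` and ``|true| >= margin``.
    Direction is binary: decrease iff delta < 0 (zero counts as increase).
    An empty surviving set yields ``n_evaluated=0`` and NaN accuracy.
    """
    pred, true, mask = (np.asarray(a, dtype=float) for a in (pred_deltas, true_deltas, mask))
    if pred.shape != true.shape or pred.shape != mask.shape:
        raise ValueError("pred, true and mask must share a shape")
    keep = (mask > 0) & (np.abs(true) >= margin)
    n = int(keep.sum())
    if n == 0:
        return MetricReport(float("nan"), float("nan"), 0, margin)
    correct = (pred[keep] < 0) == (true[keep] < 0)
    mse = float(((pred[keep] - true[keep]) ** 2).mean())
    return MetricReport(float(correct.mean()), mse, n, margin)


def mse_ranking(pred_deltas: np.ndarray, true_deltas: np.ndarray, mask: np.ndarray) -> float:
    """MSE of predicted vs true deltas over unmasked entries (ranking metric)."""
    return masked_mse(pred_deltas, true_deltas, mask)


def srd(pred_scores, ref_scores) -> tuple[float, float]:
    """Sum of ranking differences between a model ranking and a reference.

    Both lists are ranked (ties get average ranks); returns the total absolute
    rank difference and its normalisation by the maximum attainable SRD
    (``n^2/2`` for even n, ``(n^2-1)/2`` for odd n — the fully reversed ranking).
    """
    pred = np.asarray(pred_scores, dtype=float)
    ref = np.asarray(ref_scores, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("pred and ref must have equal length")
    n = pred.size
    if n < 2:
        raise ValueError("SRD needs at least 2 items")
    value = float(np.abs(rankdata(pred) - rankdata(ref)).sum())
    max_srd = n**2 / 2 if n % 2 == 0 else (n**2 - 1) / 2
    return value, value / max_srd


# ---------------------------------------------------------------------------
# Saliency maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SaliencyMap:
    """Per-atom attribution of one (atom, substituent) prediction."""

    values: np.ndarray
    mode: str
    target: tuple[int, int]


def saliency_from_gradient(gradient: np.ndarray, mode: str) -> np.ndarray:
    """Reduce an (n_atoms, n_features) input gradient to per-atom attributions.

    classical: per-atom Euclidean norm of ReLU(grad); negative: the same of
    ReLU(-grad); pos_neg: classical minus negative.
    """
    g = np.asarray(gradient, dtype=float)
    classical = np.linalg.norm(np.maximum(g, 0.0), axis=1)
    if mode == "classical":
        return classical
    negative = np.linalg.norm(np.maximum(-g, 0.0), axis=1)
    if mode == "negative":
        return negative
    if mode == "pos_neg":
        return classical - negative
    raise ValueError(f"unknown saliency mode: {mode!r}")


def saliency(
    model: GNNNodeRegressor,
    graph: LabeledGraph,
    atom_index: int,
    substituent_index: int,
    mode: str = "classical",
    library: SubstituentLibrary | None = None,
) -> SaliencyMap:
    """Gradient saliency of one predicted delta w.r.t. the input features.

    The target must be a feasible substitution of the molecule; requesting an
    infeasible (masked) target is an error. The dummy node, when present, is
    excluded from the returned per-atom values.
    """
    model._check_fitted()
    library = library or SubstituentLibrary()
    mol = graph.molecule
    if not 0 <= substituent_index < len(library):
        raise ValueError(f"substituent index {substituent_index} out of range")
    try:
        feasible = attach_substituent(mol, atom_index, library[substituent_index]) is not None
    except ValueError:
        feasible = False
    if not feasible:
        raise ValueError(
            f"saliency target ({atom_index}, {substituent_index}) is not a "
            f"feasible substitution of {mol.id!r}"
        )
    prepared = prepare_graph(graph, model.use_dummy_node)
    batch = collate([prepared])
    x = Tensor(batch.x, requires_grad=True)
    out = model._forward(batch, training=False, x_input=x)
    grad_seed = np.zeros_like(out.data)
    grad_seed[atom_index, substituent_index] = 1.0
    out.backward(grad_seed)
    gradient = x.grad[prepared.real]
    return SaliencyMap(
        values=saliency_from_gradient(gradient, mode),
        mode=mode,
        target=(atom_index, substituent_index),
    )


# ---------------------------------------------------------------------------
# Aggregate substitution-effect analyses
# ---------------------------------------------------------------------------

def substituent_effect_summary(
    delta_records: list[DeltaRecord],
    library: SubstituentLibrary | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Distribution of score changes per substituent + |delta| magnitude histogram.

    Returns a per-substituent table (count, mean, median, quartiles) indexed by
    fragment SMILES, and the histogram of |delta| over bins [0,1), [1,2),
    [2,4), [4,inf) whose counts sum to the number of records.
    """
    if not delta_records:
        raise ValueError("no delta records to summarise")
    library = library or SubstituentLibrary()
    df = pd.DataFrame(
        {
            "substituent": [library[r.substituent_index] for r in delta_records],
            "delta": [r.delta for r in delta_records],
        }
    )
    stats = (
        df.groupby("substituent", sort=False)["delta"]
        .agg(
            count="count",
            mean="mean",
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
        )
        .reindex([f for f in library if f in set(df["substituent"])])
    )
    magnitudes = df["delta"].abs()
    labels = ["[0,1)", "[1,2)", "[2,4)", "[4,inf)"]
    binned = pd.cut(magnitudes, bins=MAGNITUDE_BINS, labels=labels, right=False)
    histogram = binned.value_counts().reindex(labels).fillna(0).astype(int)
    return stats, histogram


def mono_vs_di_summary(
    mono_records: list[DeltaRecord],
    di_records: list[tuple[DiDerivativeRecord, float]],
    library: SubstituentLibrary | None = None,
) -> pd.DataFrame:
    """Mean score change of single vs double substitutions, per substituent.

    Each di-substitution delta is attributed to both involved substituents.
    ``mono_preferred`` is True where the mono mean is lower (better) than the
    di mean; an ``overall`` row aggregates across substituents.
    """
    if not mono_records or not di_records:
        raise ValueError("need both mono and di records")
    library = library or SubstituentLibrary()
    mono = pd.DataFrame(
        {
            "substituent": [library[r.substituent_index] for r in mono_records],
            "delta": [r.delta for r in mono_records],
        }
    )
    di_rows = []
    for rec, delta in di_records:
        for _, sub_idx in rec.positions:
            di_rows.append((library[sub_idx], delta))
    di = pd.DataFrame(di_rows, columns=["substituent", "delta"])
    table = pd.DataFrame(
        {
            "mono_mean": mono.groupby("substituent")["delta"].mean(),
            "di_mean": di.groupby("substituent")["delta"].mean(),
        }
    ).dropna()
    table.loc["overall"] = [mono["delta"].mean(), di["delta"].mean()]
    table["difference"] = table["mono_mean"] - table["di_mean"]
    table["mono_preferred"] = table["mono_mean"] < table["di_mean"]
    return table


# ---------------------------------------------------------------------------
# Viewer payload export
# ---------------------------------------------------------------------------

def export_viewer_payload(
    parent: MoleculeGraph,
    derivative: MoleculeGraph,
    parent_score: float,
    derivative_score: float,
    out_dir: str | Path,
    poses: dict[str, str | Path] | None = None,
) -> Path:
    """Write a JSON manifest (plus pose files when given) for external viewers.

    The manifest holds ids, canonical SMILES, both scores and their delta;
    pose files are copied alongside and referenced by relative name.
    """
    if parent_score is None or derivative_score is None:
        raise ValueError("both scores are required for the viewer payload")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "parent": {"id": parent.id, "smiles": parent.smiles, "score": float(parent_score)},
        "derivative": {
            "id": derivative.id,
            "smiles": derivative.smiles,
            "score": float(derivative_score),
        },
        "delta": compute_delta(derivative_score, parent_score),
        "poses": {},
    }
    if poses:
        import shutil

        for name, src in poses.items():
            dest = out_dir / Path(src).name
            shutil.copyfile(src, dest)
            manifest["poses"][name] = dest.name
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
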