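"""GNN node-regression models, masked-MSE training, hyperparameter grid, baselines.

The central estimator is :class:`GNNNodeRegressor`: a graph network that reads a
molecule and predicts, for every atom, the vector of docking-score changes over
the whole substituent library in a single forward pass. Two message-passing
layer types are available — spectral graph convolution (symmetric-normalised
adjacency with self loops) and single-head graph attention — each wrapped in a
block with batch normalisation, ReLU, dropout and an additive skip connection.
An optional dummy node (an extra vertex connected to every atom) widens the
receptive field to the whole molecule.

Training minimises the masked MSE: squared error restricted to the label
entries whose substitution is feasible and scored; everything else is invisible
to the optimiser. Optimisation is Adam with optional L2 weight decay and a
reduce-on-plateau learning-rate schedule.

Reference models: a majority-sign baseline, and a random forest that regresses
absolute docking scores from Morgan fingerprints and classifies a modification
by the sign of the difference of its two independent score predictions.

Estimators follow scikit-learn conventions (``fit``/``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes) so they
compose with sklearn model-selection utilities where the graph-shaped inputs
allow it.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor

from ._autodiff import Tensor, edge_aggregate, gather, leaky_relu, relu, segment_sum, spmm
from ._graph_batch import GraphBatch, collate, prepare_graph
from .chem import FEATURE_LENGTH, MoleculeGraph, morgan_fingerprint
from .data import LabeledGraph

__all__ = [
    "masked_mse",
    "GNNNodeRegressor",
    "MajoritySignBaseline",
    "RandomForestScorePredictor",
    "hyperparameter_grid",
    "grid_search",
    "save_model",
    "load_model",
    "GRID_DIMENSIONS",
]

DECREASE, INCREASE = "decrease", "increase"


def sign_class(delta: float | np.ndarray):
    """Binary direction of a score change: decrease iff delta < 0 (0 -> increase)."""
    if np.isscalar(delta):
        return DECREASE if delta < 0 else INCREASE
    return np.where(np.asarray(delta) < 0, DECREASE, INCREASE)


def masked_mse(pred: np.ndarray, values: np.ndarray, mask: np.ndarray) -> float:
    """Mean squared error over mask=1 entries only.

    Raises ``ValueError`` when the mask selects nothing — an all-masked batch
    is a caller error, not a zero loss.
    """
    pred, values, mask = (np.asarray(a, dtype=float) for a in (pred, values, mask))
    if pred.shape != values.shape or pred.shape != mask.shape:
        raise ValueError("pred, values and mask must share a shape")
    total = mask.sum()
    if total == 0:
        raise ValueError("masked_mse over an all-masked batch is undefined")
    return float((((pred - values) * mask) ** 2).sum() / total)


# ---------------------------------------------------------------------------
# Hyperparameter grid
# ---------------------------------------------------------------------------

#: The six binary architecture/training choices whose cross-product forms the
#: 64-point hyperparameter grid.
GRID_DIMENSIONS: dict[str, tuple] = {
    "n_conv": (3, 5),
    "layer_type": ("gcn", "gat"),
    "n_linear": (1, 2),
    "dropout": (0.2, 0.5),
    "learning_rate": (0.01, 0.001),
    "weight_decay": (0.0, 0.0005),
}


def hyperparameter_grid(dimensions: list[str] | None = None) -> list[dict]:
    """Enumerate the hyperparameter grid (full: 2^6 = 64 configurations).

    ``dimensions`` restricts the grid to a subset of the six choices (the
    remaining ones stay at their first listed value) for desk-scale runs.
    """
    dims = list(GRID_DIMENSIONS) if dimensions is None else list(dimensions)
    unknown = set(dims) - set(GRID_DIMENSIONS)
    if unknown:
        raise ValueError(f"unknown grid dimensions: {sorted(unknown)}")
    fixed = {k: v[0] for k, v in GRID_DIMENSIONS.items() if k not in dims}
    configs = []
    for combo in product(*(GRID_DIMENSIONS[d] for d in dims)):
        cfg = dict(fixed)
        cfg.update(dict(zip(dims, combo)))
        configs.append({k: cfg[k] for k in GRID_DIMENSIONS})
    return configs


# ---------------------------------------------------------------------------
# GNN node regressor
# ---------------------------------------------------------------------------

class GNNNodeRegressor(BaseEstimator, RegressorMixin):
    """Graph network predicting per-atom vectors of docking-score changes.

    Parameters mirror the hyperparameter grid: ``n_conv`` message-passing
    blocks (3 or 5) of type ``gcn`` or ``gat`` with hidden size 256, one or two
    output linear layers, dropout 0.2/0.5, Adam with learning rate 0.01/0.001
    and weight decay 0 or 5e-4, 200 epochs, graph batch size 256, and a
    reduce-on-plateau schedule with patience 10. ``use_dummy_node`` switches on
    the whole-graph aggregation vertex.

    ``fit`` takes a list of :class:`~deltadock.data.LabeledGraph`; labels live
    inside the graphs, so ``y`` is unused (sklearn-clusterer style signature).
    """

    def __init__(
        self,
        n_conv: int = 3,
        layer_type: str = "gcn",
        n_linear: int = 1,
        hidden: int = 256,
        dropout: float = 0.2,
        learning_rate: float = 0.01,
        weight_decay: float = 0.0,
        use_dummy_node: bool = False,
        epochs: int = 200,
        batch_size: int = 256,
        scheduler_patience: int = 10,
        scheduler_factor: float = 0.1,
        n_substituents: int = 15,
        random_state: int = 0,
        verbose: bool = False,
    ):
        self.n_conv = n_conv
        self.layer_type = layer_type
        self.n_linear = n_linear
        self.hidden = hidden
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.use_dummy_node = use_dummy_node
        self.epochs = epochs
        self.batch_size = batch_size
        self.scheduler_patience = scheduler_patience
        self.scheduler_factor = scheduler_factor
        self.n_substituents = n_substituents
        self.random_state = random_state
        self.verbose = verbose

    # -- parameter initialisation -------------------------------------------

    def _init_weights(self, rng: np.random.Generator) -> None:
        def glorot(n_in, n_out):
            bound = np.sqrt(6.0 / (n_in + n_out))
            return Tensor(rng.uniform(-bound, bound, size=(n_in, n_out)), requires_grad=True)

        self.weights_: dict[str, Tensor] = {}
        self.bn_stats_: dict[str, dict[str, np.ndarray]] = {}
        w = self.weights_
        for b in range(self.n_conv):
            n_in = FEATURE_LENGTH if b == 0 else self.hidden
            w[f"conv{b}.W"] = glorot(n_in, self.hidden)
            w[f"conv{b}.b"] = Tensor(np.zeros((1, self.hidden)), requires_grad=True)
            if self.layer_type == "gat":
                w[f"conv{b}.a_src"] = glorot(self.hidden, 1)
                w[f"conv{b}.a_dst"] = glorot(self.hidden, 1)
            if n_in != self.hidden:
                w[f"conv{b}.Wskip"] = glorot(n_in, self.hidden)
            w[f"conv{b}.gamma"] = Tensor(np.ones((1, self.hidden)), requires_grad=True)
            w[f"conv{b}.beta"] = Tensor(np.zeros((1, self.hidden)), requires_grad=True)
            self.bn_stats_[f"conv{b}"] = {
                "mean": np.zeros(self.hidden),
                "var": np.ones(self.hidden),
            }
        if self.n_linear == 2:
            w["lin0.W"] = glorot(self.hidden, self.hidden)
            w["lin0.b"] = Tensor(np.zeros((1, self.hidden)), requires_grad=True)
        w["out.W"] = glorot(self.hidden, self.n_substituents)
        w["out.b"] = Tensor(np.zeros((1, self.n_substituents)), requires_grad=True)

    # -- forward -------------------------------------------------------------

    def _batch_norm(self, name: str, x: Tensor, training: bool) -> Tensor:
        stats = self.bn_stats_[name]
        eps = 1e-5
        if training:
            mean = x.data.mean(axis=0)
            var = x.data.var(axis=0)
            momentum = 0.1
            stats["mean"] = (1 - momentum) * stats["mean"] + momentum * mean
            stats["var"] = (1 - momentum) * stats["var"] + momentum * var
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            sigma = ((centered**2).mean(axis=0, keepdims=True) + eps).sqrt()
            norm = centered / sigma
        else:
            norm = (x - stats["mean"][None, :]) * (1.0 / np.sqrt(stats["var"] + eps))[None, :]
        return norm * self.weights_[f"{name}.gamma"] + self.weights_[f"{name}.beta"]

    def _forward(
        self,
        batch: GraphBatch,
        training: bool = False,
        rng: np.random.Generator | None = None,
        x_input: Tensor | None = None,
    ) -> Tensor:
        """Full-batch forward pass; returns the (n_nodes, n_substituents) output.

        ``x_input`` lets callers supply the node features as a differentiable
        tensor (used by saliency maps to take gradients w.r.t. the input).
        """
        if batch.x.shape[1] != FEATURE_LENGTH:
            raise ValueError(
                f"expected {FEATURE_LENGTH}-dim atom features, got {batch.x.shape[1]}"
            )
        w = self.weights_
        x = x_input if x_input is not None else Tensor(batch.x)
        for b in range(self.n_conv):
            name = f"conv{b}"
            h = x @ w[f"{name}.W"]
            if self.layer_type == "gcn":
                z = spmm(batch.a_norm, h) + w[f"{name}.b"]
            else:  # single-head graph attention over the edge list
                s_src = gather(h @ w[f"{name}.a_src"], batch.src)
                s_dst = gather(h @ w[f"{name}.a_dst"], batch.dst)
                e = leaky_relu(s_src + s_dst, slope=0.2)
                # softmax over incoming edges, shifted by a per-node constant
                shift = np.full(batch.n_nodes, -np.inf)
                np.maximum.at(shift, batch.dst, e.data[:, 0])
                ex = (e - shift[batch.dst, None]).exp()
                denom = segment_sum(ex, batch.dst, batch.n_nodes)
                alpha = ex / gather(denom, batch.dst)
                z = edge_aggregate(alpha, h, batch.src, batch.dst, batch.n_nodes)
                z = z + w[f"{name}.b"]
            z = relu(self._batch_norm(name, z, training))
            if training and self.dropout > 0:
                keep = (rng.random(z.shape) >= self.dropout) / (1.0 - self.dropout)
                z = z * keep
            skip = x @ w[f"{name}.Wskip"] if f"{name}.Wskip" in w else x
            x = z + skip
        if self.n_linear == 2:
            x = relu(x @ w["lin0.W"] + w["lin0.b"])
        return x @ w["out.W"] + w["out.b"]

    def _loss(self, pred: Tensor, batch: GraphBatch) -> Tensor:
        total = batch.mask.sum()
        if total == 0:
            raise ValueError("all labels masked out in batch; masked MSE undefined")
        diff = (pred - Tensor(batch.values)) * Tensor(batch.mask)
        return (diff**2).sum() * (1.0 / total)

    # -- training ------------------------------------------------------------

    def fit(self, X: list[LabeledGraph], y=None, validation: list[LabeledGraph] | None = None):
        """Train on labelled graphs; ``validation`` drives the LR schedule."""
        if not X:
            raise ValueError("empty training set")
        rng = np.random.default_rng(self.random_state)
        self._init_weights(rng)
        prepared = [prepare_graph(g, self.use_dummy_node) for g in X]
        if not any(p.mask.sum() for p in prepared):
            raise ValueError("training set has no unmasked labels")
        val_batch = (
            collate([prepare_graph(g, self.use_dummy_node) for g in validation])
            if validation
            else None
        )
        params = self.weights_
        adam_m = {k: np.zeros_like(t.data) for k, t in params.items()}
        adam_v = {k: np.zeros_like(t.data) for k, t in params.items()}
        step = 0
        lr = self.learning_rate
        best_monitor = np.inf
        stagnant = 0
        self.history_: list[dict] = []
        self.lr_events_: list[dict] = []
        for epoch in range(self.epochs):
            order = rng.permutation(len(prepared))
            epoch_losses = []
            for start in range(0, len(prepared), self.batch_size):
                chunk = [prepared[i] for i in order[start : start + self.batch_size]]
                batch = collate(chunk)
                if batch.mask.sum() == 0:
                    continue
                pred = self._forward(batch, training=True, rng=rng)
                loss = self._loss(pred, batch)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {epoch} "
                        f"(lr={lr}, config={self.get_params()})"
                    )
                loss.backward()
                step += 1
                for k, t in params.items():
                    g = t.grad if t.grad is not None else np.zeros_like(t.data)
                    if self.weight_decay:
                        g = g + self.weight_decay * t.data
                    adam_m[k] = 0.9 * adam_m[k] + 0.1 * g
                    adam_v[k] = 0.999 * adam_v[k] + 0.001 * g**2
                    mhat = adam_m[k] / (1 - 0.9**step)
                    vhat = adam_v[k] / (1 - 0.999**step)
                    t.data -= lr * mhat / (np.sqrt(vhat) + 1e-8)
                epoch_losses.append(float(loss.data))
            record = {"epoch": epoch, "lr": lr, "train_loss": float(np.mean(epoch_losses))}
            if val_batch is not None:
                val_pred = self._forward(val_batch, training=False)
                record["val_loss"] = masked_mse(val_pred.data, val_batch.values, val_batch.mask)
            monitor = record.get("val_loss", record["train_loss"])
            if monitor < best_monitor - 1e-8:
                best_monitor = monitor
                stagnant = 0
            else:
                stagnant += 1
                if stagnant > self.scheduler_patience:
                    lr *= self.scheduler_factor
                    stagnant = 0
                    self.lr_events_.append({"epoch": epoch, "lr": lr})
            self.history_.append(record)
            if self.verbose:
                print(f"epoch {epoch:3d} " + " ".join(f"{k}={v:.5f}" for k, v in record.items() if k != "epoch"))
        self.n_features_in_ = FEATURE_LENGTH
        return self

    # -- inference -----------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "weights_"):
            raise RuntimeError("model is not fitted")

    def predict(self, X) -> np.ndarray | list[np.ndarray]:
        """Predicted delta matrix/matrices, ``n_atoms x n_substituents`` each.

        Dummy-node rows are stripped; a single graph returns a single matrix.
        """
        self._check_fitted()
        single = isinstance(X, LabeledGraph)
        graphs = [X] if single else list(X)
        prepared = [prepare_graph(g, self.use_dummy_node) for g in graphs]
        batch = collate(prepared)
        out = self._forward(batch, training=False).data
        results = []
        offset = 0
        for size, p in zip(batch.sizes, prepared):
            results.append(out[offset : offset + size][p.real])
            offset += size
        return results[0] if single else results

    def score(self, X: list[LabeledGraph], y=None) -> float:
        """Negative masked MSE (sklearn convention: larger is better)."""
        preds = self.predict(X if isinstance(X, list) else [X])
        values = np.vstack([g.labels.values for g in X])
        mask = np.vstack([g.labels.mask for g in X])
        return -masked_mse(np.vstack(preds), values, mask)


# ---------------------------------------------------------------------------
# Model persistence (config + weights + history, plain files)
# ---------------------------------------------------------------------------

def save_model(model: GNNNodeRegressor, path) -> None:
    """Serialise a fitted model: JSON config/history + npz weight arrays."""
    import json
    from pathlib import Path

    model._check_fitted()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "config.json").write_text(
        json.dumps({"params": model.get_params(), "history": model.history_,
                    "lr_events": model.lr_events_}, indent=2)
    )
    arrays = {k.replace(".", "__"): t.data for k, t in model.weights_.items()}
    for name, stats in model.bn_stats_.items():
        arrays[f"bn__{name}__mean"] = stats["mean"]
        arrays[f"bn__{name}__var"] = stats["var"]
    np.savez(path / "weights.npz", **arrays)


def load_model(path) -> GNNNodeRegressor:
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads((path / "config.json").read_text())
    model = GNNNodeRegressor(**meta["params"])
    model.history_ = meta["history"]
    model.lr_events_ = meta["lr_events"]
    arrays = np.load(path / "weights.npz")
    model.weights_ = {}
    model.bn_stats_ = {}
    for key in arrays.files:
        if key.startswith("bn__"):
            _, name, stat = key.split("__")
            model.bn_stats_.setdefault(name, {})[stat] = arrays[key]
        else:
            model.weights_[key.replace("__", ".")] = Tensor(arrays[key], requires_grad=True)
    model.n_features_in_ = FEATURE_LENGTH
    return model


# ---------------------------------------------------------------------------
# Reference models
# ---------------------------------------------------------------------------

class MajoritySignBaseline(BaseEstimator):
    """Predicts the most prevalent direction of change for every input.

    Its accuracy on any evaluation set equals that set's majority-class
    fraction whenever the two majority classes coincide, which makes it the
    natural floor for sign-prediction models. An exact 50/50 tie predicts
    ``decrease`` (documented tie-break).
    """

    def fit(self, X: list[LabeledGraph], y=None):
        deltas = np.concatenate(
            [g.labels.values[g.labels.mask > 0] for g in X if g.labels.n_labeled]
        )
        if deltas.size == 0:
            raise ValueError("no unmasked labels to fit the baseline")
        n_decrease = int((deltas < 0).sum())
        self.majority_class_ = DECREASE if n_decrease * 2 >= deltas.size else INCREASE
        self.decrease_fraction_ = n_decrease / deltas.size
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "majority_class_"):
            raise RuntimeError("baseline is not fitted")
        n = len(X) if hasattr(X, "__len__") else 1
        return np.array([self.majority_class_] * n, dtype=object)

    def accuracy(self, X: list[LabeledGraph]) -> float:
        """Sign accuracy over all unmasked labels of the evaluation graphs."""
        deltas = np.concatenate([g.labels.values[g.labels.mask > 0] for g in X])
        return float((sign_class(deltas) == self.majority_class_).mean())


class RandomForestScorePredictor(BaseEstimator, RegressorMixin):
    """Random forest on Morgan fingerprints predicting *absolute* docking scores.

    The direction of a modification is classified indirectly: the forest
    predicts scores of the original and the modified compound separately, and
    the sign of the difference of the two predictions gives the class. Input
    representation is the hashed circular fingerprint, radius 2, 1024 bits.
    """

    def __init__(self, n_estimators: int = 500, random_state: int = 0):
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X: list[MoleculeGraph], y):
        feats = np.stack([morgan_fingerprint(m) for m in X]).astype(float)
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_estimators, random_state=self.random_state, n_jobs=1
        )
        self.forest_.fit(feats, np.asarray(y, dtype=float))
        return self

    def predict(self, X: list[MoleculeGraph]) -> np.ndarray:
        if not hasattr(self, "forest_"):
            raise RuntimeError("random forest is not fitted")
        feats = np.stack([morgan_fingerprint(m) for m in X]).astype(float)
        return self.forest_.predict(feats)

    def predict_delta(self, parent: MoleculeGraph, derivative: MoleculeGraph) -> float:
        pred = self.predict([derivative, parent])
        return float(pred[0] - pred[1])

    def predict_delta_sign(self, parent: MoleculeGraph, derivative: MoleculeGraph) -> str:
        return sign_class(self.predict_delta(parent, derivative))


# ---------------------------------------------------------------------------
# Grid search with k-fold cross-validation
# ---------------------------------------------------------------------------

def grid_search(
    train_graphs: list[LabeledGraph],
    n_folds: int = 5,
    grid: list[dict] | None = None,
    seed: int = 0,
    **fit_overrides,
) -> tuple[dict, pd.DataFrame]:
    """Evaluate grid configurations by mean k-fold validation masked MSE.

    Returns the argmin configuration and the full CV table. ``fit_overrides``
    (e.g. ``epochs=20, hidden=32``) apply to every configuration and allow
    desk-scale runs; the selection criterion is unchanged.
    """
    if len(train_graphs) < n_folds:
        raise ValueError(f"need at least {n_folds} molecules for {n_folds}-fold CV")
    grid = grid if grid is not None else hyperparameter_grid()
    rng = np.random.default_rng(seed)
    fold_of = rng.permutation(len(train_graphs)) % n_folds
    rows = []
    for cfg_index, cfg in enumerate(grid):
        fold_losses = []
        for fold in range(n_folds):
            train = [g for g, f in zip(train_graphs, fold_of) if f != fold]
            val = [g for g, f in zip(train_graphs, fold_of) if f == fold]
            model = GNNNodeRegressor(**cfg, random_state=seed, **fit_overrides)
            model.fit(train, validation=val)
            fold_losses.append(-model.score(val))
        rows.append({**cfg, "config_index": cfg_index, "cv_masked_mse": float(np.mean(fold_losses))})
    table = pd.DataFrame(rows)
    best = table.loc[table["cv_masked_mse"].idxmin()]
    best_cfg = {k: best[k] for k in GRID_DIMENSIONS}
    best_cfg["n_conv"] = int(best_cfg["n_conv"])
    best_cfg["n_linear"] = int(best_cfg["n_linear"])
    return best_cfg, table
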