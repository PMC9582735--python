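"""Assembly of molecule batches for the graph networks.

A batch of molecular graphs is represented as one disjoint union: node feature
rows are concatenated, the GCN operator becomes a block-diagonal sparse matrix,
and the attention layers see one offset edge list. The optional dummy node —
an artificial vertex with all-zero features connected to every atom of its
molecule — is appended per graph here, and a boolean ``real`` mask tracks which
rows are actual atoms (dummy rows are excluded from labels, loss, predictions
and saliency).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .data import LabeledGraph

__all__ = ["GraphBatch", "prepare_graph", "collate"]


@dataclass
class PreparedGraph:
    """Cached per-graph arrays, computed once before training."""

    x: np.ndarray            # (n, 42) node features (incl. dummy row if used)
    a_norm: sp.csr_matrix    # symmetric-normalised adjacency with self loops
    edges: np.ndarray        # (2, E) src/dst incl. self loops (directed both ways)
    real: np.ndarray         # (n,) bool, False for the dummy row
    values: np.ndarray       # (n, n_sub) labels (zero rows for dummy)
    mask: np.ndarray         # (n, n_sub)
    graph_id: str


@dataclass
class GraphBatch:
    x: np.ndarray
    a_norm: sp.csr_matrix
    src: np.ndarray
    dst: np.ndarray
    real: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    sizes: list[int]          # nodes per graph (incl. dummy rows)
    ids: list[str]

    @property
    def n_nodes(self) -> int:
        return self.x.shape[0]


def _normalised_adjacency(adj: np.ndarray) -> sp.csr_matrix:
    """D^-1/2 (A + I) D^-1/2 — the symmetric GCN propagation operator."""
    a = adj + np.eye(adj.shape[0])
    d = a.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return sp.csr_matrix(a * inv_sqrt[:, None] * inv_sqrt[None, :])


def prepare_graph(graph: LabeledGraph, use_dummy_node: bool = False) -> PreparedGraph:
    n = graph.molecule.n_atoms
    adj = graph.molecule.adjacency()
    x = graph.features
    values = graph.labels.values
    mask = graph.labels.mask
    real = np.ones(n, dtype=bool)
    if use_dummy_node:
        # dummy vertex: zero features, bidirectional edges to every atom
        adj = np.pad(adj, ((0, 1), (0, 1)))
        adj[:n, n] = adj[n, :n] = 1.0
        x = np.vstack([x, np.zeros((1, x.shape[1]))])
        values = np.vstack([values, np.zeros((1, values.shape[1]))])
        mask = np.vstack([mask, np.zeros((1, mask.shape[1]))])
        real = np.append(real, False)
    src, dst = np.nonzero(adj + np.eye(adj.shape[0]))  # self loops for attention
    return PreparedGraph(
        x=x,
        a_norm=_normalised_adjacency(adj),
        edges=np.stack([src, dst]),
        real=real,
        values=values,
        mask=mask,
        graph_id=graph.id,
    )


def collate(prepared: list[PreparedGraph]) -> GraphBatch:
    sizes = [p.x.shape[0] for p in prepared]
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    src = np.concatenate([p.edges[0] + off for p, off in zip(prepared, offsets)])
    dst = np.concatenate([p.edges[1] + off for p, off in zip(prepared, offsets)])
    return GraphBatch(
        x=np.vstack([p.x for p in prepared]),
        a_norm=sp.block_diag([p.a_norm for p in prepared], format="csr"),
        src=src,
        dst=dst,
        real=np.concatenate([p.real for p in prepared]),
        values=np.vstack([p.values for p in prepared]),
        mask=np.vstack([p.mask for p in prepared]),
        sizes=sizes,
        ids=[p.graph_id for p in prepared],
    )
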