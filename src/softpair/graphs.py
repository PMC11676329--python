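"""k-nearest-neighbor similarity graphs and the graph-alignment loss.

Interacting families share evolutionary history, so the k-NN similarity graph
of family A and that of family B have overlapping structure under the correct
pairing.  Each collection is turned into a weighted graph with Gaussian-kernel
weights W_ij = exp(-d(s_i, s_j) / D^2) on the symmetrized k-NN support, where
D is the average distance of the k-th nearest neighbor over the collection.
Hamming distances are used for aligned sequences, unit-cost edit (Levenshtein)
distances otherwise.  The alignment loss is the negative overlap
-sum_{i<j} (W_A)_ij (W_B)_ij of edge weights under a candidate correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from .mi import PairingLoss
from .permutation import HardPermutation, SoftPermutation
from .sequence_io import SequenceCollection, SequenceInputError

#: Default neighbor counts: aligned paralog matching vs nonaligned mode.
DEFAULT_K_ALIGNED = 30
DEFAULT_K_NONALIGNED = 20


@dataclass
class WeightGraph:
    """Symmetric nonnegative k-NN weight matrix over one collection."""

    weights: np.ndarray
    k: int
    metric: str  # {"hamming", "edit"}
    scale: float  # D: mean k-th-neighbor distance

    def __post_init__(self) -> None:
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")

    @property
    def n(self) -> int:
        return self.weights.shape[0]


def pairwise_distances(c: SequenceCollection, metric: str) -> np.ndarray:
    """Symmetric distance matrix: Hamming (aligned) or unit-cost edit.

    In nonaligned mode, padding rows (empty strings) are placed at maximal
    distance (max real-real distance + 1) from every real sequence, and at
    distance 0 from each other, so they never enter real neighborhoods.
    """
    n = len(c)
    if metric == "hamming":
        if not c.aligned:
            raise SequenceInputError("Hamming distances require aligned sequences")
        idx = c.to_indices()
        d = (idx[:, None, :] != idx[None, :, :]).sum(axis=2).astype(np.float64)
    elif metric == "edit":
        seqs = c.sequences()
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = edlib.align(seqs[i], seqs[j])["editDistance"]
    else:
        raise ValueError(f"unknown metric {metric!r}")

    if metric == "edit":
        pad = c.padding_mask()
        if pad.any() and (~pad).any():
            real = ~pad
            d_max = float(d[np.ix_(real, real)].max())
            d[pad, :] = d_max + 1.0
            d[:, pad] = d_max + 1.0
            d[np.ix_(pad, pad)] = 0.0
    np.fill_diagonal(d, 0.0)
    return d


def default_metric(c: SequenceCollection) -> str:
    return "hamming" if c.aligned else "edit"


def default_k(c: SequenceCollection) -> int:
    k = DEFAULT_K_ALIGNED if c.aligned else DEFAULT_K_NONALIGNED
    return min(k, len(c) - 1)


def knn_weight_graph(
    c: SequenceCollection, k: int | None = None, metric: str | None = None
) -> WeightGraph:
    """Gaussian-kernel weights on the symmetrized k-NN support.

    Neighbors are ordered by (distance, index) — exactly k are kept per node
    before symmetrization; a node is never its own neighbor and the diagonal
    is forced to zero.  D is the average (over non-padding nodes) of the
    k-th-neighbor distance, computed once for the whole collection.
    """
    if metric is None:
        metric = default_metric(c)
    if k is None:
        k = default_k(c)
    n = len(c)
    if not (0 < k < n):
        raise ValueError(f"k must satisfy 0 < k < {n}, got {k}")
    d = pairwise_distances(c, metric)

    order = np.lexsort(
        (np.broadcast_to(np.arange(n), (n, n)), d), axis=1
    )  # per row: by (distance, index)
    support = np.zeros((n, n), dtype=bool)
    kth = np.empty(n)
    for i in range(n):
        neigh = order[i][order[i] != i][:k]
        support[i, neigh] = True
        kth[i] = d[i, neigh[-1]]
    support |= support.T

    pad = c.padding_mask()
    d_scale = float(kth[~pad].mean()) if (~pad).any() else float(kth.mean())
    if d_scale == 0.0:
        raise ValueError(
            "k-th neighbor distances are all zero (identical sequences); "
            "check the input data or the distance metric"
        )
    w = np.where(support, np.exp(-d / d_scale**2), 0.0)
    np.fill_diagonal(w, 0.0)
    return WeightGraph(weights=w, k=k, metric=metric, scale=d_scale)


def ga_loss(wa: WeightGraph | np.ndarray, wb: WeightGraph | np.ndarray) -> PairingLoss:
    """Negative upper-triangular overlap of the two weight matrices."""
    a = wa.weights if isinstance(wa, WeightGraph) else np.asarray(wa)
    b = wb.weights if isinstance(wb, WeightGraph) else np.asarray(wb)
    if a.shape != b.shape:
        raise ValueError(f"graph size mismatch: {a.shape} vs {b.shape}")
    iu = np.triu_indices(a.shape[0], k=1)
    return PairingLoss(
        value=float(-(a[iu] * b[iu]).sum()), kind="graph_alignment", smooth=False
    )


def permute_graph(perm: HardPermutation, wa: WeightGraph) -> np.ndarray:
    """W_A with rows and columns reordered so entry (n, m) refers to B-order."""
    idx = perm.to_global()
    return wa.weights[np.ix_(idx, idx)]


def soft_ga_loss(
    p: SoftPermutation, wa: WeightGraph, wb: WeightGraph
) -> PairingLoss:
    """Smooth extension: the loss evaluated on P W_A P^T versus W_B."""
    pg = p.to_global()
    if pg.shape[0] != wa.n or wa.n != wb.n:
        raise ValueError("shape mismatch between soft permutation and graphs")
    mixed = pg @ wa.weights @ pg.T
    iu = np.triu_indices(wa.n, k=1)
    return PairingLoss(
        value=float(-(mixed[iu] * wb.weights[iu]).sum()),
        kind="graph_alignment",
        smooth=True,
    )


def soft_loss_and_grad(
    p_global: np.ndarray, wa: WeightGraph, wb: WeightGraph
) -> tuple[float, np.ndarray]:
    """Smooth GA loss and its gradient -W_B P W_A w.r.t. the soft permutation.

    Both weight matrices are symmetric with zero diagonal, so the strict
    upper-triangular sum equals half the full elementwise product.
    """
    mixed = p_global @ wa.weights @ p_global.T
    loss = float(-0.5 * (mixed * wb.weights).sum())
    grad = -(wb.weights @ p_global @ wa.weights)
    return loss, grad
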