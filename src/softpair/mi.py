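"""Inter-chain mutual-information scores for paired aligned collections.

The inter-chain MI score of two aligned collections is the sum, over all
cross-family column pairs (i, j), of the plug-in mutual information estimate
I(A_i; B_j) computed from observed joint symbol frequencies.  Because one-body
entropies are invariant under row permutations, maximizing the MI score over
within-species permutations is equivalent to minimizing the inter-chain
two-body entropy loss: the sum of plug-in joint entropies H(A_i, B_j).

The smooth extension replaces the hard-permuted one-hot tensor by a soft
collection (soft permutation times one-hot tensor); joint counts become the
contraction sum_n m_A[i, n] (x) m_B[j, n] with fractional fibers.  All
entropies are in nats.  Gaps count as an ordinary symbol state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import entr

from .permutation import HardPermutation, apply_hard
from .sequence_io import OneHotTensor


@dataclass
class EntropyEstimate:
    """Plug-in Shannon entropy, in nats."""

    value: float


@dataclass
class PairingLoss:
    value: float
    kind: str  # {"two_body_entropy", "graph_alignment"}
    smooth: bool


def _as_flat(t) -> tuple[np.ndarray, bool]:
    """(N, L*q) float matrix plus a flag: was the input soft (plain array)?"""
    if isinstance(t, OneHotTensor):
        return t.flat().astype(np.float64, copy=False), False
    arr = np.asarray(t, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("soft tensor must have axes (sequence, column, symbol)")
    n, l, q = arr.shape
    return arr.reshape(n, l * q), True


def column_entropy(col: np.ndarray) -> EntropyEstimate:
    """Plug-in entropy of one column given as an (N, q) fiber matrix."""
    freqs = np.asarray(col, dtype=np.float64).mean(axis=0)
    return EntropyEstimate(value=float(entr(freqs).sum()))


def _joint_freqs(a_flat: np.ndarray, b_flat: np.ndarray) -> np.ndarray:
    if a_flat.shape[0] != b_flat.shape[0]:
        raise ValueError(
            f"sequence-depth mismatch: {a_flat.shape[0]} vs {b_flat.shape[0]}"
        )
    n = a_flat.shape[0]
    return (a_flat.T @ b_flat) / n


def two_body_entropy_loss(a, b) -> PairingLoss:
    """Sum over all column pairs (i, j) of the plug-in joint entropy.

    ``a`` may be a hard one-hot tensor or a soft collection (then this is the
    smooth extension, via fractional joint counts); ``b`` must be hard.
    """
    a_flat, soft = _as_flat(a)
    b_flat, _ = _as_flat(b)
    joint = _joint_freqs(a_flat, b_flat)
    return PairingLoss(
        value=float(entr(joint).sum()), kind="two_body_entropy", smooth=soft
    )


def inter_chain_mi(a: OneHotTensor, b: OneHotTensor) -> float:
    """Sum over column pairs of H(A_i) + H(B_j) - H(A_i, B_j)."""
    if not isinstance(a, OneHotTensor) or not isinstance(b, OneHotTensor):
        raise TypeError("inter_chain_mi takes hard one-hot tensors")
    na, la, qa = a.data.shape
    nb, lb, qb = b.data.shape
    if na != nb:
        raise ValueError(f"sequence-depth mismatch: {na} vs {nb}")
    joint = _joint_freqs(a.flat(), b.flat()).reshape(la, qa, lb, qb)
    h_joint = entr(joint).sum(axis=(1, 3))  # (la, lb)
    h_a = entr(a.data.mean(axis=0)).sum(axis=1)  # (la,)
    h_b = entr(b.data.mean(axis=0)).sum(axis=1)  # (lb,)
    return float((h_a[:, None] + h_b[None, :] - h_joint).sum())


def excess_loss(
    predicted: HardPermutation,
    ground_truth: HardPermutation,
    a: OneHotTensor,
    b: OneHotTensor,
) -> float:
    """Two-body entropy loss of the predicted pairing minus the ground truth's.

    Equal to minus the difference of the corresponding inter-chain MI scores,
    since one-body entropies are permutation-invariant.
    """
    lp = two_body_entropy_loss(apply_hard(predicted, a), b).value
    lt = two_body_entropy_loss(apply_hard(ground_truth, a), b).value
    return float(lp - lt)


def soft_loss_and_grad(
    p_global: np.ndarray, a: OneHotTensor, b: OneHotTensor
) -> tuple[float, np.ndarray]:
    """Smooth two-body entropy loss and its gradient w.r.t. the soft permutation.

    d(-f ln f)/df = -(ln f + 1); zero-count joint states are structural zeros
    whose subgradient contribution is taken as 0.
    """
    a_flat = a.flat()
    b_flat = b.flat()
    n = a_flat.shape[0]
    soft_a = p_global @ a_flat
    joint = (soft_a.T @ b_flat) / n
    loss = float(entr(joint).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(joint > 0.0, -(np.log(joint) + 1.0), 0.0)
    d_soft_a = (b_flat @ g.T) / n
    d_p = d_soft_a @ a_flat.T
    return loss, d_p
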