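"""The single-gradient-step bootstrap over within-species soft permutations.

Each elementary optimization starts from the uniform ("as soft as possible")
soft permutation, takes exactly one gradient step of the smooth loss with
respect to the free parameterization entries, renormalizes with the Sinkhorn
operator, and reads off the nearest hard permutation.  The bootstrap repeats
this with a growing fixed-pair context: after each iteration, n pairs are
sampled uniformly at random from the latest hard permutation and frozen for
the next run, with n increasing from 0 to the number of pairable sequences in
steps of ``step_size``.  Fixed pairs are excluded from the gradient but always
included in the loss.  The single step from the uniform initialization makes
the procedure insensitive to learning rate and to the Sinkhorn hyperparameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import graphs as _graphs
from . import mi as _mi
from .permutation import (
    FixedPairs,
    HardPermutation,
    ParameterizationMatrices,
    SinkhornTape,
    embed_fixed,
    hard_from_soft,
    sinkhorn,
    sinkhorn_vjp,
)
from .sequence_io import (
    OneHotTensor,
    PairedCollections,
    SequenceCollection,
    SequenceInputError,
    one_hot_encode,
)


@dataclass
class BootstrapConfig:
    """Configuration of one bootstrap run.

    ``step_size`` is the context growth increment (default 1 — the only
    parameter of the method worth tuning); ``temperature`` and ``n_iter``
    parameterize the truncated Sinkhorn operator; ``loss`` selects the score
    family ("mi" needs aligned collections, "ga" does not).
    """

    step_size: int = 1
    temperature: float = 1.0
    n_iter: int = 100
    seed: int = 0
    loss: str = "mi"  # {"mi", "ga"}
    knn_k: int | None = None  # GA only; None -> per-mode default
    metric: str | None = None  # GA only; None -> hamming/edit by alignment

    def __post_init__(self) -> None:
        if self.step_size < 1:
            raise ValueError("step_size must be >= 1")
        if self.loss not in ("mi", "ga"):
            raise ValueError(f"unknown loss kind {self.loss!r}")


@dataclass
class TraceEntry:
    fixed: FixedPairs
    hard: HardPermutation
    loss: float


@dataclass
class BootstrapTrace:
    """Every hard permutation and discrete loss observed during one bootstrap."""

    entries: list[TraceEntry] = field(default_factory=list)

    @property
    def best(self) -> int:
        losses = [e.loss for e in self.entries]
        return int(np.argmin(losses))

    @property
    def best_entry(self) -> TraceEntry:
        return self.entries[self.best]

    def __len__(self) -> int:
        return len(self.entries)


class MutualInformationModel:
    """Discrete and smooth inter-chain two-body entropy loss."""

    kind = "mi"

    def __init__(self, a: SequenceCollection, b: SequenceCollection):
        if not (a.aligned and b.aligned):
            raise SequenceInputError(
                "MI scoring requires aligned collections on both sides"
            )
        self.a = one_hot_encode(a)
        self.b = one_hot_encode(b)
        self._b_flat = self.b.flat()

    def discrete_loss(self, perm: HardPermutation) -> float:
        a_flat = self.a.flat()[perm.to_global()]
        n = a_flat.shape[0]
        joint = (a_flat.T @ self._b_flat) / n
        from scipy.special import entr

        return float(entr(joint).sum())

    def smooth_loss_and_grad(self, p_global: np.ndarray) -> tuple[float, np.ndarray]:
        return _mi.soft_loss_and_grad(p_global, self.a, self.b)


class GraphAlignmentModel:
    """Discrete and smooth k-NN graph-alignment loss."""

    kind = "ga"

    def __init__(
        self,
        a: SequenceCollection,
        b: SequenceCollection,
        k: int | None = None,
        metric: str | None = None,
    ):
        self.wa = _graphs.knn_weight_graph(a, k=k, metric=metric)
        self.wb = _graphs.knn_weight_graph(b, k=k, metric=metric)

    def discrete_loss(self, perm: HardPermutation) -> float:
        permuted = _graphs.permute_graph(perm, self.wa)
        return _graphs.ga_loss(permuted, self.wb.weights).value

    def smooth_loss_and_grad(self, p_global: np.ndarray) -> tuple[float, np.ndarray]:
        return _graphs.soft_loss_and_grad(p_global, self.wa, self.wb)


def build_loss_model(a: SequenceCollection, b: SequenceCollection, cfg: BootstrapConfig):
    if cfg.loss == "mi":
        return MutualInformationModel(a, b)
    return GraphAlignmentModel(a, b, k=cfg.knn_k, metric=cfg.metric)


def _single_step(model, partition, fixed: FixedPairs, cfg: BootstrapConfig):
    """One gradient step from the uniform initialization, then discretize."""
    x0 = ParameterizationMatrices.zeros(partition)
    constrained = embed_fixed(x0, fixed)
    tapes: list[SinkhornTape] = []
    soft0 = sinkhorn(
        constrained, temperature=cfg.temperature, n_iter=cfg.n_iter, _tapes=tapes
    )
    _, d_p = model.smooth_loss_and_grad(soft0.to_global())
    grads = sinkhorn_vjp(constrained, tapes, d_p)

    # normalized descent step X = -G / ||G||_inf per species, free entries only
    x1 = ParameterizationMatrices(
        blocks=tuple(xb.copy() for xb in x0.blocks), partition=partition
    )
    constrained1 = embed_fixed(x1, fixed)
    for k in range(partition.n_species):
        g = grads[k]
        if g.size == 0:
            continue
        gmax = float(np.abs(g).max())
        if gmax == 0.0:
            continue
        rows, cols = constrained1.free_indices(k)
        x1.blocks[k][np.ix_(rows, cols)] = -g / gmax

    soft1 = sinkhorn(constrained1, temperature=cfg.temperature, n_iter=cfg.n_iter)
    hard = hard_from_soft(soft1)
    return hard, model.discrete_loss(hard)


def single_gradient_run(
    a: SequenceCollection,
    b: SequenceCollection,
    fixed: FixedPairs | None = None,
    cfg: BootstrapConfig | None = None,
) -> tuple[HardPermutation, float]:
    """One single-gradient-step optimization; returns (hard permutation, discrete loss).

    The returned loss is the discrete loss of the returned hard permutation,
    with fixed pairs included in the loss computation.
    """
    cfg = cfg or BootstrapConfig()
    partition = a.partition
    if b.partition != partition:
        raise ValueError("collections must be harmonized to a shared partition")
    if fixed is None:
        fixed = FixedPairs.empty(partition)
    model = build_loss_model(a, b, cfg)
    return _single_step(model, partition, fixed, cfg)


def _sample_context(
    rng: np.random.Generator,
    hard: HardPermutation,
    initial_fixed: FixedPairs,
    n: int,
) -> FixedPairs:
    """Uniformly sample n pairs from ``hard``, excluding initially fixed ones."""
    partition = hard.partition
    candidates = [
        (k, a, b)
        for (k, a, b) in hard.pairs()
        if b not in initial_fixed.fixed_b_indices(k)
    ]
    chosen_idx = rng.choice(len(candidates), size=n, replace=False)
    blocks = [set(p) for p in initial_fixed.blocks]
    for i in chosen_idx:
        k, a, b = candidates[int(i)]
        blocks[k].add((a, b))
    return FixedPairs(
        blocks=tuple(frozenset(p) for p in blocks), partition=partition
    )


def run_bootstrap(
    a: SequenceCollection,
    b: SequenceCollection,
    cfg: BootstrapConfig | None = None,
    initial_fixed: FixedPairs | None = None,
    log=None,
) -> BootstrapTrace:
    """Full bootstrap: context size n = 0, step, 2*step, ..., N_free.

    Iteration 0 uses only ``initial_fixed``; each later iteration freshly
    samples its size-n context from the most recent hard permutation
    (``initial_fixed`` always retained).  The trace records every iteration.
    """
    cfg = cfg or BootstrapConfig()
    partition = a.partition
    if b.partition != partition:
        raise ValueError("collections must be harmonized to a shared partition")
    if initial_fixed is None:
        initial_fixed = FixedPairs.empty(partition)

    model = build_loss_model(a, b, cfg)
    rng = np.random.default_rng(cfg.seed)
    n_free = partition.total - initial_fixed.n_pairs()
    schedule = list(range(0, n_free, cfg.step_size)) + [n_free]

    trace = BootstrapTrace()
    robust: frozenset | None = None
    for it, n in enumerate(schedule):
        if n == 0:
            fixed = initial_fixed
        else:
            fixed = _sample_context(rng, trace.entries[-1].hard, initial_fixed, n)
        hard, loss = _single_step(model, partition, fixed, cfg)
        trace.entries.append(TraceEntry(fixed=fixed, hard=hard, loss=loss))
        pair_set = frozenset(hard.pairs())
        robust = pair_set if robust is None else (robust & pair_set)
        if log is not None:
            frac_robust = len(robust) / partition.total
            log.write(
                f"iter={it}\tn_fixed={n}\tloss={loss:.6f}"
                f"\trobust_frac={frac_robust:.4f}\n"
            )
    return trace


def fraction_correct(
    perm: HardPermutation,
    truth: HardPermutation,
    pair: PairedCollections | None = None,
    exclude_padding: bool = True,
) -> float:
    """Fraction of predicted pairs that match the ground-truth pairing.

    When ``pair`` is given and ``exclude_padding`` is set, predicted pairs
    that involve a padding row on either side are excluded from both the
    numerator and the denominator.
    """
    if perm.partition != truth.partition:
        raise ValueError("permutations belong to different partitions")
    p = perm.to_global()
    t = truth.to_global()
    keep = np.ones(len(p), dtype=bool)
    if exclude_padding and pair is not None:
        pad_a = pair.a.padding_mask()
        pad_b = pair.b.padding_mask()
        keep = ~(pad_b | pad_a[p])
    if not keep.any():
        return float("nan")
    return float((p[keep] == t[keep]).mean())
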