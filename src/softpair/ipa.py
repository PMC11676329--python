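"""Robust pairs and the iterative pairing refinement.

Pairs that appear in every hard permutation explored during a bootstrap are
called robust; empirically they have high precision, which makes them a good
seed set of fixed pairs for another bootstrap.  The iterative pairing
algorithm (IPA) repeats the bootstrap, unioning newly robust pairs (found
among the not-yet-fixed sequences) into the accumulated fixed set F_AB after
each run.  The final output is the hard permutation with the lowest observed
discrete loss across all runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .bootstrap import BootstrapConfig, BootstrapTrace, run_bootstrap
from .permutation import FixedPairs, HardPermutation
from .sequence_io import PairedCollections, SequenceCollection

DEFAULT_N_IPA = 3


@dataclass
class RobustPairSet:
    """Per-species pairs present in every hard permutation of a trace."""

    blocks: tuple[frozenset[tuple[int, int]], ...]
    provenance: int = 0  # IPA run index (1-based) in which the set was found

    def n_pairs(self) -> int:
        return sum(len(p) for p in self.blocks)

    def as_fixed(self, partition) -> FixedPairs:
        return FixedPairs(blocks=self.blocks, partition=partition)


@dataclass
class IpaResult:
    traces: list[BootstrapTrace]
    fixed_history: list[FixedPairs]  # F_AB after each run
    robust_entry_run: dict[tuple[int, int, int], int]  # (k, a, b) -> run index
    final: HardPermutation
    final_loss: float
    n_ipa: int


def robust_pairs(trace: BootstrapTrace, provenance: int = 0) -> RobustPairSet:
    """Exact intersection of all assignments recorded in a bootstrap trace."""
    if len(trace) == 0:
        raise ValueError("cannot extract robust pairs from an empty trace")
    partition = trace.entries[0].hard.partition
    common: list[set[tuple[int, int]]] = [
        {(int(a), int(b)) for b, a in enumerate(blk.tolist())}
        for blk in trace.entries[0].hard.blocks
    ]
    for entry in trace.entries[1:]:
        for k, blk in enumerate(entry.hard.blocks):
            common[k] &= {(int(a), int(b)) for b, a in enumerate(blk.tolist())}
    return RobustPairSet(
        blocks=tuple(frozenset(c) for c in common), provenance=provenance
    )


def run_ipa(
    a: SequenceCollection,
    b: SequenceCollection,
    cfg: BootstrapConfig | None = None,
    n_ipa: int = DEFAULT_N_IPA,
    log=None,
) -> IpaResult:
    """Iterated bootstraps seeded by accumulated robust pairs.

    Run 1 is a plain bootstrap.  After each run, robust pairs found among the
    sequences not yet in F_AB are added to F_AB, which seeds the next run as
    its initial fixed context.  If F_AB covers all sequences early, the
    remaining runs are skipped.
    """
    cfg = cfg or BootstrapConfig()
    if n_ipa < 1:
        raise ValueError("n_ipa must be a positive integer")
    partition = a.partition
    seeds = (np.random.SeedSequence(cfg.seed).generate_state(n_ipa) >> 1).tolist()

    f_ab = FixedPairs.empty(partition)
    traces: list[BootstrapTrace] = []
    fixed_history: list[FixedPairs] = []
    robust_entry_run: dict[tuple[int, int, int], int] = {}
    best_perm: HardPermutation | None = None
    best_loss = np.inf

    for r in range(1, n_ipa + 1):
        run_cfg = replace(cfg, seed=int(seeds[r - 1]))
        trace = run_bootstrap(a, b, run_cfg, initial_fixed=f_ab, log=log)
        traces.append(trace)
        for entry in trace.entries:
            if entry.loss < best_loss:
                best_loss = entry.loss
                best_perm = entry.hard

        rp = robust_pairs(trace, provenance=r)
        new_blocks = []
        for k, pairs in enumerate(rp.blocks):
            already_b = f_ab.fixed_b_indices(k)
            fresh = frozenset(p for p in pairs if p[1] not in already_b)
            for aa, bb in fresh:
                robust_entry_run[(k, aa, bb)] = r
            new_blocks.append(fresh | f_ab.blocks[k])
        f_ab = FixedPairs(blocks=tuple(new_blocks), partition=partition)
        fixed_history.append(f_ab)

        if f_ab.n_pairs() == partition.total and r < n_ipa:
            if log is not None:
                log.write(
                    f"# F_AB covers all {partition.total} sequences after run {r}; "
                    f"skipping remaining runs\n"
                )
            break

    assert best_perm is not None
    return IpaResult(
        traces=traces,
        fixed_history=fixed_history,
        robust_entry_run=robust_entry_run,
        final=best_perm,
        final_loss=float(best_loss),
        n_ipa=n_ipa,
    )


def robust_pair_precision(
    rp: RobustPairSet,
    truth: HardPermutation,
    pair: PairedCollections | None = None,
) -> tuple[int, int, float]:
    """(n_robust, n_correct, precision) of a robust-pair set; pads excluded."""
    n_robust = 0
    n_correct = 0
    pad_a = pair.a.padding_mask() if pair is not None else None
    pad_b = pair.b.padding_mask() if pair is not None else None
    offsets = truth.partition.offsets
    for k, pairs in enumerate(rp.blocks):
        off = offsets[k]
        for a, b in pairs:
            if pad_a is not None and (pad_a[off + a] or pad_b[off + b]):
                continue
            n_robust += 1
            if truth.blocks[k][b] == a:
                n_correct += 1
    precision = n_correct / n_robust if n_robust else float("nan")
    return n_robust, n_correct, precision
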