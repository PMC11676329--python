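"""Seeded generators of species-partitioned paired collections with planted truth.

Two signal models mirror the two score families:

* coupled mode — a set of designated cross-family column pairs share a latent
  symbol with probability ``coupling`` in each interacting pair of sequences,
  planting inter-family correlation in amino-acid usage (the premise of
  mutual-information scoring) on a uniform random background;
* phylogeny mode — each interacting pair descends from a common ancestor
  string, and ancestors are related through a random-attachment genealogy, so
  partners of similar A-sequences are themselves similar B-sequences and the
  two k-NN similarity graphs share structure under the true pairing (the
  premise of graph-alignment scoring).  Optionally emits nonaligned sequences
  with indels.

Also provides the exhaustive brute-force oracle over all within-species
permutations, used to certify optimality on tiny instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.special import entr

from . import graphs as _graphs
from .permutation import HardPermutation
from .sequence_io import (
    PROTEIN_ALPHABET,
    PairedCollections,
    SequenceCollection,
    SequenceRecord,
    harmonize_pair,
    one_hot_encode,
)

#: Guard on the brute-force search-space size prod(N_k!).
BRUTE_FORCE_GUARD = 1_000_000

#: Default test-scale configuration: ~100 pairs with strong coupling signal.
DEFAULT_TEST_SCALE = dict(
    n_species=25,
    species_size=4,
    length_a=40,
    length_b=40,
    alphabet_size=21,
    n_coupled=60,
    coupling=0.9,
)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic planted-pairing generators.

    ``species_size`` may be an int (fixed) or an (lo, hi) tuple (sampled
    uniformly per species, inclusive).  ``coupling`` is the probability that a
    designated column pair copies the shared latent symbol.  ``mutation_rate``
    is the per-site substitution rate from ancestor to descendant in
    phylogeny mode; in nonaligned mode each site is additionally deleted with
    probability ``mutation_rate / 4`` and followed by a geometric number of
    insertions with the same rate.
    """

    n_species: int = 25
    species_size: int | tuple[int, int] = 4
    length_a: int = 40
    length_b: int = 40
    alphabet_size: int = 21
    n_coupled: int = 60
    coupling: float = 0.9
    phylogeny: bool = False
    mutation_rate: float = 0.05
    ancestor_divergence: float = 0.3
    unequal_prob: float = 0.0
    aligned: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.coupling <= 1.0):
            raise ValueError("coupling must lie in [0, 1]")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.n_coupled > self.length_a * self.length_b:
            raise ValueError("n_coupled exceeds the number of column pairs")
        if not (2 <= self.alphabet_size <= len(PROTEIN_ALPHABET)):
            raise ValueError(
                f"alphabet_size must lie in [2, {len(PROTEIN_ALPHABET)}]"
            )

    def symbols(self) -> str:
        return PROTEIN_ALPHABET[: self.alphabet_size]

    def sizes(self, rng: np.random.Generator) -> list[int]:
        if isinstance(self.species_size, tuple):
            lo, hi = self.species_size
            return rng.integers(lo, hi + 1, size=self.n_species).tolist()
        return [self.species_size] * self.n_species


def _to_strings(mat: np.ndarray, symbols: str) -> list[str]:
    lut = np.array(list(symbols))
    return ["".join(row) for row in lut[mat]]


def _finalize(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    sizes: list[int],
    seqs_a: list[str],
    seqs_b: list[str],
    aligned_a: bool,
    aligned_b: bool,
) -> tuple[PairedCollections, HardPermutation]:
    """Shuffle A within species, optionally unbalance B, harmonize, build truth."""
    rec_a: list[SequenceRecord] = []
    rec_b: list[SequenceRecord] = []
    truth_blocks: list[np.ndarray] = []
    offset = 0
    for k, m in enumerate(sizes):
        sp = f"sp{k:03d}"
        # drop the last B member of this species with probability unequal_prob
        # (its A partner then pairs with the all-gap padding row)
        drop_last_b = m > 1 and rng.random() < cfg.unequal_prob
        new_order = rng.permutation(m)  # A-row at position p is original new_order[p]
        inv = np.argsort(new_order)  # original o sits at position inv[o]
        for p in range(m):
            o = int(new_order[p])
            rec_a.append(
                SequenceRecord(id=f"A_{sp}_{o}", species=sp, seq=seqs_a[offset + o])
            )
        n_b = m - 1 if drop_last_b else m
        for o in range(n_b):
            rec_b.append(
                SequenceRecord(id=f"B_{sp}_{o}", species=sp, seq=seqs_b[offset + o])
            )
        truth_blocks.append(inv.copy())  # truth[b] = position of A partner
        offset += m

    coll_a = SequenceCollection(records=rec_a, aligned=aligned_a)
    coll_b = SequenceCollection(records=rec_b, aligned=aligned_b)
    pair = harmonize_pair(coll_a, coll_b)
    # after harmonization, a dropped B row is replaced by a padding row at the
    # end of the species block, which restores its original local index
    truth = HardPermutation(blocks=tuple(truth_blocks), partition=pair.partition)
    return pair, truth


def generate_coupled_pair(
    cfg: GeneratorConfig,
) -> tuple[PairedCollections, HardPermutation]:
    """Planted coevolution instance: correlated cross-family column pairs."""
    rng = np.random.default_rng(cfg.seed)
    sizes = cfg.sizes(rng)
    n_total = int(sum(sizes))
    q = cfg.alphabet_size

    mat_a = rng.integers(q, size=(n_total, cfg.length_a))
    mat_b = rng.integers(q, size=(n_total, cfg.length_b))
    flat = rng.choice(cfg.length_a * cfg.length_b, size=cfg.n_coupled, replace=False)
    col_pairs = [divmod(int(f), cfg.length_b) for f in flat.tolist()]
    # Column pairs may share columns.  One latent per connected component of
    # the bipartite coupled-column graph keeps overlapping writes consistent,
    # so every designated pair carries the full coupling strength.
    graph = sparse.lil_matrix(
        (cfg.length_a + cfg.length_b, cfg.length_a + cfg.length_b), dtype=np.int8
    )
    for i, j in col_pairs:
        graph[i, cfg.length_a + j] = 1
    _, labels = sparse.csgraph.connected_components(graph.tocsr(), directed=False)
    latents = {
        c: rng.integers(q, size=n_total) for c in sorted(set(labels.tolist()))
    }
    for i, j in col_pairs:
        latent = latents[labels[i]]
        mask = rng.random(n_total) < cfg.coupling
        mat_a[mask, i] = latent[mask]
        mat_b[mask, j] = latent[mask]

    symbols = cfg.symbols()
    return _finalize(
        cfg,
        rng,
        sizes,
        _to_strings(mat_a, symbols),
        _to_strings(mat_b, symbols),
        aligned_a=True,
        aligned_b=True,
    )


def _mutate(row: np.ndarray, rate: float, q: int, rng: np.random.Generator):
    out = row.copy()
    mask = rng.random(len(row)) < rate
    out[mask] = rng.integers(q, size=int(mask.sum()))
    return out


def _apply_indels(row: np.ndarray, rate: float, q: int, rng: np.random.Generator):
    """Per-site deletions (prob rate) and geometric insertions (prob rate)."""
    out: list[int] = []
    for sym in row.tolist():
        if rng.random() >= rate:
            out.append(sym)
        if rng.random() < rate:
            n_ins = int(rng.geometric(0.5))
            out.extend(rng.integers(q, size=n_ins).tolist())
    if not out:  # never emit an empty real sequence
        out.append(int(rng.integers(q)))
    return np.array(out, dtype=np.int64)


def generate_phylo_pair(
    cfg: GeneratorConfig,
) -> tuple[PairedCollections, HardPermutation]:
    """Planted shared-genealogy instance for graph-alignment scoring."""
    if not cfg.phylogeny:
        raise ValueError("generate_phylo_pair requires a config with phylogeny=True")
    rng = np.random.default_rng(cfg.seed)
    sizes = cfg.sizes(rng)
    n_total = int(sum(sizes))
    q = cfg.alphabet_size
    length = cfg.length_a

    # random-attachment genealogy of per-pair ancestors
    ancestors = np.empty((n_total, length), dtype=np.int64)
    ancestors[0] = rng.integers(q, size=length)
    for n in range(1, n_total):
        parent = int(rng.integers(n))
        ancestors[n] = _mutate(ancestors[parent], cfg.ancestor_divergence, q, rng)

    rows_a = [_mutate(ancestors[n], cfg.mutation_rate, q, rng) for n in range(n_total)]
    rows_b = [_mutate(ancestors[n], cfg.mutation_rate, q, rng) for n in range(n_total)]
    if not cfg.aligned:
        indel_rate = cfg.mutation_rate / 4.0
        rows_a = [_apply_indels(r, indel_rate, q, rng) for r in rows_a]
        rows_b = [_apply_indels(r, indel_rate, q, rng) for r in rows_b]

    symbols = cfg.symbols()
    lut = np.array(list(symbols))
    seqs_a = ["".join(lut[r]) for r in rows_a]
    seqs_b = ["".join(lut[r]) for r in rows_b]
    return _finalize(
        cfg, rng, sizes, seqs_a, seqs_b, aligned_a=cfg.aligned, aligned_b=cfg.aligned
    )


def _search_space(sizes) -> int:
    total = 1
    for s in sizes:
        for i in range(2, s + 1):
            total *= i
    return total


def brute_force_best(
    a: SequenceCollection,
    b: SequenceCollection,
    loss: str = "mi",
    knn_k: int | None = None,
    metric: str | None = None,
) -> tuple[HardPermutation, float]:
    """Global optimum of the discrete loss by exhaustive enumeration.

    Candidates are visited in lexicographic permutation order and ties are
    broken toward the first (lexicographically smallest) optimum.  Guarded by
    ``BRUTE_FORCE_GUARD`` on the search-space size prod(N_k!).
    """
    partition = a.partition
    if b.partition != partition:
        raise ValueError("collections must be harmonized to a shared partition")
    space = _search_space(partition.sizes)
    if space > BRUTE_FORCE_GUARD:
        raise ValueError(
            f"search space prod(N_k!) = {space} exceeds the guard "
            f"({BRUTE_FORCE_GUARD}); brute force refused"
        )

    if loss == "mi":
        a_flat = one_hot_encode(a).flat()
        b_flat = one_hot_encode(b).flat()
        n = a_flat.shape[0]

        def evaluate(rows: np.ndarray) -> float:
            joint = (a_flat[rows].T @ b_flat) / n
            return float(entr(joint).sum())

    elif loss == "ga":
        wa = _graphs.knn_weight_graph(a, k=knn_k, metric=metric)
        wb = _graphs.knn_weight_graph(b, k=knn_k, metric=metric)
        iu = np.triu_indices(wa.n, k=1)
        wb_flat = wb.weights[iu]

        def evaluate(rows: np.ndarray) -> float:
            permuted = wa.weights[np.ix_(rows, rows)]
            return float(-(permuted[iu] * wb_flat).sum())

    else:
        raise ValueError(f"unknown loss kind {loss!r}")

    offsets = partition.offsets
    best_loss = np.inf
    best_blocks: tuple | None = None
    per_species = [
        list(itertools.permutations(range(s))) for s in partition.sizes
    ]
    rows = np.empty(partition.total, dtype=np.int64)
    for combo in itertools.product(*per_species):
        for off, blk in zip(offsets, combo):
            rows[off : off + len(blk)] = off + np.array(blk)
        val = evaluate(rows)
        if val < best_loss:  # strict: first optimum in lex order wins ties
            best_loss = val
            best_blocks = combo
    assert best_blocks is not None
    perm = HardPermutation(
        blocks=tuple(np.array(blk, dtype=np.int64) for blk in best_blocks),
        partition=partition,
    )
    return perm, float(best_loss)
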