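# softpair

Differentiable pairing of interacting biological sequences.

## The problem

Many proteins act in one-to-one complexes: histidine kinases with their
response regulators, ABC-transporter subunits, TCR α with β chains.  Sequence
databases, however, list the members of each family per species without
saying *who partners whom*.  Given two ordered sequence collections
`M_A`, `M_B`, each partitioned into K species with `N_k` members, the paralog
matching problem asks for the within-species permutation π of the rows of
`M_A` that recovers the interacting pairs.  The search space `∏_k N_k!` rules
out brute force beyond toy sizes.

Two signals make the problem tractable:

* **Coevolution** — interface contacts maintain physico-chemical
  complementarity, producing correlated amino-acid usage between partners.
  For aligned collections we score a candidate pairing with the inter-chain
  mutual information summed over all cross-family column pairs,

  `S_MI = Σ_{i,j} [H(A_i) + H(B_j) − H(A_i, B_j)]`,

  whose maximization is equivalent to minimizing the inter-chain two-body
  entropy loss `L_2BE(π) = Σ_{i,j} H(π(A)_i, B_j)` (one-body entropies are
  permutation-invariant).  All entropies are plug-in estimates in nats; gaps
  count as an ordinary 21st state.

* **Shared evolutionary history** — partners of similar A-sequences tend to
  be similar B-sequences.  We build k-nearest-neighbor similarity graphs with
  Gaussian kernel weights `W_ij = exp(−d(s_i, s_j)/D²)` on the symmetrized
  k-NN support (`d` = Hamming for aligned, edit distance otherwise; `D` =
  mean k-th-neighbor distance) and minimize the graph-alignment loss
  `L_GA = −Σ_{i<j} (W_A)_ij (W_B)_ij` under the candidate correspondence.
  This mode needs no alignment at all.

## The method

Both losses extend smoothly from permutation matrices to *soft permutations*
(block-diagonal, approximately doubly stochastic matrices) produced by a
truncated Sinkhorn operator from real parameterization matrices X: for MI,
joint counts become `Σ_n m_A,i,n ⊗ m_B,j,n` with fractional one-hot fibers of
the soft collection `P̂ M_A`; for GA the loss is evaluated on `P̂ W_A P̂ᵀ`.

Rather than running full gradient descent (which stalls in poor local
optima), the optimizer is a **bootstrap of single gradient steps**: starting
from the maximally soft (uniform) initialization, one exact reverse-mode
gradient step through the unrolled Sinkhorn iterations already lands near a
hard permutation far better than random.  The bootstrap repeats this with a
growing context of `n = 0, Δn, 2Δn, …` pairs sampled at random from the
latest hard permutation and frozen (excluded from the gradient, included in
the loss).  Pairs found by *every* hard permutation explored — **robust
pairs** — are empirically high-precision and seed the iterative refinement
(IPA): three bootstraps, each starting from the accumulated robust set
`F_AB`; the answer is the lowest-loss hard permutation seen anywhere.  The
single normalized step makes the whole procedure insensitive to learning
rate, Sinkhorn temperature and iteration count; the only tunable is Δn.

## Worked example

Generate a synthetic instance with planted ground truth (25 species × 4
pairs, 40 columns, 60 coupled column pairs at coupling 0.9), pair it blind,
and score the prediction:

```text
$ softpair generate --n-species 25 --species-size 4 --length 40 \
      --n-coupled 60 --coupling 0.9 --seed 11 --out-dir demo/data
wrote 100 + 100 sequences (25 species) to demo/data

$ softpair pair demo/data/family_A.fasta demo/data/family_B.fasta \
      --score mi --ipa 3 --seed 0 --truth demo/data/truth.tsv --out-dir demo/run
final discrete loss: 6374.739974
fraction of correct pairs (padding excluded): 1.0000

$ softpair evaluate demo/run/pairing.tsv demo/data/truth.tsv
{
  "n_pairs": 100,
  "n_correct": 100,
  "fraction_correct": 1.0,
  "n_robust": 100,
  "robust_precision": 1.0
}
```

The final loss is the discrete two-body entropy (nats) of the reported
pairing — the minimum over every hard permutation the three IPA runs
visited.  `pairing.tsv` lists one predicted pair per row with its species,
both identifiers, a padding flag (all-gap rows inserted to square up unequal
family sizes, excluded from all metrics) and the IPA run in which the pair
entered the robust set:

```text
# species	id_A	id_B	is_padding	is_robust	ipa_run
sp000	A_sp000_0	B_sp000_0	0	1	1
sp000	A_sp000_1	B_sp000_1	0	1	1
```

Nonaligned mode works the same way with `--mode phylo --nonaligned` at the
generate step; `pair` then auto-selects the graph-alignment score with edit
distances.

The same pipeline is available as a library: `generate_coupled_pair` /
`generate_phylo_pair`, `harmonize_pair`, `run_bootstrap`, `run_ipa`,
`fraction_correct`, and `brute_force_best` as the exhaustive oracle on tiny
instances.

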