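# Methods

## Scores

**Inter-chain mutual information / two-body entropy.**  For aligned
collections the score of a pairing is the sum over all cross-family column
pairs (i, j) of the plug-in mutual information between columns, estimated
from observed joint frequencies with no pseudocounts and no sequence
weighting — any reweighting would be a different estimator.  Because the
one-body column entropies do not depend on the row order, maximizing the MI
score is identical to minimizing the inter-chain two-body entropy loss
`L_2BE(π) = Σ_{i,j} H(π(A)_i, B_j)`, which is what the optimizer works with.
Entropies are in nats throughout; the base only rescales every loss and can
never change an argmin.  The gap symbol is an ordinary 21st alphabet state,
including in the all-gap padding rows that square up unequal family sizes;
no column filtering or weighting is applied before the computation.  The
smooth extension replaces the hard-permuted one-hot tensor by `P̂ M_A` and
computes joint counts as a single matrix product between the flattened
`(N, L_A·q)` soft tensor and the flattened B tensor — an `L_A·L_B·q²` cost
that dominates runtime and is delegated entirely to BLAS.  Degenerate joint
states with zero count contribute 0 to the entropy (0·ln 0 := 0) and 0 to
the gradient; they are structural zeros that soft mixing of observed symbols
cannot create.

**Graph alignment.**  Each collection becomes a weighted graph on its
sequences: neighbors ordered by (distance, index), exactly k kept per node
before symmetrizing the support, weights `exp(−d/D²)` with `D` the mean
k-th-neighbor distance over the collection (computed once, not per species).
A node is never its own neighbor and the diagonal is forced to zero —
self-similarity carries no pairing information and would only add a
constant.  Distances are Hamming counts for aligned collections and
unit-cost edit distances (via edlib) otherwise.  Defaults are k = 30
(aligned) and k = 20 (nonaligned), capped at N − 1.  Padding rows in
nonaligned mode are empty strings placed at maximal distance (max real-real
distance + 1) from every real sequence and excluded from the computation of
D, so they can never infiltrate real neighborhoods.  If every k-th-neighbor
distance is zero the graph is refused: the data are degenerate for this
metric.  The loss is the negative strict-upper-triangle overlap
`−Σ_{i<j}(W_A)_ij(W_B)_ij`; its smooth extension evaluates the same form on
`P̂ W_A P̂ᵀ`, with gradient `−W_B P̂ W_A`.

## Optimization

**Soft permutations.**  Within-species permutations are parameterized by one
real `N_k × N_k` matrix per species.  The truncated Sinkhorn operator —
elementwise `exp(X/T)` followed by `n_iter` alternating row/column
normalizations (rows first) — yields blocks that are doubly stochastic to
well below the recorded tolerance 1e-3 at the defaults T = 1, n_iter = 100.
A constant block is an exact fixed point and is returned as the uniform
matrix directly, avoiding rounding drift in the "as soft as possible"
initialization.  Gradients are exact reverse-mode derivatives of the
unrolled normalization iterations (each normalization has the closed-form
VJP `g ↦ (g − ⟨g, z⟩_line)/s`), not an implicit-function approximation, so
they differentiate exactly the operator that is computed.

**Discretization.**  The nearest hard permutation is the per-block
maximum-weight linear assignment (scipy's Hungarian solver).  Exact ties are
broken toward the lexicographically smallest column sequence by row via an
additive bias of at most 2e-9 per assignment — far below any meaningful
score gap (the exhaustive-oracle tests pass at 1e-12) but enough to make the
output platform-independent for the small blocks where exact ties actually
occur.

**Fixed pairs.**  A fixed pair is embedded exactly: its row and column are
removed from the free sub-block before normalization and re-inserted as 0/1
entries afterwards, so the free problem is a genuine
`(N_k − f_k) × (N_k − f_k)` Sinkhorn problem, fixed pairs are reproduced by
construction, and gradients flow only to free entries.  Fixed pairs always
count in the loss.

**Bootstrap.**  Every elementary run starts from X = 0 (uniform blocks),
takes one gradient step normalized per species to unit infinity-norm
(`X ← −G/‖G‖_∞`), renormalizes, and discretizes.  The sign-preserving
normalized step removes learning-rate sensitivity entirely while keeping the
gradient direction; together with the single step it also makes temperature
irrelevant at the evaluation point (it cancels against the normalization)
and leaves only a weak dependence through the second forward pass — the
hyperparameter-spread measurement in the acceptance script confirms the
insensitivity empirically.  The context schedule is n = 0, Δn, 2Δn, …,
N_free, with Δn = 1 by default; each iteration freshly resamples its n
context pairs uniformly without replacement from the latest hard
permutation (initially fixed pairs always retained), rather than growing one
sampled set cumulatively.  Sampling is global across species.  Incorrectly
sampled pairs are accepted; the planted-signal experiments show correct
context helps and incorrect context is tolerable.  All randomness flows
through one seeded generator per run.

**Robust pairs and IPA.**  Robust pairs are the exact intersection of all
hard permutations in a trace.  IPA runs n_ipa = 3 bootstraps; after each
run, robust pairs found among the not-yet-fixed sequences are unioned into
F_AB, which seeds the next run (robustness is evaluated per run over the
remaining sequences, not recomputed over pooled traces).  Per-run bootstrap
seeds derive from the configured seed through a SeedSequence, so runs differ
but the whole procedure is reproducible bit-for-bit.  If F_AB ever covers
all sequences, the remaining runs are skipped and logged.  The final answer
is the lowest-loss hard permutation across all runs, which by construction
never degrades on run 1.

## Synthetic data

The generators define the study conditions for all tests and for the
acceptance script.

*Coupled mode* plants coevolution: C designated cross-family column pairs
each copy a shared latent symbol with probability p per interacting pair of
sequences, on a uniform i.i.d. background.  Designated pairs may share
columns; one latent per connected component of the bipartite coupled-column
graph keeps overlapping writes consistent, so every designated pair carries
the full coupling strength p (independent per-pair latents would silently
cancel each other on shared columns).  The default test scale is 25 species
of 4 pairs, L_A = L_B = 40 columns, q = 21 states, C = 60, p = 0.9 — about
100 pairs, seconds per run, strong but not saturated signal.  The tiny
instances used with the exhaustive oracle are 3 species of 4 with L = 10,
q = 8, C = 40, p = 0.95: 13 824 candidate permutations, enumerable in about
a second while leaving MI signal comparable to its sampling noise.

*Phylogeny mode* plants shared history: each interacting pair descends from
a common ancestor string; ancestors form a random-attachment genealogy
(each new ancestor mutates a uniformly chosen earlier one at rate 0.3 per
site), and both family members mutate their ancestor at per-site rate μ
(default 0.05).  Partners of similar A-sequences are then similar
B-sequences, so the two k-NN graphs share structure under the true pairing.
Nonaligned output additionally applies per-site deletions (probability μ/4)
and geometric insertions, producing the variable lengths that make edit
distance differ from Hamming.  Note that with substitution semantics the
pairing signal decays gradually: leaves retain about `1 − μ + μ/q` identity
with their ancestor, so the graph signal vanishes only at μ = 1, not at
μ = 0.5.

What the generators do *not* emulate: position-specific background
frequencies, realistic gap patterns, phylogenetic correlations *between*
the coupled-column signal and the tree (in real data both signals are
entangled), species-level tree structure, or the depth/diversity trade-offs
of real MSAs.  Recovery rates measured here therefore certify the
optimization machinery and the score implementations — not expected
performance on any particular biological dataset.

## Numerical and design choices

* Uniform background symbols over the first q letters of the 21-letter
  alphabet — the simplest null with analytically known entropies.
* Truth bookkeeping survives family-size imbalance because the dropped
  member is always the last of its species block, so the padding row
  restores its local index.
* Brute-force enumeration is guarded at `∏ N_k! ≤ 1e6` and visits candidates
  in lexicographic order, keeping the first optimum — a deterministic
  tie-break.
* `hard_from_soft` equals exhaustive maximum-weight assignment on all tested
  block sizes; the bias tie-break is exact for blocks up to ~20 rows and
  falls back to the solver's deterministic choice beyond.
* Entropy of a 2×2 swap is relabeling-invariant, so a two-sequence species
  can never have strictly positive excess loss; distinguishability starts at
  three sequences.

## Limitations

* One-to-one pairing only; unequal family sizes are handled by gap-padding,
  not by rectangular transport.
* The MI score needs aligned input; no alignment is constructed internally.
* Plug-in entropy estimates are biased at small depths, where the loss
  optimum can legitimately differ from the planted (or biological) truth —
  the tiny-instance experiments measure optimality against the loss, not
  against the truth.
* No average-product correction, Potts/pairwise-maximum-entropy scores, or
  protein-language-model scores; no Gumbel/stochastic permutation sampling.
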