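# Methods

## Model and assumptions

The method rests on one generative assumption: proteins in a common complex
are likely to interact, so complexes are dense regions of the PPI network.
Rather than searching for a fixed topological pattern, it estimates a
nonnegative propensity θ_ik of every protein i for every one of K candidate
complexes and asks the pairwise cocomplex coefficients C_ij = Σ_z θ_iz θ_jz
to reproduce the observed interaction weights S_ij — a symmetric nonnegative
matrix factorization of the weight matrix with a ridge penalty:

    L(Θ) = Σ_{i,j} ½ (C_ij − S_ij)² + λ Σ_{i,k} θ_ik²,   Θ ≥ 0.

The double sum runs over **all ordered pairs, including i = j**. This is the
convention under which the gradient
∂L/∂θ_ik = 2 Σ_j θ_jk C_ij − 2 Σ_j θ_jk S_ij + 2λ θ_ik holds exactly and
the multiplicative update below is consistent. Since S_ii = 0, the diagonal
terms add Σ_i ½(Σ_z θ_iz²)², an implicit extra shrinkage on row norms. A
measurable consequence: the optimal rank-1 fit of an all-ones off-diagonal
block of size m has member propensities √((m−1)/m), so the off-diagonal
reconstruction saturates at (m−1)/m rather than 1 (2/3 for a triangle). The
test suite asserts this analytic optimum rather than near-perfect
reconstruction.

## Edge weighting

Closed neighborhoods N(i) (protein i plus its neighbors) give, for each
edge, |N(i) ∩ N(j)| ≥ 2. Two normalizations are exposed because the
weighting's published form is typeset ambiguously:

* `product` (default): S_ij = |N(i)∩N(j)| / (|N(i)|·|N(j)|) — the literal
  printed form; values scale like 1/m inside a dense module of size m.
* `geometric`: S_ij = |N(i)∩N(j)| / √(|N(i)|·|N(j)|) — cosine-like,
  bounded in (0, 1] on edges.

Non-edges and the diagonal get weight 0. Input edge weights are ignored;
the weighting is always recomputed from topology. Self-loops are dropped at
parse time.

## Optimization

* **Update rule.** The damped multiplicative rule (average of the identity
  and the bare KKT ratio rule) preserves nonnegativity, keeps exact zeros
  at zero, and empirically never increases L (asserted to 1e-9·(1+L₀) per
  iteration across randomized instances).
* **Initialization.** Entries uniform on (0, s] with s = √(mean(S)/K), so
  the initial ΘΘᵀ is on the scale of S.
* **Stopping.** Relative objective change |L_t − L_{t−1}|/(1 + L_{t−1}) <
  `rel_tol` (default 1e-6), capped at `max_iter` = 1000. At rel_tol 1e-9
  the KKT residual max|θ·∂L/∂θ| lands near 1e-6·(1+L) on random instances;
  the acceptance suite uses that tighter setting when asserting
  stationarity ≤ 1e-4·(1+L).
* **Restarts.** Restart r draws from an RNG seeded by the pair (seed, r),
  so results are independent of execution order and fully reproducible;
  the minimum-L run wins, ties to the lowest index. The full protocol uses
  100 restarts (library default); the CLI defaults to a desk-friendly 10.
* **Guard.** eps = 1e-12 in the denominator protects all-zero columns.

## Choosing K, λ and τ

* **K** per subnetwork defaults to ceil(n/3): complexes have ≥ 3 members,
  so at most n/3 disjoint complexes fit. Spare columns empty out under the
  penalty and are discarded by postprocessing.
* **λ** defaults to 1.0, the center of the conventional 2⁻⁵…2⁵ selection
  grid. λ must be read against the scale of S: stationarity for a dense
  module of size m under product weights puts member propensities near
  √((1−λ)/m), so λ ≥ 1 collapses Θ entirely on small dense networks while
  λ ≈ 2⁻⁵ leaves members comfortably above τ = 0.2 for m ≤ 10. When a gold
  standard is available, `grid_search` (or `plsmc run --param-grid`) sweeps
  λ × τ (τ over 0.05–0.5, step 0.05) and keeps the composite-score maximum —
  the intended selection protocol. Without one, prefer the geometric weight
  variant or a small λ.
* **τ** (default 0.2) is a single global threshold; no per-complex
  adaptation is attempted, and near-duplicate (non-identical) complexes are
  not merged — only exact duplicates collapse.
* **Column-splitting degeneracy.** When K exceeds the number of true
  complexes, a module can split across two propensity columns with exactly
  the same objective value: the reconstruction ΘΘᵀ and the penalty
  (Σθ² = trace of ΘΘᵀ restricted to the module) are both invariant to the
  split, so minimum-L restart selection cannot break the tie. A split
  halves the squared propensities and can push members below a fixed τ.
  This is why τ should be data-selected: at a low τ the split columns
  threshold to identical member sets and collapse in deduplication. The
  shipped recovery checks grid-select τ for exactly this reason.

## Decomposition

Subnetworks are produced by greedy agglomerative modularity maximization
(Clauset–Newman–Moore, via networkx) on the **unweighted** graph, applied
recursively to parts larger than N_s (default 200, matching the size of the
largest catalogued yeast complexes). Connected components are separated
first. Parts are vertex-induced, so inter-part edges are discarded and a
complex spanning two parts is undetectable — an accepted cost of the
strategy. An oversized part that forms a single modularity community is
processed whole (with a warning) rather than force-bisected, which would
invent structure. Merge-order tie-breaking is delegated to the library's
deterministic heap given the fixed lexicographic node order.

## Synthetic benchmark generator

A planted-partition construction: proteins are allocated to `n_complexes`
complexes (sizes uniform on `size_range`; with probability `overlap_prob` a
member is recycled from earlier complexes), plus `n_background` proteins in
no complex; co-complex pairs get edges with probability `p_in`, all other
pairs with `p_out`. Defaults (10 complexes of 5–10 proteins, p_in = 0.9,
p_out = 0.005, 10 background proteins) give a ~90-protein benchmark whose
planted density matches the model's own premise. The generator does **not**
emulate AP-MS artifacts (bait–prey asymmetry, sticky proteins, systematic
false negatives), so passing tests demonstrate correctness of the machinery
and recoverability under the model's assumption — not performance on real
interaction maps.

## Evaluation

f-measure (complex-level matching at os ≥ 0.25), Acc = √(Sn·PPV)
(protein-level; the geometric mean is the metric's standard form — a switch
restores the literal product), and MMR, summed into the composite score.
Matching uses os ≥ ov (≥, not >, so the conventional 0.25 threshold behaves
as in the benchmark literature; a strict mode exists). "Perfect match" is
exact set equality, the only way os = 1. Reference catalogues are filtered
to complexes of ≥ 3 proteins before scoring.

## Problem sizes in the shipped checks

The test suite and acceptance script run on synthetic networks of roughly
50–100 proteins (10 planted complexes), 10 restarts, and 5 benchmark seeds;
optimizer diagnostics use random instances up to N = 30, K = 5. These sizes
exercise every code path — decomposition recursion is additionally covered
with small caps on random graphs — while keeping a full run to seconds.

## Known limitations

* Complexes spanning decomposition parts cannot be found (see above).
* The objective is non-convex; restarts mitigate but do not guarantee the
  global optimum.
* The product weighting makes propensity scales network-dependent; τ and λ
  should be selected per network when a reference is available.
* No confidence-score preprocessing of raw AP-MS data is included; inputs
  are assumed to be already-filtered binary interaction lists.
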