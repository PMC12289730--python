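# Methods

## Problem and model

The package predicts unknown drug–disease associations from a binary
association matrix A (m drugs × n diseases, about 1% of cells positive in
real datasets) and one or more similarity matrices per entity type, each
square, symmetric, valued in [0, 1] with unit diagonal. Similarities are
fused by the element-wise arithmetic mean (the only combiner used; no
similarity-network fusion) and re-symmetrized as (M + Mᵀ)/2 to absorb float
asymmetry.

Each entity view concatenates its fused similarity with the (optionally
densified) association block into an integrated matrix — X_R = [R, A_RD1]
for drugs, X_D = [D, A_RD2ᵀ] for diseases — which is factorized through l
layers, X ≈ W_l H_l ⋯ H_1, under four regularizers: a graph-Laplacian term
α Σ Tr(W_iᵀ L W_i) that keeps similar entities close in every layer's
embedding, a layer-consistency (relaxation) term β Σ ‖W_i − W_{i+1}H_{i+1}‖²
tying adjacent layers together, and ridge terms λ, μ on all factors. L is
the unnormalized Laplacian U − S where U is the diagonal of *full* row sums
of the fused similarity, diagonal included; a drug similar only to itself
therefore contributes a zero Laplacian row and receives no local-structure
signal.

The final score matrix is the element-wise mean of the two views'
reconstructed association blocks. Scores are not clamped, re-binarized, or
overwritten at training positives; ranking consumers exclude known pairs
themselves.

## Cold-start (weighted-KNN) preprocessing

A drug with no known association has an all-zero row in A, which the data
term would otherwise fit toward zero. For every such row p, the k most
similar *other* rows are taken in descending similarity (ties broken by row
id, self excluded) and combined with weights w_i = decay^(i−1)·S(p, j_i),
normalized by Σw; the same procedure applies to empty disease columns via
Aᵀ. Rows with at least one positive are never modified, so the fill is
idempotent on them, and filled values stay in [0, 1]. decay = 1 recovers
plain similarity-weighted averaging; the default decay = 0.9 makes the
neighbor *rank* matter in addition to the similarity value. The drug-view
and disease-view fills are computed independently from the same raw A,
yielding the two blocks A_RD1 and A_RD2. A k of at least the row count is
clamped to rows − 1 with a logged warning.

## Optimization

**Pretraining.** Layers are initialized greedily by plain NMF with the
classical Frobenius multiplicative updates (uniform(0,1) init): X ≈ W₁H₁,
then W₁ ≈ W₂H₂, and so on; each layer's rank is clamped to the dimensions of
the matrix it factorizes. Layer dimensions are l_i = round(τ_i·min(m, n)),
floored at 1, with m×n the association shape, so both views share one layer
structure. Pretraining can be replaced by uniform random init (the
"w/o pretraining" ablation).

**Multiplicative updates.** Each factor update has the form
F ← F·√(num/den), where num/den collect the positive/negative parts
([M]⁺ = (|M|+M)/2, [M]⁻ = (|M|−M)/2) of the KKT gradient pieces: data terms
XΦᵢᵀ vs W_iΦᵢΦᵢᵀ (Φᵢ = Hᵢ⋯H₁), the Laplacian αLW_i, the ridge, and — where
the adjacent layer exists — the β couplings W_{i−1}Hᵢᵀ, W_iHᵢHᵢᵀ and
W_{i+1}H_{i+1}. The ridge coefficient on W_i is (β+λ) for layers with a
successor and λ for the last layer; with a single layer every β term is
absent. First-layer H sees the data through X ≈ W₁H₁; deeper H_i through
X ≈ W_iH_iΦ_{i−1}.

**Division guard.** Update denominators are floored at 1e-10
(`max(den, ε)`) rather than shifted by an additive ε. The floor leaves the
ratio exact whenever the denominator is healthy — so an exact positive
factorization is a fixed point of every unregularized update to machine
precision, a property the test suite asserts at 1e-12 — while still guarding
the degenerate zero-denominator case, where the corresponding entries decay
toward zero as in the classical guarded updates.

**Sweep schedule.** One sweep updates layers in order i = 1…l, W_i then H_i
(`sweep_order="layer"`); an all-W-then-all-H schedule is available
(`"factors"`) since only the rules, not their order, are fixed by the
derivation. Monotone decrease of the full regularized objective is not
guaranteed in general and is asserted only where classical theory provides
it (single-layer unregularized sweeps); empirically the regularized W-sweep
also decreases the objective on random instances, which the tests check on
frozen seeds.

**Stopping.** After each sweep, h = ‖A*_{t} − A*_{t−1}‖_F/‖A*_{t−1}‖_F is
computed on the reconstructed *association block* of the current view (the
quantity of interest), with h defined as 0 when the previous block vanishes.
Iteration stops when h ≤ ξ₁ = 5·10⁻⁴ and |Δh|/max(1, h_prev) ≤ ξ₂ = 5·10⁻⁷
(both conditions need two history entries), or at max_iter = 500 sweeps;
pretraining uses 200 iterations per layer. The caps were chosen so that the
default desk-scale problems converge well before hitting them.

**Determinism.** All randomness flows through numpy Generators seeded from
`Hyperparams.seed`; per-layer and per-view seeds are derived arithmetically,
so every entry point is bit-reproducible under a fixed seed. Exact
invariance under permutation of input ids is *not* guaranteed for fitted
scores (initialization is positional and float summation is
order-sensitive); the deterministic preprocessing steps do commute with
permutation exactly.

## Evaluation protocols

**10-fold CV** partitions the positive cells (never the zeros — 0 means
*unknown*, the matrix-completion convention) into ten near-equal folds. Each
fold is zeroed in training; its cells are scored with label 1 against all
originally-zero cells with label 0, so training positives never enter the
candidate set (enforced by hard assertions, as is the absence of test cells
from the training matrix). Aggregate metrics are the arithmetic mean over
folds. One hyperparameter set is used for all folds.

**Cold start** takes every drug with exactly one known association, hides
that association (emptying the row, which exercises the KNN fill), refits,
and records the drug's row scores: label 1 on the hidden disease, 0 on the
drug's originally-unknown diseases. Per-drug lists are pooled before
computing metrics — a per-drug AUC is undefined with a single positive.
Similarity sources that would not exist for a genuinely new drug
(interaction- and side-effect-based ones, recognized by the names `ddi` and
`se`) are excluded by default in this protocol.

**Metrics.** AUC is the Mann–Whitney statistic computed from tie-averaged
ranks; AUPR is the area under the precision–recall step curve with tied
scores processed as one block; "precision" is R-precision (precision among
the top-P items, P = number of positives), chosen as the least arbitrary
threshold-free operating point. All three are verified against brute-force
enumeration oracles to 1e-12 and cross-checked against scikit-learn.

## Synthetic data

The generator plants the structure the model assumes: non-negative latent
factors U (m×r), V (n×r) with |N(0,1)| entries; ground truth U Vᵀ;
associations set to 1 at the ⌈density·m·n⌉ largest ground-truth entries (a
thresholding rather than Bernoulli sampling, so the true ranking is
unambiguous and recovery tests have a clean oracle); similarities as the
Gram matrices U Uᵀ, V Vᵀ rescaled to [0, 1] with the diagonal forced to 1,
plus symmetric Gaussian noise (clipped, re-symmetrized, diagonal re-forced).
Finally, a requested number of positive rows are thinned to their single
best-scoring positive to create cold-start target drugs. Defaults — density
0.01, noise 0.1 — mirror the ~1% sparsity of the real datasets the package
emulates; desk-scale protocol runs use m = 60, n = 40, r = 5 so a full CV
plus cold-start pass completes in seconds on one CPU.

What the generator does *not* emulate: the marginal distributions of real
chemical-fingerprint or ontology similarities, block/cluster structure, or
weakly informative similarity sources. Its similarities are a noisy Gram
matrix of the *true* factors — close to the best case for the model — so
recovery results on synthetic data are an upper bound on real-data behavior,
and the measured advantage of the KNN fill over the no-fill ablation is
small here (both variants score high), even though the fill's mechanism is
exactly exercised. Passing tests demonstrate correctness of the machinery
and recoverability of planted signal, not real-data effect sizes.

## Known limitations

- Dense linear algebra only; problem sizes in the thousands of entities are
  fine, far larger ones are not the target.
- No joint convergence proof exists for the full regularized objective; the
  stopping rule monitors score-matrix stability instead.
- The two views are fit independently and averaged; no shared latent space.
- Hyperparameter search is left to the user (a simple loop over
  `Hyperparams` values); no built-in grid-search driver.
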