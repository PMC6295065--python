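# Methods

## Problem and data model

The package scores unobserved miRNA–disease pairs given (i) a binary
association matrix *A* (n miRNAs × m diseases), (ii) a disease ontology from
which semantic similarity is computed, and (iii) a miRNA functional
similarity derived from *A* itself. All labeled matrices are pandas
DataFrames whose index/columns carry the entity ids; ids are opaque,
case-sensitive strings.

## Disease semantic similarity

Each disease *d* is represented by its ancestor closure T(d) and the
parent→child edges among those nodes. Contributions decay geometrically
from the disease upward:

    D_d(d) = 1,    D_d(t) = decay · max{ D_d(t') : t' child of t },

evaluated in reverse topological order so every node is a single max over
already-computed children. The decay defaults to 0.5 — the conventional
value for this construction — and is exposed as a parameter. The semantic
value DV(d) = Σ_t D_d(t), and

    S(i, j) = Σ_{t ∈ T(i)∩T(j)} (D_i(t) + D_j(t)) / (DV(i) + DV(j)),

which lies in [0, 1], equals 1 for identical profiles and 0 for disjoint
ones. A disease appearing at several ontology positions (several MeSH-style
tree numbers) is modeled as one DAG over the union of its ancestor sets;
the max in the recursion resolves multi-path contributions. Inputs with
cycles, or nodes that cannot reach the disease, are rejected rather than
silently pruned.

## MiRNA functional similarity

For miRNAs with associated-disease sets DT1, DT2, similarity is the
best-match average

    MISIM(M1, M2) = ( Σ_{d∈DT1} S(d, DT2) + Σ_{d∈DT2} S(d, DT1) ) / (|DT1| + |DT2|),

with S(d, DT) = max_{t∈DT} S(d, t). A miRNA with no known disease gets
similarity 0 to every other miRNA (the expression is 0/0 there; 0 encodes
"no functional evidence") and 1 to itself. Both similarity matrices are
built upper-triangle-then-mirror, so symmetry is exact by construction, and
the diagonal is forced to exactly 1.

## The ℓ1-norm graph solver

Per space the objective is Σ_ij W_ij‖q^i − q^j‖₂ + Tr (Q−A)ᵀU(Q−A) with
q^i the *i*-th **row** of Q. (Writing the smoothness sum over the k×k
similarity matrix only type-checks when q^i is a row — one entity's score
profile — and the implementation follows that reading.) The solver:

1. initialise Q = A (the only label information available; this also makes
   the zero-graph case exact);
2. re-weight: W̃_ij = W_ij / (2·max(‖q^i − q^j‖₂, ε)), diagonal zeroed;
3. solve (2L̃ + U) Q = U A, where L̃ = D̃ − W̃;
4. repeat until the relative objective change drops below `tol` or
   `max_iter` is reached.

Step 3 is the exact stationarity condition of the re-weighted quadratic
surrogate (its gradient is 4L̃Q, the fidelity gradient 2U(Q−A)), which makes
the iteration a true majorise–minimise scheme: the objective is
monotonically non-increasing and, the objective being convex, converges to
the global optimum. The update is often written as (L̃ + U)⁻¹UA with the
factor 2 folded elsewhere; the two operators coincide up to doubling U, and
the package's default `anchor_weight = 2.0` makes its default prediction
operator identical to that conventional form taken at a unit anchor. The
test suite checks the converged objective against an independent numerical
minimisation (multi-start quasi-Newton on a smoothed surrogate) on small
instances.

Numerical choices:

* **U** is uniform, `anchor_weight`·I (default 2.0, see above). Per-entity
  anchors are out of scope.
* **ε = 1e-8** floors the re-weighting denominator; the ℓ1 penalty actively
  merges similar rows, so coincident profiles are the normal course of
  convergence, not an edge case.
* **tol = 1e-6** relative objective change, **max_iter = 100**.
* The linear system is solved as a symmetric positive-definite solve
  (Cholesky), never by explicit inversion. When the re-weighted graph is
  all zeros the system is diagonal and Q = A is returned exactly.
* The per-iteration trace records the objective and its ℓ1 smoothness term;
  the dense W̃/D̃/L̃/U snapshots are kept only on request
  (`trace_matrices=True`), since retaining them inside cross-validation
  would cost memory quadratic in the entity count per iteration.
* Everything is deterministic; no step draws random numbers.

Fusion: Q_final = (Q_m + Q_dᵀ)/2, computed from the miRNA-space solve on A
and the disease-space solve on Aᵀ.

## Evaluation

Leave-one-out cross validation zeroes each known association in turn,
re-runs the full prediction, and ranks the held-out pair's score against
the unconfirmed pairs — all of them (global) or those of the held-out
disease (local). Folds are pooled into a Mann–Whitney statistic: each fold
contributes its wins and half-ties against its own candidate set, and the
sums are normalised by the total comparisons. Ties in top-k lists break
lexicographically by miRNA id so output is deterministic; tied scores get
average rank in AUC computations. Per-disease AUCs are the same pooled
statistic restricted to one disease's folds.

Similarity matrices are held fixed across folds by default. This mirrors
evaluation against precomputed similarity tables; because the miRNA
similarity is association-derived, the held-out link does inform it, and a
`refit_mirna_similarity=True` flag recomputes MISIM per fold for a
leak-free (but slower and non-standard) variant.

Whether a LOOCV ROC should pool all folds into one ranking or average
per-fold curves is underdetermined in this literature; the pooled rank
statistic implemented here is the common construction and is what the
reported AUCs mean.

## Synthetic data

Fixtures emulate the real inputs' structure: one balanced subtree per
planted block under a shared ontology root (so within-block diseases share
a deep ancestor and out-rank between-block similarity), and a Bernoulli
block model for associations — matched miRNA/disease blocks at `p_within`,
mismatched at `p_between`. The miRNA similarity is then derived from the
sampled A, mirroring the real data flow. Defaults — 20 miRNAs × 12 diseases,
3 blocks, p_within = 0.8, p_between = 0.05, tree depth 3, branching 2 —
are the study conditions used across the tests and the acceptance script:
large enough to separate signal from noise, small enough that full LOOCV
(one solver run per known association) completes in about a second.

What the generator does **not** emulate: the heavy-tailed degree
distributions of curated association databases, correlated annotation
noise, and ontology nodes shared between blocks at intermediate depths.
Passing tests therefore demonstrate correctness of the machinery and
recoverability of clean block structure, not expected AUC on curated human
data. All randomness flows from one seed through per-component child
streams, so fixtures are bit-identical across runs and adding a component
does not perturb earlier draws.

## Known limitations

* The two spaces are optimised independently and fused by averaging; no
  joint objective couples them.
* Only association-profile similarity is implemented for miRNAs (no
  sequence, family or cluster information).
* Dense linear algebra throughout: intended for up to ~1000 entities per
  axis.
* A disease with no known associations after ablation is scored purely
  through the disease-similarity space; with an empty column, the
  miRNA-space solve contributes nothing to it.
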