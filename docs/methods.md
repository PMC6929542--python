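# Methods

## Model and assumptions

`ddigip` treats DDI prediction as link prediction on an undirected,
unweighted graph. The central assumption is that drugs with similar
*interaction partner sets* interact with similar drugs: the GIP kernel
turns profile distance into similarity, and kernel RLS propagates the
observed labels through that similarity. Two consequences follow:

- A zero in `Y` means *unknown*, not *confirmed non-interaction*. The
  method ranks unknown pairs; it cannot certify negatives.
- A drug with no known interactions is invisible to the kernel (its
  profile is the zero vector). The KNN cold-start fill exists precisely to
  bootstrap such drugs from feature similarity; without features their
  scores are uninformative.

Self-interactions are structurally excluded: the diagonal is pinned to
zero, edge lists with self-pairs are rejected, and the candidate universe
is the set of unordered distinct pairs.

## Pipeline order

The fill runs first, and the *filled* matrix is used both to build the GIP
kernel and as the label matrix in the RLS solve. The fill applies to any
all-zero row regardless of cause, so a drug whose every edge falls into a
cross-validation test fold is also treated as new. The GIP formulas are
well-defined for the real-valued filled profiles; filled values are left
as computed (no clipping or renormalisation — with positive neighbour
similarities they are convex combinations of 0/1 values anyway).

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| `sigma` | RLS regularization strength (dimensionless) | 1 | larger values shrink all scores toward 0; eigenvalues of `G(G+σI)⁻¹` lie in [0,1) |
| `gamma_prime` | GIP bandwidth scaling (dimensionless) | 1 | the bandwidth itself is `γ'_d` divided by the mean squared profile norm, computed over **all** N drugs including zero rows |
| `k_neighbors` | neighbours in the cold-start fill | 9 | grid search over the de novo protocol (`grid_search_k`, K = 1…15) selects it on real-scale data |
| `knn_enabled` | run the fill | auto | on whenever a feature table is supplied; `--no-knn` disables |

Neighbour eligibility: the K-set excludes the query drug, drugs that are
themselves new (their zero profiles would only propagate zeros), and the
fill is skipped — with a warning — for drugs whose features are missing
from the table or degenerate (constant vector, Pearson undefined).
Negative Pearson similarities are allowed as weights; a non-positive
weight sum aborts the fill for that drug (the weighted average is then
undefined) and leaves the row zero. Similarity ties in the top-K selection
break by ascending drug identifier, so results are reproducible
byte-for-byte. When two new drugs face each other, the two independently
computed fill values are averaged, preserving symmetry.

## Evaluation protocols

- **k-fold CV** partitions the unordered *known pairs* (never matrix
  cells, so a test edge cannot leak through its mirror cell) into
  near-equal folds, independently per repeat, from a single PCG64 seed.
  Both symmetric entries of each test pair are zeroed in the training
  matrix; the GIP kernel is recomputed from the masked matrix in every
  fold because its bandwidth depends on it (the Pearson feature similarity
  depends only on the features and is computed once).
- **AUC** is the midrank Wilcoxon–Mann–Whitney statistic — the probability
  that a random test positive outranks a random candidate, with half
  credit for ties — computed per fold against the negatives: all unordered
  pairs unknown in the *original* matrix. Fold AUCs are averaged and
  reported with their sample SD; aggregation conventions differ across the
  literature, so the per-fold values are reported too.
- **De novo validation** zeroes each interacting drug's row/column in
  turn, re-runs the pipeline (the drug becomes a cold-start case) and
  ranks its true partners against its non-partners. Both the per-drug AUC
  distribution and one pooled AUC over all drugs' scores are reported,
  again because the aggregation convention is not standardised.

## Synthetic data generator

The generator emulates the statistical structure of real DDI benchmarks:
drugs fall into latent groups; each group is compatible with itself and
one randomly chosen partner group; compatible pairs interact with
probability `p_in = 0.35` against a background `p_out = 0.02`; each drug's
300 feature bits are its group prototype (density 0.2) with 5% per-bit
flip noise. Defaults (120 drugs, 6 groups) keep a full 5CV×10-repeat run
in seconds on one CPU. Group *compatibility* rather than pure
assortativity is used so that the signal lives in shared partner sets —
the GIP kernel's mechanism — not mere co-membership.

What it does **not** emulate: co-reporting biases of pharmacovigilance
databases, the extreme sparsity (~21 000 bits) and redundancy of real
concatenated feature tables, degree heavy tails, or any directionality of
pharmacokinetic interactions. Passing tests on synthetic data show the
machinery is correct and recovers planted structure; they do not certify
real-data accuracy.

### A known ceiling on synthetic CV AUC

Given group compatibility, the generator draws edges i.i.d., so a held-out
test edge is statistically exchangeable with a compatible non-edge: no
scorer can separate them, and the Bayes-optimal AUC (block oracle: score 1
on compatible pairs, 0 elsewhere) is about 0.78–0.80 under the default
configuration — bounded by the tie mass `p_in` leaves inside compatible
blocks. The pipeline reaches ≈0.73–0.76, close to that ceiling; the gap is
RLS shrinkage and kernel noise. De novo pooled AUC behaves the same way
(≈0.77 with the fill, ≈0.5 without it or with pure-noise features, which
is the designed null).

## Numerical choices

- The RLS solve uses a symmetric positive-definite factorisation of
  `G + σI` (`scipy.linalg.solve(..., assume_a="pos")`); no explicit
  inverse is formed anywhere in the pipeline (tests use one as the
  oracle).
- Squared profile distances are computed via the Gram matrix with tiny
  negatives clipped to 0; the kernel diagonal is pinned to exactly 1.
- Pearson similarity uses population SDs (the n vs n−1 choice cancels in
  the ratio) and is clipped to [−1, 1] against floating-point overshoot.
- The kernel container tolerates entries equal to 0 (mathematically the
  GIP kernel is strictly positive, but `exp` may underflow and limiting
  test kernels such as the identity are admitted).
- All randomness (fold assignment, synthetic generation) flows through
  `numpy.random.default_rng` (PCG64) from explicit integer seeds; every
  report echoes its seed and configuration.
- Degenerate inputs fail loudly with named errors: all-zero networks
  (undefined bandwidth), σ ≤ 0, fewer known pairs than folds, empty score
  lists, self-pairs, non-binary feature cells.

## Design choices where the design was open

- Drug ordering after any alignment is sorted-lexicographic, making all
  outputs deterministic.
- Edge lists are deduplicated as unordered pairs.
- Drugs absent from the feature table keep an all-zero feature row plus a
  "missing" flag; the fill and the de novo protocol skip them (with a
  warning and a report entry) rather than silently imputing from a zero
  vector.
- Constant feature vectors get similarity 0 (flagged degenerate) instead
  of raising, so one featureless drug cannot abort a batch run.
- Dense feature tables only; sparse dialects, directed or weighted
  interactions, alternative feature similarities (Jaccard, cosine) and
  precision–recall metrics are out of scope.

## Limitations

- Closed-form RLS is O(N³) per solve and the de novo protocol re-solves
  once per drug; the implementation targets desk-scale networks (hundreds
  to a few thousand drugs), not millions.
- Scores are ranking scores, not calibrated interaction probabilities.
- The cold-start fill is only as good as the feature similarity; with
  uninformative features it collapses to chance by design rather than
  failing loudly.
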