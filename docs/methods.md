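# Methods

This note documents the models implemented in `evinet`, the assumptions
behind them, the parameters that matter, and the design choices made where
the construction was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Score model

All scores are probabilities in `[0, 1]`. The 0–999 integer scale of the
on-disk edge-list dialect is an encoding only: integers map to
probabilities as `s/1000` on read and `round(1000·p)` clipped to `[0, 999]`
on write (the dialect has no 1000, so `p = 1` encodes as 999; the encoding
error is at most 0.0005 for `p ≤ 0.999`). Edges are unordered pairs of
distinct proteins, canonicalised with the lexicographically smaller
identifier first so that files round-trip deterministically.

## Evidence combination

Channel scores are treated as independent estimates of the probability that
a pair is functionally associated, each inflated by a shared prior `p₀`
(the probability that a random pair is associated at all). Integration is

1. prior removal: `s' = max(0, (s − p₀)/(1 − p₀))`,
2. noisy-OR: `S = 1 − Π_c (1 − s'_c)` over enabled channels,
3. prior re-addition: `S_final = S + p₀(1 − S)`.

Consequences used as test invariants: the result is bounded in `[p₀, 1]`,
non-decreasing in every channel, permutation-invariant, and a channel
scoring exactly `p₀` contributes nothing. The default prior is 0 — priors
are dataset properties, and none is shipped. The floor at step 1 means
channels *below* the prior cannot push the combined score below `p₀`; this
is deliberate (a weak channel is "no evidence", not "counter-evidence").

Document pooling for literature-derived physical-interaction probabilities
uses a different algebra because the prior there is per *sentence*: with
`p*` the prior probability that a sentence mentions an interacting pair,

    (1 − p) = (1 − p*) · Π_i (1 − p_i)/(1 − p*).

Each document with `p_i > p*` multiplies the survival ratio down; documents
at the prior are neutral; documents *below* the prior legitimately pull `p`
below `p*` — the algebra is applied literally, with only the final result
clipped to `[0, 1]`. The same functional form is applied twice: first over
the sentences of one document (yielding that document's `p_i`), then over
documents. An empty evidence list returns the prior.

## Gold-standard benchmark and calibration

A gold standard is a set of curated complexes. A scored pair is **TP** if
some single complex contains both proteins (directly or indirectly
interacting), **FP** if both proteins occur in the gold standard but never
together in one complex, and **unjudged** otherwise — proteins absent from
the gold standard carry no evidence of non-interaction and never enter
precision estimates.

Because a complex of size `k` contributes `k(k−1)/2` pairs, large complexes
would dominate any unweighted precision estimate. Judged pairs are
therefore weighted by the reciprocal geometric mean of the co-complex
degrees, `w = 1/√(deg_a · deg_b)`, where the degree is the number of
distinct partners a protein shares at least one complex with (set union
across complexes, i.e. degree in the co-complex graph — not
`Σ(complex size − 1)`, which would double-count shared partners).

Judged pairs are ranked by raw score (ties broken by canonical pair order,
so the ranking is reproducible), and a sliding window of size
`max(100, 1% of judged pairs)` — configurable — yields local weighted
precision points `(median raw score, Σw_TP/Σw)`. These are fitted with
pool-adjacent-violators isotonic regression (scikit-learn) and linearly
interpolated; evaluation clamps to the boundary precisions outside the
anchor range, and tied raw scores collapse to one anchor so equal scores
always calibrate identically. A calibration function must be monotone to
preserve score order; PAV plus linear interpolation is the simplest
standard construction. "Calibration transfer" is evaluation of a fitted
curve on any other score list — e.g. applying a curve fitted on one
organism's benchmark to another organism's experiments-channel scores.

Evidence supported only by genetic-interference assays is excluded before
benchmarking (purely functional, not physical); records with unknown assay
class are kept.

## Over-representation analysis

For background size `N`, `K` annotated proteins, query size `n` (after
restriction to the background) and overlap `k`, the p-value is the exact
hypergeometric upper tail `P(X ≥ k)`, computed as an integer-arithmetic
tail sum (exact up to one final float division; tiny tails keep full
precision — the test suite cross-checks against `scipy.stats.hypergeom`).
The default background is the framework's annotation universe; a
user-supplied background restricts both sets and query, and query proteins
outside it are dropped with a warning. Multiple testing is
Benjamini–Hochberg within each framework independently (frameworks answer
different questions; a three-million-set publication framework should not
inflate the q-values of a curated pathway collection), with Bonferroni as
an option.

The whole-network test compares the edge count among the query proteins
(at a combined-score threshold, default 0.4 — the conventional
medium-confidence cut) with the counts among `n_null` uniformly sampled
node subsets of the same size. The p-value is add-one smoothed,
`p = (1 + #{null ≥ obs})/(n_null + 1)`, so it is never 0. The null is
uniform node sampling because the question is "more interactions than
expected for an input of that size"; a degree-weighted sampling option is
exposed for hub-rich queries. Under uniform sampling the expected count has
the closed form `m·k(k−1)/(n(n−1))`, which serves as the independent oracle
for the sampler.

## Functional class scoring

Inputs are protein→value maps; all tests are rank-based within the input,
so no statistical background is needed and results are invariant under
strictly monotone transforms of the values. Ties get mid-rank treatment:
the ECDF gap is evaluated only where the sorted value changes, so a
constant profile carries no ordering information (D = 0 for every set).

* **KS.** `D = sup_t |F_in(t) − F_out(t)|` along the ranking (two-sided),
  or the one-sided sup toward the top or bottom. The primary p-value is a
  permutation tail over random same-size subsets of the input (exact for
  the rank statistic at any set size, add-one smoothed); the classical
  asymptotic two-sample approximation is available as a fast option.
  Within one call, permutation nulls are shared across sets of equal size —
  the null distribution depends only on the set size and the tie structure.
  This is purely computational; note that it correlates the p-values of
  equally sized sets within a call, which is why the calibration studies in
  the acceptance suite use independent per-replicate nulls.
* **Both-ends.** The in-set is split at its median value (the middle
  element of an odd-size set is dropped); each half is scored for outward
  skew against the rest of the profile with the normalized rank-sum
  statistic `A = U/(h(N−h))` — the probability that a half member outranks
  a random non-member — and the statistic is `B = min(A_high, A_low)`.
  `B` is large only when both halves sit at their respective extremes; a
  set concentrated in the middle ranks scores ≈ 0.5, in the far-left tail
  of the permutation null, hence p ≈ 1. A min-of-two-one-sided-KS
  construction was considered and rejected: the one-sided KS sup saturates
  near 0.5 for any half concentrated just above (below) the median, so a
  compact middle set — the conceptual opposite of a both-ends set — would
  score as high as a genuinely bimodal one. The permutation null applies
  the identical split-and-score procedure to random subsets, which keeps
  the median-split selection effect inside the null.
* **Aggregate fold change.** The statistic is the mean in-set value,
  compared with size-matched random subsets. When `C(N, m) ≤ 20000` the
  null is enumerated exhaustively and the p-value is the exact subset
  fraction (the observed set is one of the subsets, so p > 0 without
  smoothing); otherwise it is resampled with add-one smoothing. The
  two-sided variant doubles the smaller tail.

Sets with fewer than `min_set_size = 3` profiled members are skipped
(both-ends needs 4 to split); q-values are BH within one framework and
direction. Directions are reported separately; the package does not merge
both-ends results into the single-tail ranking.

Note on permutation resolution: with `n_perm` permutations the smallest
achievable p is `1/(n_perm + 1)`, so after BH over `m` sets the smallest
achievable q is `m/(n_perm + 1)`. Detecting a single planted set at
`q < 0.05` among 51 sets therefore needs `n_perm ≥ 1020`; the power studies
use `n_perm = 1999`.

### Bias report

For each covariate column the report gives: Spearman correlation with the
profile over the shared proteins, a two-sided permutation p-value (Pearson
on mid-ranks under label permutation), and the mean covariate value within
equal-size rank bins (default 20, top bin first) — the compact numerical
form of a trend plot. A constant covariate (or profile slice) is flagged
degenerate and reported with ρ = 0, p = 1. The five covariates
conventionally screened — average protein abundance, protein length,
publication count, predicted disorder, transcript GC content — are the
generator's defaults; the table itself is always user-supplied, never
computed from sequence or literature.

## Synthetic data: what it emulates, what it does not

All generators are pure functions of a `SimulationSpec` (seed included);
identical specs give byte-identical outputs, and each generator returns a
manifest of the planted truth.

* **Networks** are uniform `G(n, m)` with exactly `m` edges (matching the
  closed-form null of the network-enrichment test), combined scores uniform
  in (0.4, 1.0), an optional planted clique, and an optional
  preferential-attachment mode for degree-matched-null experiments.
  Defaults: n = 200, m = 400.
* **Gold standards** are 340 disjoint complexes of fixed size 6
  (~10,200 judged pairs). Disjoint equal-size complexes make every
  co-complex degree equal, so degree weighting is exactly neutral and the
  calibration recovery target is clean. True-positive pairs draw raw scores
  from Beta(2, 1), false-positive pairs from Beta(1, 2); with equally many
  of each, the true precision at raw score `s` is exactly `s` (recorded in
  the manifest). Real gold standards have overlapping, size-skewed
  complexes and score–degree correlations; passing the recovery test shows
  the estimator is correct under the stated sampling model, not that real
  benchmarks are free of residual degree bias.
* **Profiles** have i.i.d. standard-normal background values (so the pooled
  SD is 1 and effect sizes are in SD units); one planted set (default 20
  members, shift +2) among 50 uniform decoy sets of sizes 10–40. Both-ends
  fixtures shift half the set up and half down. Real measurements have
  heavier tails and correlated proteins; the rank-based tests are
  insensitive to the former but calibration under strong inter-protein
  correlation is not covered by these fixtures.
* **Covariates** are Gaussian-copula transforms of the profile's normal
  scores with a requested Spearman correlation (`r = 2·sin(πρ/6)` converts
  rank to Pearson correlation of the underlying normals); `ρ = 1` is a
  monotone copy, and a pure-noise column is always appended. Default
  biases: abundance 0.5, length 0.3, publications 0.6, disorder 0.2,
  GC content 0.0 (the deliberately unbiased control).

The both-ends fixture used in the acceptance suite has 12 members at ±2 SD
and is evaluated at α = 0.01. The regime matters: a one-sided KS toward the
top is itself sensitive to the up-shifted half of a both-ends set
(`D⁺_full ≈ 0.5·D⁺_half`, while critical values shrink only as `1/√m`), so
for large balanced fixtures the single-tail test also fires. Only for
small sets at stringent α do the two tests dissociate cleanly; detection is
asserted as rates over 40 seeded replicates rather than from a single draw.

## Numerical and degenerate-input choices

* Permutation p-values are add-one smoothed everywhere (never 0); the
  exhaustive AFC null needs no smoothing.
* Float comparisons in permutation counting use a `1e−12` tolerance so that
  algebraically tied statistics computed through different float paths
  count as ties.
* Rank ties: stable sorts with deterministic key (value, then identifier),
  mid-rank semantics for ECDFs and correlations.
* The prior `p₀` and sentence prior `p*` must be < 1; evidence
  probabilities of exactly 1 are rejected (they make the survival algebra
  degenerate) rather than silently truncated.
* Calibration on fewer than 2 precision points, all-identical raw scores,
  windows larger than the judged-pair count, and both-ends sets smaller
  than 4 are errors, not silent defaults.

## Problem sizes in the test and acceptance suites

Type-I calibration uses a 1000-protein null profile, 20-member sets,
499 permutations and 2000 replicates per test (network test: `G(400,
4000)`, 100-node queries — a denser graph keeps the edge-count statistic
fine-grained; on sparse graphs tie-heavy counts make the smoothed
permutation p conservative). Power uses 100 replicates of the default
generator conditions with `n_perm = 1999`. The acceptance script repeats
the same computations with 1000 type-I replicates. These sizes are the
package's own validation choices; all of them scale up by passing larger
`n_perm`, replicate counts or generator specs.

## Known limitations

* The combined-score prior is a single scalar; no per-channel or
  per-organism priors are modelled.
* Calibration transfer applies a fitted curve verbatim; no ortholog mapping
  or cross-species rescaling is performed.
* The ORA expected-edge display uses uniform-subset sampling by default;
  degree-matched nulls are optional and slower.
* Both-ends significance depends on the median-split convention; sets whose
  bimodality is far from 50/50 lose power (the minority half dominates the
  minimum).
* The bias report quantifies marginal trends only; it does not adjust
  enrichment results for the detected confounders.
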