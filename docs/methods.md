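# Methods

## Pairwise scores and their denominator

For each gene pair the package computes the full-sample Spearman rank
correlation per condition (average ranks on ties; a pair is flagged
undefined and excluded when either gene is constant). The three
comparative scores are

- C = |ρ₁ + ρ₂| / d,
- S = ||ρ₁| − |ρ₂|| / d,
- D = (|ρ₁| + |ρ₂| − |ρ₁ + ρ₂|) / d,

with d = √(σ₁² + σ₂²). Two identities follow algebraically and are
enforced by tests: C + D = (|ρ₁| + |ρ₂|)/d, and D > 0 exactly when
ρ₁ρ₂ < 0. Because Spearman correlation is invariant to monotone
per-dataset transforms, no normalisation is applied and the two
conditions may even be on different measurement scales (log microarray
vs. linear RNA-seq).

When d = 0 for a pair — possible only when both σ are 0, i.e. when
subsampling was unavailable in both conditions and the fallback constant
is 0 — the denominator is replaced by 1, so the scores degrade to their
plain numerators. If only one condition lacks subsampling its σ enters
as the fallback (default 0) and d is carried by the other condition.

## Subsampling standard errors

σ is the standard error of the mean of the per-subsample Spearman
values: sample standard deviation with denominator (m − 1), divided by
√m. The estimator choice is not dictated by the score definitions; it is
the standard SEM and is documented here as the package's convention.
Subsample values that are undefined (a gene constant within a subsample)
are dropped and m reduced; below two valid values σ falls back to the
configured constant.

Subsamples are pair-unique: the deterministic construction first cuts
the ordered samples into consecutive disjoint blocks of size n, then
runs greedy passes from each initiating sample, adding any sample that
has never shared a subsample with a current member, emitting whenever
size n is reached and re-initiating from the same point until exhausted.
Sample order is the input column order — no shuffling — so the design
depends only on (N, n). Remainder samples that do not fill a first-pass
block are picked up by the greedy passes.

Defaults: n = max(7, ⌊√N⌋). √N maximises the number of subsamples
(n² ≈ N makes blocks and cross-blocks balance), while n < 7 makes the
per-subsample correlation too coarse to be informative. The same n is
required for both conditions — enforced by construction in the model
object — because σ shrinks systematically with n and an unbalanced pair
of σ's would bias the shared denominator toward one condition. Fewer
than 49 samples triggers a warning, not an error: the SEM remains
computable but increasingly unreliable. As a caution for very small N,
`expected_spurious_perfect_correlations` reports the expected count of
perfect rank correlations arising by chance, pairs/(N!) — about 12 for
1000 genes with 8 samples each.

## Thresholds at a common importance level

Each score distribution gets its own cutoff X_p: the mean of the maxima
of m random draws of size L from the scores, p = 1/L. Draws are without
replacement within a draw and independent across draws (overlap across
draws allowed); with-replacement drawing is exposed as an option. The
draw count default m = 100 balances Monte-Carlo error of the cutoff
(∝ 1/√m) against cost; draws are seeded and reproducible. On a
Uniform(0,1) score distribution the cutoff has closed form L/(L+1),
which the tests use for calibration. p ranks scores on a common scale
across the three distributions; it is deliberately not a significance
level — no null hypothesis is involved.

Default L = 10⁵ (p = 10⁻⁵), appropriate for transcriptome-scale inputs
with millions of pairs; L must not exceed the number of scored pairs, so
small analyses pass a smaller L. A pair exceeding several cutoffs (which
happens at permissive p) is assigned the single type with the largest
score/cutoff ratio — deterministic and invariant to rescaling all
thresholds — and the multi-hit count is logged; at stringent p the
categories become mutually exclusive on their own.

## Network statistics

Nodes are genes with at least one retained link. Homogeneity
H = Σₜ (kₜ/k)² lies in [⅓, 1]; H = 1 iff exactly one link type is
present, and degree-2 nodes can only attain 1 or 0.5. Hubs are ranked
per type by that type's degree, ties broken by total degree then gene
id; k > 10 is labelled "hub" and 3 ≤ k ≤ 10 "intermediate" in the node
table. Components sort by node count, then edge count, then smallest
member.

Null models are double-edge-swap randomizations: 10 accepted swaps per
edge by default, rejecting any swap that would create a self-loop or
parallel edge, so the degree multiset is preserved exactly; rigid graphs
(stars, triangles) return unchanged and the comparison is flagged
degenerate when the null spread is zero. Assortativity is Newman's
excess-degree Pearson formulation (NaN on regular graphs). Empirical
p-values use the add-one convention (1 + #{null ≥ obs})/(n + 1).

For reference-network comparison, the edge-overlap null resamples both
the node set and the pair set uniformly at the observed sizes; the
shortest-path null draws same-size samples of connected node pairs
(component-weighted) from the reference. The reference formulation is
ambiguous between sampling pairs and sampling nodes; pairs are sampled
here because the empirical quantity is a mean over pairs, and the
alternative is noted. Intermediary ranking enumerates all shortest paths
of length ≤ 3 between linked pairs and counts each internal node once
per path. Gene-set enrichment is the upper-tail hypergeometric test with
population = user-supplied background, Bonferroni-corrected by the
number of sets in the collection.

## Synthetic benchmark

The generator emulates a perturbation experiment on a known regulatory
network: a preferential-attachment-style directed network (signs ±1
equiprobable, weight magnitudes Uniform(0.2, 1.0), no self-loops,
weakly connected when enough edges are requested), from which a second
condition is derived by removing round(5% · |E|) edges and sign-flipping
an equal, disjoint set (rounding half away from zero — relevant because
5% of a realistic edge count is fractional). Unchanged edges are
ground-truth C pairs, removed edges S, flipped edges D.

Expression is a linear-Gaussian structural model: each sample solves
x = A x + e with standard-normal exogenous input, plus observation noise
of 0.1 × each gene's signal sd (the noise level is a package choice,
exposed in the config). Weights are rescaled so the spectral radius of
|A| is 0.75, which bounds the radius of every perturbed variant of the
same network, keeping both conditions at identical interaction
magnitudes. What this model reproduces is exactly the sign/strength
correlation structure the scores consume; what it does not reproduce is
mRNA kinetics, saturation, bursty counts, batch effects or confounded
subpopulations — so a passing benchmark shows the ranking machinery
works when correlations do encode the perturbations, not that any real
data set is this clean.

Evaluation restricts to directly regulated (labeled) pairs: per score
type the positives are its own label and the negatives the other
labeled pairs (an option widens negatives to all pairs). ROC curves
group tied scores; AUC is the trapezoid rule and equals the
Mann-Whitney statistic (checked against a brute-force oracle in tests).
Default desk-scale protocol: 200 genes, 480 edges, 200 samples per
condition, 5 repeats with fresh networks and data each time, curves and
AUCs averaged across repeats; a label-shuffling switch provides the
chance-level control. Perturbing single edges in a connected network
often barely moves a pairwise correlation — shared regulators and
cascades buffer it — so the benchmark is judged by AUC margins over 0.5,
not by near-perfect recovery.

## Numerical and interface choices

- Correlation matrices are computed as normalized rank-row products and
  clipped into [−1, 1]; subsample moments are accumulated streaming
  (no m × P × P array), with tiny negative round-off variances clamped
  to zero.
- TSV outputs use 6 significant digits so reruns diff cleanly; the
  stage-by-stage CLI caches pair tables at the same precision, which is
  the tolerance to use when comparing cached-path and full-path scores.
- All randomness (threshold draws, rewiring, benchmark generation) flows
  through seeded `numpy` generators; every pipeline output is
  deterministic given its seed, and the run manifest echoes every
  parameter needed to reproduce a run.
- Missing or non-numeric expression values are rejected at load; tied
  values pass through untouched and are handled by average ranks.
- Gene identity is exact string match; constructing a one-to-one match
  across conditions (ortholog mapping, ID conversion) is upstream of
  this package.

## Known limitations

- The all-pairs correlation stage is O(P²) in memory and time per
  condition; transcriptome-scale inputs (≳2 × 10⁴ genes) need tens of
  gigabytes for the dense pair tables and are best run on a large
  machine or restricted by a keep-list.
- σ and ρ are dependent (correlations near ±1 cannot scatter), so the
  scores are not pure z-statistics; the common-importance thresholding
  is what makes them comparable.
- The S score does not distinguish which condition lost the correlation;
  the per-condition ρ columns in the score table carry that information.
- Homogeneity is undefined for isolated genes, which are never nodes.
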