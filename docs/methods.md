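# Methods

## Model and procedure

For m molecules with activities A ∈ ℝᵐ (log-scale potencies) and a
similarity matrix S ∈ [0,1]^{m×m} (symmetric, unit diagonal), the landscape
statistic is the pairwise SALI value

    SALI_ij = |A_i − A_j| / (1 − S_ij),   i < j,

a vector of m(m−1)/2 nonnegative values. The numerator carries absolute
value bars: SALI is a statistic of unordered pairs and must be symmetric in
(i, j).

**Null construction.** One scrambled landscape is produced by drawing two
*independent* uniform permutations π, σ of the molecules and recomputing
SALI from S′ = S[π, π] (rows and columns permuted together — exactly
equivalent to shuffling which molecule carries which fingerprint and
recomputing Tanimoto) and A′ = A[σ]. The permutations must be independent:
applying one shared permutation to both merely relabels the pairs and
reproduces the observed SALI multiset exactly (asserted as a test), so it
carries no information about the null. Similarities are never permuted
entry-wise (they are not statistically independent) and bits within a
fingerprint are never scrambled — whole fingerprints change owners. N
scrambled SALI vectors are stored per iteration and concatenated into an
accumulated null of N·m(m−1)/2 values (fewer if pairs are undefined, see
below).

**Landscape validity.** The observed SALI sample is compared with the
accumulated null by a two-sample Kolmogorov–Smirnov test; the landscape is
declared valid when p < α. The statistic D is computed exactly; the
p-value is the asymptotic two-sided one, since the accumulated pool runs to
millions of values where exact two-sample p-values are intractable (and the
asymptotic form is what R, the original computing environment for this kind
of analysis, uses at these sizes).

**Cliff significance.** The magnitude threshold is the q-quantile of the
defined observed SALI values, with q = 0.95 by default; quantiles use
linear interpolation (R type 7, the numpy default). A pair at or above the
threshold (≥, so that heavily tied distributions behave deterministically)
is a magnitude cliff; F_magnitude is the fraction of defined pairs above
threshold. For each pair, N_greater counts iterations whose random SALI at
the *same pair position* is strictly greater than the observed value; the
empirical p-value is exactly N_greater/N (no +1 correction, so p = 0 is
attainable), and a pair is a significant cliff when it is a magnitude cliff
with empirical p < α. F_significant is the fraction of defined pairs that
are significant cliffs, reported as NA whenever the landscape validity test
itself failed — per-cliff statistics on an invalid landscape are not
interpretable. No multiple-testing correction is applied across pairs: the
raw per-pair α is the procedure. An alternative interval formulation
(`quantile_interval_test`: significant iff outside the (0.05, 0.95)
quantile interval of the pair's null) is provided for cross-checking.

**Per-iteration diagnostics.** `per_iteration_check` counts the iterations
whose own SALI values are KS-distinguishable (p < α) from the accumulated
null, each iteration compared against the full accumulation including
itself (the literal reading; excluding the iteration changes the pool by
≤ 1/N of its mass). High counts flag datasets where single scramblings are
unrepresentative of the pooled null.

## Parameters

| parameter | default | meaning |
|---|---|---|
| N (`n_iterations`) | 1000 | scrambled landscapes per test; empirical p resolution is 1/N |
| α (`alpha`) | 0.05 | significance level for both the KS test and per-pair p-values |
| q (`threshold_quantile`) | 0.95 | observed-SALI quantile defining magnitude cliffs; 0.90 is the other conventional choice and is one flag away |
| `undefined_pair_policy` | exclude | treatment of pairs with S_ij = 1 but A_i ≠ A_j (division by zero) |
| `cap_value` | — | finite sentinel used when the policy is `cap` |
| `seed` | 0 | seeds one generator consumed in a fixed order (similarity permutation, then activity permutation, per iteration), so pools are bit-reproducible and replayable |

Degenerate pairs: S_ij = 1 with equal activities is a duplicate pair and
contributes SALI = 0; S_ij = 1 with differing activities is undefined and,
under the default policy, is excluded from the observed *and* every random
SALI distribution so the KS comparison stays like-for-like. Tanimoto of two
all-zero fingerprints is defined as 1 (identical objects). Similarity
matrices read from files are symmetrized by averaging when the asymmetry is
≤ 1e−8 and rejected otherwise; diagonals within 1e−8 of 1 are snapped to 1.

## Synthetic landscapes

The generators emulate the statistical structure of small-molecule SAR
benchmark sets — tens to hundreds of molecules, binary fingerprints
(default L = 166 bits at density 0.3, the scale of MACCS keys), activities
on a pIC50-like scale (default range 4–9) — and nothing else: no scaffolds,
no R-group chemistry, no assay error model. Four kinds:

- **flat** — all activities at the range midpoint; every SALI value is 0.
  Certainly not random, but not an SAR either; the validity test does not
  reject it (both distributions are the same point mass).
- **random** — activities i.i.d. uniform on the range (a normal-core +
  exponential-tail mixture marginal is available, emulating the skewed
  potency marginals of real assay data), independent of the fingerprints:
  the truth of the null hypothesis.
- **planted_sar** — a positive control with a genuine SAR. Activity is an
  affine function (weights = structural footprint, see below) of
  `n_informative_bits` bit indicators, min–max rescaled to the activity
  range, plus Gaussian noise. The fingerprints follow a hierarchical
  scaffold model: each informative bit owns a geometrically sized block of
  background keys (the "scaffold" bit has the largest footprint), half of
  each block copying the bit and half its complement, every key flipped
  independently with probability 0.1. Two design points matter. First,
  with i.i.d. background bits a handful of informative bits is
  asymptotically invisible to Tanimoto similarity as L grows, which would
  make the positive control vacuous — real substructure keys are strongly
  correlated (a scaffold toggles many keys at once), and the block
  structure reproduces that. Second, Tanimoto counts shared *on*-bits
  only, so the complement half-blocks make agreement on informative zeros
  visible in similarity too (alternative substituents light up different
  keys). Activity weights equal block sizes, as in a congeneric series
  where the scaffold dominates both structure and potency.
- **jagged** — random activities, after which the members of the
  `cliff_pairs` most-similar (non-duplicate) pairs are pinned to opposite
  extremes of the activity range, manufacturing cliffs exactly where
  similarity is highest; overlapping pairs are resolved so that earlier
  cliffs are never destroyed.

All generators are deterministic given the spec and seed; all-zero
fingerprints are resampled.

What passing tests on these generators shows — and what it does not: they
exercise every code path and the directional behaviour of the tests
(smooth SAR detected, independent activities not, planted cliffs
individually significant), but uniform activities and Bernoulli/block
fingerprints are far cleaner than real assay data, so calibration numbers
measured on them do not transfer to any particular experimental dataset.

## Statistical behaviour worth knowing

**The validity test is conservative on continuous data.** Scrambling the
activities permutes the molecules, and the set of unordered pairs is
invariant under any such permutation: the *multiset* of |A_i − A_j| over
all pairs is identical in every iteration, and likewise the off-diagonal
similarity multiset. Observed and null samples therefore share their
marginals exactly and differ only in how activity differences are coupled
to similarities. The two-sample KS p-value, which assumes independent
samples, is computed against fluctuations far larger than this coupling
variability, so under a true null with continuous activities the test
rejects essentially never (measured rejection 0/200 at α = 0.05 on the
random generator; p-values concentrate near 1). Consequences: a rejection
is trustworthy (the effective type-I error is far below nominal), but the
test's power comes entirely from real dA–similarity coupling, and weakly
structured landscapes will be missed. On heavily tied, discrete SALI
distributions (coarse fingerprints) the same marginal-sharing makes single
iterations lumpy and the per-iteration distinguishability count can instead
run high — calibration is dataset-dependent, which is precisely why the
per-iteration diagnostic exists.

**Smooth vs jagged.** A valid (smooth-SAR) landscape typically has *no*
individually significant cliffs — its high-SALI tail is reproduced by
chance couplings in the null — while a jagged landscape can fail the
validity test yet contain individually significant engineered cliffs. The
two layers of the test answer different questions by design.

## Numerical choices

- KS: exact D; asymptotic two-sided p (`scipy.stats.ks_2samp`,
  `method="asymp"`); cross-checked in the tests against a brute-force ECDF
  scan for D and against an R `ks.test` oracle value for p. Ties are
  tolerated (they are common with coarse fingerprints).
- Quantiles: type 7 (linear interpolation) everywhere.
- Empirical p: strictly-greater count over N; ≥ for the magnitude
  threshold.
- Permutations: Fisher–Yates via `numpy.random.Generator.permutation` from
  a single `default_rng(seed)`; consumption order documented and replayed
  by the oracle tests.
- Serialization: floats written with 17 significant digits (lossless
  float64 round trip).
- Mean fusion requires identical molecule id ordering; file inputs are
  aligned by id with one canonical sort, so row order never affects
  results; molecules missing from any input are a hard error unless
  subsetting is explicitly requested.

## Problem sizes

The test suite and the reproduction script use m = 12–40 molecules with
N = 50–1000 scramblings, and 50–200 replicate datasets for the
power/calibration measurements — sizes at which every quantity is
recomputable from scratch in seconds to a couple of minutes on one CPU
while matching the m = 48–299, N = 1000 scale of typical benchmark sets
closely enough for the statistics to behave the same way.

## Limitations

- The per-pair empirical p has resolution 1/N and no continuity
  correction; p = 0 means "never exceeded in N draws", not impossibility.
- No multiple-testing control across the m(m−1)/2 pairs, by design.
- The conservativeness described above means a non-significant validity
  result is weak evidence of randomness on small datasets.
- Fingerprint generation from chemical structures is out of scope; inputs
  are bitstrings or precomputed similarity matrices.
- Landscape metrics other than SALI (SARI, SAS maps) are not implemented;
  the machinery is metric-agnostic in principle but no interface is
  exposed.
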