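# Methods

## Information-content metrics

**Homolog count** is the number of non-query rows of the supplied
alignment. Retrieval (e.g. jackhmmer, HHblits) is outside the toolkit;
the alignment on disk stands in for the search result, and iteration
count or search tool are treated as metadata of the input.

**NEFF** is the mean, over *all* alignment columns, of the number of
distinct canonical amino-acid types observed in the column. It ranges
from 1 (all rows identical) to 20 (complete variability in every
column). Two boundary decisions:

* gaps and ambiguity codes (X, B, Z, U, O, J) never count as types —
  otherwise the 1–20 range would not hold;
* a column containing only gaps contributes 0 to the mean and triggers a
  warning, since "number of distinct residue types present" is the only
  reading that needs no imputation.

This is a *diversity-count* NEFF, distinct from the weighted-sequence
NEFF (Henikoff weights, 80 %-identity clustering) used elsewhere in the
literature; no sequence weighting is applied anywhere in the package.

**Per-residue entropy** is the plug-in Shannon entropy (base 2, no
pseudocounts, 0·log 0 = 0) of the canonical-letter frequencies in each
column aligned to a query residue; the headline number is the mean over
those query columns. Entropy deliberately averages over *query* columns
(it is a per-residue quantity of the query protein) while NEFF averages
over all alignment columns (it is a property of the MSA). Values lie in
[0, log₂ 20 ≈ 4.322] bits.

**Depth subsampling** keeps the query and draws the requested number of
homolog rows uniformly without replacement from a `numpy` generator
seeded by the caller; the same seed always yields the same row set.

A3M input is normalised by deleting lowercase letters (insert states
outside the query frame) and mapping `.` to `-`; aligned FASTA and
Stockholm are read through Biopython.

## Contact maps

Residues are indexed 1-based by order along the parsed chain; insertion
codes collapse into sequential positions, and the same frame is assumed
for predictions. The representative atom is Cβ, or Cα for glycine;
non-glycine residues missing their Cβ fall back to Cα with a warning
rather than being dropped (incomplete side chains are common, and
dropping them would silently shrink L). Residues with neither atom are
recorded as missing and excluded from pair derivation. A pair (i, j) is
a contact iff the representative-atom distance is strictly below the
threshold (default 8.0 Å; "closer than" is exclusive). Alternate
locations resolve to the highest-occupancy conformer. Contacts at all
sequence separations are stored; separation filtering is an evaluation
concern, so the ≥ L-contacts dataset filter counts pairs at any
separation while scoring uses |i − j| ≥ 5.

## Evaluation

`top_l_precision` discards predicted pairs with |i − j| < 5 (sequence
separation "greater than 4"), takes the best ⌊fraction × L⌋ survivors
(fraction defaults to 1, i.e. top-L; L/2 and L/5 reporting use 0.5 and
0.2), and reports the fraction that are true contacts. Ranking is total:
score descending, then i, then j ascending — so ties cannot make results
run-dependent, and any strictly monotone rescoring leaves PPV unchanged.
If the filtered list is shorter than the budget the denominator is the
number of pairs actually taken and a loud warning is raised; padding the
denominator would silently redefine the statistic for sparse predictors.
Dataset summaries give mean, median and the 25/40/60/75 percentiles with
linear interpolation.

## Dataset construction

`filter_records` applies a length window and, optionally, the
≥ L-contacts requirement, preserving order and logging removal counts.
The classic benchmark windows are 50–275 (contact-prediction sets) and
50–1500 (sequence-population sets); both are plain parameters.
Upstream properties — non-redundancy clustering, BLAST screening against
structures, disorder prediction, taxonomy — arrive as precomputed record
annotations and are trusted as given.

`match_distribution` implements distribution matching as quantile
matching: target quantiles at probabilities (k − 0.5)/n for k = 1…n are
computed on log1p-transformed counts, visited in seeded random order,
and each claims the unused candidate with the nearest log1p count.
Design rationale: homolog counts span orders of magnitude, so matching
in log space weights relative rather than absolute discrepancies; the
(k − 0.5)/n grid is the standard plotting-position estimate of an
empirical distribution; randomising the visiting order avoids a
systematic advantage for low quantiles when candidates are scarce; and
greedy nearest-unused assignment keeps the procedure deterministic given
the seed. Candidates are canonicalised by (count, id) before assignment,
so the selected *set* is invariant under permutation of the input. The
closeness diagnostic is the two-sample Kolmogorov–Smirnov statistic
between selected and target counts (scipy). On a pool that contains the
target distribution the sampler reaches KS ≈ 0; on a 6×-shifted pool it
still beats uniform-random selection in ≥ 95 % of seeds (tested).

`match_msa_depths` pairs records with target counts rank-to-rank (both
sorted ascending) and prescribes depth = min(own count, paired target):
rank pairing preserves the target's distribution shape as far as the
records allow, and the min rule encodes that homologs can be removed but
never invented. Each prescription carries a seed derived from
blake2s(seed, record id), so per-record subsampling is reproducible and
independent of processing order.

## Statistics

The two-tailed Wilcoxon rank-sum test uses midranks for ties. For
n₁ + n₂ ≤ 12 the p-value is exact: all C(n, n₁) assignments of the
observed midranks are enumerated and the two-sided tail mass of the rank
sum is counted. Larger samples use the normal approximation with the
standard tie-corrected variance and a 0.5 continuity correction. The
reported statistic is the (corrected) z in both regimes. The exact
type-I error of the large-sample form at α = 0.05 with n = 50 per arm is
0.0495 (computed from the distribution-free null of the rank sum), i.e.
the test is calibrated. No multiple-testing correction is applied across
strata by default; Bonferroni adjustment is available and off by
default. Pearson correlation delegates to scipy and refuses constant
input.

## Baseline predictor

MI+APC was chosen over re-implementing sparse-inverse-covariance or
pseudolikelihood DCA methods: the experiments here treat predictors as
interchangeable black boxes whose shared, load-bearing property is that
accuracy rises with alignment depth. Plug-in MI has that property, has
exact small-sample oracles (direct summation; MI equals the source
column's entropy under a sample-level bijection), and keeps the package
free of external binaries. Outputs of real predictors enter through the
RR/matrix readers instead.

For a column pair, rows gapped or ambiguous at either position are
dropped for that pair only (pairwise-complete); MI is computed in bits
from the joint frequencies, and APC subtracts
MI̅ᵢ·MI̅ⱼ/MI̅ (off-diagonal row means over the overall mean). Known
limitations: plug-in MI is biased upward by ≈ (|A| − 1)²/(2N ln 2) on
independent columns at depth N; no sequence weighting, so phylogenetic
redundancy is not discounted; APC removes shared background but is not a
model of indirect couplings.

## Synthetic data

Every generator is a pure function of its `SimConfig` (seed included).

* `gen_msa` draws letters iid per column, uniform over a seeded k-letter
  support (k configurable per column, default 20); the query row is
  gap-free. Expected NEFF and entropies follow in closed form, e.g.
  mean entropy → log₂ k at large depth.
* `gen_coupled_msa` plants covarying pairs: with probability c the
  letter at column j is a fixed bijective recoding of the letter at
  column i, else independent. Bijective coupling was chosen because its
  MI is exactly H(i) at c = 1, giving an analytic oracle. Planted pairs
  must have separation ≥ 5 and may not share columns (unambiguous ground
  truth).
* `gen_structure` grows a self-avoiding walk with consecutive Cα
  spacing 3.8 Å (the physical Cα–Cα virtual bond), non-consecutive
  approach ≥ 4.0 Å, and a unit inward pull toward the running centroid
  that keeps chains compact enough to guarantee, for L ≥ 30, at least
  one contact at separation ≥ 5 (verified, retried with derived seeds
  otherwise). Pseudo-Cβ atoms sit 1.5 Å from Cα in a random direction;
  glycines carry none, exercising the Cα fallback.
* `gen_predictions` plants exactly round(p·K) true contacts among the
  top K at separation ≥ 5, in seeded random order with strictly
  decreasing scores, so the evaluator can be tested for exact closure.
* `gen_count_populations` draws integerised log-normal samples for the
  two populations. Defaults: μ = 4.0, σ = 1.5 for the reference
  (median ≈ 55 homologs, heavy right tail spanning orders of magnitude)
  and μ = 4.0 + ln 6 with the same σ for the structure-biased
  population, making the population mean ratio exactly 6; 5000 draws
  per population. These defaults are the simulated study conditions and
  are not adjusted per experiment.

What the generators do **not** emulate: phylogenetic correlation between
rows (real MSAs are tree-structured, which inflates apparent depth),
realistic gap architecture, amino-acid composition bias, and real
side-chain geometry. Passing tests therefore demonstrate correctness of
the algorithms and the direction and mechanism of the depth effect, not
quantitative performance numbers on real proteins.

## Problem sizes used in the test suite

The deeper experiments run at deliberately modest scale chosen to make
the signals unambiguous while keeping the suite quick: coupled MSAs of
L = 60 with 20 planted pairs at depth 500 (truncation control: 5 % =
25 homologs, 10 seeds), recovery-monotonicity grids of 3 seeds × 3
levels, 100 sampler trials against 5000-count populations, and 2000
null replicates for calibration, cross-checked against the exact null
distribution.
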