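# Methods

## Model and procedure

The central question is whether a toxin ribonuclease's recognition site is
underrepresented in (+)ssRNA phage genomes.  Two nulls are used, both
deliberately simple:

1. **Composition expectation (zero order).**  The expected frequency of a
   k-mer is the product of the genome-wide base fractions at each motif
   position; the expected count multiplies that frequency by the genome
   length L.  The observed frequency divides the overlapping occurrence
   count by the number of windows, L − k + 1.  The two denominators (L vs
   L − k + 1) follow the published convention for these quantities; the
   difference is below 0.06% at the ~3.5 kb genome lengths involved, far
   inside the 2-decimal precision at which relative frequencies are
   reported.  No higher-order Markov background or RNA-structure
   accessibility weighting is applied: avoidance is measured against
   composition alone.

2. **Permutation null.**  Uniform random permutation of all nucleotide
   positions (a mononucleotide shuffle), preserving base composition
   exactly, repeated n_shuffles times (default 10,000).  The summary is the
   percentage of shuffles with *strictly* more sites than the original;
   ties are tallied separately and also exposed as a tie-split ("mid-p")
   exceedance `(n_higher + n_equal/2)/n`, the quantity that is uniformly
   distributed under the null for a discrete count statistic.  No
   dinucleotide- or codon-preserving shuffle is offered: the hypothesis
   concerns arrangements of the same nucleotide pool.

Sequences are held as RNA (T→U on read, uppercased).  IUPAC ambiguity
codes are preserved, count toward genome length and composition
denominators, and never match any motif position; degenerate letters in a
*motif* (e.g. ACD) match their expansion sets, and the expected frequency
of a degenerate motif is the sum over its concrete expansions (computed as
a product of per-position fraction sums).

**Cohorts.**  Host assignment is a case-insensitive prefix match on the
genus string, so "Escherichia coli" and broad-host entries such as
"Escherichia; Pseudomonas" join the focal cohort; hosts recorded as
"unclassified" are excluded from every cohort.  (+)ssRNA phages of
bacterial hosts other than the focal genus are reported as unclassified
rather than silently merged into another bin.  The test of cohort-mean
departure from 1 is not uniquely determined by the source analyses; the
default is the Wilcoxon signed-rank test (robust for skewed, bounded
ratios), with a one-sample t-test available behind a flag.

**Fitness.**  Wrightian relative fitness is the ratio of the two strains'
CFU fold-changes.  Inference fits an intercept-only linear model to the
replicate w values and tests the intercept against 1 — algebraically a
one-sample t-test on w − 1 — with a t-based 95% CI.  Zero-variance inputs
degenerate by convention (p = 1 when the common value is 1, else 0; the CI
collapses to a point).  No multiple-testing correction is applied across
conditions; each phage × MOI combination is tested separately.

**Single-cell fates.**  The at-risk set is the cells present at the start
of phage exposure; survival at time t is the fraction without a lysis
event at or before t, and non-lysed cells count as surviving through the
end of observation (no censoring model beyond that truncation).  Lysis
times are compared by the Mann–Whitney test: exact enumeration when both
samples have ≤ 8 untied observations, otherwise the tie-corrected normal
approximation *without* continuity correction, so perfectly balanced
samples give p = 1 exactly.  Cell-length change uses the Wilcoxon
signed-rank test in paired mode, Mann–Whitney otherwise.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_shuffles` | 10,000 | permutations per genome; Monte-Carlo SE of the exceedance percentage is ≤ 0.5 points at this depth |
| `min_length` | 1,000 nt | genomes must be strictly longer to enter a cohort scan |
| `host_filter` | Escherichia | genus defining the focal cohort |
| motifs | ACA, GCU, ACG, ACU | MazF, MqsR and ChpB recognition sites |
| histogram bins | width 0.05 on [0, 2], open top | cohort display binning |
| `alpha` | 0.05 | significance threshold in reports |

One top-level seed drives everything; per-(genome, motif) streams are
derived by hashing the pair into a substream, so shuffle results are
independent of processing order and reproducible under parallel or
reordered execution.

## Synthetic data: what it emulates, what it does not

`simulate_genome` draws an i.i.d. sequence from a given composition; an
avoidance factor ρ < 1 is then enforced by repeatedly picking a random
motif occurrence and substituting its centre base with a random
non-matching base, rescanning after each edit, until the count first falls
to or below ρ × the expected count under the current composition (ρ > 1
symmetrically completes near-miss windows).  Disruption was chosen over
rejection sampling because rejection is infeasible for strong avoidance at
multi-kilobase lengths.  The edits drift the composition slightly (a few
centre bases per genome); the realized count and composition are recorded
in the record description rather than assumed away.  Because the loop
stops at the first crossing, realized relative frequencies sit about half
a count below the target on average — well inside the ±0.05 recovery
tolerance used in the tests.

The competition generator thins each strain binomially by its survival
probability and applies a common deterministic growth fold, so the
expected fitness is exactly the survival-probability ratio.  The fate
generator draws fates categorically and lysis times from a lognormal
(default median 150 min, log-sd 0.4, right-skewed positive support chosen
as realistic for single-cell lysis timing; gamma available), truncated at
the end of observation by resampling; a shift factor multiplies the time
scale.  Growth curves are logistic with replicate-level multiplicative
yield noise (default CV 5%).

None of the generators model real biology beyond these moments: no
secondary structure, codon usage or gene boundaries in genomes, no
phage-replication dynamics in assays, no correlation between a cell's fate
and its length.  Passing recovery tests therefore demonstrates that the
estimators are unbiased and calibrated under the stated sampling models —
not that real genomes or cells satisfy those models.

## Numerical choices

- Display rounding is half-away-from-zero (2 decimals for relative
  frequencies, nearest integer for expected counts), matching how such
  tables are conventionally printed; full precision is always kept
  alongside.
- A zero expected frequency with zero observed count yields an undefined
  relative frequency (NaN, flagged) rather than 0/0; a zero expected
  frequency with a positive count is rejected as an impossible composition.
- "Longer than 1,000 nucleotides" is a strict inequality.
- The endpoint biomass comparison snaps the requested time to the nearest
  recorded grid point within half the median sampling interval and errors
  beyond that.
- The fold-protection CI is a seeded percentile bootstrap (10,000
  resamples by default).

## Problem sizes in the checks

The bundled checks run at desk scale: counting properties on ~1,000 random
sequences across all 64 trinucleotides; null-uniformity on 200 simulated
3 kb genomes at 500 shuffles each; parameter recovery on 200 genomes of
3.5 kb, 200 competition replicates and 200 fate-table pairs of 150 cells;
calibration on 2,000 simulated nulls per test.  These sizes give
Monte-Carlo errors comfortably inside the asserted tolerances while
keeping a full run in tens of seconds.

## Known limitations

- The zero-order expectation ignores dinucleotide bias; a genome can look
  "avoided" purely through, e.g., CpA depletion.  The shuffle null shares
  this limitation by design.
- Shuffle-exceedance percentages are Monte-Carlo estimates; published
  values are reproducible only within permutation error, as the original
  random streams are unknown.
- Completeness of partial genomes is a user-supplied flag; no taxonomy
  resolution beyond string matching on host genus.
- The per-genome table reproduction and the 57-genome cohort means require
  sequence sets that must be fetched from NCBI (helper script provided);
  without them those checks report the missing input.
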