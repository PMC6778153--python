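# Methods

`lfqpipe` implements the quantitative core of a label-free (LFQ) shotgun
proteomics comparison of two biological conditions with a small number of
replicates — the design used for tomato fruit pericarp microsomes at the
mature-green (MG30) and red-ripe (R45) stages, three biological replicates
each.  This note records the model, the parameter choices, the numerical
conventions, and what the synthetic benchmark does and does not show.

## Input model and filtering

The input is a MaxQuant-style `proteinGroups` table: one row per protein
group with per-sample LFQ intensities, peptide-evidence counts and quality
flags.  Raw intensity 0 is the missing-value sentinel ("not quantified in
this run"); negative intensities are rejected.  Sample-to-condition
assignment always comes from an explicit design table — never from column
name parsing — so a mislabelled sample fails loudly.

Identification-quality filtering removes decoy (reverse) hits,
contaminants, proteins identified only by a modification site, and
proteins with insufficient peptide evidence.  The default evidence gate is
the stringent one (at least 2 razor+unique peptides, at least 1 unique);
setting `min_razor_unique=1` reproduces the permissive one-peptide set.

Intensities are log2-transformed (zeros become explicit missing values)
and then filtered by the valid-value rule: a protein is retained when it
has valid values in at least 4 of the 6 samples, **or** when it is
*stage-specific* — valid in all three replicates of one stage and in none
of the other (3:0 / 0:3).  Patterns such as 3:1 qualify only through the
≥4 rule; the stage-specific rule requires a completely empty other stage.
The decision table over all 2^6 = 64 missingness patterns is pinned
against a brute-force oracle in the test suite.

## Missing-value imputation

LFQ missingness is treated as missing-not-at-random: the probability that
a cell is missing increases as abundance falls toward the detection limit.
Two branches fill the retained table:

- **Downshifted normal** (protein missing in 1 or 2 of 6 samples): each
  missing cell in sample *s* draws independently from
  `Normal(mean_s − downshift·sd_s, (width·sd_s)²)` where `mean_s`/`sd_s`
  are that sample's observed-value statistics (n−1 denominator).  The
  defaults width = 0.3 and downshift = 1.8 are the established convention
  for this imputation, interpreted as multiples of the per-sample observed
  SD.  Draws are made in (protein id, sample id) lexicographic order from
  one seeded stream, so results do not depend on row storage order.
- **Condition-absent** (stage-specific proteins): every missing cell is
  set to the same deterministic constant — the unweighted mean over all 6
  samples of each sample's minimum observed log2 intensity.  The
  "average minimum" is computed across *all* runs (not per condition);
  this is the simplest reading of the convention and is the interpretive
  choice most open to variation.

Branch routing partitions the retained set (complete / downshift /
condition-absent); anything else is unreachable after the valid-value
filter and is asserted.  Observed cells are never modified.

## Differential abundance

The relative abundance ratio is the difference of mean log2 intensity,
treatment minus reference (log2(R45/MG30)), imputed values included.
Significance uses a two-sided two-sample t-test (Student pooled-variance
by default, df = 4 for 3v3; Welch available), followed by
Benjamini–Hochberg FDR (label-permutation FDR over all 10 distinct 3v3
splits available as an alternative).  Degenerate rows with zero variance
in both groups get t = 0, p = 1 when means agree and p = 0 (flagged)
otherwise.

**FDR family.** Only proteins quantified in both stages enter the FDR
adjustment.  Stage-specific proteins are categorized by their presence
pattern, never by the test, and their nominal p-values are artifacts of
the constant condition-absent fill (zero within-group variance, p ≈ 0);
letting those p = 0 values into the family would anti-conservatively
shrink every other protein's q.  Their `q_value` is reported as NaN.

Categories (cut c = 0.58 log2 units — the printed two-decimal rounding of
log2(1.5) — and FDR gate α = 0.05, both configurable):

| category | rule |
|---|---|
| MG30-specific / R45-specific | 3:0 / 0:3 presence pattern (overrides the test) |
| MG30-enriched | log2 ratio ≤ −c and q < α |
| R45-enriched | log2 ratio ≥ +c and q < α |
| invariant | \|log2 ratio\| ≤ c |
| putatively-invariant | \|log2 ratio\| > c but q ≥ α |

At exactly \|ratio\| = c the enriched and invariant rules overlap; the
closed invariant interval wins (conservative tie-break).
Putatively-invariant is kept as a distinct sixth label so both groupings
(as invariant, or as a separate class) can be reported.

## GO over-representation

One-sided Fisher exact test: p = P(X ≥ observed) with X hypergeometric
(population = background proteome, successes = background proteins
annotated with the term, draws = query set).  Expected count =
query_size · background_annotated / background_size; fold enrichment =
observed / expected.  Correction across all tested terms is BH by default
(Bonferroni available); significance is corrected p < 0.05.  Annotations
are used exactly as supplied — no GO-graph ancestor propagation; a closure
must be precomputed upstream if wanted.

## Transcript–protein correlation

Per-gene transcript log2 fold-change is `log2((rpm_R45+ε)/(rpm_MG30+ε))`
with pseudocount ε = 1 RPM by default (ε = 0 drops undefined points and is
appropriate when all RPM are strictly positive, as for generated data).
Proteins pair with transcripts through the annotation's gene id; each
quantified protein — stage-specific ones included, with their
imputation-derived ratio — contributes one point.  Pearson's r with the
two-sided t-based p-value (`t = r·√((n−2)/(1−r²))`, the R `cor.test`
convention, pinned against a frozen `cor.test` oracle) is reported
globally and per functional class with ≥ 3 points, along with the
regression slope of protein on transcript.

## Synthetic data generator

The generator is the test bench: it produces `proteinGroups`, transcript,
annotation and truth tables with the structure the analysis assumes.

- Baseline log2 intensity ~ Normal(25, 2²) per protein (the scale of LFQ
  intensities); condition means are baseline ± FC/2; replicate noise
  Normal(0, 0.25²) log2 units.
- 10% of proteins are differential by default, |log2FC| ~ Uniform(0.58, 3)
  with random sign; 4% are stage-specific (a subset of the differential
  ones): the low condition is deterministically fully censored and the
  high one forced complete, giving exact 3:0/0:3 truth.  The 4% default is
  roughly half the stage-specific fraction seen among quantified proteins
  in the motivating study, a conservative planted rate.
- MNAR dropout: each cell is censored to raw intensity 0 with logistic
  probability `1/(1+exp(steepness·(x − midpoint)))` of its true log2 value
  (midpoint 20.5, steepness 0.8 — about 8–10% missing cells at the default
  abundance scale, typical of LFQ experiments).  Low-abundance proteins
  therefore drop out preferentially, which is exactly the regime the
  downshifted imputation presumes — and also means random 3:0 patterns
  occur, so some presence/absence calls are unavoidable false positives of
  the rule itself.
- Transcripts: per functional class (14 named classes by default), mRNA
  log2 fold-changes are built by an exact Gram–Schmidt bivariate
  construction so the in-sample correlation with the planted protein
  fold-changes equals the class target exactly (when the class has
  variation), with transcript dynamic range widened by 1/slope
  (slope = 0.6): mRNA changes overshoot protein changes.  RPM levels are
  log-normal (log2 mean 7, SD 1.5).
- GO terms: three planted terms annotate differential proteins at rate 0.6
  (background rate 0.05), so enrichment has known positives.  Extra rows
  flagged reverse/contaminant/site-only and single-peptide rows exercise
  the quality filters; the truth table marks them `excluded`.

What the generator does **not** emulate: peptide-level roll-up, shared
peptides between groups, intensity normalization artifacts, batch or
run-order effects, and correlated replicate noise.  Passing benchmarks
therefore validate the statistical pipeline, not robustness to those
real-data phenomena.

## Benchmark results and honest limits

The bundled benchmarks (`lfqpipe.benchmarks`, re-run from scratch by
`scripts/acceptance.py` and the test suite) measure:

- **Exactness**: Fisher p equals exact rational hypergeometric tail sums
  (≤ 1e-10); BH equals the brute-force step-up oracle (≤ 1e-12); the
  filter matches its 64-pattern oracle exactly; 10^5 downshifted draws
  match the target normal in mean and SD to ±0.01.
- **Null calibration**: over 200 no-effect simulations (1000 proteins,
  3v3, σ = 0.25), the mean false-discovery proportion of q < 0.05 calls
  is ≈ 0.03–0.06, consistent with BH control at 0.05.
- **Power at small effects — a real limitation**: with planted
  |log2FC| = 1.0 and σ = 0.25, a 3v3 Student t-test has non-centrality
  ≈ 4.9 at df = 4, and the BH threshold at 1000 proteins with ~10%
  alternatives sits near p < 0.005 (critical |t| ≈ 6–7), so the median
  alternative (p ≈ 0.008) is *not* rejected: measured sensitivity is
  ≈ 0.05–0.12, and most of the few differential calls at that effect size
  are accidental 3:0/0:3 dropout patterns.  This is an inherent property
  of the design (3 replicates, unmoderated variance), not an
  implementation defect: reliable detection at q < 0.05 needs effects of
  roughly 2 log2 units or more at this noise level, which is why the
  five-category scheme leans on the large-effect and presence/absence
  calls.  Moderated-variance tests would change this trade-off but are
  out of scope.
- **Correlation recovery**: class targets {0.9, 0.5, 0.0, −0.1} at n = 100
  per class are recovered with mean absolute error ≈ 0.077 over 50 seeds;
  the error is dominated by the systematic attenuation of high-r classes
  by measurement noise and imputation.

## Numerical conventions

Tables are pandas DataFrames indexed by protein id; missing log2 values
are NaN.  Results TSVs serialize floats to 6 significant digits and
round-trip through the package readers.  All randomness (imputation draws,
generator) flows from explicit integer seeds; benchmark sub-seeds derive
from a `numpy` `SeedSequence`.  Benchmark problem sizes (200 null runs of
1000 proteins; 20 recovery runs; 50 correlation seeds) keep the full
validation under a minute on one CPU while holding Monte-Carlo error on
the reported rates to a few percent.
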