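# Methods

This note documents the models and procedures implemented in
`mirtyper`, the assumptions behind them, the parameters that matter, and
what the synthetic-data experiments do and do not demonstrate.

## Coordinate conventions

All intervals are 0-based half-open internally; converters at the
package boundary handle the two external dialects and nothing else does
coordinate arithmetic:

* miRBase-style GFF3 is 1-based fully inclusive: GFF3 `[100, 121]`
  becomes `[99, 121)` (length 22).
* TCGA isoform tables are 1-based with the start included and the end
  excluded: `[100, 122)` becomes `[99, 121)`.

Both conversions are involutions (tested by property). Annotation IDs
duplicated across distinct genomic loci — a known defect of one miRBase
release for a handful of precursors — are disambiguated with `-1`, `-2`
suffixes in (chromosome, start) order; the suffix scheme is this
package's convention, chosen to be deterministic and order-independent.

## Read-to-mature assignment

The quantifier consumes name-sorted alignments (SAM/BAM via pysam, or
in-memory records). For each alignment the *effective interval* is the
aligned reference span minus any terminal run of mismatching bases (MD
tag); soft-clipped bases never consume reference and are already outside
the span. This trimming exists because small-RNA protocols produce
non-templated 3' additions which an end-to-end aligner renders as
terminal mismatches or clips; they carry no positional information.

A candidate mature locus matches when strands agree and the total end
deviation ≤ `max_dev` (default 4 nt). "Total" is the sum
|Δstart| + |Δend| by default; `dev_mode="max"` switches to the maximum
of the two, exposed because either reading of "total deviation" is
defensible — the sum is stricter and is the default.

Per read group:

* unique mapper, ≥1 candidate → assigned to the minimal-deviation
  mature; an exact deviation tie between distinct matures (e.g.
  overlapping −5p/−3p annotations) is discarded and flagged rather than
  arbitrarily broken;
* unique mapper, no candidate → `unannotated`;
* multi-mapper → assigned once iff every alignment matches annotation
  and all matched matures share one identical mature sequence; the
  count goes to the lexicographically smallest mature ID so column sums
  are well defined. Anything else → `ambiguous_discard`.

Read conservation (assigned + unannotated + discarded = reads seen) is
asserted by test, as is order-invariance of the rule under permutation
of the alignment list. Sample-level QC flags libraries below a
configurable read count (default 500,000); flagged samples are kept in
the matrix and the exclusion decision is left to the caller.

Strand agreement between read and locus is mandatory. It is an
assumption — miRNA biogenesis is strand-specific — and reads from the
antisense strand of a locus are deliberately not counted.

## Isoform remapping

Cross-annotation-version remapping reuses the same deviation rule on
isoform-level records: each record is assigned to the minimal-deviation
mature locus within 4 nt total deviation; records matching nothing are
dropped into a report, and deviation ties between distinct matures are
dropped rather than split fractionally — fractional splitting would
complicate mass accounting and there is no principled split ratio.
Assigned + dropped read counts always equal the input total.

## Normalization

log2-CPM: `log2((c + p_j) / (N_j + 2 p_j) · 1e6)` with library-scaled
pseudo-count `p_j = prior · N_j / mean(N)` and `prior = 0.25`. The
scaling keeps the zero-count floor depth-independent; a plain fixed
pseudo-count is available via `library_scaled_prior=False`. Library
sizes are raw assigned-read totals; no between-sample scaling factors
are applied (factors are fixed at 1). The implementation is verified
against the reference count-package implementation (via Rscript) to
1e-6 on a toy matrix, and the prior→0 limit restores exact
counts-per-million column sums.

Expression complexity is the per-sample count of miRNAs at or above
each threshold on a −5…20 log2-CPM grid spaced 0.5, plus the mean curve.

Row standardization (for heatmaps) uses the sample SD (n−1). Constant
rows cannot be scaled; they are zeroed with a warning instead of
propagating NaN into clustering.

## Differential expression and the signature

Contrasts are one-vs-rest and all pairwise combinations of the subtype
labels. The per-miRNA statistic is pluggable; the default is the
two-sided Wilcoxon rank-sum on log2-CPM. A count-model test (e.g. a
negative-binomial GLM) could be substituted through the same interface;
the rank-sum default is distribution-free, calibrated (null rejection
0.044 at α = 0.05 over 1000 replicates), and powerful at the effect
sizes the generator plants (a +4 log2 shift at n = 20/20 reaches
q < 0.01 in ≥95 % of replicates).

Multiple testing uses Benjamini–Hochberg within each contrast,
verified against the brute-force step-up definition. The signature is
the union over contrasts of the top-k (default 15) miRNAs passing
q ≤ 0.01, ranked by q with ties broken by |log2 FC| (descending) then
ID — "most significant" is read as smallest q. Provenance records which
contrasts contributed each member.

## Consensus clustering

The Monti scheme: `reps` subsamples of ⌈0.8·n⌉ samples (and optionally
a feature fraction), each clustered by average linkage on
1 − Pearson correlation and cut at every k in 2…6;
consensus(i,j) = co-cluster count / co-sample count. Final labels come
from average linkage on 1 − consensus. Pairs never co-sampled are NA in
the stored matrix and imputed as column means for final clustering,
with a warning. Hierarchical merging ties are resolved by scipy's
deterministic lowest-index rule, and the whole procedure is
bit-reproducible under a fixed seed.

The consensus CDF is integrated over the full [0, 1] range (so a
perfectly binary matrix scores 1 − fraction of co-clustered pairs), and
the delta area at k is the relative gain over k−1. k is selected as the
smallest k whose k+1 gain falls below a threshold (default 0.1):
"moving further buys < 10 % more consensus area". Two low-confidence
situations are flagged rather than hidden: all gains below threshold,
and a 2-cluster area below an advisory floor (default 0.25), which
means no stable split exists at all — on unstructured data the
*relative* delta area keeps "gaining" against a near-zero baseline, so
the floor, not the delta rule, catches the single-cluster case. The
floor errs on the side of flagging heavily imbalanced true splits; the
selection is advisory and always reported next to the full curve.

χ² enrichment of clinical labels in clusters is the Pearson statistic
without continuity correction (so the canonical perfect-2×2 example
equals 20); expected counts below 5 trigger a warning.

Heatmap clustering is Euclidean/Ward in the variance-minimizing
(distance-squared, "ward.D2") formulation, verified against a naive
Lance–Williams implementation, with k-cuts for rows (default 5 miRNA
clusters) and columns (default 4 sample clusters).

## Subtype classification

Gene centering subtracts each gene's mean over a *fixed reference
cohort* only, so calls are stable under cohort growth — the reason this
design is used instead of per-cohort centering, which biases calls when
the cohort's subtype mix differs from the classifier's training mix.
Classification correlates the centered sample with each centroid over
shared genes (≥10 required) and takes the argmax; Spearman is the
default metric (standard for this classifier family), Pearson
available. Samples whose best correlation is below the threshold
(default 0.1) are unassigned with a reason, as are constant vectors;
centroid ties break alphabetically and are flagged. Centroid matrices
are an input file, never bundled.

Classification is exactly invariant to gene-wise constant shifts
applied to both reference and test data (tested), and recovery accuracy
is non-increasing in noise.

## Survival

Scores are arithmetic means of member miRNA rows; members may be given
as mature IDs or precursor stems, in which case all annotated arms
(−5p/−3p) are averaged — the choice of arms is configurable because
co-transcribed cluster members are usually reported at the precursor
level. The median split sends scores strictly above the median to
"high" and the rest (including the median itself) to "low". Per-stratum
analyses compute the median within the stratum only, after any clinical
subgroup filter (e.g. ER+/HER2−, node-negative, endocrine-treated
only). Kaplan–Meier estimation and the log-rank test are delegated to
lifelines and checked against closed forms, a brute-force product-limit
computation, and a permutation reference. A host-gene expression column
(for a co-transcribed long non-coding RNA) runs through the same code
path as a miRNA-cluster score.

## Synthetic data

The generators define the study conditions for every test:

* **Annotation**: 20 mature miRNAs on 2 toy chromosomes, both strands;
  2 paralog groups (one mature sequence at two loci — rescuable
  multi-mappers) and 1 decoy pair (sequences differing at one internal
  base — never rescuable). A toy genome is generated so SAM records
  carry real sequences.
* **Alignments**: reads drawn multinomially from an expression profile
  (uniform by default); 5'/3' end offsets are round(N(0, sd)) truncated
  at a configurable bound (sd = 1, bound 3 by default — most isomiRs
  within a couple of nucleotides of the annotated ends); with
  probability 0.1 a 1–3 nt non-templated 3' addition is emitted as a
  soft-clip whose bases are guaranteed to mismatch the flanking genome.
  Output is name-sorted SAM with NH tags.
* **Cohort**: four subtypes with group sizes 49/42/40/53 (a classified
  breast-tumor cohort's composition), 150 features, 15 planted marker
  miRNAs per subtype shifted +3 log2 units over a shared N(4, 2)
  baseline, i.i.d. N(0, 1) noise — or samples drawn around an explicit
  centroid matrix.
* **Survival**: exponential event times with a multiplicative group
  hazard ratio and independent exponential censoring (baseline hazard
  0.05 per time unit, censor rate 0.02).

All generators are seed-deterministic to the byte. What passing tests
show: the implementation applies its stated rules exactly, recovers
planted structure at the stated signal-to-noise, and is calibrated
under its nulls. What they do not show: robustness to features real
data has and the generator lacks — sequencing error, adapter artifacts,
expression-dependent dispersion, correlated miRNA co-expression beyond
the planted blocks, non-exponential hazards, and informative censoring.

## Problem sizes and runtime choices

Test and acceptance runs use 10 samples × 10,000 reads for quantifier
recovery, 30 samples for planted-k consensus (reps = 100), 184–200
samples for cohort analyses, and 1000 replicates for null calibration;
the demo pipeline runs 4 × 20,000 reads with reps = 200 consensus.
These sizes keep the full suite in the minutes range while leaving
every rule exercised at its boundary (deviation 4 vs 5, median ties,
k = 2 vs 3 selection, and so on).

## Known limitations

* The default DE statistic ignores count-level dispersion; very low
  counts are better served by substituting a count-model test.
* Multi-mapper rescue requires *identical* mature sequences; paralogs
  differing by one base are all-or-nothing discarded.
* The delta-area k selection inherits the known weakness of consensus
  clustering on unstructured data; the area floor mitigates but does
  not remove it, which is why selection is advisory.
* The unassignment threshold (0.1) and the consensus thresholds are
  conventions exposed in configuration, not estimated quantities.
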