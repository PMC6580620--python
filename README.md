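# mirtyper

Small RNA sequencing can recover the intrinsic molecular subtypes of
breast tumors from mature-miRNA expression alone. `mirtyper` implements
that analysis end to end as a tested Python library plus a set of
numbered analysis drivers: mature-miRNA quantification from genomic
alignments, cross-annotation-version isoform remapping, log2-CPM
normalization, subtype signature construction by differential
expression, consensus clustering, reference-centered nearest-centroid
subtype classification, and median-split survival stratification. A
first-class synthetic-data module generates inputs with known ground
truth for every stage, so the whole pipeline is exercised and verified
without any external downloads.

It is written for computational biologists who want the counting and
classification rules of a miRNA subtyping study as importable,
inspectable functions rather than an opaque in-house script.

## Methods at the core

**Read assignment.** A read's aligned reference span, after trimming
terminal mismatching bases (which typically represent non-templated 3'
additions, not genomic position), is compared to each annotated mature
locus on the same strand. The read is assigned when the total end
deviation |Δstart| + |Δend| ≤ 4 nt. Multi-mapping reads are discarded
*unless* every alignment hits an annotated mature locus and all matched
matures share one identical mature sequence (true paralogs, e.g. the
let-7a loci); such reads are counted once. Each read contributes at most
one count.

**Normalization.** log2-CPM with a library-scaled pseudo-count:
`value = log2((c + p_j) / (N_j + 2 p_j) * 1e6)` with
`p_j = 0.25 * N_j / mean(N)`, matching the standard count-package
implementation of this transform.

**Signature.** One-vs-rest and all pairwise subtype contrasts (pluggable
test statistic; two-sided rank-sum by default), Benjamini–Hochberg FDR
control at 0.01, and the union of each contrast's top-15 miRNAs.

**Clustering.** Monti consensus clustering (subsample 80 % of samples,
average linkage on 1 − Pearson correlation, 2…6 clusters); k is chosen
from the relative delta-area of the consensus CDF. Heatmap views use
row standardization with Euclidean/Ward (ward.D2) clustering.

**Subtyping.** Gene-centering against a fixed reference cohort (test
samples never influence the centering), then Spearman correlation to
each subtype centroid; samples whose best correlation stays below 0.1
are left unassigned.

**Survival.** Per-stratum median split of an expression score — e.g.
the mean of the miR-99a/let-7c/miR-125b cluster arms — compared by
Kaplan–Meier curves and the log-rank test, with optional clinical
subgroup filters.

## Worked example

Run the numbered drivers from the repository root:

```bash
for s in analysis/0*.py; do python "$s"; done
```

Tables land under `results/`, bulky intermediates (SAM files, figures)
under `scratch/`. A run prints, among other lines:

```
wrote annotation with 20 matures (2 paralog groups, 1 decoy pair) and 4 x 20000 reads to scratch/reads/
signature: 60 unique miRNAs; 60/60 planted markers recovered
selected k=4; subtype enrichment chi2=552.0 (df=9, p=4.15e-113)
ward cut: 5 miRNA clusters, 4 sample clusters
164/184 samples assigned; accuracy among assigned: 100.0%
stratum  n      chi2        p
  Basal 49  0.783619 0.376037
   Her2 42  0.478867 0.488936
   LumA 40 18.153894 0.000020
   LumB 53  0.958180 0.327646
```

Reading: the simulated 184-sample cohort carries 15 planted marker
miRNAs per subtype; all 60 are recovered in the differential-expression
signature; consensus clustering on the signature picks k = 4 groups that
align almost perfectly with the true subtypes (the χ² line); and the
survival stage recovers the protective high-expression effect that was
planted in the Luminal-A-like stratum only — its log-rank p is 2 × 10⁻⁵
while the other strata stay null.

The full pipeline can also be driven from one YAML config:

```python
from mirtyper.pipeline import run_all
run_all({"seed": 7, "outdir": "runs/demo",
         "reads": {"min_reads": 1000}})   # writes a hashed manifest
```

Re-running with the same config reproduces every output hash.

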