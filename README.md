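# polyte

Non-reference transposable-element (TE) insertion calling from short-read
alignments, and cross-ploidy population-genetic analysis of the resulting
insertion landscape — built for diploid/autotetraploid plant cohorts where
the question is whether TE over-accumulation after whole-genome duplication
comes from **relaxed purifying selection** (polysomic masking of recessive
deleterious insertions) or from **transposition bursts**.

The package is aimed at population genomicists working with resequencing
cohorts aligned to a close-relative reference. It ships a fully synthetic
data generator (genome, cohort, reads, expression) with known ground truth,
so every stage of the analysis is testable offline.

## What it computes

**Detection.** Split reads (soft-clip ≥ 20 bp) and discordant pairs are
extracted per individual, clipped portions / unmapped mates are assigned to
a TE family against a library (identity ≥ 0.9 over ≥ 15 bp), anchors are
clustered into candidate sites (100-bp window), and sites are intersected
across individuals. A site is retained when at least one individual has
≥ 3 supporting reads including ≥ 1 upstream and ≥ 1 downstream junction
read. Every individual at every retained site is then scored:

- **carrier** if it meets the support rule itself;
- **non-carrier** if its *negative coverage* (minimum depth over the two
  site boundaries) lies in [5, 100];
- **NA** otherwise (too little or suspiciously much coverage).

Sites with too many NA individuals in both ploidy groups are dropped as
non-informative. Zygosity is never inferred: a carrier holds 1..ploidy
copies.

**Landscape.** Carrier frequency f = carriers / non-NA individuals per
site; LF/HF classes from the 10th/90th percentiles of the diploid spectrum
(applied unchanged to tetraploids); genomic categories with priority
3'UTR > 5'UTR > exon > intron > upstream&lt;250 bp > downstream&lt;250 bp >
near-gene&lt;2 kb > intergenic, the closest gene deciding orientation;
arm/pericentromere fractions; 100-kb densities with a LOWESS smooth.

**Population statistics.** Under Hardy–Weinberg with random (tetrasomic)
segregation, carrier and allele frequency relate by

    (1 − p)^k = 1 − f        (k = ploidy)

so f = 12.2% in diploids corresponds to p = 6.3%, and the same carrier
frequency in tetraploids to p ≈ 3.2% — most carriers are heterozygous
(diploids) or simplex (tetraploids). On top of this: 2×2 χ² proportion
tests; stepwise multiple linear models of per-individual TE content
(haplo-coverage = depth/ploidy, ploidy, insertion category; terms added or
removed by F-tests on the change in residual sum of squares); content
comparisons over repeated 100-individual subsamples with t-tests; and a
per-family burst test (families with > 10 non-reference copies per ploidy
group; χ² of high-frequency non-genic proportions between ploidies).

**Clades and expression.** Clade-specific (private/shared) insertion
classes, locally-high-frequency (HF3: ≥ 3 carriers in one clade) contrasts
by genomic compartment, hypergeometric gene-class enrichment, and
carrier/non-carrier (C/NC) population expression ratios with KS tests
against random-relabeling and intergenic nulls.

**Targeted locus genotyping.** Presence/absence of one known insertion
allele from reads against two references (with/without the insertion):
carrier on ≥ 1 read bridging an insertion extremity by ≥ 20 bp on both
sides; non-carrier on ≥ 4 reads spanning the target-site duplication;
NA otherwise.

## Worked example

```python
from polyte import simdata, detect
from polyte.annotation import CategoryMap
from polyte.config import SimConfig

cfg = SimConfig(seed=11, coverage_range=(8.0, 8.0))   # 2 x 10 Mb, 20+20
sequences, annotation = simdata.simulate_genome(cfg)
truth = simdata.simulate_population(cfg, annotation, CategoryMap(annotation))
paths, _log = simdata.simulate_reads(truth, sequences, cfg, "bams/")
res = detect.detect_pipeline(paths, truth.te_library, truth.samples)
print(len(res["sites"]), "informative sites")
m = detect.match_to_truth(res["sites"], truth.insertions)
print("false discoveries:", int(m["truth_id"].isna().sum()))
```

prints

```
61 informative sites
false discoveries: 0
```

i.e. of the 200 planted insertions, those leaving enough junction evidence
at 8X (73 at this seed) are all recovered at the support stage, none of
the calls is spurious, and 61 sites survive the missingness QC in this
small cohort. The same computation (at the seed passed on the command
line) is reproduced end to end by the acceptance script below.

The whole pipeline (simulate → detect → landscape → stats → clades →
expression) also runs from the shell:

```bash
polyte run --seed 11 --out run_dir/
polyte detect --bam-dir bams/ --te-library te.fa --samples samples.tsv --out calls/
```

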