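# Methods

This note documents the models, defaults and numerical choices behind
`polyte`, and what the synthetic validation does and does not establish
about real data.

## Insertion model and detection

A non-reference TE insertion at reference position P with target-site
duplication (TSD) of t bp turns the haplotype into
`ref[:P+t] + TE + ref[P:]`: the t bases at the target site appear on both
sides of the element. Reads crossing the upstream junction align up to
P+t and carry the element's 5' terminus as a 3' soft clip; reads crossing
the downstream junction carry the 3' terminus as a 5' clip and align from
P. Fragments whose mate falls inside the element yield a mapped read with
an unmapped mate; the mate sequence identifies the family.

Caller thresholds (all exposed as `DetectParams` / CLI flags):

| parameter | default | role |
|---|---|---|
| `min_clip` | 20 bp | minimum soft-clip to treat a read as split |
| `min_identity` / `min_match` | 0.9 / 15 bp | family assignment of the clip or mate against the library (exact substring fast path, edlib infix alignment otherwise, both strands; equal-best hits go to the first library entry and are flagged ambiguous) |
| `cluster_window` | 100 bp | same-family anchor clustering, per individual and across individuals |
| `discordant_window` | 500 bp | attribution of discordant anchors (the mapped mate's position, up to ~insert size from the junction) to the nearest same-family split site; discordant-only clusters are dropped since they can never satisfy the up+down rule |
| `min_support` | 3 reads | site retention: some individual has ≥ 3 supporting reads including ≥ 1 up and ≥ 1 down |
| `neg_cov_min..max` | 5..100 | non-carrier band of negative coverage; boundaries inclusive ("less than five" and "more than 100" read literally) |
| `na_max_2x/4x` | ceil(0.1 × group) | per-ploidy NA limits of the informativeness QC; both groups must exceed their limit (`na_rule="and"`, a flag switches to "or") |

Negative coverage is the minimum of the per-base depths at the two site
boundary positions (one base each, all aligned reads counted). Site
intervals span [min anchor, max anchor + 1), i.e. [P, P+t+1) for a clean
TSD; classification and arm assignment use the interval start / midpoint
respectively, indistinguishable at landscape scale.

Two properties matter for interpreting the outputs. First, a *carrier*
call requires the individual itself to meet the support rule, so at
moderate depth a true carrier with thin junction coverage is scored N or
NA — the state matrix is conservative for carriers and exact for
non-carriers (with error-free reads, no called carrier is ever truly
dosage 0). Second, the NA-informativeness QC removes sites for
cross-individual missingness, not for lack of evidence; detection
sensitivity is therefore a property of the support-filtered list
(`sites_support` in the pipeline result), which is how the package reports
recall, while false-discovery is measured on the final informative list.
At a 20-per-ploidy cohort with uniform 8X depth, the per-cell NA
probability is ~0.10–0.13 (Poisson depth below 5), so the QC removes
roughly 15% of perfectly detected sites; this is the same trade-off the
rule makes at full cohort size, scaled by ceil(0.1 × group).

## Hardy–Weinberg dosage math

With random chromosome segregation, dosage is Binomial(k, p) at ploidy k,
so the carrier fraction is f = 1 − (1−p)^k and p = 1 − (1−f)^(1/k)
(exact inversion; machine-precision round trip is a tested invariant).
The carrier-conditional minimal-dosage fraction
C(k,1)p(1−p)^{k−1} / (1 − (1−p)^k) → 1 as p → 0 and decreases
monotonically — at f = 12.2% that is ~96.8% heterozygotes in diploids and
~95.2% simplex carriers in tetraploids by per-frequency enumeration.
Averages over an empirical frequency spectrum are slightly higher because
the spectrum concentrates below its upper bound; `hw_convert` provides the
per-frequency enumeration and the caller can average it over any spectrum.

## Stepwise content models

Per-individual TE content (counts of carried insertions by category group
non-genic / introns+UTRs / exonic and frequency class) is modeled by OLS
with bidirectional stepwise selection: at each round the candidate term
with the smallest F-test p-value for the change in residual sum of squares
enters if p < α_in (0.05), then the included term with the largest such
p-value leaves if p > α_out (0.10), under strict model hierarchy
(interactions only with their margins present; no term leaves while a
superset interaction remains). With α_in = α_out = 1 the procedure
reproduces the full OLS fit exactly (tested to 1e−8). α defaults are the
classical values; the selection trace is logged for audit. Note that with
m candidate terms the forward step's family-wise type-I error exceeds the
per-test α (min of m p-values); the calibration test therefore measures
the single-candidate rate.

Subsampled content comparisons draw n individuals per ploidy without
replacement (100 of each at full scale; scaled down with a warning when
the cohort is smaller), count distinct insertions present per stratum, and
compare ploidies with Welch t-tests across repetitions. When a stratum's
presence probability saturates (high-frequency sites in modest subsample
sizes) the across-repetition variance collapses and the t-test degenerates;
cross-ploidy conclusions for such strata should rest on the relative count
difference, which is how the direction-recovery checks are phrased.

The burst test restricts to families with strictly more than 10
non-reference copies present in each ploidy group and computes per family
a 2×2 χ² (1 df, no continuity correction) of high-frequency vs other
non-genic insertions between ploidies. Raw p-values are reported (a
Benjamini–Hochberg column is optional), mirroring per-family reporting
practice; on 1000 null families the flag rate at p < 0.05 is ~4–5%,
slightly conservative from χ² discreteness at these counts.

## Synthetic cohort

The generator emulates a resequenced diploid/autotetraploid plant cohort:

- **Genome**: 2 chromosomes × 10 Mb by default, centromere at the
  midpoint, "pericentromere" = ±1 Mb (the 5-Mb arm rule of full-size
  genomes is a parameter, scaled accordingly in synthetic runs). Genes
  (5'UTR–exon/intron–3'UTR, strand random) concentrate on arms at a 10:1
  arm:pericentromere density ratio; annotated reference TEs concentrate
  pericentromerically at 1:10.
- **Cohort**: 20 diploids + 20 tetraploids by default (two clades per
  ploidy, two populations per clade); per-individual depth drawn from a
  scaled Beta over 2.8–18.1X with mean ≈ 8.4X, the regime of low-coverage
  population resequencing. Statistics-level analyses use a 100+100 cohort
  at truth-dosage level (no reads), since the cross-ploidy statistics do
  not require alignments.
- **Insertions**: 8 superfamilies; "type A" (Copia, Gypsy, CACTA, hAT)
  with genic insertion preference, "type B" (LINE, Mariner, MuDR,
  Harbinger) exon-depleted, via per-superfamily category weight vectors.
  Positions are sampled from the actual annotated compartments through the
  same category map the classifier uses, so generator labels and
  classifier output agree exactly by construction. TSD 5 bp by default
  (per-superfamily override). Base carrier frequencies are Beta(0.4, 8)
  distributed — no generative spectrum is implied by the data, this is a
  modeling choice giving a rare-skewed spectrum with ~10th/90th
  percentiles near 1%/15% at cohort scale.
- **Selection modes**: `neutral` (equal f in both ploidies); `purifying`
  (young genic insertions purged or frequency-reduced in both ploidies);
  `relaxed_in_4x` (the default study condition: young genic insertions are
  purged in diploids — completely with probability 0.35 for exonic /
  0.15 other genic, else reduced to 0.7× — but retained in tetraploids).
  "Young" means below 10% carrier frequency: variants above that are
  treated as predating the ploidy split and left symmetric, which is why
  high-frequency content stays similar between ploidies while the
  low-frequency exonic excess accumulates in 4x. The magnitudes are free
  parameters documented here, not measured quantities. `burst_family`
  optionally plants a family-specific burst (non-genic insertions of one
  family at high frequency in 4x only).
- **Dosages**: Binomial(ploidy, p) with p converted from the
  ploidy-specific carrier frequency — the spectra, not the allele
  frequencies, are matched across ploidies, mirroring carrier-frequency-
  based cross-ploidy comparison.
- **Reads**: error-free by default (an optional uniform substitution rate
  exists); fragment length Normal(300, 30), 100-bp pairs, per-haplotype
  Poisson fragment counts so depth is flat on both haplotypes. The default
  `focused` mode generates pairs only within 1 kb of planted insertions:
  with error-free reads, fragments far from any insertion cannot produce
  split or discordant evidence and only add I/O, and negative coverage at
  retained sites lies inside the windows; `genome` mode covers whole
  chromosomes. Fragments are attributed to the nearest insertion, valid
  because the minimum insertion spacing (800 bp) exceeds the fragment
  span.
- **Expression**: log-normal per-gene baselines, per-individual log-normal
  noise (σ = 0.3), and a multiplicative cis effect (default 0.5) on genes
  whose carried nearest insertion is within the gene or < 250 bp away;
  insertions ≥ 2 kb away have no effect (the 250 bp–2 kb band is left
  neutral). Population-level C/NC ratios are diluted toward 1 by
  non-carrier members of carrier populations — with ~3-member populations
  the planted 0.5 effect appears as a median ratio ~0.8, which is the
  correct behavior of the population-mean estimator, not a loss of signal.

All randomness derives from one master seed through named sub-streams
(genome / library / population / per-individual reads / expression), so a
seed + config pair reproduces byte-identical outputs, including BAMs.

**What passing tests do not show about real data**: reads are error-free
and uniquely placed, so the family-assignment identity threshold, mapping
ambiguity in repeats, reference-TE polymorphism and coverage biases are
unexercised; detection performance on real alignments will be lower and
parameter-sensitive. The generator also plants no insertions inside
annotated reference TEs and simulates no solo-LTR recombination.

## Numerical choices and conventions

- Coordinates: 0-based half-open internally; GFF3 emitted 1-based
  inclusive, BED 0-based half-open; TSVs are tab-separated with a
  '#'-prefixed header.
- Percentiles: linear interpolation between order statistics
  (`np.percentile` default); a degenerate spectrum (equal thresholds) is
  an error.
- Gene distance: 0 inside genes, 1 for the first flanking base; at exact
  distance ties between two genes the upstream reading wins, matching the
  category priority order and making classification invariant under
  coordinate mirroring plus strand flip (a tested property).
- LOWESS: tricube weights, span 0.1, 1 robustness iteration — plotting
  only; statistics always use raw window counts.
- Gene-distance bootstraps resample the median (mean by flag), 1000 draws,
  minimum 100.
- χ² compartment contrasts are skipped (p = NaN) when an expected cell
  count falls below 1.
- The GO-style enrichment is a local hypergeometric upper-tail test
  against a user-supplied gene→class table with BH correction, plus an
  optional length-decile-matched resampling null (10,000 draws) for the
  gene-length confound.
- Locus genotyping: "bridging by ≥ 20 bp" requires 20 aligned bases on
  *both* sides of the extremity (the stricter reading); TSD bridging
  requires the full TSD plus one base on each side; alignment tolerance
  5% mismatches per read, both strands.

## Problem sizes

Desk-scale runs use: the 2 × 10 Mb / 20+20 / 200-insertion / 8X cohort for
read-level detection; 2 × 5 Mb / 100+100 / 1400 insertions at truth level
for the cross-ploidy statistics (enough exonic LF/HF sites for stable
direction estimates); 1000 synthetic families for the burst null; 100
seeds × 2 haplotypes at 10X for the locus genotyper. The full acceptance
recomputation takes ~1 minute on one CPU.

## Known limitations

- Breakpoints are resolved to the anchor cluster, not assembled to base
  precision; TE absences relative to the reference are out of scope, as is
  dosage/zygosity calling.
- The stepwise selection trace depends on tie-breaking only through
  floating-point p-value comparisons; with heavily collinear designs the
  selected set can differ across platforms even though the final fit at
  α = 1 is exact.
- `subsampled_content` treats repetitions as independent samples in the
  t-test, as is conventional for this design; the repetitions share the
  underlying cohort, so p-values are anti-conservative for strata near
  saturation (see above).
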