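# Methods

## Scan statistics

The scan compares two groups of diploid individuals at bi-allelic,
polymorphic SNPs. Internally all intervals are 0-based half-open; VCF
positions (1-based) are converted on read, and every output table states
its convention.

**Per-site Weir–Cockerham components.** For r = 2 groups with sample
sizes n_i (called diploid individuals at the site), alternate-allele
frequencies p_i and observed heterozygote fractions h_i, the variance
components a (between-population), b (between individuals within
populations) and c (within individuals) follow the 1984 estimator as
written in the `sweepscan.windows` docstring. Sites where either group
has fewer than two called individuals are unusable and skipped. A site
monomorphic in both groups contributes exact zeros. The window statistic
is the ratio of sums Σa / Σ(a+b+c) — the standard weighting, which is
robust to low-information sites. Negative window values are retained:
the Z-transform removes location and scale, and truncating at zero would
distort the permutation null.

**Windowed π.** Per-site π = 2·c_ref·c_alt / (n(n−1)) with n the called
allele count (n ≥ 2). Window π sums per-site π and divides by window
length in bp, not by the number of variant sites — the convention of the
common windowed-diversity tools, which makes |Δπ| comparable across
windows and insensitive to site density. Terminal windows truncated at
the chromosome end use their true length. A group with no usable site in
a window has window π = 0 (diversity absence is signal, not missing
data); windows with no sites at all carry no information and are dropped
from scoring.

**Window grid.** Windows start at multiples of the step while the start
is inside the chromosome, default 40 kb size / 20 kb step, final window
truncated at the chromosome end. Whether windows should instead extend
past the end is a free choice; truncation avoids phantom territory.

## Permutation null and Z-scores

The null reassigns per-site payload tuples (both groups' n, p, h and π
jointly) to the fixed SNP positions by a uniform genome-wide permutation.
Two interpretation choices deserve note:

- payloads are shuffled **jointly**, not per group independently, so each
  site's internal consistency (h and π are functions of its genotype
  counts) is preserved; only the spatial arrangement is destroyed, which
  is precisely the structure windowing detects;
- shuffling is **genome-wide** rather than within-chromosome, matching a
  single global null mean/SD per statistic.

K replicates (default 100; the test suite and the acceptance study use
K = 20, which already pools thousands of windows) are recomputed and all
scored windows of all replicates pooled; μ is the pooled mean and σ the
pooled sample SD (N−1). Because per-site components depend only on the
payload, the implementation permutes the precomputed component arrays,
making a replicate a pair of bincount aggregations — the null for a
50,000-site genome costs milliseconds per replicate. If σ = 0 (all
payloads identical) the scan aborts with a degenerate-null error.

Z-scores are the exact affine transforms of defined window statistics;
undefined statistics (e.g. F_ST in an all-monomorphic window) propagate
as undefined and are never counted as significant.

## Sweep calling

Cutoffs Z_FST > 6 and Z|Δπ| > 3.09 (strict: a window exactly at the
cutoff is not significant). 3.09 is the one-sided standard-normal 0.001
quantile; the F_ST cutoff is deliberately higher because the F_ST scan is
the more sensitive of the two. Significant windows overlapping by ≥ 1 bp
merge transitively into DSSs; abutting half-open intervals (end == start)
do not merge. The final prediction is the interval union of the two
per-statistic DSS sets, re-merged, with provenance flags (fst / dpi /
dpi+fst) and the cross-statistic overlap fractions reported. Each
comparison rebuilds its own null from its own site payloads.

## Hard filters and site selection

GATK-style removal thresholds, strict inequalities exactly as printed:
SNPs removed when QD < 2, FS > 60, MQ < 40, SOR > 3, MQRankSum < −12.5 or
ReadPosRankSum < −8; indels when QD < 2, FS > 200, SOR > 10,
InbreedingCoeff < −0.8 or ReadPosRankSum < −20. Boundary values are
kept. An absent INFO metric is not evaluable and never removes a site
(callers emit rank-sum metrics conditionally). Multi-allelic records are
excluded from the scan rather than decomposed, and sites monomorphic
across all groups pooled are dropped. Missing genotypes reduce the
per-group sample size at that site; no imputation.

## Synthetic cohorts

The generator emulates two (or more) diploid populations diverged by
drift. Per site, an ancestral frequency p ~ Uniform(0.05, 0.95) is drawn
and each group's frequency from the Balding–Nichols Beta distribution
with mean p and variance F·p(1−p); the default background F = 0.05 is a
typical between-breed divergence for livestock populations. Genotypes
are Binomial(2, p_i) per individual — Hardy–Weinberg within group, no
linkage, no inbreeding. A sweep interval redraws the target group's
frequencies with a higher drift parameter (default F_sweep = 0.6) and
pushes them toward the nearer boundary with strength s (default 0.9):
p' = p(1−s) below 0.5, p + s(1−p) above. This jointly produces the
elevated differentiation and reduced target-group diversity that real
sweeps show. Default cohort geometry: 25 diploids per group and a SNP
density of 0.005/bp, i.e. ~50,000 sites on the 10 Mb study chromosome.

What the generator does **not** emulate: linkage disequilibrium and
recombination structure (sites are independent, so LD-decay analyses on
simulated data decay within the first distance bin by construction),
demographic history, allele-frequency spectra shaped by mutation and
selection, sequencing error, or genotype-caller artifacts beyond the
single-metric INFO failures it plants (a configurable fraction of sites
receives exactly one filter-failing metric so the filtering path is
exercised). Consequently, passing tests demonstrate the statistical
machinery — estimator correctness, null calibration, recovery power at
the planted effect sizes — not robustness to LD-induced window
correlation or caller noise in real cohorts.

VCF emission is plain-text v4.2 with GT fields and constant passing INFO
values (QD=25, FS=1, MQ=60, SOR=1, rank sums 0, InbreedingCoeff=0);
reading is via cyvcf2, and the write/read round trip is covered by a
test.

## Annotation

Seven exclusive location categories with fixed precedence
coding > splicing > ncRNA > UTR5 > UTR3 > intronic > up/downstream >
intergenic, where up/downstream means within 1 kb of a transcript start
or end and splicing means the first or last 2 bp of an intron (hence
never in conflict with coding). Coding effects substitute the alternate
base into the reference codon, strand-aware with complementation, and
translate with the standard code (synonymous / nonsynonymous /
stop-gain / stop-loss); transcripts whose CDS length is not a multiple
of 3 are skipped with a warning. Gene models load from GFF3 (gffutils),
reference bases from FASTA (pyfaidx). QTLs are plain BED-like intervals
from any source; no database is bundled.

Group-specific SNPs: alternate allele present (p > 0) in the focal group
and absent among called alleles in every other group; nearly fixed means
p > 0.9, strict. Category enrichment is the ratio of a SNP set's
category fractions to genome composition fractions supplied by the user.

## Summaries

Mean π averages window π over windows with data. MAF spectra fold
frequencies to min(p, 1−p) and use three bins — rare < 0.005, low
[0.005, 0.01] (closed on both sides so the three thresholds partition
[0, 0.5]), common > 0.01 — normalised within SNP class. LD is composite
r²: the squared Pearson correlation of unphased dosages over individuals
called at both sites (phase is unavailable in the pipeline's inputs);
zero-variance pairs are excluded. The LD decay rate is the first
distance-bin midpoint at which mean r² ≤ 0.2 (bin width 100 bp, maximum
distance 300 kb by default), undefined if never reached.

## Problem sizes and determinism

The acceptance study and the heavier tests run 2 × 25 diploids on a
10 Mb chromosome (~50 k sites) with K = 20 permutation replicates and
three simulation seeds — enough windows (~1,500) to measure exceedance
rates at the 0.001–0.01 scale while keeping a full run to a few seconds.
Every stochastic component takes an explicit seed and is bit-reproducible
given it; dataset emission is byte-identical across calls.

## Known limitations

- The folded half-normal shape of the |Δπ| null means the Z > 3.09 rule
  has a true neutral exceedance near 0.008, not 0.001; the F_ST tail at
  Z > 6 is conservative. Both are properties of the published rule, not
  of this implementation.
- Overlapping windows are correlated by construction (adjacent windows
  share half their sites); exceedance fractions are unbiased but their
  sampling variance is roughly doubled.
- With r = 2 groups the estimator cannot distinguish b from c when
  heterozygosity data are degenerate; sites with n_i < 2 in either group
  are simply skipped.
- `ld_decay` is quadratic in sites within the maximum distance; it is
  meant for cohort-scale summaries, not genome-wide all-pairs scans.
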