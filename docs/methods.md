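# Methods

`gbstx` implements the post-alignment genotype-processing stages of
genotyping-by-sequencing through transcriptomics (GBS-t): SNP genotyping
from shallow mRNA sequencing aligned to a transcriptome reference.  The
package starts where the aligner/pileup caller stops — a VCF or a pair of
genotype/allele-count matrices — and ends with filtered genotype sets,
tetraploid dosage calls, and the validation analytics used to judge them.

## Data model

All stages operate on rectangular loci × samples matrices keyed by
`chrom:pos`: diploid genotypes coded as alternate-allele counts
{0, 1, 2}, tetraploid dosages {0..4}, and per-entry (ref, alt) read
counts.  Missing is `-1` internally and `NA` in the TSV dialect.
Positions are 1-based (VCF convention); phase is discarded; half-missing
VCF genotypes (`./1`) are treated as missing.  When a VCF carries no
per-sample allelic depths (`AD`), the allele-count matrix is missing
there and dosage calling refuses those loci rather than guessing from
total depth.

## Filter chain

The generic chain runs in a fixed order so that stage reports are
reproducible: per-entry low-support masking → sparse-sample removal →
locus missingness → MAF.  Thresholds (all configurable, defaults in
`FilterConfig`):

| parameter | default | meaning |
|---|---|---|
| `min_depth` | 5 reads | below this an entry is masked missing |
| `min_alt_reads` | 4 reads | alt-carrying entries need this much alternate support; site-level variant (`site_alt_support`) requires it summed over the locus column before a site counts as a SNP |
| `maf_threshold` | 0.02 | locus retained at MAF ≥ threshold (inclusive); 0.05 is the per-population convention |
| `max_missing` | 0.5 | locus removed when its missing fraction is strictly greater |
| `het_excess_threshold` | 0.4 | heterozygote proportion above which a locus is a homoeolog-misalignment artefact |
| `dosage_tolerance` | 0.05 | half-width of the dosage allele-frequency bins |

Comparison directions were fixed once: "MAF of x" retains inclusively,
"maximum missing" removes strictly above.  An all-missing locus is
removed at the missingness stage even when `max_missing = 1.0`, because
its MAF is undefined.

Population-aware mode retains a locus when MAF and missingness are
satisfied in *at least one* population — structured panels (e.g. spring
and winter growth types) otherwise lose loci fixed in one group and
polymorphic in another.  Per-group SNP lists are merged with
`consolidate_lists`, which drops loci whose alternate allele differs
between groups (tri-allelic across groups) and raises on reference-allele
conflicts.

## Inbred consensus and retention classes

Inbred panels genotyped as several seedlings per line are collapsed to a
per-line consensus (modal non-missing call; ties and all-missing →
missing, preferring determinism over coverage).  Loci are then classified
with a strict priority — both-homozygous > one-hom-plus-het (≥4
heterozygous consensus *lines*) > opposing-homs-within-line > rejected —
making the three retained classes disjoint and their counts additive.
Within-line heterogeneity is the heterozygote fraction of a line's
consensus calls; the panel summary is the unweighted mean over lines.

## Outbred segregation validation

F1 pseudo-testcross loci are tested for strict adherence to 1:1
(het × hom) or 1:2:1 (het × het) with a plain Pearson chi-square (no
continuity correction — immaterial at ~95 progeny and keeps the
enumeration oracle exact).  The applicable model is chosen from the
parental genotypes when not forced.  Default α = 0.001 per locus, no
multiple-testing correction (an optional Bonferroni is deliberately
omitted: "strict adherence" is a per-locus criterion); missing progeny
are excluded, not imputed.  Loci failing or absent in the family can be
rescued into the high-confidence set when the discovery panel calls them
in every sample with a homozygous class present.

## Tetraploid dosage calling

The alternate-read fraction of each entry (after the `min_depth` mask) is
binned around the expected dosage frequencies 0, ¼, ½, ¾, 1 with ±5%
inclusive edges; gap frequencies become missing.  A 1e-9 absolute guard
on the edge comparison prevents one-ulp float asymmetries (e.g.
|0.8 − 0.75| evaluating just above 0.05 while |0.2 − 0.25| does not).
Binning uses raw proportions with no error model by design — a
likelihood-based caller is a non-goal.  Loci are kept when ≥3 distinct
dosage classes segregate; inheritance is tetrasomic only when all five
classes are observed, disomic only for exactly {0, 2, 4}, ambiguous
otherwise (including four-class loci, on which the classification rules
are silent).

The misalignment filter for allotetraploids genotyped as diploids removes
loci whose heterozygote proportion exceeds 0.4 among non-missing calls,
locus-by-locus rather than gene-by-gene since homoeolog similarity varies
within a gene.  Known limitation: a published worked example shows a
retained SNP heterozygous in 44.7% of samples, which the stated >0.4 rule
would remove; the rule is applied uniformly here.

## Diversity and ASE analytics

Nei's (1972) standard distance D = −ln(Jxy/√(Jx·Jy)) is computed from
per-sample allele-frequency profiles (call/ploidy — dosage-aware for
tetraploids) with pairwise deletion of missing loci; zero identity maps
to +∞ and must be capped or dropped before tree building.
Population-level distances use population mean frequencies.
Neighbour-joining trees are built with the Saitou–Nei algorithm
(delegated to scikit-bio; negative branch estimates clamped to zero) and
serialized to Newick.

The ASE model: with major-allele expression fraction p and n independent
reads, both alleles are seen with probability 1 − pⁿ − (1−p)ⁿ.  This is
the ceiling on heterozygote detectability from mRNA and motivates depth
over breadth when expression imbalance is suspected.

## Synthetic data

The generators emit ground truth plus observations and are fully
determined by seed and parameters.  Defaults are the study conditions:
38 inbred lines × ≤5 seedlings with residual heterozygosity 0.0435
(F7/F8 single-seed descent), 95 F1 progeny, 285 tetraploid samples with
tetrasomic proportion 0.8.  Read sampling is Poisson depth × binomial
allele draws; an optional log-normal per-locus expression weight
(mean 1) reproduces the qualitative missingness-vs-yield decay of
transcriptome genotyping; no per-read error by default (the filters under
test target depth and misalignment, not base noise), with an optional
`error_rate` for robustness checks.

Tetraploid locus allele frequencies default to U(0.4, 0.6).  This models
the loci the binning caller can actually genotype: under tetrasomic
Hardy–Weinberg at p = 0.3 the dosage-4 class is absent from a 100-sample
panel with probability ≈ 0.44, so extreme-frequency loci rarely display
all five classes and would not enter the reliably-called set; requiring
intermediate frequencies matches the ≥3-class retention rule's selection
effect.  The range is configurable (`alt_freq_range`).

What the simulations do *not* emulate: sequencing error profiles, mapping
ambiguity, reference bias, linkage between loci, and real expression
heterogeneity across genes.  Passing tests therefore demonstrate the
correctness of the decision rules under their stated assumptions, not
end-to-end accuracy on real libraries.

## Problem sizes and numerical choices

Test and acceptance simulations run at desk scale chosen to make the
statistical checks sharp yet quick: 1000 loci × 100 samples at depth
1000 for dosage recovery (binomial frequency concentration makes ≥99%
call accuracy provable by a normal bound and verified by simulation),
1000 loci × 95 progeny for segregation calibration, 50 random additive
5-taxon trees against a brute-force 15-topology oracle.  Acceptance-style
statistical bands are 95% binomial bands around the nominal value;
internal property tests use 3–4σ bands to keep false alarms rare.
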