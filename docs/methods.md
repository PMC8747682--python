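# Methods

This note documents the models, rules and numerical choices behind
`somavar`, and what the synthetic study does and does not establish
about real data.

## Variant QC

Filtering operates at the VCF level on one sample at a time. A call is
retained iff all of the following hold, evaluated in a fixed order so
rejection logs are deterministic:

1. **quality** — site quality Q ≥ 30 and mapping quality q ≥ 30. Q is
   the record's QUAL field and q its MQ annotation; per-read base
   qualities are not recoverable from a VCF, so the thresholds apply at
   the record level.
2. **allelicity** — at most two distinct alleles at the site
   (reference + one alternate).
3. **SNV** — reference and alternate both single bases; indels are
   excluded.
4. **depth** — heterozygous (Ht) calls need *more than* five reads per
   allele (i.e. ≥ 6: the contrast between "> 5" for Ht and "≥ 5" for Ho
   is taken as intended); homozygous (Ho) calls need total depth ≥ 5.

A call missing a required field rejects with rule `missing-field` at
the step that needs the field. Homozygous-reference (0/0) records are
not variants and are dropped silently. Allele depths are per allele
summed over strands; whether the original depth rule was applied per
strand is not determinable from a VCF with plain AD fields, so the
per-allele interpretation is used.

## Cross-sample classification

Two calls are the same variant iff (chromosome, position, ref, alt) all
match; the same position with a different alternate allele is a
different variant. Genotype class does not enter the key. With *n*
samples, "shared" means present in all *n* and "de novo" means present
in 1..*n*−1 — with three pools this is exactly the conservative rule
that treats triple-shared SNPs as standing heterogeneity of the donor
rather than culture-induced mutation (at the cost of underestimating
mutations that swept the callus before regeneration). The identity
de novo = union − shared-by-all then holds by construction, overall and
within every region category.

## Effect annotation

Placement is by interval containment: inside a CDS segment → CDS;
inside a gene span but no CDS segment → genic (introns/UTR-like);
otherwise intergenic. Overlapping genes each receive an effect call;
per-gene summaries count the variant in every overlapping gene, while
variant-level category counts (diversity report) count it once.

For CDS variants the transcript coordinate is the offset along the
concatenation of CDS segments in translation order (descending genomic
coordinate on the minus strand), codons are read at in-frame offsets —
codons split across segment boundaries are assembled in transcript
order before substitution — the alternate base is complemented on the
minus strand, and both codons are translated with the standard nuclear
code. Ss iff the residue is unchanged; a change to or from a stop is
Sn. Each SNP is evaluated independently against the reference codon;
two SNPs hitting the same codon are not combined (a deliberate,
documented divergence from annotators that report compound effects).
A ref allele that disagrees with the FASTA is an error, not a warning:
it means the inputs belong to different references.

## Diversity statistics

A region category is a gene set plus a length: the whole genome (sum of
chromosome lengths) or the merged union of member gene spans, introns
included. Gene-span lengths (not CDS-only) are used because genic
heterozygote counts include non-CDS variants and the published genic
length (~9.5% of the genome) is consistent with whole spans. A variant
counts toward a category at most once even if it lies in several member
genes.

Ht/Kb is rounded **half-up** to 2 decimals — verified to reproduce all
twenty per-Kb cells of the published genome-scale table from its
printed counts and lengths. Per-Mb Ss/Sn rates are reported to 3
significant figures; because the published region lengths are
themselves rounded (3.20 × 10⁸ etc.), re-derived per-Mb rates can
differ from printed ones in the last digit and are only asserted to
±1%.

## Mutation spectrum

Windows are half-open [k·w, (k+1)·w) internally and reported 1-based
inclusive; the default w is 1% of the chromosome with a 10 kb floor;
the last, short window uses its true width for density. No published
definition of a "mutation cluster" exists, so the package uses a
simple deterministic rule: a window qualifies when its density exceeds
mean + k·SD (k = 2 default, population SD) of **that chromosome's**
window densities — per-chromosome backgrounds because mutation load
differs between chromosomes — and adjacent qualifying windows merge. A
constant track has SD 0 and yields no clusters. Doubling w merges
counts exactly pairwise, a property the tests pin down.

Centromere positions are not modeled; the distal-vs-interstitial
summary uses relative position bands (outer 25% of each arm vs middle
50%) as a proxy, reporting band densities, their ratio and a two-sided
Mann–Whitney comparison without asserting a direction.

## Expression association

Per-gene expression is the mean across samples (the source data plot
per-gene levels without specifying an aggregation). Comparisons are
two-sided Wilcoxon–Mann–Whitney — chosen because expression is not
assumed normal and the published comparison is distributional — with
rank-biserial effect size r = 2U/(n₁n₂) − 1 and Holm adjustment across
the three pairwise tests of the three-way grouping. An empty group
skips its comparison with a warning. Rank statistics are invariant
under strictly increasing transforms of expression, which the tests
verify.

## Synthetic study generator

The generator emulates the three-pool study design, treating each pool
of regenerated plantlets as one diploid-like call set (matching how
the published counts are tabulated per sample column; within-pool
allele frequencies are not modeled and no sub-pool deconvolution is
attempted).

Defaults (all configurable): 4 chromosomes × 500 kb with uniform
A/C/G/T composition; 200 genes with Poisson(3) CDS segments of 60–300
bp, total CDS length padded to a multiple of 3 (individual segments
deliberately not codon-aligned, so split codons occur), 15% of genes
tagged totipotency and 20% chromosome-stability; 1,000 shared variants
and (1,000, 600, 2,000) de novo calls per sample — per-sample loads in
roughly the published 1.8 : 1 : 3.4 proportion at toy scale — of which
10% of de novo keys are pairwise-shared (present in exactly 2 of 3
pools); 90% Ht genotypes; allele depths Poisson around 30, resampled
until QC-passing so truth labels stay exact; 2 hotspot windows per
chromosome at 10× background per-bp density (hotspot windows sit on
the same grid as the default analysis window so recovery is
well-defined); expression log-normal with σ = 0.5, log-mean 2.0,
shifted +0.5 for mutated genes and a further +0.25 for genes carrying a
non-synonymous variant, producing the Sn > Ss-only > wild-type
ordering the analysis is meant to detect. Planted truth effects are
computed by mutating the genome sequence and comparing whole translated
proteins — an independent path from the annotator's codon-local rule,
which is what makes the oracle-equivalence tests meaningful.

QC-failure injection flags a stated fraction of planted variant keys
and rewrites every member sample's record to violate exactly one rule
(low quality, third allele, indel, Ht allele depth ≤ 5, or Ho depth
< 5), recording the rule; positions are unique genome-wide so
(chromosome, position) identifies the planted key even when alleles
were rewritten.

The study is a deterministic function of the config: identical seeds
give byte-identical files.

### What the synthetic study does not show

Uniform base composition, uniform variant placement (outside
hotspots), non-overlapping genes, exact Poisson depths, no genotyping
error, no missing data, and pools treated as single diploid call sets
— none of these hold in real resequencing data. Passing the recovery
tests shows the *logic* of the pipeline is correct (set algebra,
coordinate arithmetic, codon handling, rule order), not that the QC
thresholds are well-calibrated for any particular sequencing depth or
that cluster calls on real data are biologically meaningful.

## Problem sizes

The default study (2 Mb genome, ~4,300 variants) keeps a full pipeline
run under two seconds and the whole test suite under a minute; hotspot
and oracle checks use purpose-built configurations (10,000 variants for
enrichment ratios, ≥ 1,000 random CDS SNPs for annotator equivalence,
100 replicates for expression power). These sizes were chosen so
sampling error stays well inside the asserted bounds while the suite
remains quick to run; everything scales upward through
`SimulationConfig`.

## Known limitations

- The annotator handles biallelic SNVs only; the QC stage guarantees
  that upstream, but feeding unfiltered variants to `annotate` directly
  will reject indels via the ref-mismatch/length checks rather than
  annotate them.
- Cluster calling has no significance model beyond the z-rule; with
  strong hotspots the background SD is inflated by the hotspots
  themselves, which is conservative.
- GO-term enrichment of mutated genes and subgenome/homeolog contrasts
  are out of scope (they depend on external databases or are
  descriptive only).
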