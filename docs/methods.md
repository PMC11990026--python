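# Methods

## Scope and data model

`haplomerge` operates strictly downstream of variant calling and
read-based phasing. Its inputs are phased VCFs (diploid GT with `/` or
`|`, optional PS phase-set tag, QUAL, DP) as produced by a
bcftools-call + WhatsHap pathway, one call set per sample per
platform. Upstream concerns — read filtering, alignment, genotype
likelihoods, indel left-alignment, the phasing algorithm itself — are
out of scope; the package assumes caller-normalized input and performs
only case-folding and multi-allelic splitting when building site keys.
Site identity is (contig, position, ref, alt) after splitting, so two
platforms reporting different alt alleles at one position yield two
platform-only records rather than one discrepant record; such
positions are visible in the merged table and left to reviewer
judgment.

In a multi-allelic split, each alt allele becomes its own biallelic
call and any genotype index other than that alt's original index is
recoded to 0. This preserves presence/absence of each alt, which is
the property the concordance classifier consumes; it deliberately
discards which *other* allele occupied the second haplotype.

## Concordance classification

Per (sample, site) reported by at least one platform:
both present with equal unordered genotypes → AGREE; both present,
genotypes differ → DISCREPANT; otherwise ILLUMINA_ONLY or ONT_ONLY.
Unordered comparison is used because haplotype order within a phase
set is arbitrary — `0|1` and `1|0` describe the same genotype.
Hom-ref (`0/0`) and missing (`./.`) genotypes count as "not reported":
variant-only VCFs omit non-variant sites, so presence of a record is
the only evidence of a reported variant, and absence is never imputed
as reference. Overall frequencies use all merged records — the
(sample, site) union — as denominator; per-position and per-sample
aggregations are also produced. No automatic reconciliation of
discrepancies is attempted or offered.

## Target windows

From one transcript's gene model (GFF3 via gffutils, or BED12 block
arithmetic), three nested window sets are built with two flank
parameters (defaults: 50 bp intronic, 200 bp noncoding):

* **CDS**: every coding interval ± the intronic flank. The flank is
  applied uniformly at both ends of every CDS interval, including the
  UTR-facing ends of the first and last interval — no separate rule is
  defined for those two boundaries, and uniform extension is the
  simplest defensible choice.
* **exons-plus**: every exon extended by the intronic flank at
  intron-facing boundaries; at the two gene-terminal boundaries the
  200 bp noncoding flank *replaces* the intronic flank (it is anchored
  at the gene ends, not added on top).
* **complete gene**: the gene span ± the noncoding flank.

All public coordinates are 1-based inclusive (VCF/GFF3 convention);
BED export converts to 0-based half-open on write. Windows are merged
(bookended intervals coalesce) and clipped at position 1. With
CDS ⊆ exons and intronic ≤ noncoding flank, the three definitions are
nested, and the test suite checks this against base-by-base
enumeration.

## Quality filtering

Two thresholds, both optional: minimum QUAL and minimum DP. A call
lacking DP fails a configured depth threshold — unknown depth cannot
certify the minimum — and this is the documented, conservative
behavior rather than an accident of implementation.

## Per-site statistics

With genotype counts (n_RR, n_RA, n_AA), n = their sum and alt
frequency q = (2·n_AA + n_RA)/2n, the Hardy–Weinberg test compares
observed counts to n(1−q)², 2nq(1−q), nq² with the classical 1-df χ²
statistic; p-values come from `scipy.stats.chi2.sf`. No continuity
correction and no exact test are applied (an exact-test variant would
be a natural extension for rare alleles, where the χ² approximation is
weakest). Monomorphic sites (q ∈ {0, 1}) are reported as such with NA
statistics. P-values are raw: no multiple-testing correction is
applied across sites, and users scanning many positions should correct
on their side.

The reference-frequency comparison is a 1-df χ² on the 2n allele
observations against expected counts 2n·f and 2n·(1−f) for a supplied
frequency f ∈ (0, 1), significant at p < 0.05 by default. Reference
frequencies are user-supplied via TSV; nothing is fetched from the
network.

Two cohort denominators are supported because amplicon designs cover
every target base in every sample: `amplicon_complete` counts samples
without a call as hom-ref (requires the cohort size), `called_only`
(the default) excludes them. Both are exposed; the choice is the
user's statement about their assay, not something the package infers.

## Haplotype assembly

Phase blocks are read directly off GT/PS: phased heterozygous calls
group by PS; haplotype A is the first allele of each ordered genotype,
haplotype B the second, so column j of (hap_a, hap_b) reproduces the
ordered genotype of site j (a tested invariant). Homozygous-alt calls
join every block with identical alleles on both haplotypes. Unphased
heterozygous calls join no block; a phased het lacking PS is an error
when other phase sets exist, and a single implicit block otherwise.

*Percent phased* = 100 × phased het calls / het calls. Homozygous
genotypes carry no phase information and are excluded from the
denominator; a call set with no heterozygous calls reports 100% with
an explicit vacuous flag. The denominator choice is switchable in the
sense that callers can compute any ratio from the returned counts.

A sample's diplotype for a region is complete iff every heterozygous
site lies in one phase block. Incomplete samples (unphased hets, or
hets split across blocks) carry their largest block's haplotypes,
flagged, and are excluded from cohort frequency tables with the
exclusion count disclosed — concatenating blocks would assert phase
the reads never established. Haplotypes are labelled by their carried
alt alleles (`pos REF>ALT` joined, `REF` for none) and can be rendered
as sequence strings against a reference, applying variants
right-to-left so earlier coordinates stay valid. Frequency tables sort
by descending count with lexicographic tie-break; haplotype-level
counts sum to twice the complete samples, diplotype-level counts to
the complete samples.

## Synthetic cohorts

The simulator works at the call level: the analyzer consumes VCFs, so
corrupting call sets exercises everything in scope without read-level
simulation machinery. Truth diplotypes are two independent
Bernoulli(q) draws per sample and site — Hardy–Weinberg proportions by
construction, with phase known. Per platform, each non-hom-ref truth
genotype is dropped with `missed_call_rate`, an emitted genotype is
toggled het↔hom-alt with `genotype_error_rate` (errors never fabricate
hom-ref emissions, keeping the model identifiable from concordance
counts; spurious-site emission exists as a separate rate, default 0),
and each emitted het is phased — truth order, one shared PS per
amplicon — with `phased_rate`. QUAL and DP are normal draws floored at
0 and 1; QUAL is rounded to two decimals so written VCFs round-trip
exactly.

Defaults describe the emulated study design: 400 samples; ten sites
per ~10 kb amplicon (about one naturally occurring SNV per kilobase);
ONT QUAL 165.5 ± 52.7 and DP 690.5 ± 175.4, Illumina QUAL 222.6 ± 1.2
and DP 880 ± 156.8; phasing rates 99.7% (ONT) and 91.9% (Illumina).
Alt-allele frequencies cycle through a fixed spread (0.05–0.5) rather
than being drawn, so default cohorts are comparable across seeds.

What the simulator does *not* emulate: sequence-context error
structure (homopolymers, GC bias, AT repeats — where real
cross-platform discrepancies concentrate), correlated errors across
sites or samples, indel-rich loci, allelic imbalance in QUAL/DP, or
switch errors within phase blocks (phasing is either correct or
absent). Passing tests therefore demonstrate that the *analysis* is
correct given well-formed phased calls, not that any platform pairing
achieves a particular accuracy on real amplicons.

## Numerical and interface choices

* QUAL and Float INFO fields pass through htslib's float32; values are
  re-rounded to six significant digits on read so files written by the
  fixture writer round-trip field-identically.
* Summary statistics use the sample standard deviation (n−1) and
  linear-interpolation quartiles with 1.5×IQR Tukey whiskers — the
  conventional boxplot definitions.
* Merged records sort by (contig, pos, ref, alt, sample); haplotype
  table ties break lexicographically; category colors are fixed but
  overridable hex values.
* Degenerate inputs are explicit: empty call sets produce empty
  summaries; an empty cohort fails the HWE contract; reference
  frequencies of exactly 0 or 1 are rejected (zero expected counts).

## Problem sizes in the validation suite

The test suite and `scripts/acceptance.py` use cohorts of 400 samples
over 10–50 sites, 2000 replicate sites for type-I-error calibration,
and 10 seeds for corruption-rate recovery. These sizes make binomial
standard errors small enough that 3-SE recovery checks are meaningful
while keeping the whole suite in the seconds-to-a-minute range.

## Known limitations

* Biallelic SNV-centric: indels are carried through faithfully but
  not re-aligned or normalized; complex/overlapping variants are out
  of scope.
* One transcript per gene model; isoform selection is the caller's
  job.
* The HWE χ² is asymptotic; rare alleles at small n deserve an exact
  test the package does not yet provide.
* Cross-gene (joint multi-locus) haplotype tables are not built;
  tables are per region.
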