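# haplomerge

Cross-platform concordance analysis and haplotype tabulation for
phased amplicon variant calls.

Amplicon sequencing of the same samples on a long-read platform
(Oxford Nanopore, ONT) and a short-read platform (Illumina) yields two
independent phased call sets per sample: the long reads phase nearly
every heterozygous variant but are noisier per base; the short reads
are highly accurate but often cannot bridge distant heterozygous
sites. `haplomerge` is the comparison layer that sits downstream of a
standard calling + read-based-phasing pipeline (bcftools / WhatsHap):
it merges the two platforms' phased VCFs per sample, flags where they
agree and where they do not, restricts output to gene target windows,
computes per-site population-genetic statistics, and assembles phased
haplotypes into cohort frequency tables. It is aimed at labs running
high-throughput amplicon panels (e.g. blood-group genotyping) who need
an automated, reviewable comparison rather than a black-box consensus.

## What it computes

* **Four-state concordance.** Every (sample, site) reported by at
  least one platform is classified: *agree* (green), *discrepant*
  (red), *Illumina-only* (yellow), *ONT-only* (orange). Genotypes are
  compared unordered (`0|1` ≡ `1|0`); a site absent from one platform
  is "not reported", never imputed as homozygous reference.
  Discrepancies are deliberately left unreconciled for human review.
* **Target windows.** Three nested definitions built from a GFF3/BED12
  gene model: CDS ± 50 bp intronic flank, exons-plus (exons ± 50 bp,
  with 200 bp of 5′/3′ noncoding sequence at the gene ends), and the
  complete gene ± 200 bp.
* **Per-site statistics.** Genotype counts, alt-allele frequency
  q = (2·n_homalt + n_het)/2n, a 1-df χ² goodness-of-fit test against
  Hardy–Weinberg proportions (p², 2pq, q²), and a 1-df allele-count χ²
  against user-supplied reference population frequencies.
* **Haplotypes.** Phase blocks are read off WhatsHap-style GT/PS
  output (haplotype A = first allele of each ordered genotype);
  per-sample diplotypes and cohort haplotype/diplotype frequency
  tables follow, with samples whose phase is split across blocks
  excluded and counted. The *percent phased* statistic is the fraction
  of heterozygous calls assigned to a phase block.
* **Reports.** TSV, color-coded XLSX, or static HTML, plus quality-
  metric summaries (QUAL, DP, bcftools bias statistics) as mean ± sd
  and Tukey boxplot numbers.
* **Synthetic cohorts.** A call-level simulator draws truth diplotypes
  under Hardy–Weinberg equilibrium and corrupts them per platform
  (missed calls, het↔hom-alt genotype errors, incomplete phasing,
  QUAL/DP from configurable normal distributions), so the whole
  pipeline is testable against known truth.

## Worked example

```python
from haplomerge import (SimulationConfig, simulate_paired_cohort,
                        merge_cohorts, summarize, percent_phased)
from haplomerge.synthetic_cohort import (default_ont_profile,
                                         default_illumina_profile)

config = SimulationConfig(
    seed=42, n_samples=400,
    ont=default_ont_profile(genotype_error_rate=0.01, missed_call_rate=0.02),
    illumina=default_illumina_profile(),
)
truth, illumina, ont = simulate_paired_cohort(config)
records = merge_cohorts(illumina, ont)
(overall,) = summarize(records)
for cat in overall.counts:
    print(f"{cat.value:14s} {overall.counts[cat]:5d}  "
          f"{100 * overall.frequencies[cat]:6.2f}%")
print(f"ONT      phased: {percent_phased(ont).percent:.1f}%")
print(f"Illumina phased: {percent_phased(illumina).percent:.1f}%")
```

```
AGREE           1782   97.22%
DISCREPANT        13    0.71%
ILLUMINA_ONLY     38    2.07%
ONT_ONLY           0    0.00%
ONT      phased: 99.9%
Illumina phased: 92.9%
```

A 400-sample cohort over a ten-site amplicon was simulated with a 1%
genotype-error and 2% missed-call rate on the ONT side and a clean
Illumina side. Of the 1833 (sample, site) pairs reported by either
platform, 97.2% agree; the 13 discrepant records reflect ONT genotype
errors, and the 38 Illumina-only records are calls the ONT side
dropped. The long-read platform phases essentially all heterozygous
calls (99.9%), the short-read platform 92.9%.

The same workflow is available from the shell:

```sh
haplomerge simulate --seed 42 --n-samples 400 --out cohort/
haplomerge analyze --out-prefix out/run1 --report-format xlsx \
    $(for f in cohort/illumina/*.vcf; do echo --illumina-vcf $f; done) \
    $(for f in cohort/ont/*.vcf; do echo --ont-vcf $f; done)
haplomerge windows --gene-model genes.gff3 --gene-id MYGENE \
    --target CDS --out mygene_cds.bed
```

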