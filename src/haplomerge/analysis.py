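"""End-to-end paired-platform analysis pipeline.

Composes the individual modules — region restriction, quality
filtering, cross-platform merging, per-site statistics, phasing
summaries and haplotype tables — into one call, for the CLI and for
scripted use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import concordance, haplotyping, popgen_stats, reporting
from .filters import FilterPolicy, apply_filters
from .io_vcf import Platform, SampleVariantCall, SiteKey
from .popgen_stats import CohortMode
from .regions import IntervalSet, filter_by_region


@dataclass
class PairedAnalysisResult:
    records: list[concordance.ConcordanceRecord]
    overall: list[concordance.ConcordanceSummary]
    per_position: list[concordance.ConcordanceSummary]
    per_sample: list[concordance.ConcordanceSummary]
    site_stats: dict[Platform, pd.DataFrame]
    phasing: dict[Platform, haplotyping.PhasingSummary]
    haplotype_tables: dict[Platform, haplotyping.HaplotypeTable]
    quality: list[reporting.QualityMetricsSummary]
    n_filtered: dict[Platform, int] = field(default_factory=dict)

    @property
    def agreement_fraction(self) -> float:
        if not self.overall:
            return float("nan")
        return self.overall[0].frequencies[concordance.ConcordanceCategory.AGREE]


def run_paired_analysis(
    illumina_calls: Sequence[SampleVariantCall],
    ont_calls: Sequence[SampleVariantCall],
    windows: Optional[IntervalSet] = None,
    policy: Optional[FilterPolicy] = None,
    cohort_mode: CohortMode = CohortMode.CALLED_ONLY,
    cohort_size: Optional[int] = None,
    reference_freqs: Optional[dict[SiteKey, float]] = None,
    region_id: str = "region",
    sample_ids: Optional[Sequence[str]] = None,
) -> PairedAnalysisResult:
    """Run the full merge/compare/summarize pipeline on two call sets.

    ``sample_ids`` lists the full cohort; samples without any variant
    call still contribute a REF/REF diplotype to the haplotype tables.
    Without it, only samples present in a call set are tabulated.
    """
    call_sets = {Platform.ILLUMINA: list(illumina_calls), Platform.ONT: list(ont_calls)}
    n_filtered: dict[Platform, int] = {}
    for platform, calls in call_sets.items():
        if windows is not None:
            calls = filter_by_region(calls, windows)
        if policy is not None:
            calls, removed = apply_filters(calls, policy)
            n_filtered[platform] = removed
        call_sets[platform] = calls

    records = concordance.merge_cohorts(
        call_sets[Platform.ILLUMINA], call_sets[Platform.ONT]
    )
    site_stats: dict[Platform, pd.DataFrame] = {}
    phasing: dict[Platform, haplotyping.PhasingSummary] = {}
    tables: dict[Platform, haplotyping.HaplotypeTable] = {}
    for platform, calls in call_sets.items():
        sites = sorted({c.site for c in calls if c.genotype and c.genotype != (0, 0)})
        counts, hwes, comparisons = [], [], []
        for site in sites:
            c = popgen_stats.count_genotypes(
                calls, site, mode=cohort_mode, cohort_size=cohort_size
            )
            counts.append(c)
            hwes.append(popgen_stats.hwe_test(c))
            if reference_freqs and site in reference_freqs:
                comparisons.append(
                    popgen_stats.compare_to_reference(c, reference_freqs[site])
                )
            else:
                comparisons.append(None)
        site_stats[platform] = popgen_stats.site_statistics_table(
            hwes, comparisons, counts, platform
        )
        phasing[platform] = haplotyping.percent_phased(calls)
        by_sample: dict[str, list[SampleVariantCall]] = (
            {sid: [] for sid in sample_ids} if sample_ids is not None else {}
        )
        for c in calls:
            by_sample.setdefault(c.sample_id, []).append(c)
        diplotypes = [
            haplotyping.assemble_diplotype(sample_calls, region_id, sample_id=sid)
            for sid, sample_calls in by_sample.items()
        ]
        tables[platform] = haplotyping.cohort_haplotype_frequencies(
            diplotypes, level="diplotype"
        )

    all_calls = call_sets[Platform.ILLUMINA] + call_sets[Platform.ONT]
    return PairedAnalysisResult(
        records=records,
        overall=concordance.summarize(records, "overall"),
        per_position=concordance.summarize(records, "per_position"),
        per_sample=concordance.summarize(records, "per_sample"),
        site_stats=site_stats,
        phasing=phasing,
        haplotype_tables=tables,
        quality=reporting.summarize_quality_metrics(all_calls, ("QUAL", "DP")),
        n_filtered=n_filtered,
    )
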