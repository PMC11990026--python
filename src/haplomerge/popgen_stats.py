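"""Per-site population-genetic statistics.

For every variant site the cohort's genotype counts are tallied and a
1-df chi-square goodness-of-fit test against Hardy–Weinberg proportions
(p², 2pq, q²) is computed, along with an allele-count chi-square against
externally supplied reference allele frequencies (e.g. population
frequencies exported from a database as a TSV).

The classical chi-square is used without continuity correction and
without an exact-test variant; p-values are reported raw, with no
multiple-testing correction across sites — users comparing many sites
should apply their own correction.

Two cohort denominators are supported.  With ``amplicon_complete`` every
amplicon is assumed to cover every site, so samples without a call are
counted as homozygous reference; with ``called_only`` they are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from scipy import stats

from .concordance import ConcordanceRecord
from .io_vcf import Platform, SampleVariantCall, SiteKey


class CohortMode(str, Enum):
    AMPLICON_COMPLETE = "amplicon_complete"
    CALLED_ONLY = "called_only"


class HWEStatus(str, Enum):
    OK = "OK"
    MONOMORPHIC = "MONOMORPHIC"


@dataclass(frozen=True)
class GenotypeCounts:
    site: SiteKey
    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    def __post_init__(self):
        if min(self.n_hom_ref, self.n_het, self.n_hom_alt) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt


@dataclass(frozen=True)
class HWEResult:
    site: SiteKey
    allele_freq_alt: float
    chi_square: float  # NaN when monomorphic
    df: int
    p_value: float  # NaN when monomorphic
    status: HWEStatus


@dataclass(frozen=True)
class ReferenceComparison:
    site: SiteKey
    chi_square: float
    p_value: float
    significant: bool


class DuplicateGenotypeError(ValueError):
    """Conflicting genotypes for one sample at one site."""


def count_genotypes(
    records: Sequence[Union[SampleVariantCall, ConcordanceRecord]],
    site: SiteKey,
    platform: Optional[Platform] = None,
    mode: CohortMode = CohortMode.CALLED_ONLY,
    cohort_size: Optional[int] = None,
) -> GenotypeCounts:
    """Tally hom-ref / het / hom-alt genotypes at one site.

    Accepts either plain calls (one platform's call set) or merged
    concordance records, in which case ``platform`` selects which
    platform's call to count.  In ``amplicon_complete`` mode,
    ``cohort_size`` samples are assumed and the uncalled remainder is
    counted as hom-ref.
    """
    mode = CohortMode(mode)
    genotypes: dict[str, tuple[int, int]] = {}
    for item in records:
        if isinstance(item, ConcordanceRecord):
            if platform is None:
                raise ValueError("platform is required for ConcordanceRecord input")
            call = (
                item.ont_call
                if Platform(platform) is Platform.ONT
                else item.illumina_call
            )
        else:
            call = item
            if platform is not None and call.platform is not Platform(platform):
                continue
        if call is None or call.genotype is None or call.site != site:
            continue
        gt = tuple(sorted(call.genotype))
        if call.sample_id in genotypes:
            if genotypes[call.sample_id] != gt:
                raise DuplicateGenotypeError(
                    f"conflicting genotypes for sample {call.sample_id} at "
                    f"{site.contig}:{site.pos}"
                )
            continue
        genotypes[call.sample_id] = gt
    n_het = sum(1 for g in genotypes.values() if g == (0, 1))
    n_hom_alt = sum(1 for g in genotypes.values() if g == (1, 1))
    n_hom_ref = sum(1 for g in genotypes.values() if g == (0, 0))
    if mode is CohortMode.AMPLICON_COMPLETE:
        if cohort_size is None:
            raise ValueError("amplicon_complete mode requires cohort_size")
        if cohort_size < len(genotypes):
            raise ValueError("cohort_size smaller than number of called samples")
        n_hom_ref += cohort_size - len(genotypes)
    return GenotypeCounts(site, n_hom_ref, n_het, n_hom_alt)


def hwe_test(counts: GenotypeCounts) -> HWEResult:
    """1-df chi-square goodness-of-fit test against HWE proportions.

    With alt allele frequency q = (2·n_hom_alt + n_het) / (2n), expected
    genotype counts are n(1−q)², 2nq(1−q) and nq²; the statistic sums
    (obs−exp)²/exp over the three classes.  Monomorphic sites (q ∈ {0,1})
    have no test; chi-square and p are NaN with MONOMORPHIC status.
    """
    n = counts.n_total
    if n <= 0:
        raise ValueError("hwe_test requires at least one genotype")
    q = (2 * counts.n_hom_alt + counts.n_het) / (2 * n)
    if q == 0.0 or q == 1.0:
        return HWEResult(
            counts.site, q, math.nan, 1, math.nan, HWEStatus.MONOMORPHIC
        )
    p = 1.0 - q
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    observed = (counts.n_hom_ref, counts.n_het, counts.n_hom_alt)
    chi = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    return HWEResult(
        counts.site, q, chi, 1, float(stats.chi2.sf(chi, df=1)), HWEStatus.OK
    )


def compare_to_reference(
    observed: GenotypeCounts, expected_alt_freq: float, alpha: float = 0.05
) -> ReferenceComparison:
    """1-df chi-square of observed allele counts vs a reference frequency.

    The 2n allele observations (alt = 2·n_hom_alt + n_het) are compared
    against expected counts 2n·f and 2n·(1−f).  ``significant`` is
    p < alpha (default 0.05).

    Raises
    ------
    ValueError
        expected_alt_freq of 0 or 1 (zero expected count), or empty cohort.
    """
    if not 0.0 < expected_alt_freq < 1.0:
        raise ValueError("expected_alt_freq must be strictly between 0 and 1")
    n_alleles = 2 * observed.n_total
    if n_alleles == 0:
        raise ValueError("no allele observations")
    obs_alt = 2 * observed.n_hom_alt + observed.n_het
    obs_ref = n_alleles - obs_alt
    exp_alt = n_alleles * expected_alt_freq
    exp_ref = n_alleles - exp_alt
    chi = (obs_alt - exp_alt) ** 2 / exp_alt + (obs_ref - exp_ref) ** 2 / exp_ref
    p_value = float(stats.chi2.sf(chi, df=1))
    return ReferenceComparison(observed.site, chi, p_value, p_value < alpha)


def site_statistics_table(
    results: Sequence[HWEResult],
    comparisons: Optional[Sequence[Optional[ReferenceComparison]]] = None,
    counts: Optional[Sequence[GenotypeCounts]] = None,
    platform: Optional[Platform] = None,
) -> pd.DataFrame:
    """Assemble the per-site statistics export table."""
    rows = []
    for i, res in enumerate(results):
        row = {
            "contig": res.site.contig,
            "pos": res.site.pos,
            "ref": res.site.ref,
            "alt": res.site.alt,
            "platform": Platform(platform).value if platform else ".",
            "allele_freq_alt": res.allele_freq_alt,
            "hwe_chi_square": res.chi_square,
            "hwe_p_value": res.p_value,
            "hwe_status": res.status.value,
        }
        if counts is not None:
            c = counts[i]
            row.update(
                n_hom_ref=c.n_hom_ref, n_het=c.n_het, n_hom_alt=c.n_hom_alt,
                n_total=c.n_total,
            )
        if comparisons is not None and comparisons[i] is not None:
            cmp_ = comparisons[i]
            row.update(
                ref_chi_square=cmp_.chi_square,
                ref_p_value=cmp_.p_value,
                ref_significant=cmp_.significant,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_site_statistics(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
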