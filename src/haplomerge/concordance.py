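"""Cross-platform merging and four-state concordance classification.

Every (sample, site) reported by at least one platform is classified:

* ``AGREE`` (green) — both platforms report the site with the same
  unordered genotype;
* ``DISCREPANT`` (red) — both report it but the genotypes differ;
* ``ILLUMINA_ONLY`` (yellow) — reported by Illumina only;
* ``ONT_ONLY`` (orange) — reported by ONT only.

Genotype comparison is unordered (``0|1`` == ``1|0`` == ``0/1``):
haplotype order within a phase set is arbitrary, so phase labels carry
no information about call agreement.  A site absent from one platform's
call set is "not reported" — it is never imputed as homozygous
reference, matching variant-only VCF semantics.  Calls that *are*
hom-ref (possible in multi-sample VCFs) or have missing genotypes are
likewise treated as not reported.

Discrepancies are deliberately not reconciled: the merged table is for
human review, and records where the two platforms disagree on the alt
allele itself appear as two platform-only records (site identity
includes the alleles).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Hashable, Iterable, Optional, Sequence

import pandas as pd

from .io_vcf import Platform, SampleVariantCall, SiteKey


class ConcordanceCategory(str, Enum):
    AGREE = "AGREE"
    DISCREPANT = "DISCREPANT"
    ILLUMINA_ONLY = "ILLUMINA_ONLY"
    ONT_ONLY = "ONT_ONLY"


#: Human-readable color names for each category.
CATEGORY_COLORS = {
    ConcordanceCategory.AGREE: "green",
    ConcordanceCategory.DISCREPANT: "red",
    ConcordanceCategory.ILLUMINA_ONLY: "yellow",
    ConcordanceCategory.ONT_ONLY: "orange",
}


class DuplicateCallError(ValueError):
    """Two calls for the same (sample, site) within one platform."""


@dataclass
class ConcordanceRecord:
    sample_id: str
    site: SiteKey
    category: ConcordanceCategory
    illumina_call: Optional[SampleVariantCall] = None
    ont_call: Optional[SampleVariantCall] = None


@dataclass
class ConcordanceSummary:
    """Category counts and frequencies for one aggregation key."""

    scope: str  # "overall", "per_position" or "per_sample"
    key: Optional[Hashable]  # None, SiteKey, or sample_id
    counts: dict[ConcordanceCategory, int]
    frequencies: dict[ConcordanceCategory, float]


def classify_pair(
    illumina_call: Optional[SampleVariantCall],
    ont_call: Optional[SampleVariantCall],
) -> ConcordanceCategory:
    """Classify one (sample, site) from its two optional platform calls.

    Phase order is ignored: genotypes are compared as unordered pairs.

    Raises
    ------
    ValueError
        If both calls are absent, or both are present at different sites.
    """
    if illumina_call is None and ont_call is None:
        raise ValueError("classify_pair requires at least one call")
    if illumina_call is None:
        return ConcordanceCategory.ONT_ONLY
    if ont_call is None:
        return ConcordanceCategory.ILLUMINA_ONLY
    if illumina_call.site != ont_call.site:
        raise ValueError(
            f"site mismatch: {illumina_call.site} vs {ont_call.site}"
        )
    if sorted(illumina_call.genotype) == sorted(ont_call.genotype):
        return ConcordanceCategory.AGREE
    return ConcordanceCategory.DISCREPANT


def _reported(call: SampleVariantCall) -> bool:
    """Variant-only semantics: hom-ref and missing genotypes are not 'reported'."""
    return call.genotype is not None and call.genotype != (0, 0)


def _index(
    calls: Iterable[SampleVariantCall], platform_label: str
) -> dict[tuple[str, SiteKey], SampleVariantCall]:
    index: dict[tuple[str, SiteKey], SampleVariantCall] = {}
    for call in calls:
        if not _reported(call):
            continue
        key = (call.sample_id, call.site)
        if key in index:
            raise DuplicateCallError(
                f"duplicate {platform_label} call for sample {call.sample_id} "
                f"at {call.site.contig}:{call.site.pos} {call.site.ref}>{call.site.alt}"
            )
        index[key] = call
    return index


def merge_cohorts(
    illumina_calls: Sequence[SampleVariantCall],
    ont_calls: Sequence[SampleVariantCall],
) -> list[ConcordanceRecord]:
    """Merge two platforms' call sets into classified concordance records.

    One record is produced per (sample, site) reported by either
    platform, sorted by (contig, pos, sample_id).
    """
    ill = _index(illumina_calls, "Illumina")
    ont = _index(ont_calls, "ONT")
    records = []
    for sample_id, site in set(ill) | set(ont):
        a = ill.get((sample_id, site))
        b = ont.get((sample_id, site))
        records.append(
            ConcordanceRecord(
                sample_id=sample_id,
                site=site,
                category=classify_pair(a, b),
                illumina_call=a,
                ont_call=b,
            )
        )
    records.sort(key=lambda r: (r.site.contig, r.site.pos, r.site.ref, r.site.alt, r.sample_id))
    return records


def _summary(scope: str, key, cats: Iterable[ConcordanceCategory]) -> ConcordanceSummary:
    counter = Counter(cats)
    total = sum(counter.values())
    counts = {c: counter.get(c, 0) for c in ConcordanceCategory}
    freqs = {c: (counts[c] / total if total else 0.0) for c in ConcordanceCategory}
    return ConcordanceSummary(scope=scope, key=key, counts=counts, frequencies=freqs)


def summarize(
    records: Sequence[ConcordanceRecord], scope: str = "overall"
) -> list[ConcordanceSummary]:
    """Aggregate category counts/frequencies overall, per position or per sample.

    The overall frequencies are computed over all records, i.e. the
    (sample, site) union is the denominator.
    """
    if not records:
        return []
    if scope == "overall":
        return [_summary("overall", None, (r.category for r in records))]
    if scope == "per_position":
        groups: dict[SiteKey, list] = defaultdict(list)
        for r in records:
            groups[r.site].append(r.category)
        return [
            _summary("per_position", site, cats)
            for site, cats in sorted(groups.items())
        ]
    if scope == "per_sample":
        groups = defaultdict(list)
        for r in records:
            groups[r.sample_id].append(r.category)
        return [
            _summary("per_sample", sid, cats) for sid, cats in sorted(groups.items())
        ]
    raise ValueError(f"unknown scope {scope!r}")


def _gt_str(call: Optional[SampleVariantCall]) -> str:
    if call is None or call.genotype is None:
        return "."
    sep = "|" if call.phased else "/"
    return sep.join(str(a) for a in call.genotype)


def records_to_frame(records: Sequence[ConcordanceRecord]) -> pd.DataFrame:
    """Flatten records into the merged-table export layout."""
    rows = []
    for r in records:
        rows.append(
            {
                "sample": r.sample_id,
                "contig": r.site.contig,
                "pos": r.site.pos,
                "ref": r.site.ref,
                "alt": r.site.alt,
                "category": r.category.value,
                "color": CATEGORY_COLORS[r.category],
                "illumina_gt": _gt_str(r.illumina_call),
                "illumina_qual": r.illumina_call.qual if r.illumina_call else None,
                "illumina_dp": r.illumina_call.depth if r.illumina_call else None,
                "ont_gt": _gt_str(r.ont_call),
                "ont_qual": r.ont_call.qual if r.ont_call else None,
                "ont_dp": r.ont_call.depth if r.ont_call else None,
            }
        )
    return pd.DataFrame(rows)


def write_merged_tsv(records: Sequence[ConcordanceRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False, na_rep=".")
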