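"""Haplotype assembly from phased genotypes, and cohort frequency tables.

The phasing itself happens upstream (read-based phasing, e.g. WhatsHap);
this module consumes its GT/PS output.  Within a phase block, the two
haplotypes are read directly off the ordered genotypes: ``hap_a`` takes
the first allele of each ``a|b`` genotype, ``hap_b`` the second.
Homozygous sites carry the same allele on both haplotypes and belong to
every block.  Unphased heterozygous sites carry no haplotype assignment
and are excluded from blocks (their count feeds the percent-phased
statistic).

A sample's diplotype for a region is *complete* only when all its
heterozygous sites fall into a single phase block; otherwise the phase
between blocks is unknown, the sample is flagged incomplete and excluded
from cohort frequency tables (with the exclusion count disclosed) —
concatenating blocks would assert phase the data does not support.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .io_vcf import Platform, SampleVariantCall, SiteKey
from .regions import IntervalSet


class PhaseSetError(ValueError):
    """Phased call lacks a PS tag while multiple phase sets exist."""


@dataclass
class PhaseBlock:
    """One phase block: co-phased sites and their two allele vectors."""

    sample_id: str
    platform: Platform
    phase_set: Optional[int]
    sites: list[SiteKey]
    hap_a: list[int]
    hap_b: list[int]

    def __post_init__(self):
        if not (len(self.sites) == len(self.hap_a) == len(self.hap_b)):
            raise ValueError("haplotype vectors must match the site list")
        if any(
            a.pos >= b.pos for a, b in zip(self.sites, self.sites[1:])
        ):
            raise ValueError("block sites must be strictly increasing by pos")

    @property
    def n_het(self) -> int:
        return sum(1 for a, b in zip(self.hap_a, self.hap_b) if a != b)


@dataclass(frozen=True)
class Diplotype:
    sample_id: str
    region_id: str
    haplotype_pair: tuple[str, str]  # sorted, order-independent
    complete: bool


@dataclass
class HaplotypeTable:
    """Cohort haplotype (or diplotype) counts, sorted by descending count."""

    region_id: str
    level: str  # "haplotype" or "diplotype"
    rows: list[tuple[str, int, float]]
    n_complete_samples: int
    n_excluded_incomplete: int


@dataclass(frozen=True)
class PhasingSummary:
    """Percent of heterozygous calls assigned to a phase block."""

    percent: float
    n_het: int
    n_het_phased: int
    vacuous: bool  # True when there were no heterozygous calls at all


def haplotype_label(sites: Sequence[SiteKey], alleles: Sequence[int]) -> str:
    """Render one haplotype as its carried alt alleles, or ``REF``."""
    parts = [
        f"{s.pos}{s.ref}>{s.alt}" for s, a in zip(sites, alleles) if a == 1
    ]
    return ";".join(parts) if parts else "REF"


def _restrict(calls, windows: Optional[IntervalSet]):
    if windows is None:
        return list(calls)
    return [c for c in calls if c.contig == windows.contig and windows.contains(c.pos)]


def build_phase_blocks(
    calls: Sequence[SampleVariantCall],
    windows: Optional[IntervalSet] = None,
) -> list[PhaseBlock]:
    """Group one sample+platform's calls into phase blocks.

    Phased heterozygous calls are grouped by their PS tag; homozygous-alt
    calls are appended to every block (or form a block of their own when
    no phased hets exist).  Unphased heterozygous calls are excluded.

    Raises
    ------
    PhaseSetError
        A phased het lacks PS while other phase sets exist, making its
        block membership ambiguous.
    ValueError
        Calls from more than one sample or platform.
    """
    calls = _restrict(calls, windows)
    idents = {(c.sample_id, c.platform) for c in calls}
    if len(idents) > 1:
        raise ValueError("build_phase_blocks expects one sample and one platform")
    variant_calls = [c for c in calls if c.genotype is not None and c.genotype != (0, 0)]
    if not variant_calls:
        return []
    sample_id, platform = next(iter(idents))

    phased_hets = defaultdict(list)
    homs: list[SampleVariantCall] = []
    for c in variant_calls:
        if c.is_het:
            if c.phased:
                phased_hets[c.phase_set].append(c)
        else:  # hom-alt
            homs.append(c)
    if None in phased_hets and len(phased_hets) > 1:
        bad = phased_hets[None][0]
        raise PhaseSetError(
            f"phased call at {bad.contig}:{bad.pos} lacks PS while "
            f"{len(phased_hets) - 1} other phase set(s) exist"
        )

    keys = sorted(phased_hets, key=lambda k: (k is None, k)) or [None]
    blocks = []
    for ps in keys:
        members = phased_hets.get(ps, []) + homs
        if not members:
            continue
        members.sort(key=lambda c: c.pos)
        blocks.append(
            PhaseBlock(
                sample_id=sample_id,
                platform=platform,
                phase_set=ps,
                sites=[c.site for c in members],
                hap_a=[c.genotype[0] for c in members],
                hap_b=[c.genotype[1] for c in members],
            )
        )
    return blocks


def percent_phased(
    calls: Sequence[SampleVariantCall],
    windows: Optional[IntervalSet] = None,
) -> PhasingSummary:
    """Fraction of heterozygous calls that are phased, as a percentage.

    Homozygous genotypes carry no phase information and are excluded
    from the denominator.  With no heterozygous calls at all the result
    is vacuously 100.0, flagged via ``vacuous``.
    """
    calls = _restrict(calls, windows)
    hets = [c for c in calls if c.is_het]
    if not hets:
        return PhasingSummary(100.0, 0, 0, True)
    n_phased = sum(1 for c in hets if c.phased)
    return PhasingSummary(100.0 * n_phased / len(hets), len(hets), n_phased, False)


def haplotype_sequence(
    reference: str,
    block: PhaseBlock,
    ref_start: int = 1,
    windows: Optional[IntervalSet] = None,
) -> tuple[str, str]:
    """Render a block's two haplotypes as sequence strings.

    ``reference`` is the contiguous reference sequence beginning at
    genomic position ``ref_start`` (1-based).  Alt alleles (substitutions
    or simple indels) are applied right-to-left so earlier coordinates
    stay valid.  Sites outside ``windows`` (when given) are skipped.

    Raises
    ------
    ValueError
        A site's REF allele disagrees with the reference sequence, or a
        site falls outside the reference span.
    """
    out = []
    for hap in (block.hap_a, block.hap_b):
        seq = reference
        for site, allele in sorted(
            zip(block.sites, hap), key=lambda t: t[0].pos, reverse=True
        ):
            if windows is not None and not windows.contains(site.pos):
                continue
            off = site.pos - ref_start
            if off < 0 or off + len(site.ref) > len(reference):
                raise ValueError(f"site {site.pos} outside reference span")
            if reference[off : off + len(site.ref)].upper() != site.ref:
                raise ValueError(
                    f"REF mismatch at {site.contig}:{site.pos}: expected "
                    f"{site.ref}, reference has "
                    f"{reference[off : off + len(site.ref)].upper()}"
                )
            if allele == 1:
                seq = seq[:off] + site.alt + seq[off + len(site.ref):]
        out.append(seq)
    return out[0], out[1]


def assemble_diplotype(
    calls: Sequence[SampleVariantCall],
    region_id: str,
    windows: Optional[IntervalSet] = None,
    sample_id: Optional[str] = None,
) -> Diplotype:
    """Build one sample's diplotype for a region from its phased calls.

    The diplotype is complete iff every heterozygous site in the region
    is phased into a single block.  Incomplete samples carry the
    haplotypes of their largest block (most het sites, then leftmost),
    flagged ``complete=False``.
    """
    calls = _restrict(calls, windows)
    blocks = build_phase_blocks(calls)
    n_unphased_het = sum(1 for c in calls if c.is_het and not c.phased)
    if sample_id is None:
        sample_ids = {c.sample_id for c in calls}
        sample_id = next(iter(sample_ids)) if sample_ids else "?"
    het_blocks = [b for b in blocks if b.n_het > 0]
    complete = n_unphased_het == 0 and len(het_blocks) <= 1
    if not blocks:
        pair = ("REF", "REF")
    else:
        chosen = max(blocks, key=lambda b: (b.n_het, -b.sites[0].pos))
        pair = (
            haplotype_label(chosen.sites, chosen.hap_a),
            haplotype_label(chosen.sites, chosen.hap_b),
        )
    return Diplotype(
        sample_id=sample_id,
        region_id=region_id,
        haplotype_pair=tuple(sorted(pair)),
        complete=complete,
    )


def cohort_haplotype_frequencies(
    diplotypes: Sequence[Diplotype], level: str = "haplotype"
) -> HaplotypeTable:
    """Tabulate cohort haplotype or diplotype frequencies.

    At the haplotype level each complete sample contributes its two
    haplotypes; at the diplotype level it contributes one unordered
    pair.  Rows are sorted by descending count, ties lexicographically.
    Incomplete diplotypes are excluded, with their count reported.
    """
    regions = {d.region_id for d in diplotypes}
    if len(regions) > 1:
        raise ValueError(f"diplotypes span multiple regions: {sorted(regions)}")
    region_id = next(iter(regions)) if regions else "?"
    complete = [d for d in diplotypes if d.complete]
    n_excluded = len(diplotypes) - len(complete)
    counter: Counter[str] = Counter()
    for d in complete:
        if level == "haplotype":
            counter.update(d.haplotype_pair)
        elif level == "diplotype":
            counter[" / ".join(d.haplotype_pair)] += 1
        else:
            raise ValueError(f"unknown level {level!r}")
    total = sum(counter.values())
    rows = [
        (item, count, count / total)
        for item, count in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return HaplotypeTable(
        region_id=region_id,
        level=level,
        rows=rows,
        n_complete_samples=len(complete),
        n_excluded_incomplete=n_excluded,
    )


def haplotype_table_to_frame(table: HaplotypeTable) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"region": table.region_id, table.level: item, "count": c, "frequency": f}
            for item, c, f in table.rows
        ]
    )


def write_haplotype_table(table: HaplotypeTable, path: str | Path) -> None:
    haplotype_table_to_frame(table).to_csv(path, sep="\t", index=False)


def write_haplotype_fasta(
    sequences: dict[str, str], path: str | Path, width: int = 70
) -> None:
    """Write distinct haplotype sequences as FASTA (one record per name)."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
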