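"""Reading phased variant calls from VCF.

Calls are normalized into :class:`SampleVariantCall` records keyed by
:class:`SiteKey` so that call sets from different platforms (or samples)
can be merged site-by-site.  Input is assumed to come from a
bcftools-call + WhatsHap-phase pathway: diploid GT (``/`` or ``|``
separated), an optional PS phase-set tag, QUAL, and DP either per-sample
or in INFO.  Indel left-alignment is the upstream caller's job; this
module only case-folds alleles and splits multi-allelic records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import pysam


class Platform(str, Enum):
    """Sequencing platform of origin for a call set."""

    ONT = "ONT"
    ILLUMINA = "ILLUMINA"


#: INFO metrics carried through into ``extra_metrics`` when present
#: (bcftools' standard per-variant bias statistics plus mapping quality).
EXTRA_METRIC_NAMES = ("SCBZ", "RPBZ", "MQBZ", "MQSBZ", "BQBZ", "MQ0F", "MQ")


class VcfFormatError(ValueError):
    """The VCF lacks a required field or carries an unusable record."""


class PloidyError(VcfFormatError):
    """A genotype is not diploid; only diploid organisms are supported."""


@dataclass(frozen=True, order=True)
class SiteKey:
    """Identity of a biallelic variant site: contig, position and alleles.

    Equal keys compare equal regardless of which platform or sample the
    underlying call came from, which is what makes cross-platform merging
    well defined.
    """

    contig: str
    pos: int
    ref: str
    alt: str


def normalize_site(contig: str, pos: int, ref: str, alt: str) -> SiteKey:
    """Build a :class:`SiteKey` with uppercased alleles.

    No indel re-alignment is attempted: input is assumed left-aligned by
    the upstream caller.

    Raises
    ------
    ValueError
        If an allele is empty, ref equals alt, or pos < 1.
    """
    if not ref or not alt:
        raise ValueError(f"empty allele at {contig}:{pos} (ref={ref!r}, alt={alt!r})")
    ref_u, alt_u = ref.upper(), alt.upper()
    if ref_u == alt_u:
        raise ValueError(f"ref equals alt at {contig}:{pos}: {ref_u}")
    if pos < 1:
        raise ValueError(f"position must be >= 1, got {pos}")
    return SiteKey(contig=contig, pos=int(pos), ref=ref_u, alt=alt_u)


@dataclass
class SampleVariantCall:
    """One genotype call at one normalized site, for one sample on one platform.

    ``genotype`` is a pair of allele indices (0 = ref, 1 = alt) after
    multi-allelic splitting, or ``None`` when the source GT was missing
    (``./.``).  ``phased`` records whether the GT used the ``|``
    separator; ``phase_set`` carries the PS tag when present.
    """

    sample_id: str
    platform: Platform
    contig: str
    pos: int
    ref: str
    alt: str
    genotype: Optional[tuple[int, int]]
    phased: bool = False
    phase_set: Optional[int] = None
    qual: float = 0.0
    depth: Optional[int] = None
    extra_metrics: dict[str, float] = field(default_factory=dict)

    @property
    def site(self) -> SiteKey:
        return SiteKey(self.contig, self.pos, self.ref, self.alt)

    @property
    def is_missing(self) -> bool:
        return self.genotype is None

    @property
    def is_het(self) -> bool:
        return self.genotype is not None and self.genotype[0] != self.genotype[1]

    @property
    def is_hom_alt(self) -> bool:
        return self.genotype == (1, 1)

    @property
    def is_hom_ref(self) -> bool:
        return self.genotype == (0, 0)


def _record_label(rec) -> str:
    return f"{rec.chrom}:{rec.pos}"


def _f32_clean(x: float) -> float:
    # htslib stores QUAL and Float INFO values as float32; re-rounding to six
    # significant digits recovers the value as printed in the file.
    return float(f"{x:.6g}")


def read_phased_vcf(
    path: str | Path,
    platform: Platform,
    sample_override: Optional[str] = None,
) -> list[SampleVariantCall]:
    """Read a (plain or bgzipped) VCF into a list of :class:`SampleVariantCall`.

    One call is produced per (sample, site, alt allele): multi-allelic
    records are split into biallelic calls, with allele indices recoded
    against each split alt (any index not equal to that alt's original
    index becomes 0, preserving per-alt presence/absence).  Records with
    ``./.`` genotypes are returned with ``genotype=None``.

    Parameters
    ----------
    path:
        VCF file path.
    platform:
        Platform label stamped onto every returned call.
    sample_override:
        If given, replaces the sample name from the VCF header.  Only
        valid for single-sample files.

    Raises
    ------
    VcfFormatError
        Missing GT FORMAT declaration, no sample columns, or an
        override on a multi-sample file.
    PloidyError
        A genotype with ploidy other than 2.
    """
    platform = Platform(platform)
    with pysam.VariantFile(str(path)) as vf:
        if "GT" not in vf.header.formats:
            raise VcfFormatError(f"{path}: no GT FORMAT field declared")
        samples = list(vf.header.samples)
        if not samples:
            raise VcfFormatError(f"{path}: VCF has no sample columns")
        if sample_override is not None and len(samples) > 1:
            raise VcfFormatError(
                f"{path}: sample_override given but file has {len(samples)} samples"
            )
        calls: list[SampleVariantCall] = []
        for rec in vf:
            alts = rec.alts or ()
            if not alts:
                continue
            qual = _f32_clean(float(rec.qual)) if rec.qual is not None else 0.0
            info_dp = rec.info.get("DP")
            metrics = {
                name: _f32_clean(float(rec.info[name]))
                for name in EXTRA_METRIC_NAMES
                if name in rec.info and rec.info[name] is not None
            }
            for sample in samples:
                data = rec.samples[sample]
                if "GT" not in data:
                    raise VcfFormatError(
                        f"{path}: record {_record_label(rec)} lacks GT for {sample}"
                    )
                gt = data["GT"]
                if gt is None or len(gt) == 0 or all(a is None for a in gt):
                    gt = None
                elif len(gt) != 2:
                    raise PloidyError(
                        f"{path}: record {_record_label(rec)} sample {sample} "
                        f"has ploidy {len(gt)}; only diploid GT is supported"
                    )
                dp = data.get("DP")
                if dp is None:
                    dp = info_dp
                ps = data.get("PS") if "PS" in vf.header.formats else None
                phased = bool(data.phased) and gt is not None
                sample_id = sample_override if sample_override is not None else sample
                for alt_index, alt in enumerate(alts, start=1):
                    try:
                        key = normalize_site(rec.chrom, rec.pos, rec.ref, alt)
                    except ValueError:
                        warnings.warn(
                            f"{path}: skipping invalid alleles at {_record_label(rec)}"
                        )
                        continue
                    if gt is None:
                        genotype = None
                    else:
                        genotype = tuple(1 if a == alt_index else 0 for a in gt)
                    calls.append(
                        SampleVariantCall(
                            sample_id=sample_id,
                            platform=platform,
                            contig=key.contig,
                            pos=key.pos,
                            ref=key.ref,
                            alt=key.alt,
                            genotype=genotype,
                            phased=phased,
                            phase_set=int(ps) if ps is not None else None,
                            qual=qual,
                            depth=int(dp) if dp is not None else None,
                            extra_metrics=dict(metrics),
                        )
                    )
        return calls
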