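"""Target-window construction from gene models.

Three nested target definitions are supported, built from one
transcript's gene model:

* **CDS** — each coding interval extended by an intronic flank
  (default 50 bp) on both ends, to capture splice-site variants;
* **exons-plus** — each exon extended by the intronic flank at
  intron-facing boundaries, with the two gene-terminal boundaries
  extended instead by a noncoding flank (default 200 bp) into the 5'
  and 3' noncoding regions;
* **complete gene** — the full gene span extended by the noncoding
  flank on both ends.

All coordinates in the public data model are 1-based inclusive
(VCF/GFF3 convention).  Windows are merged, non-overlapping interval
sets clipped at position 1.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils

from .io_vcf import SampleVariantCall

Interval = tuple[int, int]


class TargetKind(str, Enum):
    CDS = "CDS"
    EXONS_PLUS = "EXONS_PLUS"
    COMPLETE_GENE = "COMPLETE_GENE"


@dataclass(frozen=True)
class TargetDefinition:
    """Which window definition to build, and with which flank widths (bp)."""

    kind: TargetKind
    intronic_flank: int = 50
    noncoding_flank: int = 200

    def __post_init__(self):
        if self.intronic_flank < 0 or self.noncoding_flank < 0:
            raise ValueError("flank widths must be non-negative")


def _merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or bookended 1-based inclusive intervals."""
    merged: list[Interval] = []
    for start, end in sorted(intervals):
        if start > end:
            raise ValueError(f"invalid interval ({start}, {end})")
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class IntervalSet:
    """A sorted, merged set of 1-based inclusive intervals on one contig."""

    contig: str
    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self):
        self.intervals = [
            (max(1, int(s)), int(e)) for s, e in _merge(self.intervals)
        ]
        self._starts = [s for s, _ in self.intervals]

    @property
    def total_length(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)

    def contains(self, pos: int) -> bool:
        i = bisect_right(self._starts, pos) - 1
        return i >= 0 and self.intervals[i][0] <= pos <= self.intervals[i][1]

    def __contains__(self, pos: int) -> bool:
        return self.contains(pos)

    def merged(self) -> "IntervalSet":
        """Re-merge; a no-op on an already canonical set."""
        return IntervalSet(self.contig, list(self.intervals))


@dataclass
class GeneModel:
    """Exon/CDS structure of one transcript in genomic coordinates.

    ``exons`` must be sorted, non-overlapping and inside ``gene_span``;
    every CDS interval must lie within the exon union.
    """

    gene_id: str
    contig: str
    strand: str
    gene_span: Interval
    exons: list[Interval]
    cds: list[Interval]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted(tuple(iv) for iv in self.exons)
        self.cds = sorted(tuple(iv) for iv in self.cds)
        gs, ge = self.gene_span
        prev_end = None
        for s, e in self.exons:
            if s > e or s < gs or e > ge:
                raise ValueError(f"exon ({s},{e}) outside gene span {self.gene_span}")
            if prev_end is not None and s <= prev_end:
                raise ValueError("exons overlap")
            prev_end = e
        exon_set = IntervalSet(self.contig, list(self.exons))
        for s, e in self.cds:
            if not all(exon_set.contains(p) for p in (s, e)):
                raise ValueError(f"CDS ({s},{e}) not contained in exons")
            # containment of both ends within one merged exon interval
            if not any(es <= s and e <= ee for es, ee in exon_set.intervals):
                raise ValueError(f"CDS ({s},{e}) spans an intron")


class GeneLookupError(KeyError):
    """Requested gene_id not found in the annotation file."""


def _read_bed12(path: Path, gene_id: str) -> GeneModel:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}: BED12 requires 12 columns, got {len(f)}")
            if f[3] != gene_id:
                continue
            chrom = f[0]
            chrom_start = int(f[1])  # 0-based
            thick_start, thick_end = int(f[6]), int(f[7])
            strand = f[5] if f[5] in ("+", "-") else "+"
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path}: block count mismatch for {gene_id}")
            exons: list[Interval] = []
            cds: list[Interval] = []
            for size, rel in zip(sizes, starts):
                b0, b1 = chrom_start + rel, chrom_start + rel + size  # half-open
                exons.append((b0 + 1, b1))
                c0, c1 = max(b0, thick_start), min(b1, thick_end)
                if c0 < c1:
                    cds.append((c0 + 1, c1))
            span = (exons[0][0], exons[-1][1])
            return GeneModel(gene_id, chrom, strand, span, exons, cds)
    raise GeneLookupError(f"{path}: gene {gene_id!r} not found")


def _read_gff3(path: Path, gene_id: str) -> GeneModel:
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    gene = None
    for feat in db.features_of_type("gene"):
        ids = set(feat.attributes.get("ID", [])) | set(feat.attributes.get("Name", []))
        if feat.id == gene_id or gene_id in ids:
            gene = feat
            break
    if gene is None:
        raise GeneLookupError(f"{path}: gene {gene_id!r} not found")
    exons = sorted(
        (f.start, f.end) for f in db.children(gene, featuretype="exon")
    )
    cds = sorted((f.start, f.end) for f in db.children(gene, featuretype="CDS"))
    if not exons:
        # gene with no annotated exons: treat the span as one exon
        exons = [(gene.start, gene.end)]
    return GeneModel(
        gene_id, gene.seqid, gene.strand if gene.strand in "+-" else "+",
        (gene.start, gene.end), exons, cds,
    )


def read_gene_model(path: str | Path, gene_id: str) -> GeneModel:
    """Load one gene's model from GFF3 or BED12 (chosen by file extension)."""
    path = Path(path)
    if path.suffix.lower() in (".bed", ".bed12"):
        return _read_bed12(path, gene_id)
    return _read_gff3(path, gene_id)


def build_target_windows(model: GeneModel, definition: TargetDefinition) -> IntervalSet:
    """Build the merged window set for one target definition.

    Raises
    ------
    ValueError
        Requesting CDS windows for a model with no CDS intervals.
    """
    fi = definition.intronic_flank
    fn = definition.noncoding_flank
    gs, ge = model.gene_span
    if definition.kind is TargetKind.CDS:
        if not model.cds:
            raise ValueError(f"gene {model.gene_id} has no CDS intervals")
        raw = [(s - fi, e + fi) for s, e in model.cds]
    elif definition.kind is TargetKind.EXONS_PLUS:
        raw = []
        for s, e in model.exons:
            left = fn if s == gs else fi
            right = fn if e == ge else fi
            raw.append((s - left, e + right))
    elif definition.kind is TargetKind.COMPLETE_GENE:
        raw = [(gs - fn, ge + fn)]
    else:  # pragma: no cover
        raise ValueError(f"unknown target kind {definition.kind}")
    return IntervalSet(model.contig, raw)


def filter_by_region(
    calls: Sequence[SampleVariantCall], windows: IntervalSet
) -> list[SampleVariantCall]:
    """Keep calls whose position lies inside any window (order preserved).

    Window bounds are inclusive.  If no call shares the windows' contig a
    warning is emitted and the result is empty.
    """
    kept = [
        c for c in calls if c.contig == windows.contig and windows.contains(c.pos)
    ]
    if calls and not any(c.contig == windows.contig for c in calls):
        warnings.warn(
            f"no call on contig {windows.contig!r}; check contig naming", stacklevel=2
        )
    return kept


def write_bed6(windows: IntervalSet, path: str | Path, name: str = "target") -> None:
    """Export windows as BED6 (0-based half-open on write, per BED)."""
    with open(path, "w") as fh:
        for i, (s, e) in enumerate(windows.intervals):
            fh.write(f"{windows.contig}\t{s - 1}\t{e}\t{name}_{i + 1}\t0\t+\n")
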