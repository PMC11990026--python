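from __future__ import annotations

import pytest

from haplomerge.io_vcf import Platform, SampleVariantCall
from haplomerge.regions import GeneModel

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID={contig}>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_vcf_text(path, records, contig="chr19", samples=("S1",)):
    """Hand-write a VCF for parser tests (independent of the fixture writer)."""
    body = "\n".join("\t".join(str(f) for f in rec) for rec in records)
    path.write_text(
        VCF_HEADER.format(contig=contig, samples="\t".join(samples))
        + body
        + ("\n" if body else "")
    )
    return path


@pytest.fixture
def make_call():
    """Factory for SampleVariantCall with sensible defaults."""

    def factory(
        sample_id="S1",
        platform=Platform.ONT,
        contig="chr19",
        pos=100,
        ref="A",
        alt="G",
        genotype=(0, 1),
        phased=False,
        phase_set=None,
        qual=100.0,
        depth=500,
        extra_metrics=None,
    ):
        return SampleVariantCall(
            sample_id=sample_id,
            platform=Platform(platform),
            contig=contig,
            pos=pos,
            ref=ref,
            alt=alt,
            genotype=tuple(genotype) if genotype is not None else None,
            phased=phased,
            phase_set=phase_set,
            qual=qual,
            depth=depth,
            extra_metrics=extra_metrics or {},
        )

    return factory


@pytest.fixture
def toy_gene_model():
    """Three-exon toy gene on [1001, 4000] with CDS inside exons."""
    return GeneModel(
        gene_id="GENE1",
        contig="chr19",
        strand="+",
        gene_span=(1001, 4000),
        exons=[(1001, 1200), (1901, 2100), (3801, 4000)],
        cds=[(1051, 1200), (1901, 2100), (3801, 3950)],
    )
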