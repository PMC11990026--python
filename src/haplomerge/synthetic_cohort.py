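"""Synthetic paired-platform cohort generation with known truth.

The generator works at the *call-set* level: it draws true diplotypes
for a cohort under Hardy–Weinberg equilibrium, then corrupts them
independently per platform with a minimal, identifiable error model —
missed calls, het↔hom-alt genotype errors, and incomplete phasing —
and emits WhatsHap-style phased VCF call sets.  Every downstream module
(merging, concordance, HWE, haplotyping) is thereby testable against
known truth without external sequencing data.

Defaults emulate an amplicon study design: a 400-sample cohort, ten
variant sites on a ~10 kb amplicon (roughly one naturally occurring SNV
per kilobase), QUAL/DP drawn from normal distributions matching
observed per-platform amplicon summaries (ONT QUAL 165.5 ± 52.7,
DP 690.5 ± 175.4; Illumina QUAL 222.6 ± 1.2, DP 880 ± 156.8), and
per-platform phasing rates of 99.7% (ONT long reads) and 91.9%
(Illumina short reads).

Hom-ref truth genotypes are never emitted (variant-only VCF semantics),
and genotype errors only toggle het↔hom-alt; false-positive site
emission is available as an explicit extra rate, default 0.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .haplotyping import Diplotype, haplotype_label
from .io_vcf import Platform, SampleVariantCall, SiteKey

_BASES = "ACGT"


@dataclass(frozen=True)
class SiteSpec:
    """One simulated biallelic site with its population alt-allele frequency."""

    pos: int
    ref: str
    alt: str
    alt_freq: float

    def __post_init__(self):
        if not 0.0 <= self.alt_freq <= 1.0:
            raise ValueError("alt_freq must be in [0, 1]")
        if self.ref == self.alt or not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty and differ")


@dataclass(frozen=True)
class PlatformProfile:
    """Corruption model and quality-annotation distributions for one platform."""

    platform: Platform
    genotype_error_rate: float = 0.0
    missed_call_rate: float = 0.0
    phased_rate: float = 1.0
    false_positive_rate: float = 0.0  # per hom-ref truth genotype
    qual_mean: float = 200.0
    qual_sd: float = 50.0
    depth_mean: float = 700.0
    depth_sd: float = 180.0

    def __post_init__(self):
        for name in ("genotype_error_rate", "missed_call_rate", "phased_rate",
                     "false_positive_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def default_ont_profile(**overrides) -> PlatformProfile:
    params = dict(
        platform=Platform.ONT,
        phased_rate=0.997,
        qual_mean=165.5, qual_sd=52.7,
        depth_mean=690.5, depth_sd=175.4,
    )
    params.update(overrides)
    return PlatformProfile(**params)


def default_illumina_profile(**overrides) -> PlatformProfile:
    params = dict(
        platform=Platform.ILLUMINA,
        phased_rate=0.919,
        qual_mean=222.6, qual_sd=1.2,
        depth_mean=880.0, depth_sd=156.8,
    )
    params.update(overrides)
    return PlatformProfile(**params)


def default_sites(
    n_sites: int = 10, start: int = 1001, spacing: int = 1000
) -> list[SiteSpec]:
    """Evenly spaced substitution sites with a fixed cycle of alt frequencies."""
    freqs = (0.05, 0.10, 0.20, 0.30, 0.40, 0.50, 0.35, 0.25, 0.15, 0.45)
    sites = []
    for i in range(n_sites):
        ref = _BASES[i % 4]
        alt = _BASES[(i + 1) % 4]
        sites.append(
            SiteSpec(
                pos=start + i * spacing,
                ref=ref,
                alt=alt,
                alt_freq=freqs[i % len(freqs)],
            )
        )
    return sites


@dataclass
class SimulationConfig:
    seed: int = 0
    n_samples: int = 400
    contig: str = "amplicon1"
    sites: list[SiteSpec] = field(default_factory=default_sites)
    ont: PlatformProfile = field(default_factory=default_ont_profile)
    illumina: PlatformProfile = field(default_factory=default_illumina_profile)

    def __post_init__(self):
        positions = [s.pos for s in self.sites]
        if positions != sorted(positions) or len(set(positions)) != len(positions):
            raise ValueError("sites must be sorted by pos and unique")

    def site_keys(self) -> list[SiteKey]:
        return [
            SiteKey(self.contig, s.pos, s.ref.upper(), s.alt.upper())
            for s in self.sites
        ]


@dataclass
class TruthCohort:
    """True phased diplotypes: alleles[sample, site, haplotype] ∈ {0, 1}."""

    config: SimulationConfig
    sample_ids: list[str]
    alleles: np.ndarray  # shape (n_samples, n_sites, 2), dtype int8

    def genotype(self, i_sample: int, i_site: int) -> tuple[int, int]:
        a = self.alleles[i_sample, i_site]
        return int(a[0]), int(a[1])


def simulate_truth(config: SimulationConfig) -> TruthCohort:
    """Draw the cohort's true diplotypes.

    Each sample's two alleles at each site are independent Bernoulli
    draws with the site's alt frequency, which yields Hardy–Weinberg
    genotype proportions by construction.  Reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    freqs = np.array([s.alt_freq for s in config.sites])
    u = rng.random((config.n_samples, len(config.sites), 2))
    alleles = (u < freqs[None, :, None]).astype(np.int8)
    width = max(3, len(str(config.n_samples)))
    sample_ids = [f"S{i + 1:0{width}d}" for i in range(config.n_samples)]
    return TruthCohort(config=config, sample_ids=sample_ids, alleles=alleles)


def truth_diplotypes(truth: TruthCohort, region_id: str = "region") -> list[Diplotype]:
    """The true diplotype of every sample, as haplotype label pairs."""
    keys = truth.config.site_keys()
    out = []
    for i, sid in enumerate(truth.sample_ids):
        pair = tuple(
            sorted(
                (
                    haplotype_label(keys, truth.alleles[i, :, 0]),
                    haplotype_label(keys, truth.alleles[i, :, 1]),
                )
            )
        )
        out.append(Diplotype(sid, region_id, pair, complete=True))
    return out


def corrupt_for_platform(
    truth: TruthCohort, profile: PlatformProfile, seed: int
) -> list[SampleVariantCall]:
    """Emit one platform's corrupted call set for the whole cohort.

    Per non-hom-ref truth genotype: the call is dropped with probability
    ``missed_call_rate``; an emitted genotype is toggled het↔hom-alt
    with probability ``genotype_error_rate``; each emitted het is phased
    (truth haplotype order, one shared PS per amplicon region) with
    probability ``phased_rate``.  QUAL and DP are drawn from the
    profile's normal distributions, floored at 0 and 1.  Hom-ref truths
    are emitted (as spurious hets) only under a non-zero
    ``false_positive_rate``.
    """
    rng = np.random.default_rng(seed)
    config = truth.config
    keys = config.site_keys()
    region_ps = min(k.pos for k in keys) if keys else 1
    calls: list[SampleVariantCall] = []
    for i, sample_id in enumerate(truth.sample_ids):
        for j, key in enumerate(keys):
            gt = truth.genotype(i, j)
            if gt == (0, 0):
                if profile.false_positive_rate > 0 and (
                    rng.random() < profile.false_positive_rate
                ):
                    gt = (0, 1) if rng.random() < 0.5 else (1, 0)
                else:
                    continue
            else:
                if rng.random() < profile.missed_call_rate:
                    continue
                if rng.random() < profile.genotype_error_rate:
                    if gt[0] != gt[1]:
                        gt = (1, 1)
                    else:
                        gt = (0, 1) if rng.random() < 0.5 else (1, 0)
            is_het = gt[0] != gt[1]
            phased = bool(is_het and rng.random() < profile.phased_rate)
            qual = round(max(0.0, rng.normal(profile.qual_mean, profile.qual_sd)), 2)
            depth = max(1, int(round(rng.normal(profile.depth_mean, profile.depth_sd))))
            genotype = gt if (phased or not is_het) else tuple(sorted(gt))
            calls.append(
                SampleVariantCall(
                    sample_id=sample_id,
                    platform=profile.platform,
                    contig=key.contig,
                    pos=key.pos,
                    ref=key.ref,
                    alt=key.alt,
                    genotype=genotype,
                    phased=phased,
                    phase_set=region_ps if phased else None,
                    qual=qual,
                    depth=depth,
                )
            )
    return calls


def simulate_paired_cohort(
    config: SimulationConfig,
) -> tuple[TruthCohort, list[SampleVariantCall], list[SampleVariantCall]]:
    """Truth plus both platforms' corrupted call sets, all seeded from config."""
    truth = simulate_truth(config)
    ill = corrupt_for_platform(truth, config.illumina, seed=config.seed + 1)
    ont = corrupt_for_platform(truth, config.ont, seed=config.seed + 2)
    return truth, ill, ont


def _fmt_qual(q: float) -> str:
    return f"{q:.10g}"


def write_vcf_fixture(
    calls: Sequence[SampleVariantCall],
    path: str | Path,
    contig: Optional[str] = None,
    sample_id: Optional[str] = None,
) -> Path:
    """Write one sample+platform call set as a plain-text VCF 4.2 file.

    Records carry QUAL, FORMAT GT (``|`` when phased, with PS) and DP,
    and any ``extra_metrics`` as INFO fields.  The output round-trips
    through :func:`haplomerge.io_vcf.read_phased_vcf`.
    """
    path = Path(path)
    idents = {(c.sample_id, c.platform) for c in calls}
    if len(idents) > 1:
        raise ValueError("write_vcf_fixture expects one sample and one platform")
    if calls:
        sample_id = calls[0].sample_id
        contig = calls[0].contig
    if sample_id is None or contig is None:
        raise ValueError("sample_id and contig are required for an empty call set")
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig}>",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">',
    ]
    metric_names = sorted({m for c in calls for m in c.extra_metrics})
    for m in metric_names:
        lines.append(
            f'##INFO=<ID={m},Number=1,Type=Float,Description="{m} metric">'
        )
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id,
    ]
    for c in sorted(calls, key=lambda c: c.pos):
        if c.genotype is None:
            gt = "./."
        else:
            sep = "|" if c.phased else "/"
            gt = sep.join(str(a) for a in c.genotype)
        info_parts = [f"{m}={c.extra_metrics[m]:.10g}" for m in sorted(c.extra_metrics)]
        info = ";".join(info_parts) if info_parts else "."
        fmt_keys, fmt_vals = ["GT"], [gt]
        if c.phased and c.phase_set is not None:
            fmt_keys.append("PS")
            fmt_vals.append(str(c.phase_set))
        if c.depth is not None:
            fmt_keys.append("DP")
            fmt_vals.append(str(c.depth))
        lines.append(
            "\t".join(
                [
                    c.contig, str(c.pos), ".", c.ref, c.alt,
                    _fmt_qual(c.qual), ".", info,
                    ":".join(fmt_keys), ":".join(fmt_vals),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_cohort(
    config: SimulationConfig, outdir: str | Path
) -> dict[str, list[Path]]:
    """Simulate and write the full paired cohort to disk.

    Produces one VCF per sample per platform, a truth-table TSV (one row
    per sample × site with the true ordered genotype) and the
    configuration used, as YAML, for provenance.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth, ill, ont = simulate_paired_cohort(config)
    written: dict[str, list[Path]] = {"ILLUMINA": [], "ONT": []}
    for platform, calls in (("ILLUMINA", ill), ("ONT", ont)):
        by_sample: dict[str, list[SampleVariantCall]] = {
            sid: [] for sid in truth.sample_ids
        }
        for c in calls:
            by_sample[c.sample_id].append(c)
        pdir = outdir / platform.lower()
        pdir.mkdir(exist_ok=True)
        for sid in truth.sample_ids:
            p = pdir / f"{sid}.vcf"
            write_vcf_fixture(
                by_sample[sid], p, contig=config.contig, sample_id=sid
            )
            written[platform].append(p)

    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("sample\tcontig\tpos\tref\talt\thap_a\thap_b\n")
        for i, sid in enumerate(truth.sample_ids):
            for j, key in enumerate(config.site_keys()):
                a, b = truth.genotype(i, j)
                fh.write(
                    f"{sid}\t{key.contig}\t{key.pos}\t{key.ref}\t{key.alt}\t{a}\t{b}\n"
                )

    config_path = outdir / "simulation_config.yaml"
    payload = dataclasses.asdict(config)
    payload["ont"]["platform"] = config.ont.platform.value
    payload["illumina"]["platform"] = config.illumina.platform.value
    with open(config_path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
    written["truth"] = [truth_path]
    written["config"] = [config_path]
    return written
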