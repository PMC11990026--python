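"""YAML configuration for the analysis CLI.

Example
-------
::

    filters:
      min_qual: 100
      min_depth: 500
    target:
      kind: CDS          # CDS | EXONS_PLUS | COMPLETE_GENE
      intronic_flank: 50
      noncoding_flank: 200
    cohort:
      mode: called_only  # or amplicon_complete
      size: 400
    reference_frequencies: ref_freqs.tsv   # contig, pos, ref, alt, alt_freq
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .filters import FilterPolicy
from .io_vcf import SiteKey
from .popgen_stats import CohortMode
from .regions import TargetDefinition, TargetKind


@dataclass
class AnalysisConfig:
    policy: FilterPolicy = field(default_factory=FilterPolicy)
    target: Optional[TargetDefinition] = None
    cohort_mode: CohortMode = CohortMode.CALLED_ONLY
    cohort_size: Optional[int] = None
    reference_frequencies: Optional[dict[SiteKey, float]] = None


def read_reference_frequencies(path: str | Path) -> dict[SiteKey, float]:
    """Load expected alt-allele frequencies from a TSV.

    Columns: contig, pos, ref, alt, alt_freq.  Frequencies are
    user-supplied (e.g. exported from a population database); nothing is
    fetched over the network.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"contig", "pos", "ref", "alt", "alt_freq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return {
        SiteKey(str(r.contig), int(r.pos), str(r.ref).upper(), str(r.alt).upper()):
            float(r.alt_freq)
        for r in df.itertuples()
    }


def load_config(path: str | Path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    filters = raw.get("filters") or {}
    policy = FilterPolicy(
        min_qual=filters.get("min_qual"), min_depth=filters.get("min_depth")
    )
    target = None
    if "target" in raw and raw["target"]:
        t = raw["target"]
        target = TargetDefinition(
            kind=TargetKind(t["kind"].upper()),
            intronic_flank=int(t.get("intronic_flank", 50)),
            noncoding_flank=int(t.get("noncoding_flank", 200)),
        )
    cohort = raw.get("cohort") or {}
    ref = None
    if raw.get("reference_frequencies"):
        ref_path = Path(raw["reference_frequencies"])
        if not ref_path.is_absolute():
            ref_path = Path(path).parent / ref_path
        ref = read_reference_frequencies(ref_path)
    return AnalysisConfig(
        policy=policy,
        target=target,
        cohort_mode=CohortMode(cohort.get("mode", "called_only")),
        cohort_size=cohort.get("size"),
        reference_frequencies=ref,
    )
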