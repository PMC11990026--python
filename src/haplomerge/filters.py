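"""Quality-threshold filtering of variant calls.

A call passes when its QUAL meets ``min_qual`` (if set) and its DP meets
``min_depth`` (if set).  Calls lacking DP fail a configured ``min_depth``:
depth-unknown cannot certify the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .io_vcf import SampleVariantCall


@dataclass(frozen=True)
class FilterPolicy:
    min_qual: Optional[float] = None
    min_depth: Optional[int] = None

    def __post_init__(self):
        if self.min_qual is not None and self.min_qual < 0:
            raise ValueError("min_qual must be non-negative")
        if self.min_depth is not None and self.min_depth < 0:
            raise ValueError("min_depth must be non-negative")

    def passes(self, call: SampleVariantCall) -> bool:
        if self.min_qual is not None:
            if math.isnan(call.qual) or call.qual < self.min_qual:
                return False
        if self.min_depth is not None:
            if call.depth is None or call.depth < self.min_depth:
                return False
        return True


def apply_filters(
    calls: Sequence[SampleVariantCall], policy: FilterPolicy
) -> tuple[list[SampleVariantCall], int]:
    """Return (kept calls in input order, number removed)."""
    kept = [c for c in calls if policy.passes(c)]
    return kept, len(calls) - len(kept)
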