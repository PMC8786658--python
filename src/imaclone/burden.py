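"""Tumor mutational burden (TMB): counted mutations per callable megabase.

Two counting modes are offered because "nonsynonymous missense" is a literal
reading of a definition in which missense is a subset of nonsynonymous:

* ``missense_only`` (default) — missense SNVs only.
* ``all_nonsynonymous`` — additionally nonsense, frameshift, inframe indel
  and splice variants.

Germline subtraction is assumed to have happened upstream (matched-normal
calling); callable megabases must be supplied per region — there is no
hidden exome-size constant (the capture-kit target size is a reasonable
value).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .rounding import round_half_even
from .variants import RegionCallset

__all__ = ["TmbResult", "TmbSummary", "tmb_per_region", "tmb_summary", "COUNTING_MODES"]

COUNTING_MODES = ("missense_only", "all_nonsynonymous")
_NONSYN_EXTRA = {"nonsense", "frameshift", "inframe_indel", "splice"}


@dataclass(frozen=True)
class TmbResult:
    patient_id: str
    region_label: str
    n_counted: int
    callable_mb: float

    @property
    def tmb(self) -> float:
        return self.n_counted / self.callable_mb

    @property
    def tmb_reported(self) -> float:
        return round_half_even(self.tmb, 2)


@dataclass(frozen=True)
class TmbSummary:
    mean: float
    min: float
    max: float

    @property
    def reported(self) -> tuple[float, float, float]:
        return (
            round_half_even(self.mean, 2),
            round_half_even(self.min, 2),
            round_half_even(self.max, 2),
        )


def tmb_per_region(
    callset: RegionCallset, counting_mode: str = "missense_only"
) -> TmbResult:
    """Count qualifying mutations in one region and divide by callable Mb."""
    if counting_mode not in COUNTING_MODES:
        raise ValueError(f"unknown counting mode {counting_mode!r}")
    if callset.callable_mb <= 0:
        raise ValueError("callable_mb must be positive")
    n = 0
    for v in callset.variants:
        if v.consequence == "missense" and v.variant_class == "SNV":
            n += 1
        elif counting_mode == "all_nonsynonymous" and v.consequence in _NONSYN_EXTRA:
            n += 1
    return TmbResult(
        patient_id=callset.patient_id,
        region_label=callset.region_label,
        n_counted=n,
        callable_mb=callset.callable_mb,
    )


def tmb_summary(results: Sequence[TmbResult | float]) -> TmbSummary:
    """Arithmetic mean, min and max of per-region TMB values."""
    if not results:
        raise ValueError("no TMB results to summarize")
    vals = [r.tmb if isinstance(r, TmbResult) else float(r) for r in results]
    return TmbSummary(mean=sum(vals) / len(vals), min=min(vals), max=max(vals))
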