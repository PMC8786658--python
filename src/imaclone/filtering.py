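"""Somatic variant exclusion rules and driver-hotspot review.

Five deterministic exclusion rules are applied to every call, in a fixed
order used only for attributing the *first* failing rule in the report
(the passing set itself is order-independent):

1. ``pop_af``    — observed in a configured population database above
   ``max_pop_af`` (default 1%); absence from all databases passes.
2. ``oxog``      — flagged as an 8-oxoguanine artifact upstream.
3. ``alt_count`` — fewer than ``min_alt_count`` supporting reads (default 3).
4. ``depth``     — total depth below ``min_depth`` (default 20).
5. ``vaf``       — variant allele fraction below ``min_vaf`` (default 3%).

Boundary semantics are inclusive for passing: alt_count ≥ 3, depth ≥ 20,
vaf ≥ 0.03 and pop_af ≤ 0.01 all pass.

Hotspot review mirrors the manual re-inspection of KRAS codons 12, 13 and 61:
variants at hotspot protein positions removed *solely* by the VAF rule are
returned for human review, never auto-rescued.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .variants import AnnotatedVariant, VariantKey

__all__ = [
    "FilterConfig",
    "FilterReport",
    "HotspotList",
    "RULE_ORDER",
    "apply_filters",
    "failing_rules",
    "hotspot_review",
]

logger = logging.getLogger(__name__)

RULE_ORDER = ("pop_af", "oxog", "alt_count", "depth", "vaf")


@dataclass(frozen=True)
class FilterConfig:
    max_pop_af: float = 0.01
    min_alt_count: int = 3
    min_depth: int = 20
    min_vaf: float = 0.03
    drop_oxog: bool = True
    population_dbs: tuple[str, ...] = ("gnomAD", "ExAC", "Korean")

    def __post_init__(self) -> None:
        if self.max_pop_af <= 0 or self.min_alt_count <= 0 or self.min_depth <= 0:
            raise ValueError("filter thresholds must be strictly positive")
        if not 0 < self.min_vaf < 1:
            raise ValueError("min_vaf must lie in (0, 1)")


@dataclass
class FilterReport:
    """Bookkeeping of one filtering pass; input = passing + removed."""

    n_input: int
    n_passing: int
    removed_by_rule: Counter = field(default_factory=Counter)
    removed: list[tuple[VariantKey, str]] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.removed)


@dataclass(frozen=True)
class HotspotList:
    """Driver hotspots as (gene, protein-position set) entries."""

    entries: tuple[tuple[str, frozenset[int]], ...] = (
        ("KRAS", frozenset({12, 13, 61})),
    )

    def positions(self, gene: str) -> frozenset[int]:
        for g, pos in self.entries:
            if g == gene:
                return pos
        return frozenset()

    @property
    def genes(self) -> set[str]:
        return {g for g, _ in self.entries}


def failing_rules(v: AnnotatedVariant, config: FilterConfig) -> tuple[str, ...]:
    """All exclusion rules the variant fails, in the fixed reporting order."""
    failed = []
    if any(
        v.pop_af.get(db, 0.0) > config.max_pop_af for db in config.population_dbs
    ):
        failed.append("pop_af")
    if config.drop_oxog and v.oxog_flag:
        failed.append("oxog")
    if v.alt_count < config.min_alt_count:
        failed.append("alt_count")
    if v.depth < config.min_depth:
        failed.append("depth")
    if v.vaf < config.min_vaf:
        failed.append("vaf")
    return tuple(failed)


def apply_filters(
    variants: Sequence[AnnotatedVariant],
    config: FilterConfig = FilterConfig(),
) -> tuple[list[AnnotatedVariant], FilterReport]:
    """Apply all exclusion rules; return (passing, report).

    A variant is removed at most once, attributed to the first failing rule.
    """
    passing: list[AnnotatedVariant] = []
    report = FilterReport(n_input=len(variants), n_passing=0)
    for v in variants:
        failed = failing_rules(v, config)
        if failed:
            report.removed_by_rule[failed[0]] += 1
            report.removed.append((v.key, failed[0]))
        else:
            passing.append(v)
    report.n_passing = len(passing)
    return passing, report


_PROTEIN_POS = re.compile(r"^(?:p\.)?\(?[A-Za-z*]{1,3}(\d+)")


def protein_position(protein_change: str) -> int | None:
    """Extract the residue number from an HGVS-p style string (``G12D`` → 12)."""
    m = _PROTEIN_POS.match(protein_change or "")
    return int(m.group(1)) if m else None


def hotspot_review(
    all_called: Sequence[AnnotatedVariant],
    passing: Sequence[AnnotatedVariant],
    hotspots: HotspotList = HotspotList(),
    config: FilterConfig = FilterConfig(),
) -> list[AnnotatedVariant]:
    """Flag hotspot variants removed solely by the VAF rule, for human review.

    Never rescues automatically; downstream code must decide explicitly.
    Returns an empty list (with a warning) if no called variant carries a
    hotspot gene symbol at all.
    """
    passing_keys = {v.key for v in passing}
    seen_genes = {v.gene for v in all_called if v.gene}
    for gene in hotspots.genes - seen_genes:
        logger.warning("hotspot gene %s never appears in the callset", gene)
    flagged = []
    for v in all_called:
        if v.key in passing_keys or v.gene not in hotspots.genes:
            continue
        pos = protein_position(v.protein_change)
        if pos is None or pos not in hotspots.positions(v.gene):
            continue
        if failing_rules(v, config) == ("vaf",):
            flagged.append(v)
    return flagged
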