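"""Clonality classification, intra-tumor heterogeneity and Jaccard similarity.

The substrate is a per-patient binary *presence matrix*: rows are tumor
regions, columns are variant keys, a cell is 1 iff the variant passed
filtering in that region.  A mutation present in all R regions is *truncal*,
in exactly one region *private*, otherwise *branch*.  The ITH index is the
percentage of mutations that are not truncal:

    ITH = 100 · (n_branch + n_private) / V,

undefined (reported "N/A") when a patient has no truncal mutation at all —
disjoint region sets indicate independent tumors, not 100% heterogeneity.

Pairwise region similarity is the Jaccard coefficient |A∩B| / |A∪B| over the
regions' variant-key sets; per-patient medians are taken over the unique
off-diagonal pairs.  Reported values round half-to-even (2 decimals for
Jaccard, 1 for ITH); full precision is kept internally.  The cohort ITH
median is taken over the per-patient indices *as reported* at one decimal,
matching how such tables are assembled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np

from .rounding import round_half_even
from .variants import RegionCallset, VariantKey

__all__ = [
    "PresenceMatrix",
    "ClonalityTable",
    "JaccardMatrix",
    "RelatednessConfig",
    "RelatednessVerdict",
    "DEFAULT_DRIVER_GENES",
    "build_presence_matrix",
    "classify_mutations",
    "jaccard_matrix",
    "cohort_ith_median",
    "assess_relatedness",
]

DEFAULT_DRIVER_GENES = ("KRAS", "NKX2-1", "TP53", "ARID1A")


@dataclass
class PresenceMatrix:
    patient_id: str
    region_labels: list[str]
    variant_keys: list[VariantKey]
    cells: np.ndarray  # (R, V) uint8

    def __post_init__(self) -> None:
        r, v = self.cells.shape
        if r != len(self.region_labels) or v != len(self.variant_keys):
            raise ValueError("cells shape disagrees with labels/keys")
        if len(set(self.region_labels)) != r:
            raise ValueError("duplicate region labels")
        if len(set(self.variant_keys)) != v:
            raise ValueError("duplicate variant keys")
        if v and (self.cells.sum(axis=0) == 0).any():
            raise ValueError("presence matrix has an all-zero column")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    def row_set(self, label: str) -> set[VariantKey]:
        i = self.region_labels.index(label)
        return {k for k, c in zip(self.variant_keys, self.cells[i]) if c}


@dataclass
class ClonalityTable:
    patient_id: str
    classes: dict[VariantKey, str]  # truncal | branch | private
    n_truncal: int
    n_branch: int
    n_private: int

    @property
    def n_total(self) -> int:
        return self.n_truncal + self.n_branch + self.n_private

    @property
    def ith_percent(self) -> float | None:
        """Full-precision ITH index; None when no truncal mutation exists."""
        if self.n_truncal == 0:
            return None
        return 100.0 * (self.n_branch + self.n_private) / self.n_total

    @property
    def ith_percent_reported(self) -> float | None:
        p = self.ith_percent
        return None if p is None else round_half_even(p, 1)


@dataclass
class JaccardMatrix:
    patient_id: str
    region_labels: list[str]
    values: np.ndarray  # (R, R) float, NaN where undefined
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def pair(self, a: str, b: str) -> float:
        i, j = self.region_labels.index(a), self.region_labels.index(b)
        return float(self.values[i, j])

    @property
    def upper_triangle(self) -> list[float]:
        r = len(self.region_labels)
        return [float(self.values[i, j]) for i in range(r) for j in range(i + 1, r)]

    @property
    def median(self) -> float:
        vals = [v for v in self.upper_triangle if not math.isnan(v)]
        if not vals:
            raise ValueError("no defined region pairs")
        return float(median(vals))

    @property
    def median_reported(self) -> float:
        return round_half_even(self.median, 2)


@dataclass(frozen=True)
class RelatednessConfig:
    unrelated_max: float = 0.05
    related_min: float = 0.15


@dataclass
class RelatednessVerdict:
    patient_id: str
    verdicts: dict[tuple[str, str], str]  # sorted label pair -> verdict
    evidence: dict[tuple[str, str], tuple[float, list[VariantKey]]]

    def pair(self, a: str, b: str) -> str:
        return self.verdicts[tuple(sorted((a, b)))]


def build_presence_matrix(callsets: Sequence[RegionCallset]) -> PresenceMatrix:
    """Union the regions' variant keys into an R×V binary matrix.

    Columns are ordered by first appearance across regions (manifest order),
    which keeps output deterministic without imposing a genomic sort.
    """
    if len(callsets) < 2:
        raise ValueError("clonality requires at least two regions")
    patients = {c.patient_id for c in callsets}
    if len(patients) != 1:
        raise ValueError(f"callsets span multiple patients: {sorted(patients)}")
    keys: list[VariantKey] = []
    seen = set()
    for cs in callsets:
        for v in cs.variants:
            if v.key not in seen:
                seen.add(v.key)
                keys.append(v.key)
    index = {k: j for j, k in enumerate(keys)}
    cells = np.zeros((len(callsets), len(keys)), dtype=np.uint8)
    for i, cs in enumerate(callsets):
        for k in cs.keys:
            cells[i, index[k]] = 1
    return PresenceMatrix(
        patient_id=callsets[0].patient_id,
        region_labels=[c.region_label for c in callsets],
        variant_keys=keys,
        cells=cells,
    )


def classify_mutations(matrix: PresenceMatrix) -> ClonalityTable:
    """Assign truncal / branch / private classes from region presence counts."""
    r = matrix.n_regions
    counts = matrix.cells.sum(axis=0)
    classes: dict[VariantKey, str] = {}
    for key, c in zip(matrix.variant_keys, counts):
        if c == r:
            classes[key] = "truncal"
        elif c == 1:
            classes[key] = "private"
        else:
            classes[key] = "branch"
    vals = list(classes.values())
    return ClonalityTable(
        patient_id=matrix.patient_id,
        classes=classes,
        n_truncal=vals.count("truncal"),
        n_branch=vals.count("branch"),
        n_private=vals.count("private"),
    )


def jaccard_matrix(matrix: PresenceMatrix) -> JaccardMatrix:
    """Pairwise Jaccard similarity over the regions' variant sets.

    A pair with an empty union has no defined similarity; its entry is NaN
    and the pair is flagged.  The diagonal is 1 for non-empty regions.
    """
    r = matrix.n_regions
    cells = matrix.cells.astype(bool)
    values = np.ones((r, r), dtype=float)
    undefined: list[tuple[str, str]] = []
    for i in range(r):
        if not cells[i].any():
            values[i, i] = math.nan
    for i in range(r):
        for j in range(i + 1, r):
            union = int((cells[i] | cells[j]).sum())
            if union == 0:
                values[i, j] = values[j, i] = math.nan
                undefined.append(
                    tuple(sorted((matrix.region_labels[i], matrix.region_labels[j])))
                )
            else:
                inter = int((cells[i] & cells[j]).sum())
                values[i, j] = values[j, i] = inter / union
    return JaccardMatrix(
        patient_id=matrix.patient_id,
        region_labels=list(matrix.region_labels),
        values=values,
        undefined_pairs=undefined,
    )


def cohort_ith_median(tables: Iterable[ClonalityTable | float]) -> float:
    """Median ITH index across patients, reported at one decimal.

    Accepts ClonalityTables (patients with undefined ITH are excluded) or
    bare percentage values.  Each patient enters at its 1-decimal reported
    value, the same precision at which per-patient indices are published;
    the median of an even count is the mean of the two middle values.
    """
    vals: list[float] = []
    for t in tables:
        if isinstance(t, ClonalityTable):
            p = t.ith_percent_reported
            if p is not None:
                vals.append(p)
        else:
            vals.append(round_half_even(float(t), 1))
    if not vals:
        raise ValueError("no patient has a defined ITH index")
    return round_half_even(float(median(vals)), 1)


def assess_relatedness(
    matrix: PresenceMatrix,
    jaccard: JaccardMatrix,
    driver_genes: Sequence[str] = DEFAULT_DRIVER_GENES,
    config: RelatednessConfig = RelatednessConfig(),
    gene_map: Mapping[VariantKey, str] | None = None,
) -> RelatednessVerdict:
    """Classify each region pair as clonally related / unrelated / indeterminate.

    A pair is *unrelated* iff its Jaccard similarity is ≤ ``unrelated_max``
    AND the two regions share no identical driver-gene variant; *related* iff
    Jaccard ≥ ``related_min`` OR they share at least one identical driver
    variant; otherwise *indeterminate*.  ``gene_map`` maps variant keys to
    gene symbols (absent → no driver evidence available).
    """
    gene_map = gene_map or {}
    driver_set = set(driver_genes)
    row_sets = {lab: matrix.row_set(lab) for lab in matrix.region_labels}
    verdicts: dict[tuple[str, str], str] = {}
    evidence: dict[tuple[str, str], tuple[float, list[VariantKey]]] = {}
    labels = matrix.region_labels
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            pair = tuple(sorted((a, b)))
            jac = jaccard.pair(a, b)
            shared_drivers = sorted(
                k for k in row_sets[a] & row_sets[b] if gene_map.get(k) in driver_set
            )
            if shared_drivers or (not math.isnan(jac) and jac >= config.related_min):
                verdict = "related"
            elif not math.isnan(jac) and jac <= config.unrelated_max:
                verdict = "unrelated"
            else:
                verdict = "indeterminate"
            verdicts[pair] = verdict
            evidence[pair] = (jac, shared_drivers)
    return RelatednessVerdict(matrix.patient_id, verdicts, evidence)
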