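"""Synthetic multi-region cohorts with full ground truth.

The generator emulates the design of a multi-region whole-exome study of
multifocal invasive mucinous adenocarcinoma: seven patients with 2–5
regions each (24 regions in total), tens of truncal / branch / private
mutations per patient, signature-driven trinucleotide contexts, binomial
depth/VAF noise under a stated purity at ~200× mean depth, and an optional
clonally-unrelated "double primary" structure in which two anatomical
groups share zero variants.

Each simulated patient has a random bifurcating region topology per group;
trunk variants occur in every region of their group, branch variants in the
regions of one internal clade, private variants in a single region.  Every
SNV's channel is drawn from the region group's true signature mixture and
materialized as concrete ref/alt/context (with random strand, so the
pyrimidine collapse is exercised).  Per-region read evidence is
depth ~ Poisson(mean_depth), alt ~ Binomial(depth, purity·CCF/2).  Cancer
cell fraction is 1 for the trunk and configurable for branches; VAF noise
exists to exercise the filters, not to model subclonal structure.
Population-frequency and OxoG artifact contaminants are injected at
configurable per-region counts so the filters have true positives.

Everything is deterministic given the seed, and the emitted files are
byte-identical across reruns.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .signatures import CHANNELS_96, SignatureCatalog, load_default_catalog
from .variants import AnnotatedVariant, RegionCallset, VariantKey, revcomp, write_variant_table

__all__ = [
    "DriverSpec",
    "PatientSpec",
    "SimConfig",
    "TruthVariant",
    "PatientTruth",
    "CohortTruth",
    "simulate_cohort",
    "degrade_presence",
    "study_default",
]


@dataclass(frozen=True)
class DriverSpec:
    gene: str
    protein_change: str
    clone: str = "trunk"  # only trunk drivers are supported
    group: str | None = None  # restrict to one anatomical group
    consequence: str = "missense"


@dataclass
class PatientSpec:
    patient_id: str
    region_labels: list[str]
    n_truncal: int
    n_branch: int
    n_private_per_region: int
    exposures: dict[str, float]
    purity: float = 0.4
    mean_depth: float = 200.0
    callable_mb: float = 40.0
    double_primary: bool = False
    groups: dict[str, str] | None = None  # region label -> group tag
    drivers: list[DriverSpec] = field(default_factory=list)
    ccf_branch: float = 1.0
    indel_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 2 <= len(self.region_labels) <= 5:
            raise ValueError("patients have 2–5 regions")
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("duplicate region labels")
        if min(self.n_truncal, self.n_branch, self.n_private_per_region) < 0:
            raise ValueError("negative mutation counts")
        w = sum(self.exposures.values())
        if abs(w - 1.0) > 1e-8:
            raise ValueError(f"exposure weights sum to {w}, expected 1")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must lie in (0, 1]")
        if self.double_primary:
            if not self.groups:
                raise ValueError("double_primary requires a region→group mapping")
            tags = set(self.groups.values())
            if len(tags) != 2:
                raise ValueError("double_primary requires exactly two groups")
            if set(self.groups) != set(self.region_labels):
                raise ValueError("groups must cover every region")
        elif self.groups is None:
            self.groups = {lab: "tumor" for lab in self.region_labels}

    def group_regions(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for lab in self.region_labels:
            out.setdefault(self.groups[lab], []).append(lab)
        return out


@dataclass
class SimConfig:
    seed: int
    patients: list[PatientSpec]
    n_popaf_per_region: int = 3
    n_oxog_per_region: int = 3
    dialect: str = "tsv"
    catalog: SignatureCatalog | None = None  # default packaged catalog


@dataclass(frozen=True)
class TruthVariant:
    key: VariantKey
    clone: str  # trunk[:group] | branch:<clade> | private:<region> | artifact_*
    channel: str | None  # None for indels/artifacts without channel draw
    regions: tuple[str, ...]


@dataclass
class PatientTruth:
    patient_id: str
    variants: list[TruthVariant]
    trees: dict[str, str]  # group -> newick of the generating topology
    exposures: dict[str, dict[str, float]]  # region -> signature weights
    purity: dict[str, float]

    def somatic_keys(self, region: str) -> set[VariantKey]:
        return {
            t.key
            for t in self.variants
            if region in t.regions and not t.clone.startswith("artifact")
        }

    def keys_by_clone_class(self) -> dict[str, set[VariantKey]]:
        out: dict[str, set[VariantKey]] = {"trunk": set(), "branch": set(), "private": set()}
        for t in self.variants:
            base = t.clone.split(":", 1)[0]
            if base in out:
                out[base].add(t.key)
        return out


@dataclass
class CohortTruth:
    patients: dict[str, PatientTruth]


# ---------------------------------------------------------------------------
# topology helpers
# ---------------------------------------------------------------------------


def _random_topology(labels: Sequence[str], rng: np.random.Generator):
    """Random bifurcating nesting of labels, as nested 2-tuples."""
    items: list = list(labels)
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        merged = (items[i], items[j])
        items = [x for k, x in enumerate(items) if k not in (i, j)] + [merged]
    return items[0]


def _clades(node, acc: list[tuple[str, ...]]) -> tuple[str, ...]:
    if isinstance(node, str):
        return (node,)
    left = _clades(node[0], acc)
    right = _clades(node[1], acc)
    clade = tuple(sorted(left + right))
    acc.append(clade)
    return clade


def _to_newick(node) -> str:
    if isinstance(node, str):
        return node
    return f"({_to_newick(node[0])},{_to_newick(node[1])})"


# ---------------------------------------------------------------------------
# variant materialization
# ---------------------------------------------------------------------------

_CONSEQUENCE_CHOICES = ("missense", "synonymous", "nonsense", "splice", "noncoding")
_CONSEQUENCE_PROBS = (0.55, 0.20, 0.05, 0.05, 0.15)
_BASES = "ACGT"


class _PositionPool:
    """Unique genomic positions within one patient."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.used: set[int] = set()

    def draw(self) -> tuple[str, int]:
        while True:
            pos = int(self.rng.integers(1_000_000, 200_000_000))
            if pos not in self.used:
                self.used.add(pos)
                chrom = f"chr{int(self.rng.integers(1, 23))}"
                return chrom, pos


def _snv_from_channel(channel: str, rng: np.random.Generator, pool: _PositionPool):
    five, rest = channel[0], channel[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    context = five + ref + three
    if rng.random() < 0.5:  # emit on the purine strand to exercise collapsing
        context = revcomp(context)
        ref, alt = revcomp(ref), revcomp(alt)
    chrom, pos = pool.draw()
    return chrom, pos, ref, alt, context


def _indel(rng: np.random.Generator, pool: _PositionPool):
    chrom, pos = pool.draw()
    base = _BASES[rng.integers(4)]
    ins = _BASES[rng.integers(4)]
    if rng.random() < 0.5:
        return chrom, pos, base, base + ins, "INS"
    return chrom, pos, base + ins, base, "DEL"


def _evidence(rng: np.random.Generator, mean_depth: float, purity: float, ccf: float):
    depth = max(int(rng.poisson(mean_depth)), 1)
    alt = int(rng.binomial(depth, purity * ccf / 2))
    return alt, depth, alt / depth


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def _simulate_patient(
    spec: PatientSpec,
    rng: np.random.Generator,
    catalog: SignatureCatalog,
    n_popaf: int,
    n_oxog: int,
) -> tuple[dict[str, list[AnnotatedVariant]], PatientTruth]:
    pool = _PositionPool(rng)
    w = np.array([spec.exposures.get(sid, 0.0) for sid in catalog.signature_ids])
    mixture = catalog.matrix @ w
    mixture = mixture / mixture.sum()

    region_variants: dict[str, list[AnnotatedVariant]] = {
        lab: [] for lab in spec.region_labels
    }
    truth: list[TruthVariant] = []
    trees: dict[str, str] = {}

    def emit(
        regions: Sequence[str],
        clone: str,
        *,
        ccf: float = 1.0,
        gene: str = "",
        protein_change: str = "",
        consequence: str | None = None,
        force_snv: bool = False,
        pop_af: dict[str, float] | None = None,
        oxog: bool = False,
    ) -> None:
        is_indel = (
            not force_snv and not oxog and pop_af is None
            and rng.random() < spec.indel_fraction
        )
        channel: str | None = None
        if is_indel:
            chrom, pos, ref, alt, vclass = _indel(rng, pool)
            context = None
            csq = consequence or ("frameshift" if len(ref) != len(alt) else "inframe_indel")
            if csq == "missense":
                csq = "frameshift"
        else:
            channel = CHANNELS_96[int(rng.choice(96, p=mixture))]
            chrom, pos, ref, alt, context = _snv_from_channel(channel, rng, pool)
            csq = consequence or str(
                rng.choice(_CONSEQUENCE_CHOICES, p=_CONSEQUENCE_PROBS)
            )
        for lab in regions:
            alt_count, depth, vaf = _evidence(rng, spec.mean_depth, spec.purity, ccf)
            region_variants[lab].append(
                AnnotatedVariant(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=gene,
                    protein_change=protein_change,
                    consequence=csq,
                    alt_count=alt_count,
                    depth=depth,
                    vaf=vaf,
                    pop_af=dict(pop_af or {}),
                    oxog_flag=oxog,
                    context3=context,
                )
            )
        truth.append(
            TruthVariant(
                key=VariantKey(chrom, pos, ref.upper(), alt.upper()),
                clone=clone,
                channel=channel,
                regions=tuple(regions),
            )
        )

    groups = spec.group_regions()
    n_groups = len(groups)
    for tag, labels in sorted(groups.items()):
        topo = _random_topology(labels, rng) if len(labels) > 1 else labels[0]
        trees[tag] = _to_newick(topo) + ";"
        clades: list[tuple[str, ...]] = []
        if len(labels) > 1:
            acc: list[tuple[str, ...]] = []
            _clades(topo, acc)
            clades = [c for c in acc if 1 < len(c) < len(labels)]

        trunk_tag = f"trunk:{tag}" if n_groups > 1 else "trunk"
        trunk_drivers = [
            d
            for d in spec.drivers
            if d.clone == "trunk" and (d.group is None or d.group == tag)
        ]
        if len(trunk_drivers) > spec.n_truncal:
            raise ValueError("more trunk drivers than truncal mutations")
        for d in trunk_drivers:
            emit(
                labels,
                trunk_tag,
                gene=d.gene,
                protein_change=d.protein_change,
                consequence=d.consequence,
                force_snv=True,
            )
        for _ in range(spec.n_truncal - len(trunk_drivers)):
            emit(labels, trunk_tag)

        if spec.n_branch and not clades:
            raise ValueError(
                f"patient {spec.patient_id}: branch mutations requested but the "
                f"{len(labels)}-region group {tag!r} has no proper clade"
            )
        for _ in range(spec.n_branch if len(groups) == 1 else 0):
            clade = clades[int(rng.integers(len(clades)))]
            emit(list(clade), f"branch:{'+'.join(clade)}", ccf=spec.ccf_branch)
        for lab in labels:
            for _ in range(spec.n_private_per_region):
                emit([lab], f"private:{lab}", ccf=spec.ccf_branch)

    # artifact contaminants, region-private, to give the filters work
    for lab in spec.region_labels:
        for _ in range(n_popaf):
            emit([lab], "artifact_popaf", pop_af={"gnomAD": 0.05}, force_snv=True)
        for _ in range(n_oxog):
            emit([lab], "artifact_oxog", oxog=True, force_snv=True)

    ptruth = PatientTruth(
        patient_id=spec.patient_id,
        variants=truth,
        trees=trees,
        exposures={lab: dict(spec.exposures) for lab in spec.region_labels},
        purity={lab: spec.purity for lab in spec.region_labels},
    )
    return region_variants, ptruth


def simulate_cohort(
    config: SimConfig, outdir: str | os.PathLike
) -> tuple[Path, CohortTruth]:
    """Write a synthetic cohort (region files + manifest + truth tables).

    Returns the manifest path and the in-memory ground truth.  Deterministic
    and byte-identical given the same config and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    catalog = config.catalog or load_default_catalog()

    manifest_rows = []
    truth_var_rows = []
    truth_region_rows = []
    truth_tree_rows = []
    patients: dict[str, PatientTruth] = {}
    ext = "vcf" if config.dialect == "vcf" else "tsv"

    for spec in config.patients:
        region_variants, ptruth = _simulate_patient(
            spec, rng, catalog, config.n_popaf_per_region, config.n_oxog_per_region
        )
        patients[spec.patient_id] = ptruth
        pdir = outdir / spec.patient_id
        pdir.mkdir(exist_ok=True)
        for lab in spec.region_labels:
            fname = f"{spec.patient_id}_{lab}.{ext}"
            write_variant_table(region_variants[lab], pdir / fname, dialect=config.dialect)
            manifest_rows.append(
                {
                    "patient_id": spec.patient_id,
                    "region_label": lab,
                    "path": f"{spec.patient_id}/{fname}",
                    "callable_mb": repr(spec.callable_mb),
                    "purity": repr(spec.purity),
                    "group": spec.groups[lab],
                }
            )
            truth_region_rows.append(
                {
                    "patient_id": spec.patient_id,
                    "region_label": lab,
                    "purity": repr(spec.purity),
                    "exposures": "|".join(
                        f"{sid}:{wt!r}" for sid, wt in sorted(spec.exposures.items())
                    ),
                }
            )
        for t in ptruth.variants:
            truth_var_rows.append(
                {
                    "patient_id": spec.patient_id,
                    "chrom": t.key.chrom,
                    "pos": t.key.pos,
                    "ref": t.key.ref,
                    "alt": t.key.alt,
                    "clone": t.clone,
                    "channel": t.channel or "",
                    "regions": ";".join(t.regions),
                }
            )
        for tag, nwk in sorted(ptruth.trees.items()):
            truth_tree_rows.append(
                {"patient_id": spec.patient_id, "group": tag, "newick": nwk}
            )

    manifest_path = outdir / "manifest.tsv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, sep="\t", index=False)
    pd.DataFrame(truth_var_rows).to_csv(outdir / "truth_variants.tsv", sep="\t", index=False)
    pd.DataFrame(truth_region_rows).to_csv(outdir / "truth_regions.tsv", sep="\t", index=False)
    pd.DataFrame(truth_tree_rows).to_csv(outdir / "truth_trees.tsv", sep="\t", index=False)
    return manifest_path, CohortTruth(patients=patients)


def degrade_presence(
    callsets: Sequence[RegionCallset], dropout_rate: float, seed: int
) -> list[RegionCallset]:
    """Delete each variant-region presence independently with the given rate.

    Models false-negative dropout (e.g. low purity or coverage holes); a
    rate of 0 is the identity.  Deterministic given the seed.
    """
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out = []
    for cs in callsets:
        kept = [v for v in cs.variants if rng.random() >= dropout_rate]
        out.append(
            RegionCallset(
                patient_id=cs.patient_id,
                region_label=cs.region_label,
                variants=kept,
                callable_mb=cs.callable_mb,
                purity=cs.purity,
                group=cs.group,
            )
        )
    return out


def study_default(seed: int = 0) -> SimConfig:
    """The default study-scale cohort: 7 patients, 24 regions.

    Region geometry, truncal/branch/private counts and the double-primary
    patient mirror the multifocal IMA study design the package emulates:
    one 5-region patient with a 50% ITH index, a 2-region patient whose two
    lobes are clonally unrelated (zero shared variants, its own trunk per
    lobe), and per-patient signature mixtures dominated by the endogenous
    clock-like process with APOBEC, MMR-deficiency and a trace of the
    smoking signature in individual patients.
    """
    patients = [
        PatientSpec(
            "SIM01",
            ["RUL", "RML", "RLL", "LUL", "LLL"],
            n_truncal=37,
            n_branch=17,
            n_private_per_region=4,
            exposures={"1": 0.5, "5": 0.2, "2": 0.15, "13": 0.15},
            drivers=[
                DriverSpec("KRAS", "G12D"),
                DriverSpec("NKX2-1", "M360T"),
                DriverSpec("TP53", "L35F"),
            ],
        ),
        PatientSpec(
            "SIM03",
            ["RLL1", "RLL2", "RLL3"],
            n_truncal=31,
            n_branch=12,
            n_private_per_region=6,
            exposures={"1": 0.6, "5": 0.4},
            drivers=[DriverSpec("KRAS", "G12V")],
        ),
        PatientSpec(
            "SIM04",
            ["RLL", "RUL1", "RUL2"],
            n_truncal=24,
            n_branch=52,
            n_private_per_region=20,
            exposures={"1": 0.5, "2": 0.25, "13": 0.25},
            drivers=[DriverSpec("KRAS", "G12D")],
        ),
        PatientSpec(
            "SIM05",
            ["RLL1", "RLL2", "RLL3"],
            n_truncal=36,
            n_branch=26,
            n_private_per_region=14,
            exposures={"1": 0.55, "6": 0.45},
            drivers=[DriverSpec("KRAS", "Q61H"), DriverSpec("ARID1A", "R1461S")],
        ),
        PatientSpec(
            "SIM06",
            ["RUL", "RML", "LUL", "LN"],
            n_truncal=25,
            n_branch=38,
            n_private_per_region=10,
            exposures={"1": 0.6, "5": 0.3, "4": 0.1},
            drivers=[DriverSpec("KRAS", "G12V"), DriverSpec("TP53", "R273H")],
        ),
        PatientSpec(
            "SIM07",
            ["LLL", "RLL"],
            n_truncal=21,
            n_branch=0,
            n_private_per_region=0,
            exposures={"1": 0.7, "5": 0.3},
            double_primary=True,
            groups={"LLL": "left", "RLL": "right"},
            drivers=[DriverSpec("KRAS", "G12D", group="right")],
        ),
        PatientSpec(
            "SIM08",
            ["LLL1", "LLL2", "LLL3", "LLL4"],
            n_truncal=17,
            n_branch=21,
            n_private_per_region=5,
            exposures={"1": 0.5, "5": 0.3, "15": 0.1, "17": 0.1},
            drivers=[DriverSpec("KRAS", "G12S")],
        ),
    ]
    return SimConfig(seed=seed, patients=patients)
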