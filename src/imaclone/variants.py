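"""Reading, writing and in-memory model of annotated somatic variant calls.

Two interchange dialects are supported:

* ``tsv`` — a MAF-like tab-separated table with the fixed column set
  :data:`TSV_COLUMNS` (documented below); this is the native format of the
  simulator and the pipeline outputs.
* ``vcf`` — VCF 4.2 with one tumor sample column.  Per-sample ``AD``/``DP``
  carry the evidence counts; the annotations travel in INFO keys ``GENE``,
  ``PCH`` (HGVS-p), ``CSQ`` (consequence class), ``PAF`` (population allele
  frequencies as ``db:af|db:af``), ``OXOG`` (artifact flag), ``CTX3``
  (3-mer reference context) and ``VAFP`` (full-precision VAF as a string,
  so that write∘read round-trips exactly).

Coordinates are 1-based and fully closed everywhere.  Variant identity across
regions is the exact ``(chrom, pos, ref, alt)`` tuple — no fuzzy matching of
nearby indels, and chromosome names are taken verbatim (``chr1`` ≠ ``1``;
``load_cohort`` accepts an optional rename map for harmonization).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

__all__ = [
    "VariantKey",
    "AnnotatedVariant",
    "RegionCallset",
    "ManifestEntry",
    "CohortManifest",
    "TSV_COLUMNS",
    "read_variant_table",
    "write_variant_table",
    "read_manifest",
    "load_cohort",
    "SchemaError",
    "VariantTableError",
    "ManifestError",
]

VARIANT_CLASSES = ("SNV", "INS", "DEL")
CONSEQUENCES = (
    "missense",
    "nonsense",
    "frameshift",
    "inframe_indel",
    "splice",
    "synonymous",
    "noncoding",
    "other",
)

#: Fixed column order of the MAF-like TSV dialect.
TSV_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_class",
    "gene",
    "protein_change",
    "consequence",
    "alt_count",
    "depth",
    "vaf",
    "pop_af",
    "oxog_flag",
    "context3",
)


class SchemaError(ValueError):
    """A required column or field is missing from an input file."""


class VariantTableError(ValueError):
    """A variant file is malformed; the message names the offending line."""


class ManifestError(ValueError):
    """The cohort manifest violates its invariants."""


class VariantKey(NamedTuple):
    """Exact cross-region identity of a somatic variant."""

    chrom: str
    pos: int
    ref: str
    alt: str


def infer_variant_class(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref):
        return "INS"
    if len(ref) > len(alt):
        return "DEL"
    raise ValueError(f"unsupported allele pair (MNV?): {ref}>{alt}")


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AnnotatedVariant:
    """One annotated somatic call in one tumor region.

    ``pop_af`` maps database name → allele frequency; an absent entry means
    "not observed in that database", never 0.  ``context3`` is the 3-mer
    reference context centered on ``pos`` (SNVs only).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str = ""
    gene: str = ""
    protein_change: str = ""
    consequence: str = "other"
    alt_count: int = 0
    depth: int = 0
    vaf: float = 0.0
    pop_af: dict[str, float] = field(default_factory=dict)
    oxog_flag: bool = False
    context3: str | None = None

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        inferred = infer_variant_class(self.ref, self.alt)
        if not self.variant_class:
            self.variant_class = inferred
        elif self.variant_class != inferred:
            raise ValueError(
                f"variant_class {self.variant_class!r} inconsistent with alleles "
                f"{self.ref}>{self.alt} (expected {inferred})"
            )
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence class {self.consequence!r}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")
        if self.alt_count < 0 or self.depth < 0:
            raise ValueError("negative read counts")
        if self.depth > 0 and self.alt_count > self.depth:
            raise ValueError("alt_count exceeds depth")
        # evidence consistency within rounding of one read
        if self.depth > 0 and self.vaf > 0 and self.alt_count > 0:
            if abs(self.vaf * self.depth - self.alt_count) > 1.0 + 1e-6:
                raise ValueError(
                    f"vaf·depth = {self.vaf * self.depth:.2f} disagrees with "
                    f"alt_count = {self.alt_count} by more than one read"
                )
        for db, af in self.pop_af.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"pop_af[{db}] = {af} outside [0, 1]")
        if self.context3 is not None:
            if len(self.context3) != 3:
                raise ValueError(f"context3 {self.context3!r} is not a 3-mer")
            self.context3 = self.context3.upper()
            if self.variant_class == "SNV" and self.context3[1] != self.ref:
                raise ValueError(
                    f"context3 middle base {self.context3[1]} != ref {self.ref}"
                )

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)


@dataclass
class RegionCallset:
    """All passing variants for one tumor region of one patient."""

    patient_id: str
    region_label: str
    variants: list[AnnotatedVariant]
    callable_mb: float
    purity: float | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if self.callable_mb <= 0:
            raise ValueError("callable_mb must be positive")
        if self.purity is not None and not 0 < self.purity <= 1:
            raise ValueError("purity must lie in (0, 1]")
        keys = [v.key for v in self.variants]
        if len(keys) != len(set(keys)):
            raise ValueError(
                f"duplicate variant keys in {self.patient_id}/{self.region_label}"
            )

    @property
    def keys(self) -> set[VariantKey]:
        return {v.key for v in self.variants}


@dataclass(frozen=True)
class ManifestEntry:
    patient_id: str
    region_label: str
    path: str
    callable_mb: float
    purity: float | None = None
    group: str | None = None


@dataclass
class CohortManifest:
    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        pairs = [(e.patient_id, e.region_label) for e in self.entries]
        dupes = {p for p in pairs if pairs.count(p) > 1}
        if dupes:
            raise ManifestError(f"duplicate (patient, region) pairs: {sorted(dupes)}")
        if not self.entries:
            raise ManifestError("manifest has no entries")


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------


def _encode_pop_af(pop_af: Mapping[str, float]) -> str:
    for db in pop_af:
        if any(c in db for c in "=;:|"):
            raise ValueError(f"population database name {db!r} contains a delimiter")
    return ";".join(f"{db}={af!r}" for db, af in pop_af.items())


def _decode_pop_af(text: str) -> dict[str, float]:
    if not text:
        return {}
    out: dict[str, float] = {}
    for item in text.split(";"):
        db, _, af = item.partition("=")
        out[db] = float(af)
    return out


def _variant_to_row(v: AnnotatedVariant) -> dict[str, str]:
    return {
        "chrom": v.chrom,
        "pos": str(v.pos),
        "ref": v.ref,
        "alt": v.alt,
        "variant_class": v.variant_class,
        "gene": v.gene,
        "protein_change": v.protein_change,
        "consequence": v.consequence,
        "alt_count": str(v.alt_count),
        "depth": str(v.depth),
        "vaf": repr(float(v.vaf)),
        "pop_af": _encode_pop_af(v.pop_af),
        "oxog_flag": "1" if v.oxog_flag else "0",
        "context3": v.context3 or "",
    }


def _row_to_variant(row: Mapping[str, str]) -> AnnotatedVariant:
    return AnnotatedVariant(
        chrom=row["chrom"],
        pos=int(row["pos"]),
        ref=row["ref"],
        alt=row["alt"],
        variant_class=row["variant_class"],
        gene=row["gene"],
        protein_change=row["protein_change"],
        consequence=row["consequence"] or "other",
        alt_count=int(row["alt_count"]),
        depth=int(row["depth"]),
        vaf=float(row["vaf"]),
        pop_af=_decode_pop_af(row["pop_af"]),
        oxog_flag=row["oxog_flag"] in ("1", "True", "true"),
        context3=row["context3"] or None,
    )


def _read_tsv(path: Path) -> list[AnnotatedVariant]:
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pandas raises several parser error types
        raise VariantTableError(f"{path}: cannot parse TSV: {exc}") from exc
    missing = [c for c in TSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    variants: list[AnnotatedVariant] = []
    for i, row in enumerate(frame.to_dict("records")):
        try:
            variants.append(_row_to_variant(row))
        except (ValueError, KeyError) as exc:
            # header is line 1, first data row is line 2
            raise VariantTableError(f"{path}: line {i + 2}: {exc}") from exc
    return variants


def _write_tsv(variants: Sequence[AnnotatedVariant], path: Path) -> None:
    frame = pd.DataFrame([_variant_to_row(v) for v in variants], columns=list(TSV_COLUMNS))
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF dialect
# ---------------------------------------------------------------------------

_VCF_HEADER_META = [
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=PCH,Number=1,Type=String,Description="HGVS-p protein change">',
    '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">',
    '##INFO=<ID=PAF,Number=1,Type=String,Description="Population allele frequencies db:af|db:af">',
    '##INFO=<ID=OXOG,Number=0,Type=Flag,Description="8-oxoguanine artifact flag">',
    '##INFO=<ID=CTX3,Number=1,Type=String,Description="3-mer reference context">',
    '##INFO=<ID=VAFP,Number=1,Type=String,Description="Variant allele fraction, full precision">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
]


def _write_vcf(variants: Sequence[AnnotatedVariant], path: Path, sample: str = "TUMOR") -> None:
    chroms: list[str] = []
    for v in variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines += _VCF_HEADER_META
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    for v in variants:
        info = []
        if v.gene:
            info.append(f"GENE={v.gene}")
        if v.protein_change:
            info.append(f"PCH={v.protein_change}")
        info.append(f"CSQ={v.consequence}")
        if v.pop_af:
            info.append("PAF=" + "|".join(f"{db}:{af!r}" for db, af in v.pop_af.items()))
        if v.oxog_flag:
            info.append("OXOG")
        if v.context3:
            info.append(f"CTX3={v.context3}")
        info.append(f"VAFP={float(v.vaf)!r}")
        ref_count = max(v.depth - v.alt_count, 0)
        lines.append(
            "\t".join(
                [
                    v.chrom,
                    str(v.pos),
                    ".",
                    v.ref,
                    v.alt,
                    ".",
                    "PASS",
                    ";".join(info),
                    "AD:DP",
                    f"{ref_count},{v.alt_count}:{v.depth}",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def _read_vcf(path: Path, sample: str | None = None) -> list[AnnotatedVariant]:
    from cyvcf2 import VCF

    try:
        reader = VCF(str(path))
    except Exception as exc:
        raise VariantTableError(f"{path}: cannot parse VCF: {exc}") from exc
    samples = list(reader.samples)
    if not samples:
        raise SchemaError(f"{path}: VCF has no sample columns (per-sample AD/DP required)")
    if sample is None:
        if len(samples) > 1:
            raise SchemaError(
                f"{path}: multiple samples {samples}; specify one explicitly"
            )
        sidx = 0
    else:
        if sample not in samples:
            raise SchemaError(f"{path}: sample {sample!r} not in VCF ({samples})")
        sidx = samples.index(sample)

    variants: list[AnnotatedVariant] = []
    for rec in reader:
        ad = rec.format("AD")
        dp = rec.format("DP")
        if ad is None:
            raise SchemaError(f"{path}: record {rec.CHROM}:{rec.POS} lacks FORMAT/AD")
        if dp is None:
            raise SchemaError(f"{path}: record {rec.CHROM}:{rec.POS} lacks FORMAT/DP")
        depth = int(dp[sidx][0] if hasattr(dp[sidx], "__len__") else dp[sidx])
        paf_raw = rec.INFO.get("PAF")
        pop_af: dict[str, float] = {}
        if paf_raw:
            for item in str(paf_raw).split("|"):
                db, _, af = item.partition(":")
                pop_af[db] = float(af)
        vafp = rec.INFO.get("VAFP")
        ctx3 = rec.INFO.get("CTX3")
        for i, alt in enumerate(rec.ALT):
            alt_count = int(ad[sidx][i + 1])
            if vafp is not None and len(rec.ALT) == 1:
                vaf = float(vafp)
            else:
                vaf = alt_count / depth if depth else 0.0
            variants.append(
                AnnotatedVariant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    gene=rec.INFO.get("GENE") or "",
                    protein_change=rec.INFO.get("PCH") or "",
                    consequence=rec.INFO.get("CSQ") or "other",
                    alt_count=alt_count,
                    depth=depth,
                    vaf=vaf,
                    pop_af=dict(pop_af),
                    oxog_flag=bool(rec.INFO.get("OXOG")),
                    context3=str(ctx3) if ctx3 else None,
                )
            )
    return variants


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def read_variant_table(
    path: str | os.PathLike,
    dialect: str = "tsv",
    sample: str | None = None,
) -> list[AnnotatedVariant]:
    """Read annotated variants from ``path``.

    Multi-allelic VCF records are split into one variant per alternate
    allele; missing optional annotations become absent (empty/None), never 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "vcf":
        return _read_vcf(path, sample=sample)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_variant_table(
    variants: Sequence[AnnotatedVariant],
    path: str | os.PathLike,
    dialect: str = "tsv",
) -> None:
    """Write variants so that :func:`read_variant_table` recovers them exactly."""
    path = Path(path)
    if dialect == "tsv":
        _write_tsv(variants, path)
    elif dialect == "vcf":
        _write_vcf(variants, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


_MANIFEST_REQUIRED = ("patient_id", "region_label", "path", "callable_mb")


def read_manifest(path: str | os.PathLike) -> CohortManifest:
    """Read a cohort manifest TSV.

    Required columns: ``patient_id``, ``region_label``, ``path`` (relative to
    the manifest), ``callable_mb``.  Optional: ``purity``, ``group`` (an
    anatomical tag, e.g. ``left``/``right``, used for double-primary
    assessment).  Referenced files must exist at load time.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MANIFEST_REQUIRED if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing manifest column(s): {', '.join(missing)}")
    entries = []
    for row in frame.to_dict("records"):
        vpath = (path.parent / row["path"]).resolve()
        if not vpath.exists():
            raise ManifestError(f"{path}: referenced file does not exist: {row['path']}")
        entries.append(
            ManifestEntry(
                patient_id=row["patient_id"],
                region_label=row["region_label"],
                path=str(vpath),
                callable_mb=float(row["callable_mb"]),
                purity=float(row["purity"]) if row.get("purity") else None,
                group=row.get("group") or None,
            )
        )
    return CohortManifest(entries)


def load_cohort(
    manifest_path: str | os.PathLike,
    chrom_map: Mapping[str, str] | None = None,
) -> dict[str, list[RegionCallset]]:
    """Load all region callsets of a cohort, keyed by patient.

    Region lists preserve manifest order.  ``chrom_map`` optionally renames
    chromosomes on load (e.g. ``{"1": "chr1"}``); names are otherwise taken
    verbatim.
    """
    manifest = read_manifest(manifest_path)
    cohort: dict[str, list[RegionCallset]] = {}
    for entry in manifest.entries:
        dialect = "vcf" if entry.path.endswith(".vcf") else "tsv"
        variants = read_variant_table(entry.path, dialect=dialect)
        if chrom_map:
            for v in variants:
                v.chrom = chrom_map.get(v.chrom, v.chrom)
        cohort.setdefault(entry.patient_id, []).append(
            RegionCallset(
                patient_id=entry.patient_id,
                region_label=entry.region_label,
                variants=variants,
                callable_mb=entry.callable_mb,
                purity=entry.purity,
                group=entry.group,
            )
        )
    return cohort
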