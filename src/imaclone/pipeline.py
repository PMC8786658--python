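"""End-to-end orchestration: filtering → clonality/Jaccard → phylogeny → TMB
→ signatures, with TSV outputs and a rendered text report.

All outputs carry full precision plus the displayed rounding in separate
columns; every number in the rendered report is recomputable from the
per-variant TSVs written beside it.  Reruns with the same inputs and config
produce identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .burden import tmb_per_region, tmb_summary
from .clonality import (
    DEFAULT_DRIVER_GENES,
    RelatednessConfig,
    assess_relatedness,
    build_presence_matrix,
    classify_mutations,
    cohort_ith_median,
    jaccard_matrix,
)
from .filtering import FilterConfig, apply_filters, hotspot_review
from .phylo import hamming_distance_matrix, neighbor_joining, to_newick
from .signatures import (
    RefitConfig,
    SignatureCatalog,
    build_spectrum,
    load_default_catalog,
    refit_exposures,
    signature_prevalence,
)
from .variants import RegionCallset, load_cohort

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "render_report"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending unit."""


@dataclass
class PipelineConfig:
    manifest: str
    outdir: str
    catalog: str | None = None  # path to a catalog TSV; None = packaged default
    filter: FilterConfig = field(default_factory=FilterConfig)
    relatedness: RelatednessConfig = field(default_factory=RelatednessConfig)
    driver_genes: tuple[str, ...] = DEFAULT_DRIVER_GENES
    counting_mode: str = "missense_only"
    include_root: bool = True
    pooled_signatures: bool = False
    refit: RefitConfig = field(default_factory=RefitConfig)
    seed: int = 0

    def to_yaml(self, path: str | os.PathLike) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["filter"] = FilterConfig(
            **{
                **raw.get("filter", {}),
                "population_dbs": tuple(
                    raw.get("filter", {}).get("population_dbs", FilterConfig().population_dbs)
                ),
            }
        )
        raw["relatedness"] = RelatednessConfig(**raw.get("relatedness", {}))
        refit_raw = raw.get("refit", {})
        if refit_raw.get("candidates") is not None:
            refit_raw["candidates"] = tuple(refit_raw["candidates"])
        raw["refit"] = RefitConfig(**refit_raw)
        raw["driver_genes"] = tuple(raw.get("driver_genes", DEFAULT_DRIVER_GENES))
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _load_catalog(config: PipelineConfig) -> SignatureCatalog:
    if config.catalog:
        return SignatureCatalog.from_tsv(config.catalog)
    return load_default_catalog()


def _fmt(x: float | None, na: str = "NA") -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return na
    return repr(float(x))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_filter(config: PipelineConfig, outdir: Path):
    cohort = load_cohort(config.manifest)
    filtered: dict[str, list[RegionCallset]] = {}
    rows, hotspot_rows = [], []
    for pid, callsets in cohort.items():
        filtered[pid] = []
        for cs in callsets:
            try:
                passing, report = apply_filters(cs.variants, config.filter)
                flagged = hotspot_review(cs.variants, passing, config=config.filter)
            except Exception as exc:
                raise PipelineError(f"filter stage failed for {pid}/{cs.region_label}: {exc}") from exc
            filtered[pid].append(
                RegionCallset(
                    patient_id=cs.patient_id,
                    region_label=cs.region_label,
                    variants=passing,
                    callable_mb=cs.callable_mb,
                    purity=cs.purity,
                    group=cs.group,
                )
            )
            row = {
                "patient_id": pid,
                "region_label": cs.region_label,
                "n_input": report.n_input,
                "n_passing": report.n_passing,
                "n_removed": report.n_removed,
            }
            for rule in ("pop_af", "oxog", "alt_count", "depth", "vaf"):
                row[f"removed_{rule}"] = report.removed_by_rule.get(rule, 0)
            rows.append(row)
            for v in flagged:
                hotspot_rows.append(
                    {
                        "patient_id": pid,
                        "region_label": cs.region_label,
                        "gene": v.gene,
                        "protein_change": v.protein_change,
                        "chrom": v.chrom,
                        "pos": v.pos,
                        "vaf": repr(v.vaf),
                    }
                )
    pd.DataFrame(rows).to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
    pd.DataFrame(
        hotspot_rows,
        columns=["patient_id", "region_label", "gene", "protein_change", "chrom", "pos", "vaf"],
    ).to_csv(outdir / "hotspot_review.tsv", sep="\t", index=False)
    return filtered


def stage_clonality(config: PipelineConfig, filtered, outdir: Path):
    summary_rows, median_rows, verdict_rows = [], [], []
    tables = {}
    for pid, callsets in filtered.items():
        try:
            pm = build_presence_matrix(callsets)
            table = classify_mutations(pm)
            jac = jaccard_matrix(pm)
            gene_map = {
                v.key: v.gene for cs in callsets for v in cs.variants if v.gene
            }
            verdict = assess_relatedness(
                pm, jac, config.driver_genes, config.relatedness, gene_map
            )
        except Exception as exc:
            raise PipelineError(f"clonality stage failed for patient {pid}: {exc}") from exc
        tables[pid] = table
        pd.DataFrame(
            [
                {
                    "chrom": k.chrom,
                    "pos": k.pos,
                    "ref": k.ref,
                    "alt": k.alt,
                    "class": cls,
                    "n_regions_present": int(pm.cells[:, pm.variant_keys.index(k)].sum()),
                }
                for k, cls in table.classes.items()
            ]
        ).to_csv(outdir / f"clonality_{pid}.tsv", sep="\t", index=False)
        jac_frame = pd.DataFrame(
            jac.values, index=jac.region_labels, columns=jac.region_labels
        )
        jac_frame.to_csv(outdir / f"jaccard_{pid}.tsv", sep="\t")
        summary_rows.append(
            {
                "patient_id": pid,
                "n_regions": pm.n_regions,
                "n_truncal": table.n_truncal,
                "n_branch": table.n_branch,
                "n_private": table.n_private,
                "n_branch_private": table.n_branch + table.n_private,
                "n_total": table.n_total,
                "ith_percent_full": _fmt(table.ith_percent),
                "ith_percent": _fmt(table.ith_percent_reported),
            }
        )
        median_rows.append(
            {
                "patient_id": pid,
                "n_pairs": len(jac.upper_triangle),
                "median_full": _fmt(jac.median),
                "median": _fmt(jac.median_reported),
            }
        )
        for (a, b), v in verdict.verdicts.items():
            jv, drivers = verdict.evidence[(a, b)]
            verdict_rows.append(
                {
                    "patient_id": pid,
                    "region_a": a,
                    "region_b": b,
                    "verdict": v,
                    "jaccard": _fmt(jv),
                    "shared_driver_variants": ";".join(
                        f"{k.chrom}:{k.pos}:{k.ref}>{k.alt}" for k in drivers
                    ),
                }
            )
    pd.DataFrame(summary_rows).to_csv(outdir / "clonality_summary.tsv", sep="\t", index=False)
    pd.DataFrame(median_rows).to_csv(outdir / "jaccard_medians.tsv", sep="\t", index=False)
    pd.DataFrame(verdict_rows).to_csv(outdir / "verdicts.tsv", sep="\t", index=False)
    defined = [t for t in tables.values() if t.ith_percent is not None]
    cohort = {
        "n_patients": len(tables),
        "n_patients_defined_ith": len(defined),
        "median_ith_percent": cohort_ith_median(defined) if defined else "NA",
    }
    pd.DataFrame([cohort]).to_csv(outdir / "cohort_summary.tsv", sep="\t", index=False)
    return tables


def stage_phylo(config: PipelineConfig, filtered, outdir: Path):
    for pid, callsets in filtered.items():
        try:
            pm = build_presence_matrix(callsets)
            dm = hamming_distance_matrix(pm, include_root=config.include_root)
            tree = neighbor_joining(dm)
        except Exception as exc:
            raise PipelineError(f"phylo stage failed for patient {pid}: {exc}") from exc
        pd.DataFrame(dm.matrix, index=dm.labels, columns=dm.labels).to_csv(
            outdir / f"distances_{pid}.tsv", sep="\t"
        )
        to_newick(tree, outdir / f"tree_{pid}.nwk")


def stage_tmb(config: PipelineConfig, filtered, outdir: Path):
    rows = []
    results = []
    for pid, callsets in filtered.items():
        for cs in callsets:
            try:
                res = tmb_per_region(cs, config.counting_mode)
            except Exception as exc:
                raise PipelineError(f"tmb stage failed for {pid}/{cs.region_label}: {exc}") from exc
            results.append(res)
            rows.append(
                {
                    "patient_id": pid,
                    "region_label": cs.region_label,
                    "n_counted": res.n_counted,
                    "callable_mb": repr(cs.callable_mb),
                    "tmb_full": repr(res.tmb),
                    "tmb": repr(res.tmb_reported),
                }
            )
    frame = pd.DataFrame(rows)
    frame.to_csv(outdir / "tmb.tsv", sep="\t", index=False)
    summ = tmb_summary(results)
    mean_r, min_r, max_r = summ.reported
    pd.DataFrame(
        [
            {
                "n_regions": len(results),
                "mean_full": repr(summ.mean),
                "mean": repr(mean_r),
                "min": repr(min_r),
                "max": repr(max_r),
            }
        ]
    ).to_csv(outdir / "tmb_summary.tsv", sep="\t", index=False)


def stage_signatures(config: PipelineConfig, filtered, outdir: Path):
    catalog = _load_catalog(config)
    spectra_cols = {}
    fits = []
    exposure_rows = []
    for pid, callsets in filtered.items():
        units = (
            [(pid, [v for cs in callsets for v in cs.variants])]
            if config.pooled_signatures
            else [(f"{pid}_{cs.region_label}", cs.variants) for cs in callsets]
        )
        for sample_id, variants in units:
            try:
                spec = build_spectrum(variants, sample_id=sample_id)
                if spec.n_snv == 0:
                    logger.warning("sample %s has no SNVs; skipping refit", sample_id)
                    continue
                fit = refit_exposures(spec, catalog, config.refit)
            except Exception as exc:
                raise PipelineError(f"signatures stage failed for {sample_id}: {exc}") from exc
            spectra_cols[sample_id] = spec.counts
            fits.append(fit)
            for sid in fit.signature_ids:
                exposure_rows.append(
                    {
                        "sample": sample_id,
                        "signature": sid,
                        "exposure": repr(fit.exposure(sid)),
                        "selected": int(sid in fit.selected),
                        "cosine": repr(fit.cosine),
                        "n_snv": spec.n_snv,
                    }
                )
    from .signatures import CHANNELS_96

    spectra = pd.DataFrame(spectra_cols, index=list(CHANNELS_96))
    spectra.index.name = "MutationType"
    spectra.to_csv(outdir / "spectra.tsv", sep="\t")
    pd.DataFrame(exposure_rows).to_csv(outdir / "exposures.tsv", sep="\t", index=False)
    prev = signature_prevalence(fits) if fits else {}
    pd.DataFrame(
        [
            {"signature": sid, "n_samples": n, "n_total": len(fits), "percent": pct}
            for sid, (n, pct) in prev.items()
        ]
    ).to_csv(outdir / "prevalence.tsv", sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the output directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    filtered = stage_filter(config, outdir)
    stage_clonality(config, filtered, outdir)
    stage_phylo(config, filtered, outdir)
    stage_tmb(config, filtered, outdir)
    stage_signatures(config, filtered, outdir)
    log = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    config.to_yaml(outdir / "config_used.yaml")
    return outdir


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

_REPORT_STAGES = {
    "filtering": ["filter_report.tsv"],
    "clonality": ["clonality_summary.tsv", "cohort_summary.tsv", "jaccard_medians.tsv", "verdicts.tsv"],
    "tmb": ["tmb.tsv", "tmb_summary.tsv"],
    "signatures": ["prevalence.tsv"],
}


def render_report(outdir: str | os.PathLike) -> str:
    """Render a markdown summary from a completed run's TSVs."""
    outdir = Path(outdir)
    for stage, names in _REPORT_STAGES.items():
        for name in names:
            if not (outdir / name).exists():
                raise PipelineError(f"missing output of stage {stage!r}: {name}")

    def table(name: str) -> pd.DataFrame:
        return pd.read_csv(outdir / name, sep="\t", dtype=str, keep_default_na=False)

    filt = table("filter_report.tsv")
    clon = table("clonality_summary.tsv")
    cohort = table("cohort_summary.tsv").iloc[0]
    if int(cohort["n_patients"]) == 0:
        raise PipelineError("empty cohort: no patients in clonality summary")
    jmed = table("jaccard_medians.tsv")
    verd = table("verdicts.tsv")
    tmb = table("tmb.tsv")
    tmbsum = table("tmb_summary.tsv").iloc[0]
    prev = table("prevalence.tsv")

    def md(frame: pd.DataFrame, cols: list[str]) -> str:
        head = "| " + " | ".join(cols) + " |"
        sep = "|" + "|".join(["---"] * len(cols)) + "|"
        body = [
            "| " + " | ".join(str(r[c]) for c in cols) + " |"
            for _, r in frame.iterrows()
        ]
        return "\n".join([head, sep, *body])

    clon_disp = clon.copy()
    clon_disp["ith_percent"] = clon_disp["ith_percent"].replace("NA", "N/A")
    lines = [
        "# Multi-region somatic variant analysis report",
        "",
        f"Patients: {cohort['n_patients']}; regions: {len(tmb)}.",
        "",
        "## Filtering",
        "",
        md(filt, ["patient_id", "region_label", "n_input", "n_passing", "n_removed"]),
        "",
        "## Tumor mutational burden (per megabase)",
        "",
        md(tmb, ["patient_id", "region_label", "n_counted", "tmb"]),
        "",
        f"Mean {tmbsum['mean']}, range {tmbsum['min']}–{tmbsum['max']} "
        f"over {tmbsum['n_regions']} regions.",
        "",
        "## Clonality and intra-tumor heterogeneity",
        "",
        md(
            clon_disp,
            ["patient_id", "n_regions", "n_truncal", "n_branch_private", "n_total", "ith_percent"],
        ),
        "",
        f"Cohort median ITH index: {cohort['median_ith_percent']}% "
        f"({cohort['n_patients_defined_ith']} of {cohort['n_patients']} patients defined).",
        "",
        "## Jaccard similarity (per-patient medians)",
        "",
        md(jmed, ["patient_id", "n_pairs", "median"]),
        "",
        "## Clonal relatedness verdicts",
        "",
        md(verd, ["patient_id", "region_a", "region_b", "verdict", "jaccard"]),
        "",
        "## Mutational signature prevalence",
        "",
        md(prev, ["signature", "n_samples", "n_total", "percent"]),
        "",
    ]
    text = "\n".join(lines)
    (outdir / "report.md").write_text(text)
    return text
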