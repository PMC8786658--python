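"""Derived statistics recomputed from the published cohort summary tables.

The study's raw per-region variant lists were not deposited, so per-region
TMB values, pairwise Jaccard coefficients and per-patient mutation counts
are taken as published inputs (see :mod:`imaclone.cohortdata`); every
*derived* quantity — ITH indices, cohort medians, ranges, averages and
prevalence percentages — is recomputed here through the package's own
analysis functions.  Count-shaped presence matrices (truncal columns
present in all regions, non-truncal columns private) reproduce each
patient's published truncal / branch+private totals exactly, which is all
the ITH index depends on.
"""

from __future__ import annotations

import math

import numpy as np

from .burden import TmbResult, tmb_summary
from .clonality import (
    ClonalityTable,
    JaccardMatrix,
    PresenceMatrix,
    classify_mutations,
    cohort_ith_median,
)
from .cohortdata import (
    load_cohort_totals,
    load_reported_clonality_counts,
    load_reported_jaccard_pairs,
    load_reported_signature_detection,
    load_reported_tmb,
)
from .rounding import round_half_even
from .signatures import ExposureFit, signature_prevalence
from .variants import VariantKey

__all__ = [
    "count_shaped_matrix",
    "reported_ith_tables",
    "reported_jaccard_matrices",
    "reported_tmb_results",
    "detection_fits",
    "derived_statistics",
]


def count_shaped_matrix(
    patient_id: str, region_labels: list[str], n_truncal: int, n_other: int
) -> PresenceMatrix:
    """A minimal presence matrix with the given truncal / non-truncal totals.

    Truncal columns are present in every region; the remaining columns are
    distributed one region at a time (each present in exactly one region),
    so the truncal and branch+private totals — the only inputs of the ITH
    index — match the requested counts exactly.
    """
    r = len(region_labels)
    cells = np.zeros((r, n_truncal + n_other), dtype=np.uint8)
    cells[:, :n_truncal] = 1
    for j in range(n_other):
        cells[j % r, n_truncal + j] = 1
    keys = [VariantKey("chr1", 1000 + j, "C", "T") for j in range(cells.shape[1])]
    return PresenceMatrix(patient_id, list(region_labels), keys, cells)


def _regions_by_patient() -> dict[str, list[str]]:
    tmb = load_reported_tmb()
    out: dict[str, list[str]] = {}
    for _, row in tmb.iterrows():
        out.setdefault(row["patient_id"], []).append(row["region_label"])
    return out


def reported_ith_tables() -> dict[str, ClonalityTable]:
    """Classify count-shaped matrices for every published patient."""
    regions = _regions_by_patient()
    counts = load_reported_clonality_counts()
    tables = {}
    for _, row in counts.iterrows():
        pid = row["patient_id"]
        pm = count_shaped_matrix(
            pid, regions[pid], row["n_truncal"], row["n_branch_private"]
        )
        tables[pid] = classify_mutations(pm)
    return tables


def reported_jaccard_matrices() -> dict[str, JaccardMatrix]:
    """Per-patient Jaccard matrices assembled from published pair values."""
    pairs = load_reported_jaccard_pairs()
    out = {}
    for pid, sub in pairs.groupby("patient_id", sort=False):
        labels: list[str] = []
        for _, row in sub.iterrows():
            for lab in (row["region_a"], row["region_b"]):
                if lab not in labels:
                    labels.append(lab)
        r = len(labels)
        values = np.eye(r)
        for _, row in sub.iterrows():
            i, j = labels.index(row["region_a"]), labels.index(row["region_b"])
            values[i, j] = values[j, i] = row["jaccard"]
        out[pid] = JaccardMatrix(pid, labels, values)
    return out


def reported_tmb_results() -> list[TmbResult]:
    """Published per-region TMB values as TmbResult objects.

    The published values are mutations/Mb at 2 decimals; representing them
    over a 100 Mb denominator reproduces each value exactly.
    """
    frame = load_reported_tmb()
    return [
        TmbResult(row["patient_id"], row["region_label"],
                  n_counted=int(round(row["tmb"] * 100)), callable_mb=100.0)
        for _, row in frame.iterrows()
    ]


def detection_fits() -> list[ExposureFit]:
    """Synthetic per-sample fits whose selected sets reproduce the published
    per-signature detection counts (signature 1 in 23/24 samples, the APOBEC
    pair 2+13 in 6, signature 6 in 5)."""
    det = load_reported_signature_detection().set_index("signature")
    n_total = int(det["n_total"].iloc[0])
    ids = ["1", "2", "6", "13"]
    fits = []
    for i in range(n_total):
        selected = []
        if i < int(det.loc["1", "n_samples"]):
            selected.append("1")
        if i < int(det.loc["2_13", "n_samples"]):
            selected += ["2", "13"]
        if i < int(det.loc["6", "n_samples"]):
            selected.append("6")
        if not selected:
            selected = ["5"]
        all_ids = ids + ["5"]
        expo = np.array(
            [1.0 / len(selected) if s in selected else 0.0 for s in all_ids]
        )
        fits.append(
            ExposureFit(f"s{i}", all_ids, expo, tuple(selected), np.ones(96), 0.99)
        )
    return fits


def derived_statistics() -> dict[str, float | None]:
    """Every derived cohort statistic, recomputed by the package's functions."""
    out: dict[str, float | None] = {}

    tables = reported_ith_tables()
    for pid, table in tables.items():
        out[f"ith_percent_{pid}"] = table.ith_percent_reported
    defined = [t for t in tables.values() if t.ith_percent is not None]
    out["cohort_median_ith_percent"] = cohort_ith_median(defined)

    summ = tmb_summary(reported_tmb_results())
    mean_r, min_r, max_r = summ.reported
    out["tmb_mean"] = mean_r
    out["tmb_min"] = min_r
    out["tmb_max"] = max_r

    for pid, jac in reported_jaccard_matrices().items():
        out[f"jaccard_median_{pid}"] = jac.median_reported

    totals = load_cohort_totals()
    out["mean_mutations_per_region"] = round_half_even(
        totals["n_somatic_variants"] / totals["n_regions"], 1
    )

    prev = signature_prevalence(detection_fits())
    out["signature1_prevalence_percent"] = prev["1"][1]
    out["apobec_prevalence_percent"] = prev["2"][1]
    out["signature6_prevalence_percent"] = prev["6"][1]
    return out
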