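"""Published summary tables of the seven-patient multifocal IMA cohort.

The multi-region whole-exome study this pipeline re-implements published its
per-region tumor mutational burden values, per-patient truncal/branch
mutation counts, pairwise Jaccard coefficients and per-signature sample
counts as summary tables (the underlying per-region variant lists were not
deposited).  These tables ship with the package as inputs for reproducing
every *derived* statistic the pipeline defines — medians, ranges, indices
and prevalence percentages are always recomputed by the package's own
functions, never read back from the files.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

__all__ = [
    "load_reported_tmb",
    "load_reported_clonality_counts",
    "load_reported_jaccard_pairs",
    "load_reported_jaccard_medians",
    "load_reported_signature_detection",
    "load_cohort_totals",
]


def _read(name: str) -> pd.DataFrame:
    path = files("imaclone").joinpath("data", "study_cohort", name)
    with path.open("rb") as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


def load_reported_tmb() -> pd.DataFrame:
    """Per-region TMB values (mutations/Mb): patient_id, region_label, tmb."""
    frame = _read("tmb_per_region.tsv")
    frame["tmb"] = frame["tmb"].astype(float)
    return frame


def load_reported_clonality_counts() -> pd.DataFrame:
    """Per-patient branch+private and truncal mutation counts.

    ``reported_percent`` is the published branch-mutation percentage as
    printed (kept as string; "NA" marks the patient with no truncal
    mutation).
    """
    frame = _read("clonality_counts.tsv")
    frame["n_branch_private"] = frame["n_branch_private"].astype(int)
    frame["n_truncal"] = frame["n_truncal"].astype(int)
    return frame


def load_reported_jaccard_pairs() -> pd.DataFrame:
    """Published pairwise Jaccard coefficients per patient."""
    frame = _read("jaccard_pairs.tsv")
    frame["jaccard"] = frame["jaccard"].astype(float)
    return frame


def load_reported_jaccard_medians() -> pd.DataFrame:
    """Published per-patient median Jaccard coefficients (2 decimals)."""
    frame = _read("reported_medians.tsv")
    frame["reported_median"] = frame["reported_median"].astype(float)
    return frame


def load_reported_signature_detection() -> pd.DataFrame:
    """Per-signature sample detection counts (signature, n_samples, n_total)."""
    frame = _read("signature_detection.tsv")
    frame["n_samples"] = frame["n_samples"].astype(int)
    frame["n_total"] = frame["n_total"].astype(int)
    return frame


def load_cohort_totals() -> dict[str, int]:
    """Cohort bookkeeping totals (variant, region and patient counts)."""
    frame = _read("cohort_totals.tsv")
    return {row["key"]: int(row["value"]) for _, row in frame.iterrows()}
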