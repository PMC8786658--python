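"""96-channel trinucleotide mutation spectra and signature refitting.

Single-base substitutions are collapsed to the pyrimidine strand (a G>T at
context TGT is counted as C>A at ACA) and binned into the canonical 96
channels — substitution class major, then 5' flank, then 3' flank:
A[C>A]A, A[C>A]C, …, T[T>G]T.  A sample's spectrum is refit as a
non-negative combination of a fixed catalog of reference signatures
(non-negative least squares), followed by greedy backward elimination:
while dropping some signature costs less than ``epsilon_cos`` in
reconstruction cosine similarity, drop the cheapest one and refit; finally
exposures below ``min_exposure`` of the total are zeroed and the model is
refit once.  Exposures are reported as fractions summing to 1 over the
selected signatures, with the reconstruction cosine as the fit diagnostic.

The packaged default catalog covers signatures 1, 2, 4, 5, 6, 13, 15 and 17.
Its probability values are a synthetic stand-in (see
``data/signature_catalog_synthetic.tsv``) whose channels concentrate where
the corresponding processes act — CpG C>T for 1, TpC-context C>T / C>G for
the APOBEC pair 2/13, broad C>A for 4, near-flat 5, NpTpT T>G for 17 — so
mixtures are identifiable; all refitting math is catalog-agnostic and works
unchanged with a real reference catalog in the same TSV layout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from importlib.resources import files
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .rounding import round_half_even
from .variants import AnnotatedVariant, revcomp

__all__ = [
    "CHANNELS_96",
    "DEFAULT_SIGNATURE_IDS",
    "SignatureCatalog",
    "MutationSpectrum",
    "ExposureFit",
    "RefitConfig",
    "build_spectrum",
    "refit_exposures",
    "signature_prevalence",
    "cosine_similarity",
    "load_default_catalog",
    "make_synthetic_catalog",
]

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

#: Canonical channel order: substitution class, then 5' flank, then 3' flank.
CHANNELS_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)
CHANNEL_INDEX: dict[str, int] = {c: i for i, c in enumerate(CHANNELS_96)}

DEFAULT_SIGNATURE_IDS = ("1", "2", "4", "5", "6", "13", "15", "17")

_DATA_FILE = "signature_catalog_synthetic.tsv"


@dataclass
class SignatureCatalog:
    """A 96×K column-stochastic reference matrix over named signatures."""

    signature_ids: list[str]
    matrix: np.ndarray  # (96, K)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (96, len(self.signature_ids)):
            raise ValueError("catalog matrix must be 96 × n_signatures")
        if (self.matrix < 0).any():
            raise ValueError("catalog entries must be non-negative")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("catalog columns must each sum to 1")

    def column(self, signature_id: str) -> np.ndarray:
        return self.matrix[:, self.signature_ids.index(signature_id)]

    def subset(self, ids: Sequence[str]) -> "SignatureCatalog":
        idx = [self.signature_ids.index(i) for i in ids]
        return SignatureCatalog(list(ids), self.matrix[:, idx])

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "SignatureCatalog":
        frame = pd.read_csv(path, sep="\t", comment="#")
        if "MutationType" not in frame.columns:
            raise ValueError(f"{path}: missing MutationType column")
        channels = list(frame["MutationType"])
        if channels != list(CHANNELS_96):
            raise ValueError(
                f"{path}: channel rows are not in canonical order "
                "(A[C>A]A … T[T>G]T); refusing silently permuted catalogs"
            )
        ids = [c.removeprefix("Signature_") for c in frame.columns if c != "MutationType"]
        matrix = frame.drop(columns="MutationType").to_numpy(dtype=float)
        return cls(ids, matrix)

    def to_tsv(self, path: str | os.PathLike) -> None:
        frame = pd.DataFrame({"MutationType": list(CHANNELS_96)})
        for j, sid in enumerate(self.signature_ids):
            frame[f"Signature_{sid}"] = self.matrix[:, j]
        frame.to_csv(path, sep="\t", index=False)


@dataclass
class MutationSpectrum:
    sample_id: str
    counts: np.ndarray  # (96,) non-negative integers
    skipped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have 96 channels")
        if (self.counts < 0).any():
            raise ValueError("negative channel counts")

    @property
    def n_snv(self) -> int:
        return int(self.counts.sum())


@dataclass
class ExposureFit:
    sample_id: str
    signature_ids: list[str]  # all candidates, catalog order
    exposures: np.ndarray  # fractions over all candidates; unselected exactly 0
    selected: tuple[str, ...]
    reconstruction: np.ndarray  # (96,) scaled to n_snv
    cosine: float

    def exposure(self, signature_id: str) -> float:
        return float(self.exposures[self.signature_ids.index(signature_id)])


@dataclass(frozen=True)
class RefitConfig:
    epsilon_cos: float = 0.01
    min_exposure: float = 0.05
    candidates: tuple[str, ...] | None = None  # None = whole catalog


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def channel_of(ref: str, alt: str, context3: str) -> str:
    """Map an SNV to its pyrimidine-strand channel name."""
    ref, alt, context3 = ref.upper(), alt.upper(), context3.upper()
    if context3[1] != ref:
        raise ValueError(f"context {context3} middle base != ref {ref}")
    if ref in "GA":
        context3 = revcomp(context3)
        ref = revcomp(ref)
        alt = revcomp(alt)
    return f"{context3[0]}[{ref}>{alt}]{context3[2]}"


def build_spectrum(
    variants: Sequence[AnnotatedVariant],
    sample_id: str = "sample",
    context_source: str = "field",
    fasta: str | os.PathLike | None = None,
) -> MutationSpectrum:
    """Bin a callset's SNVs into the 96 channels.

    ``context_source`` is ``field`` (use each variant's ``context3``) or
    ``fasta`` (look the 3-mer up in a reference FASTA).  Indels and SNVs
    with missing or inconsistent context are skipped and counted in
    ``skipped``.
    """
    if context_source not in ("field", "fasta"):
        raise ValueError(f"unknown context source {context_source!r}")
    fa = None
    if context_source == "fasta":
        if fasta is None:
            raise ValueError("context_source='fasta' requires a fasta path")
        from pyfaidx import Fasta

        fa = Fasta(str(fasta))
    counts = np.zeros(96, dtype=np.int64)
    skipped = {"indel": 0, "missing_context": 0, "context_mismatch": 0}
    for v in variants:
        if v.variant_class != "SNV":
            skipped["indel"] += 1
            continue
        if context_source == "field":
            ctx = v.context3
        else:
            ctx = str(fa[v.chrom][v.pos - 2 : v.pos + 1]).upper()
        if not ctx or len(ctx) != 3:
            skipped["missing_context"] += 1
            continue
        if ctx[1].upper() != v.ref:
            skipped["context_mismatch"] += 1
            continue
        counts[CHANNEL_INDEX[channel_of(v.ref, v.alt, ctx)]] += 1
    return MutationSpectrum(sample_id=sample_id, counts=counts, skipped=skipped)


def _nnls_fit(s: np.ndarray, catalog: SignatureCatalog, ids: Sequence[str]):
    sub = catalog.subset(ids)
    x, _ = nnls(sub.matrix, s)
    recon = sub.matrix @ x
    return x, recon, cosine_similarity(s, recon)


def refit_exposures(
    spectrum: MutationSpectrum,
    catalog: SignatureCatalog,
    config: RefitConfig = RefitConfig(),
) -> ExposureFit:
    """Refit a spectrum as a sparse non-negative signature mixture.

    Invariant to uniform scaling of the spectrum (fractions are fitted, not
    counts).  Raises on empty spectra.
    """
    if spectrum.n_snv == 0:
        raise ValueError("cannot refit an empty spectrum")
    candidates = list(config.candidates or catalog.signature_ids)
    unknown = set(candidates) - set(catalog.signature_ids)
    if unknown:
        raise ValueError(f"candidate signatures not in catalog: {sorted(unknown)}")
    s = spectrum.counts.astype(float)

    selected = list(candidates)
    x, recon, cos = _nnls_fit(s, catalog, selected)
    # greedy backward elimination on reconstruction cosine
    while len(selected) > 1:
        trials = []
        for sid in selected:
            rest = [i for i in selected if i != sid]
            _, _, c = _nnls_fit(s, catalog, rest)
            trials.append((cos - c, sid, rest))
        trials.sort(key=lambda t: (t[0], t[1]))
        drop_cost, _, rest = trials[0]
        if drop_cost < config.epsilon_cos:
            selected = rest
            x, recon, cos = _nnls_fit(s, catalog, selected)
        else:
            break
    # prune tiny exposures, refit once
    total = x.sum()
    if total > 0:
        keep = [sid for sid, xi in zip(selected, x) if xi / total >= config.min_exposure]
        if keep and len(keep) < len(selected):
            selected = keep
            x, recon, cos = _nnls_fit(s, catalog, selected)
    if x.sum() == 0:  # degenerate: spectrum orthogonal to every signature
        raise ValueError("no signature obtains positive exposure")
    fractions = x / x.sum()
    # drop any signature whose refit exposure is exactly 0
    selected = [sid for sid, f in zip(selected, fractions) if f > 0]
    fractions = np.array([f for f in fractions if f > 0])
    exposures = np.zeros(len(candidates))
    for sid, f in zip(selected, fractions):
        exposures[candidates.index(sid)] = f
    recon_scaled = recon * (spectrum.n_snv / recon.sum()) if recon.sum() else recon
    return ExposureFit(
        sample_id=spectrum.sample_id,
        signature_ids=candidates,
        exposures=exposures,
        selected=tuple(selected),
        reconstruction=recon_scaled,
        cosine=cos,
    )


def signature_prevalence(
    fits: Sequence[ExposureFit],
) -> dict[str, tuple[int, float]]:
    """Per-signature (sample count, percent of samples) across fitted samples.

    A signature is "found" in a sample iff it is selected with exposure > 0.
    Percentages are reported at one decimal.
    """
    if not fits:
        raise ValueError("no fits given")
    ids: list[str] = []
    for f in fits:
        for sid in f.signature_ids:
            if sid not in ids:
                ids.append(sid)
    out: dict[str, tuple[int, float]] = {}
    for sid in ids:
        n = sum(
            1
            for f in fits
            if sid in f.selected and f.exposure(sid) > 0
        )
        out[sid] = (n, round_half_even(100.0 * n / len(fits), 1))
    return out


# ---------------------------------------------------------------------------
# Synthetic default catalog
# ---------------------------------------------------------------------------

# (substitution, 5' flank or N, 3' flank or N, weight) peak specifications.
_PEAKS: dict[str, list[tuple[str, str, str, float]]] = {
    "1": [("C>T", "N", "G", 1.0)],  # deamination at CpG
    "2": [("C>T", "T", "A", 0.5), ("C>T", "T", "T", 0.5)],  # APOBEC C>T at TpC
    "4": [("C>A", "N", "N", 1.0)],  # broad C>A (tobacco-like)
    "5": [],  # near-flat
    "6": [("C>T", "G", "A", 0.4), ("C>T", "G", "C", 0.3), ("T>C", "A", "N", 0.3)],
    "13": [("C>G", "T", "A", 0.5), ("C>G", "T", "T", 0.5)],  # APOBEC C>G at TpC
    "15": [("C>T", "A", "T", 0.5), ("C>T", "C", "T", 0.5)],
    "17": [("T>G", "C", "T", 0.7), ("T>G", "A", "T", 0.3)],
}


def make_synthetic_catalog(
    signature_ids: Sequence[str] = DEFAULT_SIGNATURE_IDS,
    background: float = 0.15,
) -> SignatureCatalog:
    """Deterministically construct the synthetic stand-in catalog.

    Each signature places ``1 - background`` of its mass on its peak
    channels (wildcard flanks spread mass uniformly over matching channels)
    and ``background`` uniformly over all 96 channels.
    """
    cols = []
    for sid in signature_ids:
        col = np.full(96, background / 96)
        peaks = _PEAKS[sid]
        if not peaks:
            col = np.full(96, 1.0 / 96)
        else:
            for sub, five, three, w in peaks:
                fives = _BASES if five == "N" else five
                threes = _BASES if three == "N" else three
                chans = [
                    CHANNEL_INDEX[f"{f}[{sub}]{t}"] for f in fives for t in threes
                ]
                for c in chans:
                    col[c] += (1 - background) * w / len(chans)
        cols.append(col / col.sum())
    return SignatureCatalog(list(signature_ids), np.column_stack(cols))


def load_default_catalog() -> SignatureCatalog:
    """Load the packaged synthetic default catalog (signatures 1–17 subset)."""
    path = files("imaclone").joinpath("data", _DATA_FILE)
    with path.open("rb") as fh:  # type: ignore[call-arg]
        return SignatureCatalog.from_tsv(fh)  # type: ignore[arg-type]
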