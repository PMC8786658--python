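"""Channel mapping, catalog validation, exposure refitting, prevalence."""

import numpy as np
import pytest

from imaclone.signatures import (
    CHANNELS_96,
    ExposureFit,
    MutationSpectrum,
    RefitConfig,
    SignatureCatalog,
    build_spectrum,
    channel_of,
    cosine_similarity,
    load_default_catalog,
    make_synthetic_catalog,
    refit_exposures,
    signature_prevalence,
)
from imaclone.variants import AnnotatedVariant


def snv(ref, alt, ctx, pos=1000):
    return AnnotatedVariant("chr1", pos, ref, alt, alt_count=20, depth=100, vaf=0.2,
                            context3=ctx)


class TestChannels:
    def test_canonical_order(self):
        assert CHANNELS_96[0] == "A[C>A]A"
        assert CHANNELS_96[-1] == "T[T>G]T"
        assert len(set(CHANNELS_96)) == 96

    def test_pyrimidine_direct(self):
        assert channel_of("C", "A", "ACA") == "A[C>A]A"

    def test_purine_collapsed(self):
        # G>T at TGT is C>A at ACA on the opposite strand
        assert channel_of("G", "T", "TGT") == "A[C>A]A"
        assert channel_of("A", "C", "TAG") == "C[T>G]A"


class TestBuildSpectrum:
    def test_counts_and_collapse(self):
        spec = build_spectrum([snv("C", "A", "ACA"), snv("G", "T", "TGT", pos=2000)])
        assert spec.n_snv == 2
        assert spec.counts[CHANNELS_96.index("A[C>A]A")] == 2

    def test_empty(self):
        spec = build_spectrum([])
        assert spec.n_snv == 0 and not spec.counts.any()

    def test_skips_are_counted(self):
        indel = AnnotatedVariant("chr1", 1, "AT", "A", alt_count=20, depth=100, vaf=0.2)
        no_ctx = AnnotatedVariant("chr1", 2, "C", "T", alt_count=20, depth=100, vaf=0.2)
        spec = build_spectrum([indel, no_ctx, snv("C", "T", "ACG")])
        assert spec.n_snv == 1
        assert spec.skipped == {"indel": 1, "missing_context": 1, "context_mismatch": 0}

    def test_simulated_spectrum_matches_truth_mixture(self, catalog):
        """Large simulated callsets reproduce their generating mixture."""
        from imaclone.simulate import PatientSpec, SimConfig, simulate_cohort
        import tempfile

        spec = PatientSpec(
            "BIG", ["A", "B"], n_truncal=1500, n_branch=0, n_private_per_region=0,
            exposures={"1": 0.5, "13": 0.3, "4": 0.2}, indel_fraction=0.0,
        )
        with tempfile.TemporaryDirectory() as td:
            manifest, _ = simulate_cohort(
                SimConfig(seed=3, patients=[spec], n_popaf_per_region=0, n_oxog_per_region=0),
                td,
            )
            from imaclone.variants import load_cohort

            cohort = load_cohort(manifest)
        w = np.array([spec.exposures.get(s, 0.0) for s in catalog.signature_ids])
        expected = catalog.matrix @ w
        observed = build_spectrum(cohort["BIG"][0].variants).counts
        assert cosine_similarity(observed, expected) >= 0.97


class TestCatalog:
    def test_default_catalog_valid(self, catalog):
        assert catalog.signature_ids == ["1", "2", "4", "5", "6", "13", "15", "17"]
        assert np.allclose(catalog.matrix.sum(axis=0), 1.0)

    def test_channel_permutation_rejected(self, tmp_path, catalog):
        catalog.to_tsv(tmp_path / "cat.tsv")
        lines = (tmp_path / "cat.tsv").read_text().splitlines()
        lines[1], lines[2] = lines[2], lines[1]  # swap two channel rows
        (tmp_path / "bad.tsv").write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="canonical order"):
            SignatureCatalog.from_tsv(tmp_path / "bad.tsv")

    def test_non_stochastic_rejected(self):
        m = make_synthetic_catalog().matrix.copy()
        m[0, 0] += 0.1
        with pytest.raises(ValueError, match="sum to 1"):
            SignatureCatalog(list("abcdefgh"), m)

    def test_tsv_round_trip(self, tmp_path, catalog):
        catalog.to_tsv(tmp_path / "cat.tsv")
        again = SignatureCatalog.from_tsv(tmp_path / "cat.tsv")
        assert again.signature_ids == catalog.signature_ids
        assert np.allclose(again.matrix, catalog.matrix)


class TestRefit:
    def test_pure_signature_exact(self, catalog):
        s = np.round(1000 * catalog.column("1")).astype(int)
        fit = refit_exposures(MutationSpectrum("x", s), catalog)
        assert fit.selected == ("1",)
        assert fit.exposure("1") == 1.0
        assert fit.cosine >= 0.999

    def test_two_signature_mixture_recovery(self, catalog):
        rng = np.random.default_rng(20)
        mix = 0.6 * catalog.column("1") + 0.4 * catalog.column("13")
        s = rng.multinomial(2000, mix)
        fit = refit_exposures(MutationSpectrum("x", s), catalog)
        assert abs(fit.exposure("1") - 0.6) <= 0.05
        assert abs(fit.exposure("13") - 0.4) <= 0.05
        assert fit.cosine >= 0.98

    def test_scaling_invariance(self, catalog):
        rng = np.random.default_rng(7)
        s = rng.multinomial(500, 0.5 * catalog.column("2") + 0.5 * catalog.column("17"))
        f1 = refit_exposures(MutationSpectrum("x", s), catalog)
        f2 = refit_exposures(MutationSpectrum("x", 7 * s), catalog)
        assert np.allclose(f1.exposures, f2.exposures, atol=1e-9)

    def test_noise_spectrum_still_normalizes(self, catalog):
        rng = np.random.default_rng(0)
        s = rng.integers(5, 15, size=96)
        fit = refit_exposures(MutationSpectrum("x", s), catalog)
        assert fit.cosine < 1.0
        assert np.isclose(fit.exposures.sum(), 1.0)
        assert (fit.exposures >= 0).all()

    def test_unselected_exposures_exactly_zero(self, catalog):
        s = np.round(1000 * catalog.column("17")).astype(int)
        fit = refit_exposures(MutationSpectrum("x", s), catalog)
        for sid in catalog.signature_ids:
            if sid not in fit.selected:
                assert fit.exposure(sid) == 0.0

    def test_cosine_monotone_in_candidate_set(self, catalog):
        """Enlarging the candidate set never worsens the NNLS reconstruction."""
        cfg_kwargs = dict(epsilon_cos=0.0, min_exposure=0.0)
        rng = np.random.default_rng(4)
        for _ in range(5):
            s = rng.integers(0, 30, size=96)
            if s.sum() == 0:
                continue
            small = refit_exposures(
                MutationSpectrum("x", s), catalog,
                RefitConfig(candidates=("1", "4"), **cfg_kwargs),
            )
            big = refit_exposures(
                MutationSpectrum("x", s), catalog,
                RefitConfig(candidates=("1", "4", "13", "17"), **cfg_kwargs),
            )
            assert big.cosine >= small.cosine - 1e-9

    def test_empty_spectrum_rejected(self, catalog):
        with pytest.raises(ValueError, match="empty"):
            refit_exposures(MutationSpectrum("x", np.zeros(96, dtype=int)), catalog)


def _fit_with(selected, all_ids=("1", "2", "6")):
    expo = np.array([1.0 / len(selected) if s in selected else 0.0 for s in all_ids])
    return ExposureFit("s", list(all_ids), expo, tuple(selected), np.ones(96), 0.99)


class TestPrevalence:
    def test_percentages(self):
        fits = [_fit_with(("1",))] * 23 + [_fit_with(("2",))]
        prev = signature_prevalence(fits)
        assert prev["1"] == (23, 95.8)
        fits = [_fit_with(("6",))] * 5 + [_fit_with(("1",))] * 19
        assert signature_prevalence(fits)["6"] == (5, 20.8)

    def test_absent_signature_zero(self):
        prev = signature_prevalence([_fit_with(("1",))] * 4)
        assert prev["2"] == (0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            signature_prevalence([])
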