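"""96-context tabulation and signature exposure fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from msikit.signatures import (
    CONTEXTS_96,
    SignatureCatalogue,
    fit_exposures,
    synthetic_catalogue,
    tabulate_contexts,
)


def spectrum_from_profile(profile: np.ndarray, n: int, rng) -> pd.Series:
    return pd.Series(rng.multinomial(n, profile), index=list(CONTEXTS_96))


class TestTabulate:
    def test_purine_reference_reverse_complemented(self):
        # G>A with 5' T and 3' C folds to G[C>T]A
        refseqs = {"chr1": "ATGCA"}
        snvs = pd.DataFrame([{"chrom": "chr1", "pos": 3, "ref": "G", "alt": "A"}])
        spec = tabulate_contexts(snvs, refseqs)
        assert spec.sum() == 1
        assert spec["G[C>T]A"] == 1

    def test_pyrimidine_reference_recorded_directly(self):
        refseqs = {"chr1": "AACTT"}
        snvs = pd.DataFrame([{"chrom": "chr1", "pos": 3, "ref": "C", "alt": "A"}])
        spec = tabulate_contexts(snvs, refseqs)
        assert spec["A[C>A]T"] == 1

    def test_boundary_snv_excluded_with_warning(self):
        refseqs = {"chr1": "CTGCA"}
        snvs = pd.DataFrame(
            [
                {"chrom": "chr1", "pos": 1, "ref": "C", "alt": "A"},
                {"chrom": "chr1", "pos": 3, "ref": "G", "alt": "A"},
            ]
        )
        with pytest.warns(UserWarning):
            spec = tabulate_contexts(snvs, refseqs)
        assert spec.sum() == 1

    def test_count_conservation_and_permutation_invariance(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=500))
        refseqs = {"chr1": seq}
        rows = []
        for pos in rng.choice(np.arange(2, 500), size=120, replace=False):
            ref = seq[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            rows.append({"chrom": "chr1", "pos": int(pos), "ref": ref, "alt": alt})
        snvs = pd.DataFrame(rows)
        spec = tabulate_contexts(snvs, refseqs)
        assert spec.sum() == 120
        shuffled = snvs.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert tabulate_contexts(shuffled, refseqs).equals(spec)

    def test_strand_convention_idempotent(self, rng):
        """Reverse-complementing the reference leaves the spectrum unchanged."""
        seq = "".join(rng.choice(list("ACGT"), size=400))
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(comp)[::-1]
        L = len(seq)
        rows_fwd, rows_rev = [], []
        for pos in rng.choice(np.arange(2, L), size=80, replace=False):
            ref = seq[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            rows_fwd.append({"chrom": "chr1", "pos": int(pos), "ref": ref, "alt": alt})
            rows_rev.append(
                {
                    "chrom": "chr1",
                    "pos": int(L - pos + 1),
                    "ref": ref.translate(comp),
                    "alt": alt.translate(comp),
                }
            )
        fwd = tabulate_contexts(pd.DataFrame(rows_fwd), {"chr1": seq})
        rev = tabulate_contexts(pd.DataFrame(rows_rev), {"chr1": rc})
        assert fwd.equals(rev)

    def test_sampled_spectrum_matches_source_signature(self, rng):
        """Multinomial draws from one signature pass a chi-square GOF test."""
        cat = synthetic_catalogue()
        profile = cat["mmr_like"].to_numpy()
        counts = rng.multinomial(1000, profile)
        mask = profile > 0
        _, p = stats.chisquare(counts[mask], 1000 * profile[mask] / profile[mask].sum())
        assert p > 0.01


class TestExposureFit:
    def test_identity_recovery(self, rng):
        cat = synthetic_catalogue()
        spec = spectrum_from_profile(cat["mmr_like"].to_numpy(), 100_000, rng)
        fit = fit_exposures(spec, cat)
        assert fit.dominant_signature == "mmr_like"
        assert fit.exposures["mmr_like"] == pytest.approx(1.0, abs=0.02)
        assert fit.cosine == pytest.approx(1.0, abs=0.01)

    def test_exact_profile_gives_exposure_one(self):
        cat = synthetic_catalogue()
        spec = cat["clock_like"] * 1000
        fit = fit_exposures(spec, cat)
        assert fit.exposures["clock_like"] == pytest.approx(1.0, abs=1e-6)
        assert fit.cosine == pytest.approx(1.0, abs=1e-9)

    def test_mixture_recovery(self, rng):
        cat = synthetic_catalogue()
        mix = 0.7 * cat["mmr_like"].to_numpy() + 0.3 * cat["transversion"].to_numpy()
        spec = spectrum_from_profile(mix, 5000, rng)
        fit = fit_exposures(spec, cat)
        assert fit.exposures["mmr_like"] == pytest.approx(0.7, abs=0.05)
        assert fit.exposures["transversion"] == pytest.approx(0.3, abs=0.05)

    def test_zero_spectrum_is_missing(self):
        cat = synthetic_catalogue()
        with pytest.warns(UserWarning):
            assert fit_exposures(pd.Series(0, index=list(CONTEXTS_96)), cat) is None

    def test_cosine_mode_assigns_nearest(self, rng):
        cat = synthetic_catalogue()
        spec = spectrum_from_profile(cat["transversion"].to_numpy(), 3000, rng)
        fit = fit_exposures(spec, cat, method="cosine")
        assert fit.dominant_signature == "transversion"
        assert fit.exposures["transversion"] == 1.0

    def test_residual_never_increases_with_generating_signature(self, rng):
        """Adding the true signature to the catalogue can only improve fit."""
        cat = synthetic_catalogue()
        mix = 0.6 * cat["mmr_like"].to_numpy() + 0.4 * cat["flat"].to_numpy()
        spec = spectrum_from_profile(mix, 4000, rng)
        y = spec.to_numpy() / spec.sum()

        from scipy.optimize import nnls

        def residual(names):
            sub = SignatureCatalogue(cat.profiles[names])
            _, rnorm = nnls(sub.profiles.to_numpy(), y)
            return rnorm

        assert residual(["mmr_like", "flat", "clock_like"]) <= residual(["flat", "clock_like"]) + 1e-12

    def test_catalogue_validates_sums(self):
        bad = pd.DataFrame({"x": np.ones(96)}, index=list(CONTEXTS_96))
        with pytest.raises(ValueError):
            SignatureCatalogue(bad)


def test_cohort_with_single_signature_exposure(small_cohort):
    """Cohort-level 96-profile of an MMR-dominated cohort is mmr_like-led."""
    from msikit.signatures import fit_exposures, synthetic_catalogue, tabulate_contexts

    cat = synthetic_catalogue()
    total = None
    for sample in small_cohort.samples:
        snvs = sample.variants[sample.variants["variant_class"] == "SNV"]
        spec = tabulate_contexts(snvs, small_cohort.reference.seqs)
        total = spec if total is None else total + spec
    fit = fit_exposures(total, cat)
    assert fit.dominant_signature == "mmr_like"
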