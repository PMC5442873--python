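"""Neoantigen enumeration and the binding / self / cleavage cascade."""

import numpy as np
import pandas as pd
import pytest

from msikit.neoantigen import (
    AMINO_ACIDS,
    HlaTyping,
    MutantProteinContext,
    SurrogateBindingPredictor,
    SurrogateCleavagePredictor,
    binding_filter,
    build_protein_contexts,
    cleavage_filter,
    count_neoantigens,
    enumerate_mutant_peptides,
    expression_filter,
    pooled_percentile_ranks,
    self_proteome_filter,
)
from tests.conftest import A_START, make_variant
from tests.oracles import brute_force_binding, brute_force_windows, naive_substring_matches

TYPING = HlaTyping(
    "P1",
    ("HLA-A*01:01", "HLA-A*02:01", "HLA-B*07:02", "HLA-B*08:01", "HLA-C*04:01", "HLA-C*07:01"),
)


def context_for(protein: str, novel: int) -> MutantProteinContext:
    lo = max(0, novel - 10)
    hi = min(len(protein), novel + 1 + 10)
    return MutantProteinContext(
        "m1", "G", False, protein[lo:hi], novel - lo, novel - lo + 1, lo
    )


class TestEnumeration:
    def test_interior_snv_yields_38_windows(self, rng):
        protein = "".join(rng.choice(list(AMINO_ACIDS), size=500))
        ctx = context_for(protein, 99)  # residue 100 of 500
        peps = enumerate_mutant_peptides(ctx)
        assert len(peps) == 38
        assert peps["peptide"].is_unique or len(set(peps["peptide"])) <= 38
        assert set(peps["peptide"]) == brute_force_windows(protein, {99})

    def test_n_terminal_snv_clipped(self, rng):
        protein = "".join(rng.choice(list(AMINO_ACIDS), size=500))
        ctx = context_for(protein, 2)  # residue 3: 3 windows per length
        peps = enumerate_mutant_peptides(ctx)
        assert len(peps) == 12
        assert set(peps["peptide"]) == brute_force_windows(protein, {2})

    def test_frameshift_windows_match_oracle(self, rng):
        protein = "".join(rng.choice(list(AMINO_ACIDS), size=80))
        novel = set(range(40, 80))  # frameshifted tail to the (removed) stop
        ctx = MutantProteinContext("m2", "G", True, protein[30:], 10, 50, 30, True)
        peps = enumerate_mutant_peptides(ctx)
        assert set(peps["peptide"]) == brute_force_windows(protein, novel)

    def test_synonymous_mutation_yields_no_context(self, tiny_reference):
        refseqs, annotation = tiny_reference
        df = pd.DataFrame([make_variant(pos=A_START + 8, ref="A", alt="G", gene="GENEA")])
        df["effect"] = "synonymous_SNV"
        assert build_protein_contexts(df, annotation, refseqs) == []

    def test_frameshift_context_runs_to_stop(self, tiny_reference):
        refseqs, annotation = tiny_reference
        pos = A_START + 6
        from tests.conftest import GENOME

        ref = GENOME[pos - 1 : pos + 1]
        df = pd.DataFrame([make_variant(pos=pos, ref=ref, alt=ref[0], gene="GENEA")])
        df["effect"] = "frameshift_indel"
        (ctx,) = build_protein_contexts(df, annotation, refseqs)
        assert ctx.is_frameshift
        assert "*" not in ctx.stretch
        assert ctx.novel_end == len(ctx.stretch)  # novel residues run to the end


class TestExpressionFilter:
    def frame(self):
        return pd.DataFrame(
            [make_variant(pos=p, gene=g) for p, g in [(1, "G1"), (2, "G2"), (3, "G3")]]
        )

    def test_strictly_above_median(self):
        expr = pd.Series({"G1": 10.0, "G2": 5.0, "G3": 1.0})
        kept = expression_filter(self.frame(), expr)
        assert list(kept["gene"]) == ["G1"]  # G2 sits exactly at the median

    def test_all_equal_expression_drops_everything(self):
        expr = pd.Series({"G1": 2.0, "G2": 2.0, "G3": 2.0})
        assert expression_filter(self.frame(), expr).empty

    def test_unknown_gene_dropped_with_warning(self):
        expr = pd.Series({"G1": 10.0, "G3": 1.0})
        with pytest.warns(UserWarning):
            kept = expression_filter(self.frame(), expr)
        assert "G2" not in set(kept["gene"])


class TestBindingFilter:
    def candidates(self, rng, n=300):
        peptides = {
            "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(8, 12)))
            for _ in range(n)
        }
        return pd.DataFrame(
            {
                "peptide": sorted(peptides),
                "mutation_id": "m1",
                "gene": "G",
                "is_frameshift": False,
            }
        )

    def test_degenerate_pool_single_peptide(self):
        class Fixed:
            def predict(self, peptides, allele):
                return np.full(len(peptides), 400.0)

        typing = HlaTyping("P", ("A",) * 6)
        cands = pd.DataFrame(
            [{"peptide": "ACDEFGHI", "mutation_id": "m", "gene": "G", "is_frameshift": False}]
        )
        out = binding_filter(cands, typing, Fixed())
        assert len(out) == 1  # lowest rank by construction

    def test_rank_rule_conjunct_with_ic50(self):
        class TwoValues:
            def predict(self, peptides, allele):
                # first peptide strong (rank 0), second 499 nM but high rank
                return np.array([10.0 + i for i in range(len(peptides))][: len(peptides)]) * 1.0

        # construct explicit pool: 100 peptides with increasing ic50;
        # peptide #99 has ic50 109 < 500 but rank 99 -> dropped
        typing = HlaTyping("P", ("A",) * 6)
        cands = pd.DataFrame(
            {
                "peptide": [f"ACDEFGH{a}{b}" for a in "ACDEFGHIKL" for b in "ACDEFGHIKL"],
                "mutation_id": "m",
                "gene": "G",
                "is_frameshift": False,
            }
        )
        out = binding_filter(cands, typing, TwoValues())
        ranks = pooled_percentile_ranks(np.arange(100) + 10.0)
        expected_survivors = int((ranks < 2.0).sum())
        assert len(out) == expected_survivors

    def test_matches_brute_force_oracle(self, rng):
        cands = self.candidates(rng)
        predictor = SurrogateBindingPredictor()
        out = binding_filter(cands, TYPING, predictor)
        expected = brute_force_binding(
            list(cands["peptide"]), list(TYPING.unique_alleles), predictor
        )
        assert set(out["peptide"]) == expected

    def test_surrogate_is_deterministic(self):
        p = SurrogateBindingPredictor()
        q = SurrogateBindingPredictor()
        assert p.ic50("ACDEFGHIK", "HLA-A*02:01") == q.ic50("ACDEFGHIK", "HLA-A*02:01")
        assert p.ic50("ACDEFGHIK", "HLA-A*02:01") > 0


class TestSelfAndCleavage:
    def test_wildtype_peptide_dropped(self):
        cands = pd.DataFrame(
            [{"peptide": "MAGCKFPDR", "mutation_id": "m", "gene": "G", "is_frameshift": False}]
        )
        out = self_proteome_filter(cands, ["MAGCKFPDRLEH"])
        assert out.empty

    def test_novel_peptide_kept(self):
        cands = pd.DataFrame(
            [{"peptide": "WWWWWWWW", "mutation_id": "m", "gene": "G", "is_frameshift": False}]
        )
        assert len(self_proteome_filter(cands, ["MAGCKFPDRLEH"])) == 1

    def test_empty_proteome_warns_and_passes(self):
        cands = pd.DataFrame(
            [{"peptide": "WWWWWWWW", "mutation_id": "m", "gene": "G", "is_frameshift": False}]
        )
        with pytest.warns(UserWarning):
            assert len(self_proteome_filter(cands, [])) == 1

    def test_matches_naive_substring_oracle(self, rng):
        proteome = ["".join(rng.choice(list(AMINO_ACIDS), size=60)) for _ in range(20)]
        peptides = ["".join(rng.choice(list(AMINO_ACIDS), size=9)) for _ in range(50)]
        peptides += [proteome[0][5:14], proteome[7][0:9]]  # guaranteed self hits
        cands = pd.DataFrame(
            {"peptide": peptides, "mutation_id": "m", "gene": "G", "is_frameshift": False}
        )
        out = self_proteome_filter(cands, proteome)
        matches = naive_substring_matches(peptides, proteome)
        assert set(out["peptide"]) == set(peptides) - matches

    def test_cleavage_threshold_inclusive(self):
        predictor = SurrogateCleavagePredictor()
        at = next(a for a in AMINO_ACIDS if predictor.propensity[a] >= predictor.threshold)
        below = min(AMINO_ACIDS, key=lambda a: predictor.propensity[a])
        cands = pd.DataFrame(
            {
                "peptide": ["ACDEFGH" + at, "ACDEFGH" + below],
                "mutation_id": "m", "gene": "G", "is_frameshift": False,
            }
        )
        out = cleavage_filter(cands, predictor)
        assert list(out["peptide"]) == ["ACDEFGH" + at]

    def test_self_and_cleavage_order_independent(self, rng):
        proteome = ["".join(rng.choice(list(AMINO_ACIDS), size=80)) for _ in range(10)]
        peptides = ["".join(rng.choice(list(AMINO_ACIDS), size=9)) for _ in range(80)]
        cands = pd.DataFrame(
            {"peptide": peptides, "mutation_id": "m", "gene": "G", "is_frameshift": False}
        )
        cleavage = SurrogateCleavagePredictor()
        a = cleavage_filter(self_proteome_filter(cands, proteome), cleavage)
        b = self_proteome_filter(cleavage_filter(cands, cleavage), proteome)
        assert set(a["peptide"]) == set(b["peptide"])


class TestCounting:
    def test_peptide_binding_several_alleles_counted_once(self):
        survivors = pd.DataFrame(
            {
                "peptide": ["ACDEFGHIK"] * 3,
                "mutation_id": ["m1"] * 3,
                "is_frameshift": [False] * 3,
                "best_allele": ["A1", "A2", "A3"],
            }
        )
        n, yields = count_neoantigens(survivors)
        assert n == 1
        assert yields.loc[0, "n_peptides"] == 1

    def test_empty_survivors(self):
        empty = pd.DataFrame(columns=["peptide", "mutation_id", "is_frameshift"])
        n, yields = count_neoantigens(empty)
        assert n == 0 and yields.empty
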