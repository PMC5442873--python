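"""Somatic-call filtering, effect classification and mutation load."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msikit.variants import (
    FilterThresholds,
    classify_effects,
    filter_somatic_calls,
    left_align_indel,
    mutation_load,
)
from tests.conftest import A_START, B_END, GENOME, make_variant


def run_filter(**kwargs):
    df = pd.DataFrame([make_variant(**kwargs)])
    return filter_somatic_calls(df).iloc[0]


class TestFilterRules:
    @pytest.mark.parametrize(
        "kwargs, status, reason",
        [
            # all rules pass: VAF 0.33, tumor depth 30, clean normal
            (dict(tumor_alt=10, tumor_ref=20, normal_ref=12, normal_alt=0), "PASS", ""),
            # tumor coverage boundary: depth 14 fails, 15 passes
            (dict(tumor_alt=7, tumor_ref=7, normal_ref=30), "REJECT", "tumor_coverage"),
            (dict(tumor_alt=7, tumor_ref=8, normal_ref=30), "PASS", ""),
            # normal coverage boundary: 9 fails, 10 passes
            (dict(normal_ref=9, normal_alt=0), "REJECT", "normal_coverage"),
            (dict(normal_ref=10, normal_alt=0), "PASS", ""),
            # one mutated normal read accepted, two rejected
            (dict(normal_ref=49, normal_alt=1), "PASS", ""),
            (dict(normal_ref=48, normal_alt=2), "REJECT", "normal_alt_reads"),
            # VAF rule: 4/100 = 4% out, 5/100 = 5% exactly is kept
            (dict(tumor_alt=4, tumor_ref=96), "REJECT", "vaf"),
            (dict(tumor_alt=5, tumor_ref=95), "PASS", ""),
            # zero tumor depth: explicit no-coverage reason, no division error
            (dict(tumor_alt=0, tumor_ref=0), "REJECT", "no_coverage"),
        ],
    )
    def test_boundary_variants(self, kwargs, status, reason):
        row = run_filter(**kwargs)
        assert row["filter_status"] == status
        assert row["rejection_reason"] == reason

    def test_rejection_reason_is_first_failing_rule(self):
        # fails normal coverage, tumor coverage and VAF: normal wins
        row = run_filter(tumor_alt=0, tumor_ref=5, normal_ref=3, normal_alt=0)
        assert row["rejection_reason"] == "normal_coverage"

    def test_filtering_is_idempotent(self, rng):
        df = pd.DataFrame(
            [
                make_variant(
                    tumor_alt=int(a), tumor_ref=int(r),
                    normal_ref=int(n), normal_alt=int(m),
                )
                for a, r, n, m in zip(
                    rng.integers(0, 30, 200), rng.integers(0, 120, 200),
                    rng.integers(0, 40, 200), rng.integers(0, 4, 200),
                )
            ]
        )
        once = filter_somatic_calls(df)
        retained = once[once["filter_status"] == "PASS"]
        twice = filter_somatic_calls(retained[df.columns])
        assert (twice["filter_status"] == "PASS").all()

    @given(
        min_t=st.integers(0, 40), min_n=st.integers(0, 20),
        min_v=st.floats(0, 0.5), max_a=st.integers(0, 3),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_retained_set_shrinks_as_thresholds_tighten(self, min_t, min_n, min_v, max_a):
        rng = np.random.default_rng(99)
        df = pd.DataFrame(
            [
                make_variant(
                    tumor_alt=int(a), tumor_ref=int(r),
                    normal_ref=int(n), normal_alt=int(m),
                )
                for a, r, n, m in zip(
                    rng.integers(0, 30, 100), rng.integers(0, 120, 100),
                    rng.integers(0, 40, 100), rng.integers(0, 4, 100),
                )
            ]
        )
        base = FilterThresholds()
        tight = FilterThresholds(
            min_normal_depth=base.min_normal_depth + min_n,
            min_tumor_depth=base.min_tumor_depth + min_t,
            min_vaf=base.min_vaf + min_v,
            max_normal_alt_reads=max(0, base.max_normal_alt_reads - max_a),
        )
        kept_base = set(filter_somatic_calls(df, base).query("filter_status == 'PASS'").index)
        kept_tight = set(filter_somatic_calls(df, tight).query("filter_status == 'PASS'").index)
        assert kept_tight <= kept_base


class TestEffectClassification:
    def classify_one(self, tiny_reference, **kwargs):
        refseqs, annotation = tiny_reference
        df = pd.DataFrame([make_variant(**kwargs)])
        return classify_effects(df, annotation, refseqs).iloc[0]["effect"]

    def test_synonymous_snv(self, tiny_reference):
        # codon 3 of gene A is GGA (Gly); GGA->GGG stays Gly
        pos = A_START + 8  # third base of codon 3
        assert GENOME[pos - 1] == "A"
        assert self.classify_one(tiny_reference, pos=pos, ref="A", alt="G") == "synonymous_SNV"

    def test_nonsynonymous_snv(self, tiny_reference):
        # codon 2 GCT (Ala) -> ACT (Thr)
        pos = A_START + 3
        assert GENOME[pos - 1] == "G"
        assert self.classify_one(tiny_reference, pos=pos, ref="G", alt="A") == "nonsynonymous_SNV"

    def test_stopgain_snv(self, tiny_reference):
        # codon 5 AAA (Lys) -> TAA (stop)
        pos = A_START + 12
        assert GENOME[pos - 1] == "A"
        assert self.classify_one(tiny_reference, pos=pos, ref="A", alt="T") == "stopgain"

    def test_minus_strand_nonsynonymous(self, tiny_reference):
        # gene B sense codon 2 CCT (Pro); middle base maps to genomic G
        pos = B_END - 4
        assert GENOME[pos - 1] == "G"
        assert self.classify_one(tiny_reference, pos=pos, ref="G", alt="T") == "nonsynonymous_SNV"

    def test_one_bp_deletion_is_frameshift(self, tiny_reference):
        pos = A_START + 6
        ref = GENOME[pos - 1 : pos + 1]
        effect = self.classify_one(tiny_reference, pos=pos, ref=ref, alt=ref[0])
        assert effect == "frameshift_indel"

    def test_three_bp_deletion_is_inframe(self, tiny_reference):
        pos = A_START + 6
        ref = GENOME[pos - 1 : pos + 3]
        effect = self.classify_one(tiny_reference, pos=pos, ref=ref, alt=ref[0])
        assert effect == "inframe_indel"

    def test_intergenic_variant_is_noncoding(self, tiny_reference):
        assert self.classify_one(tiny_reference, pos=3, ref="G", alt="A") == "noncoding"


class TestMutationLoad:
    def test_empty_set(self):
        load = mutation_load(pd.DataFrame(columns=["ref", "alt", "effect"]))
        assert (load.n_total, load.n_snv, load.n_indel) == (0, 0, 0)
        assert np.isnan(load.ratio_affecting_silent)

    def test_ratio_arithmetic(self):
        rows = [make_variant(pos=i) for i in range(8)]
        df = pd.DataFrame(rows)
        df["effect"] = ["nonsynonymous_SNV"] * 5 + ["frameshift_indel"] + ["synonymous_SNV"] * 2
        load = mutation_load(df)
        assert load.n_affecting == 6 and load.n_silent == 2
        assert load.ratio_affecting_silent == pytest.approx(3.0)

    def test_counts_partition_retained_set(self):
        rows = [make_variant(pos=i) for i in range(10)]
        df = pd.DataFrame(rows)
        df["effect"] = (
            ["nonsynonymous_SNV"] * 4 + ["stopgain"] + ["synonymous_SNV"] * 2
            + ["inframe_indel"] + ["noncoding"] * 2
        )
        load = mutation_load(df)
        assert load.n_affecting + load.n_silent + load.n_noncoding == load.n_total == 10

    def test_counts_match_planted_truth(self, small_cohort):
        """SNV/indel counts agree with the generator's planted classes."""
        sample = small_cohort.samples[0]
        df = sample.variants.copy()
        df["effect"] = "noncoding"
        load = mutation_load(df)
        planted_snv = int((sample.variants["variant_class"] == "SNV").sum())
        assert load.n_snv == planted_snv
        assert load.n_indel == len(df) - planted_snv


def test_left_align_indel_shifts_through_run():
    #        123456789
    seq = "GCCAAAAT"
    # deletion of one A written at the right edge of the run
    pos, ref, alt = left_align_indel(6, "AA", "A", seq)
    assert (pos, ref, alt) == (3, "CA", "C")
    # already-left-aligned representation is unchanged
    assert left_align_indel(3, "CA", "C", seq) == (3, "CA", "C")
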