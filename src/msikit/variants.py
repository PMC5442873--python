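"""Somatic-call retention filters, effect classification, mutation load.

Somatic variants arrive as a table of paired tumor-normal read counts
(one row per bi-allelic variant; multi-allelic records are decomposed on
import, see :mod:`msikit.io`).  Retention applies the study filters in a
fixed order -- normal coverage >= 10, tumor coverage >= 15, VAF >= 5%, at
most one mutated read in the normal -- recording the first failing rule
as the rejection reason.  Coverage is ref + alt reads at the locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "FilterThresholds",
    "MutationLoad",
    "VARIANT_COLUMNS",
    "EFFECTS",
    "add_vaf",
    "filter_somatic_calls",
    "classify_effects",
    "mutation_load",
    "left_align_indel",
]

#: canonical column set of the variant table
VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_class",
    "gene",
    "tumor_ref_reads",
    "tumor_alt_reads",
    "normal_ref_reads",
    "normal_alt_reads",
]

EFFECTS = (
    "nonsynonymous_SNV",
    "synonymous_SNV",
    "frameshift_indel",
    "inframe_indel",
    "stopgain",
    "splice",
    "noncoding",
)

#: effects counted as amino-acid-affecting; splice SNVs are included here
#: but also flagged separately by :func:`mutation_load` so the opposite
#: convention is recoverable.
AFFECTING_EFFECTS = ("nonsynonymous_SNV", "frameshift_indel", "stopgain", "splice")
SILENT_EFFECTS = ("synonymous_SNV", "inframe_indel")


@dataclass
class FilterThresholds:
    """Somatic-call retention thresholds (study defaults)."""

    min_normal_depth: int = 10
    min_tumor_depth: int = 15
    min_vaf: float = 0.05  # inclusive: exactly 5% is kept
    max_normal_alt_reads: int = 1

    def __post_init__(self) -> None:
        if min(self.min_normal_depth, self.min_tumor_depth, self.max_normal_alt_reads) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.min_vaf < 0:
            raise ValueError("min_vaf must be non-negative")


@dataclass
class MutationLoad:
    """Per-tumor mutation counts over the retained, classified variants."""

    n_total: int
    n_affecting: int
    n_silent: int
    n_noncoding: int
    n_snv: int
    n_indel: int
    n_splice: int
    ratio_affecting_silent: float  # NaN when no silent mutations


def variant_class(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    return "insertion" if len(alt) > len(ref) else "deletion"


def add_vaf(df: pd.DataFrame) -> pd.Series:
    """Tumor variant allele frequency; NaN at zero tumor depth."""
    depth = df["tumor_ref_reads"] + df["tumor_alt_reads"]
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = df["tumor_alt_reads"] / depth
    return vaf.where(depth > 0, np.nan)


def filter_somatic_calls(
    df: pd.DataFrame, thresholds: FilterThresholds | None = None
) -> pd.DataFrame:
    """Apply the retention filters; annotate status and rejection reason.

    Returns a copy with columns ``vaf``, ``filter_status`` ("PASS" or
    "REJECT") and ``rejection_reason`` (the first failing rule, in the
    order normal coverage, tumor coverage, VAF, normal alt reads; zero
    tumor depth is reported as "no_coverage").
    """
    if thresholds is None:
        thresholds = FilterThresholds()
    out = df.copy()
    normal_depth = out["normal_ref_reads"] + out["normal_alt_reads"]
    tumor_depth = out["tumor_ref_reads"] + out["tumor_alt_reads"]
    vaf = add_vaf(out)
    out["vaf"] = vaf

    conditions = [
        normal_depth < thresholds.min_normal_depth,
        tumor_depth == 0,
        tumor_depth < thresholds.min_tumor_depth,
        vaf < thresholds.min_vaf,
        out["normal_alt_reads"] > thresholds.max_normal_alt_reads,
    ]
    reasons = ["normal_coverage", "no_coverage", "tumor_coverage", "vaf", "normal_alt_reads"]
    out["rejection_reason"] = np.select(conditions, reasons, default="")
    out["filter_status"] = np.where(out["rejection_reason"] == "", "PASS", "REJECT")
    return out


def left_align_indel(pos: int, ref: str, alt: str, seq: str) -> tuple[int, str, str]:
    """Left-align and trim a (1-based) indel against its chromosome sequence.

    VCF dialects place the same slippage indel at different anchors; this
    normalises to the leftmost representation with a single anchor base.
    """
    ref, alt = ref.upper(), alt.upper()
    while ref[-1] == alt[-1]:
        if len(ref) > 1 and len(alt) > 1:
            ref, alt = ref[:-1], alt[:-1]
        elif pos > 1:  # extend left, then drop the shared last base
            prev = seq[pos - 2].upper()
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            pos -= 1
        else:
            break
    # trim identical leading bases beyond the single anchor
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0] and ref[1] == alt[1]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


class _TranscriptIndex:
    """Sorted-interval lookup over non-overlapping single-CDS transcripts."""

    def __init__(self, annotation: pd.DataFrame):
        self._by_chrom = {}
        for chrom, group in annotation.groupby("chrom"):
            g = group.sort_values("cds_start").reset_index(drop=True)
            self._by_chrom[chrom] = (
                g["cds_start"].to_numpy(),
                g["cds_end"].to_numpy(),
                g,
            )

    def find(self, chrom: str, pos: int, end: int):
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, g = entry
        i = int(np.searchsorted(starts, end, side="right")) - 1
        for j in (i, i - 1):  # the span may start in the previous interval
            if 0 <= j < len(g) and ends[j] >= pos and starts[j] <= end:
                return g.iloc[j]
        return None


def _find_transcript(annotation: pd.DataFrame, chrom: str, pos: int, end: int):
    return _TranscriptIndex(annotation).find(chrom, pos, end)


def _snv_effect(pos: int, alt: str, tx, refseqs: Mapping[str, str]) -> str:
    seq = refseqs[tx["chrom"]]
    cds_start, cds_end, strand = int(tx["cds_start"]), int(tx["cds_end"]), tx["strand"]
    if strand == "+":
        idx = pos - cds_start
        alt_base = alt
    else:
        idx = cds_end - pos
        alt_base = str(Seq(alt).reverse_complement())
    codon_i, within = divmod(idx, 3)
    cds = seq[cds_start - 1 : cds_end]
    if strand == "-":
        cds = str(Seq(cds).reverse_complement())
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    if len(codon) < 3:
        return "noncoding"
    mutant = codon[:within] + alt_base + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutant).translate())
    if aa_alt == aa_ref:
        return "synonymous_SNV"
    if aa_alt == "*":
        return "stopgain"
    return "nonsynonymous_SNV"


def classify_effects(
    df: pd.DataFrame, annotation: pd.DataFrame, refseqs: Mapping[str, str]
) -> pd.DataFrame:
    """Assign transcript effects (strand-aware) and gene symbols.

    The annotation table has one canonical transcript per gene with a
    single CDS interval (columns ``gene, transcript, chrom, cds_start,
    cds_end, strand``; 1-based inclusive).  Variants outside every CDS are
    classified ``noncoding``, never an error.
    """
    out = df.copy()
    index = _TranscriptIndex(annotation)
    effects, genes = [], []
    for row in out.itertuples(index=False):
        ref, alt = row.ref, row.alt
        if len(ref) == 1 and len(alt) == 1:
            span_start = span_end = row.pos
        elif len(ref) > len(alt):  # deletion: affected bases follow the anchor
            span_start, span_end = row.pos + 1, row.pos + len(ref) - 1
        else:  # insertion between pos and pos + 1
            span_start, span_end = row.pos, row.pos + 1
        tx = index.find(row.chrom, span_start, span_end)
        if tx is None:
            effects.append("noncoding")
            genes.append(getattr(row, "gene", "") or "")
            continue
        genes.append(tx["gene"])
        if len(ref) == 1 and len(alt) == 1:
            effects.append(_snv_effect(row.pos, alt, tx, refseqs))
        else:
            delta = abs(len(ref) - len(alt))
            effects.append("frameshift_indel" if delta % 3 else "inframe_indel")
    out["effect"] = effects
    out["gene"] = genes
    return out


def mutation_load(df: pd.DataFrame) -> MutationLoad:
    """Count retained mutations by class and the affecting:silent ratio.

    Operates on the classified variant table (post-filter rows only, or
    pass the full table and subset on ``filter_status`` first).  The ratio
    is reported as NaN when there are no silent mutations.
    """
    effect = df["effect"] if "effect" in df.columns else pd.Series([], dtype=str)
    n_total = int(len(df))
    n_affecting = int(effect.isin(AFFECTING_EFFECTS).sum())
    n_silent = int(effect.isin(SILENT_EFFECTS).sum())
    n_noncoding = n_total - n_affecting - n_silent
    n_splice = int((effect == "splice").sum())
    if len(df):
        is_snv = (df["ref"].str.len() == 1) & (df["alt"].str.len() == 1)
        n_snv, n_indel = int(is_snv.sum()), int((~is_snv).sum())
    else:
        n_snv = n_indel = 0
    ratio = n_affecting / n_silent if n_silent else float("nan")
    return MutationLoad(n_total, n_affecting, n_silent, n_noncoding, n_snv, n_indel, n_splice, ratio)
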