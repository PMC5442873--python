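"""Microsatellite cataloguing and MSI scoring from repeat-length histograms.

The MSI level of a tumor is summarised as the percentage of catalogued
microsatellite loci whose read-level repeat-length distribution differs
significantly between tumor and matched normal.  Loci are catalogued from
the reference sequence (homopolymers of >= 5 bp and tandem repeats with
unit length up to 5); per-locus instability is called with a two-sample
test on the paired length histograms, with Benjamini-Hochberg control of
the false discovery rate across loci within a sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MicrosatelliteLocus",
    "RepeatLengthHistogram",
    "MsiResult",
    "catalogue_microsatellites",
    "instability_pvalue",
    "call_somatic_instability",
    "score_sample",
    "msi_score",
]


@dataclass(frozen=True)
class MicrosatelliteLocus:
    """A maximal tandem repeat in the reference.

    ``start`` is the 1-based position of the first base of the run;
    ``repeat_unit`` is the primitive unit (``"AA"`` is stored as ``"A"``),
    ``n_units`` the number of complete units, and ``span`` the number of
    reference bases covered (``len(repeat_unit) * n_units``).
    """

    chrom: str
    start: int
    repeat_unit: str
    n_units: int

    @property
    def span(self) -> int:
        return len(self.repeat_unit) * self.n_units

    @property
    def end(self) -> int:
        """1-based inclusive last base of the run."""
        return self.start + self.span - 1

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.start}:{self.repeat_unit}"


@dataclass
class RepeatLengthHistogram:
    """Observed read support per repeat length (in units) at one locus."""

    locus_id: str
    tissue: str  # "tumor" | "normal"
    counts: dict[int, int]

    @property
    def total_reads(self) -> int:
        return int(sum(self.counts.values()))


@dataclass
class MsiResult:
    """Per-sample MSI summary with the per-locus score table."""

    sample: str
    loci: pd.DataFrame  # locus_id, n_tumor, n_normal, pvalue, qvalue, status
    msi_score: float
    n_scored: int
    n_unstable: int


def _is_primitive(unit: str) -> bool:
    """True if ``unit`` is not a repetition of a shorter string."""
    u = len(unit)
    for d in range(1, u):
        if u % d == 0 and unit[:d] * (u // d) == unit:
            return False
    return True


def _scan_chromosome(
    seq: str, chrom: str, min_unit: int, max_unit: int, min_span: int, min_homopolymer: int
) -> list[MicrosatelliteLocus]:
    n = len(seq)
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    loci: list[MicrosatelliteLocus] = []
    for u in range(min_unit, max_unit + 1):
        if n < 2 * u:
            continue
        eq = arr[u:] == arr[:-u]
        # maximal stretches of True in `eq`: a stretch of m Trues starting
        # at i means seq[i : i + m + u] is periodic with period u and is
        # char-level maximal on both sides.
        padded = np.concatenate(([False], eq, [False]))
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)  # exclusive in eq coordinates
        for i, j in zip(starts, ends):
            stretch = int(j - i) + u  # char-level periodic stretch length
            n_units = stretch // u
            if n_units < 2:
                continue
            unit = seq[i : i + u]
            if not _is_primitive(unit):
                continue
            span = n_units * u
            if u == 1:
                if n_units < min_homopolymer:
                    continue
            elif span < min_span:
                continue
            loci.append(MicrosatelliteLocus(chrom, int(i) + 1, unit, int(n_units)))
    loci.sort(key=lambda l: (l.start, len(l.repeat_unit)))
    return loci


def catalogue_microsatellites(
    reference: Mapping[str, str] | str,
    min_unit: int = 1,
    max_unit: int = 5,
    min_span: int = 5,
    min_homopolymer: int = 5,
) -> list[MicrosatelliteLocus]:
    """Catalogue every maximal microsatellite in the reference.

    Homopolymers require at least ``min_homopolymer`` bases; repeats with
    unit length 2..``max_unit`` require at least two complete units and a
    span of at least ``min_span`` bases.  Runs are maximal (not extendable
    in either direction) and reported once, under their primitive unit and
    leftmost start, so rotated duplicates never appear.
    """
    if isinstance(reference, str):
        reference = {"seq": reference}
    loci: list[MicrosatelliteLocus] = []
    for chrom, seq in reference.items():
        loci.extend(
            _scan_chromosome(str(seq), chrom, min_unit, max_unit, min_span, min_homopolymer)
        )
    return loci


def _merged_table(tumor: Mapping[int, int], normal: Mapping[int, int]) -> np.ndarray:
    lengths = sorted(set(tumor) | set(normal))
    table = np.array(
        [[tumor.get(k, 0) for k in lengths], [normal.get(k, 0) for k in lengths]],
        dtype=float,
    )
    return table[:, table.sum(axis=0) > 0]


def _pool_low_expected(table: np.ndarray, min_expected: float = 5.0) -> np.ndarray:
    """Merge adjacent length categories until all expected counts >= 5."""
    table = table.copy()
    while table.shape[1] > 1:
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        col_min = expected.min(axis=0)
        if col_min.min() >= min_expected:
            break
        j = int(np.argmin(col_min))
        # merge into the smaller adjacent column
        if j == 0:
            k = 1
        elif j == table.shape[1] - 1:
            k = j - 1
        else:
            k = j - 1 if table[:, j - 1].sum() <= table[:, j + 1].sum() else j + 1
        table[:, k] += table[:, j]
        table = np.delete(table, j, axis=1)
    return table


def instability_pvalue(
    tumor_counts: Mapping[int, int],
    normal_counts: Mapping[int, int],
    method: str = "chi2",
) -> float:
    """Two-sample p-value for a tumor-vs-normal repeat-length difference.

    ``chi2`` compares the full length distributions after pooling sparse
    categories (expected count < 5); ``fisher`` collapses to a 2x2 table of
    modal-normal length vs any other length and applies Fisher's exact test.
    """
    if method == "chi2":
        table = _merged_table(tumor_counts, normal_counts)
        if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
            return 1.0
        table = _pool_low_expected(table)
        if table.shape[1] < 2:
            return 1.0
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(p)
    if method == "fisher":
        ref_len = max(normal_counts, key=lambda k: normal_counts[k])
        t_ref = tumor_counts.get(ref_len, 0)
        t_alt = sum(v for k, v in tumor_counts.items() if k != ref_len)
        n_ref = normal_counts.get(ref_len, 0)
        n_alt = sum(v for k, v in normal_counts.items() if k != ref_len)
        _, p = stats.fisher_exact([[t_ref, t_alt], [n_ref, n_alt]])
        return float(p)
    raise ValueError(f"unknown method {method!r}")


def call_somatic_instability(
    tumor: RepeatLengthHistogram,
    normal: RepeatLengthHistogram,
    min_reads: int = 20,
    alpha: float = 0.05,
    method: str = "chi2",
) -> str:
    """Call one locus unstable/stable/not_scored from its paired histograms.

    This convenience form tests a single locus at level ``alpha`` without
    multiple-testing correction; cohort analyses should use
    :func:`score_sample`, which applies BH FDR control across loci.
    """
    if tumor.locus_id != normal.locus_id:
        raise ValueError(
            f"histograms refer to different loci: {tumor.locus_id} vs {normal.locus_id}"
        )
    if tumor.total_reads < min_reads or normal.total_reads < min_reads:
        return "not_scored"
    p = instability_pvalue(tumor.counts, normal.counts, method=method)
    return "unstable" if p < alpha else "stable"


def score_sample(
    histograms: pd.DataFrame,
    sample: str = "",
    min_reads: int = 20,
    alpha: float = 0.05,
    method: str = "chi2",
) -> MsiResult:
    """Score all loci of one sample and compute its MSI score.

    ``histograms`` is the long exchange table with columns
    ``locus_id, tissue, length, reads`` (tissue in {tumor, normal}).
    Loci with fewer than ``min_reads`` reads in either tissue are
    ``not_scored``; the rest are tested and called unstable at FDR
    ``alpha`` after Benjamini-Hochberg correction across the scored loci.
    """
    required = {"locus_id", "tissue", "length", "reads"}
    missing = required - set(histograms.columns)
    if missing:
        raise ValueError(f"histogram table lacks columns: {sorted(missing)}")
    rows = []
    for locus_id, group in histograms.groupby("locus_id", sort=True):
        counts = {
            tissue: dict(
                zip(sub["length"].astype(int), sub["reads"].astype(int))
            )
            for tissue, sub in group.groupby("tissue")
        }
        t = counts.get("tumor", {})
        n = counts.get("normal", {})
        n_t, n_n = sum(t.values()), sum(n.values())
        if n_t < min_reads or n_n < min_reads:
            rows.append((locus_id, n_t, n_n, np.nan, "not_scored"))
        else:
            rows.append((locus_id, n_t, n_n, instability_pvalue(t, n, method), ""))
    loci = pd.DataFrame(rows, columns=["locus_id", "n_tumor", "n_normal", "pvalue", "status"])
    scored = loci["status"] != "not_scored"
    loci["qvalue"] = np.nan
    if scored.any():
        reject, qvals, _, _ = multipletests(
            loci.loc[scored, "pvalue"].to_numpy(), alpha=alpha, method="fdr_bh"
        )
        loci.loc[scored, "qvalue"] = qvals
        loci.loc[scored, "status"] = np.where(reject, "unstable", "stable")
    score = msi_score(loci["status"])
    n_scored = int(scored.sum())
    n_unstable = int((loci["status"] == "unstable").sum())
    return MsiResult(sample, loci, score, n_scored, n_unstable)


def msi_score(statuses: Iterable[str]) -> float:
    """MSI score: 100 x unstable / (unstable + stable) over scored loci."""
    statuses = pd.Series(list(statuses))
    n_unstable = int((statuses == "unstable").sum())
    n_scored = int(statuses.isin(["unstable", "stable"]).sum())
    if n_scored == 0:
        warnings.warn("no scored loci; MSI score is undefined", stacklevel=2)
        return float("nan")
    return 100.0 * n_unstable / n_scored
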