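"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is deliberately written with a different technique than the
library code it checks (regex scans, explicit double loops, per-base
tallies) so agreement is meaningful.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd


def _primitive(unit: str) -> bool:
    return all(
        not (len(unit) % d == 0 and unit[:d] * (len(unit) // d) == unit)
        for d in range(1, len(unit))
    )


def regex_microsatellites(
    seq: str, min_homopolymer: int = 5, min_span: int = 5, max_unit: int = 5
) -> set[tuple[int, str, int]]:
    """Regex-based maximal-tandem-repeat scan.

    Returns {(1-based start, unit, n_units)}.  A lookahead at every
    position captures the greedy whole-unit repeat starting there; keeps
    only char-level left-maximal starts and primitive units.
    """
    found = set()
    for u in range(1, max_unit + 1):
        pattern = re.compile(r"(?=(([ACGT]{%d})\2+))" % u)
        for m in pattern.finditer(seq):
            i = m.start()
            unit = m.group(2)
            if not _primitive(unit):
                continue
            if i > 0 and seq[i - 1] == seq[i - 1 + u]:
                continue  # left-extendable: not the maximal start
            stretch = m.group(1)
            # extend char-level to count whole units of the maximal stretch
            j = i + len(stretch)
            while j < len(seq) and seq[j] == seq[j - u]:
                j += 1
            n_units = (j - i) // u
            span = n_units * u
            if u == 1:
                if n_units < min_homopolymer:
                    continue
            elif span < min_span:
                continue
            found.add((i + 1, unit, n_units))
    return found


def regex_homopolymers(cds: str, min_len: int = 6) -> list[tuple[int, str, int]]:
    """[(1-based cds start, base, run length)] via regex."""
    out = []
    for m in re.finditer(r"(A+|C+|G+|T+)", cds.upper()):
        if len(m.group()) >= min_len:
            out.append((m.start() + 1, m.group()[0], len(m.group())))
    return out


def brute_force_windows(
    protein: str, novel: set[int], lengths=(8, 9, 10, 11)
) -> set[str]:
    """Every L-window of the full mutant protein containing a novel residue."""
    peptides = set()
    for L in lengths:
        for i in range(0, len(protein) - L + 1):
            if any(i <= k < i + L for k in novel):
                peptides.add(protein[i : i + L])
    return peptides


def brute_force_binding(
    peptides: list[str], alleles: list[str], predictor, ic50_max=500.0, rank_max=2.0
) -> set[str]:
    """Pooled percentile-rank binding filter, re-derived peptide by peptide.

    Predictions are made one (peptide, allele) pair at a time through the
    scalar contract; the strictly-lower count uses bisect on the sorted
    pool (equivalent to the counting definition, tested separately).
    """
    from bisect import bisect_left

    pool = []
    for pep in peptides:
        for al in alleles:
            pool.append((pep, al, predictor.ic50(pep, al)))
    values = sorted(v for _, _, v in pool)
    n = len(values)
    survivors = set()
    for pep, al, v in pool:
        rank = 100.0 * bisect_left(values, v) / n
        if v < ic50_max and rank < rank_max:
            survivors.add(pep)
    return survivors


def naive_substring_matches(peptides: list[str], proteome: list[str]) -> set[str]:
    return {p for p in peptides if any(p in prot for prot in proteome)}


def per_base_fga(segments: pd.DataFrame, ploidy: float) -> float:
    """Fraction of genome altered by an explicit per-base tally."""
    altered = covered = 0
    target = int(round(ploidy))
    for row in segments.itertuples(index=False):
        for _base in range(int(row.start), int(row.end) + 1):
            covered += 1
            if int(row.n_major) + int(row.n_minor) != target:
                altered += 1
    return 100.0 * altered / covered


def random_segment_profiles(
    rng: np.random.Generator, n_samples: int, chrom_len: int = 1000
) -> pd.DataFrame:
    """Random non-overlapping multi-sample segment profiles for SRO tests."""
    rows = []
    for s in range(n_samples):
        cuts = np.sort(rng.choice(np.arange(2, chrom_len), size=rng.integers(1, 6), replace=False))
        bounds = [1, *cuts.tolist(), chrom_len + 1]
        prev_cn = None
        for a, b in zip(bounds[:-1], bounds[1:]):
            while True:
                cn = (int(rng.integers(0, 4)), int(rng.integers(0, 3)))
                cn = (max(cn), min(cn))
                if cn != prev_cn:  # adjacent segments must differ to be maximal
                    break
            prev_cn = cn
            rows.append((f"S{s}", "chr1", a, b - 1, cn[0], cn[1]))
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "n_major", "n_minor"])
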