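"""Allele-specific copy-number harmonisation, LOH calls, genome altered.

Segments arrive as per-sample tables of allele-specific copy numbers
(``n_major >= n_minor``), typically produced by an allele-specific
segmentation tool; this module harmonises breakpoints across samples into
smallest regions of overlap (SRO), calls LOH and copy-number-neutral LOH
against the sample ploidy, and computes the fraction of the covered
genome whose total copy number differs from the rounded sample ploidy.
Coordinates are 1-based inclusive throughout; BED export converts to
0-based half-open.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SEGMENT_COLUMNS",
    "validate_segments",
    "smallest_regions_of_overlap",
    "merge_equal_adjacent",
    "call_loh",
    "call_loh_segments",
    "fraction_genome_altered",
    "loh_to_bed",
]

SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "n_major", "n_minor"]


def validate_segments(df: pd.DataFrame) -> None:
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"segment table lacks columns: {sorted(missing)}")
    if (df["end"] < df["start"]).any():
        raise ValueError("segment end < start")
    if (df[["n_major", "n_minor"]] < 0).any().any():
        raise ValueError("negative copy numbers")
    for (sample, chrom), group in df.groupby(["sample", "chrom"]):
        g = group.sort_values("start")
        if (g["start"].to_numpy()[1:] <= g["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping segments within {sample}/{chrom}")


def smallest_regions_of_overlap(segments: pd.DataFrame) -> pd.DataFrame:
    """Split every sample's profile at the union of all breakpoints.

    Region boundaries are the union of all samples' segment starts and
    ends per chromosome; each (region, sample) inherits the copy-number
    values of the sample's original enclosing segment.  Regions covered by
    no sample are dropped.  Extra per-segment columns (ploidy, purity)
    are carried along.
    """
    validate_segments(segments)
    extra = [c for c in segments.columns if c not in SEGMENT_COLUMNS]
    out = []
    for chrom, group in segments.groupby("chrom", sort=True):
        bounds = np.unique(
            np.concatenate([group["start"].to_numpy(), group["end"].to_numpy() + 1])
        )
        region_starts = bounds[:-1]
        region_ends = bounds[1:] - 1
        for sample, sg in group.groupby("sample", sort=True):
            sg = sg.sort_values("start")
            idx = np.searchsorted(sg["start"].to_numpy(), region_starts, side="right") - 1
            for rs, re_, k in zip(region_starts, region_ends, idx):
                if k < 0:
                    continue
                row = sg.iloc[k]
                if row["end"] < rs:  # region falls in a gap of this sample
                    continue
                rec = {
                    "sample": sample,
                    "chrom": chrom,
                    "start": int(rs),
                    "end": int(re_),
                    "n_major": row["n_major"],
                    "n_minor": row["n_minor"],
                }
                for c in extra:
                    rec[c] = row[c]
                out.append(rec)
    return pd.DataFrame(out, columns=SEGMENT_COLUMNS + extra)


def merge_equal_adjacent(segments: pd.DataFrame) -> pd.DataFrame:
    """Re-merge touching regions with identical copy numbers per sample.

    Inverse of :func:`smallest_regions_of_overlap` for a single sample's
    profile: splitting then merging reconstructs the original segments.
    """
    extra = [c for c in segments.columns if c not in SEGMENT_COLUMNS]
    merged = []
    for (sample, chrom), group in segments.groupby(["sample", "chrom"], sort=True):
        group = group.sort_values("start")
        current = None
        for _, row in group.iterrows():
            if (
                current is not None
                and row["start"] == current["end"] + 1
                and row["n_major"] == current["n_major"]
                and row["n_minor"] == current["n_minor"]
            ):
                current["end"] = row["end"]
            else:
                if current is not None:
                    merged.append(current)
                current = row[SEGMENT_COLUMNS + extra].to_dict()
        if current is not None:
            merged.append(current)
    return pd.DataFrame(merged, columns=SEGMENT_COLUMNS + extra).reset_index(drop=True)


def call_loh(
    n_major: int, n_minor: int, sample_ploidy: float, min_retained: int = 1
) -> str:
    """Classify one segment as none / LOH / CN_neutral_LOH.

    LOH: one allele at zero copies with the other retained at
    >= ``min_retained``; copy-number-neutral LOH additionally requires the
    retained allele to equal the sample ploidy (rounded to the nearest
    integer).  ``min_retained=2`` recovers the stricter reading in which a
    hemizygous deletion does not count as LOH.
    """
    if n_major < 0 or n_minor < 0:
        raise ValueError("negative copy numbers")
    lo, hi = sorted((n_minor, n_major))  # canonical order, label-invariant
    if lo != 0 or hi < min_retained or hi == 0:
        return "none"
    if hi == int(round(sample_ploidy)):
        return "CN_neutral_LOH"
    return "LOH"


def call_loh_segments(segments: pd.DataFrame, min_retained: int = 1) -> pd.DataFrame:
    """Vectorised wrapper adding an ``loh`` column (needs ``ploidy``)."""
    out = segments.copy()
    out["loh"] = [
        call_loh(r.n_major, r.n_minor, r.ploidy, min_retained)
        for r in out.itertuples(index=False)
    ]
    return out


def fraction_genome_altered(segments: pd.DataFrame, sample_ploidy: float) -> float:
    """Percentage of covered base pairs with total copy number != ploidy.

    The denominator is the genome covered by the profile (sex chromosomes
    are expected to have been excluded upstream).  Empty profile -> NaN.
    """
    if segments.empty:
        return float("nan")
    lengths = (segments["end"] - segments["start"] + 1).to_numpy(dtype=float)
    total = (segments["n_major"] + segments["n_minor"]).to_numpy()
    altered = lengths[total != int(round(sample_ploidy))].sum()
    return 100.0 * altered / lengths.sum()


def loh_to_bed(segments: pd.DataFrame) -> pd.DataFrame:
    """LOH regions as BED (0-based half-open) with the LOH class as name."""
    loh = segments[segments["loh"] != "none"]
    return pd.DataFrame(
        {
            "chrom": loh["chrom"],
            "start": loh["start"] - 1,
            "end": loh["end"],
            "name": loh["loh"],
        }
    ).reset_index(drop=True)
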