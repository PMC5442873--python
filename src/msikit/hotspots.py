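"""Homopolymer hotspot screening and genotyping in coding sequences.

MMR-deficient tumors accumulate slippage indels in long single-nucleotide
runs; recurrent frameshifts in genes such as JAK1, CRTC1, BCL9 and PTCH1
sit in coding homopolymers of >= 6 bp.  This module scans a CDS for such
sites, genotypes them per sample from spanning-read support (a site needs
at least seven reads to be scorable), and summarises per-gene mutation
frequencies among scorable samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "HomopolymerSite",
    "HotspotGenotype",
    "scan_homopolymers",
    "genotype_hotspot",
    "cohort_frequency",
]


@dataclass(frozen=True)
class HomopolymerSite:
    """A maximal single-nucleotide run within a CDS.

    ``cds_start`` is the 1-based position of the first run base within the
    CDS; ``codon_start``/``codon_end`` give the 1-based amino-acid interval
    the run overlaps in the annotated reading frame.
    """

    gene: str
    transcript: str
    cds_start: int
    base: str
    run_length: int

    @property
    def codon_start(self) -> int:
        return (self.cds_start - 1) // 3 + 1

    @property
    def codon_end(self) -> int:
        return (self.cds_start + self.run_length - 2) // 3 + 1


@dataclass
class HotspotGenotype:
    site: HomopolymerSite
    sample: str
    n_reads: int
    n_indel_reads: int
    status: str  # mutated | wildtype | unscorable


def scan_homopolymers(
    cds: str, min_len: int = 6, gene: str = "", transcript: str = ""
) -> list[HomopolymerSite]:
    """All maximal single-nucleotide runs of length >= ``min_len`` in a CDS."""
    cds = cds.upper()
    if not cds:
        return []
    if len(cds) % 3:
        warnings.warn(
            f"CDS length {len(cds)} for {gene or transcript or 'sequence'} "
            "is not divisible by 3; codon mapping assumes frame starts at base 1",
            stacklevel=2,
        )
    sites: list[HomopolymerSite] = []
    i, n = 0, len(cds)
    while i < n:
        j = i
        while j < n and cds[j] == cds[i]:
            j += 1
        if j - i >= min_len:
            sites.append(HomopolymerSite(gene, transcript, i + 1, cds[i], j - i))
        i = j
    return sites


def genotype_hotspot(
    site: HomopolymerSite,
    sample: str,
    n_reads: int,
    n_indel_reads: int,
    min_reads: int = 7,
    min_indel_reads: int = 3,
    min_indel_frac: float = 0.10,
) -> HotspotGenotype:
    """Genotype one hotspot from reads spanning the full run.

    Unscorable below ``min_reads`` total reads (default seven); mutated
    when indel-supporting reads clear both noise knobs (>= 3 reads and
    >= 10% of spanning reads by default), otherwise wildtype.
    """
    if n_indel_reads > n_reads:
        raise ValueError("n_indel_reads cannot exceed n_reads")
    if n_reads < min_reads:
        status = "unscorable"
    elif n_indel_reads >= min_indel_reads and n_indel_reads >= min_indel_frac * n_reads:
        status = "mutated"
    else:
        status = "wildtype"
    return HotspotGenotype(site, sample, n_reads, n_indel_reads, status)


def cohort_frequency(genotypes: Iterable[HotspotGenotype] | pd.DataFrame) -> pd.DataFrame:
    """Per-gene mutation frequency among scorable samples.

    A sample is scorable for a gene if at least one of the gene's sites is
    scorable in it, and mutated if any site is mutated.  Returns a frame
    indexed by gene with columns ``n_mutated, n_scorable, frequency``
    (frequency NaN when no sample is scorable).
    """
    if isinstance(genotypes, pd.DataFrame):
        df = genotypes[["gene", "sample", "status"]].copy()
    else:
        df = pd.DataFrame(
            [(g.site.gene, g.sample, g.status) for g in genotypes],
            columns=["gene", "sample", "status"],
        )
    rows = []
    for gene, group in df.groupby("gene", sort=True):
        per_sample = group.groupby("sample")["status"].agg(
            scorable=lambda s: (s != "unscorable").any(),
            mutated=lambda s: (s == "mutated").any(),
        )
        n_scorable = int(per_sample["scorable"].sum())
        n_mutated = int((per_sample["scorable"] & per_sample["mutated"]).sum())
        freq = n_mutated / n_scorable if n_scorable else float("nan")
        rows.append((gene, n_mutated, n_scorable, freq))
    return pd.DataFrame(
        rows, columns=["gene", "n_mutated", "n_scorable", "frequency"]
    ).set_index("gene")
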