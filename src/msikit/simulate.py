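"""Synthetic paired tumor-normal cohorts with full ground truth.

The generator emulates the statistical structure an MMR-deficient (MSI+)
exome analysis assumes, on a scaled-down reference: a concatenated
exome-like genome of intron-less single-CDS genes, planted and naturally
occurring microsatellites, an MMR-deficiency mutation process (SNVs drawn
from a trinucleotide signature mixture plus length-dependent homopolymer
slippage indels), a linear-chain clonal architecture with nested cellular
prevalences, binomial read sampling at exome-like depths (273x tumor,
109x normal by default), diploid-dominant allele-specific copy-number
profiles with occasional LOH, log-normal per-gene expression, and six
class-I HLA alleles per patient.  Every stochastic choice is recorded as
ground truth so downstream stages are testable without external data.

No read-level simulation is performed (no FASTQ/BAM); sequencing error
and germline variation are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .msi import MicrosatelliteLocus, catalogue_microsatellites
from .neoantigen import HlaTyping
from .signatures import CONTEXTS_96, SignatureCatalogue, synthetic_catalogue
from .variants import variant_class

__all__ = [
    "CohortConfig",
    "Reference",
    "GroundTruth",
    "TumorSample",
    "Cohort",
    "build_reference",
    "simulate_tumor",
    "simulate_cohort",
    "simulate_vaf_clusters",
    "HLA_ALLELES",
]

#: twenty common four-digit class-I alleles patients are drawn from
HLA_ALLELES = (
    "HLA-A*01:01", "HLA-A*02:01", "HLA-A*03:01", "HLA-A*11:01", "HLA-A*24:02",
    "HLA-A*26:01", "HLA-A*68:01", "HLA-B*07:02", "HLA-B*08:01", "HLA-B*15:01",
    "HLA-B*18:01", "HLA-B*35:01", "HLA-B*40:01", "HLA-B*44:02", "HLA-B*51:01",
    "HLA-C*03:04", "HLA-C*04:01", "HLA-C*05:01", "HLA-C*07:01", "HLA-C*07:02",
)

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)


def _default_exposures() -> dict[str, float]:
    return {"mmr_like": 0.8, "flat": 0.2}


def _default_slippage() -> dict[int, float]:
    # per-locus slippage probability by run length (in units), at the
    # nominal MSI intensity of 0.2; lengths beyond the map use the last
    return {5: 0.08, 6: 0.15, 7: 0.25, 8: 0.35, 9: 0.45, 10: 0.55, 11: 0.60, 12: 0.65}


@dataclass
class CohortConfig:
    """Study conditions for a synthetic MSI+ cohort.

    Defaults mirror the structure of a deeply sequenced MSI+ CRC exome
    series: 33 tumors, 273x/109x tumor/normal depth, 2-5 clones per
    tumor, a signature mixture dominated by the MMR-deficiency-like
    entry, and per-tumor MSI intensities spanning mean scores near 20%.
    """

    n_tumors: int = 33
    genome_length: int = 200_000
    n_genes: int = 120
    microsatellite_density: float = 2.0  # planted homopolymers per kb
    signature_exposures: dict[str, float] = field(default_factory=_default_exposures)
    snv_rate: float = 2200.0  # expected SNVs per tumor before dispersion
    indel_rate_per_runlength: dict[int, float] = field(default_factory=_default_slippage)
    n_clones_range: tuple[int, int] = (2, 5)
    purity_range: tuple[float, float] = (0.5, 0.9)
    tumor_depth_mean: float = 273.0
    normal_depth_mean: float = 109.0
    msi_intensity_range: tuple[float, float] = (0.08, 0.35)
    uniform_instability_fraction: float | None = None  # overrides the slippage map
    truncal_instability_prob: float = 0.85
    deletion_insertion_odds: float = 3.0  # MSI deletions dominate
    stutter_rate: float = 0.015  # per-read polymerase stutter in histograms
    contamination_rate: float = 0.0005  # normal-tissue mutant-read rate
    load_dispersion: float = 0.35  # lognormal sigma on per-tumor SNV load
    loh_segments_range: tuple[int, int] = (0, 2)
    explicit_homopolymers: tuple[tuple[int, str, int], ...] = ()  # (pos, base, length)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.n_genes < 1:
            raise ValueError("genome_length and n_genes must be positive")
        if not (0 <= self.purity_range[0] <= self.purity_range[1] <= 1):
            raise ValueError("purity_range must be within [0, 1]")
        if self.n_clones_range[0] > self.n_clones_range[1] or self.n_clones_range[0] < 1:
            raise ValueError("empty clone range")
        total = sum(self.signature_exposures.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("signature_exposures must sum to 1")
        lengths = sorted(self.indel_rate_per_runlength)
        rates = [self.indel_rate_per_runlength[k] for k in lengths]
        if any(b < a for a, b in zip(rates, rates[1:])):
            raise ValueError("slippage probability must be non-decreasing in run length")


@dataclass
class Reference:
    """Reference sequences with annotation and microsatellite catalogue."""

    seqs: dict[str, str]
    annotation: pd.DataFrame  # gene transcript chrom cds_start cds_end strand
    microsatellites: list[MicrosatelliteLocus]
    planted: list[tuple[int, str, int]]
    proteome: dict[str, str]

    _context_pools: dict | None = field(default=None, repr=False)

    def context_pools(self) -> dict[str, np.ndarray]:
        """0-based center positions of every reference trinucleotide."""
        if self._context_pools is None:
            pools: dict[str, np.ndarray] = {}
            for chrom, seq in self.seqs.items():
                arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
                code = {ord(b): i for i, b in enumerate(_BASES)}
                lut = np.zeros(256, dtype=np.int64)
                for k, v in code.items():
                    lut[k] = v
                idx = lut[arr]
                tri = idx[:-2] * 16 + idx[1:-1] * 4 + idx[2:]
                order = np.argsort(tri, kind="stable")
                tri_sorted = tri[order]
                bounds = np.searchsorted(tri_sorted, np.arange(65))
                for t in range(64):
                    name = _BASES[t // 16] + _BASES[(t // 4) % 4] + _BASES[t % 4]
                    centers = order[bounds[t] : bounds[t + 1]] + 1
                    pools.setdefault(name, centers)  # single-chromosome references
            self._context_pools = pools
        return self._context_pools


@dataclass
class GroundTruth:
    """Everything the generator decided for one tumor."""

    clones: list[tuple[int, float]]  # (clone id, cellular prevalence)
    aberrant_cell_fraction: float
    msi_intensity: float
    variant_truth: pd.DataFrame  # clone, prevalence, zygosity, true_vaf
    unstable_loci: set[str]
    expression: pd.Series


@dataclass
class TumorSample:
    sample_id: str
    variants: pd.DataFrame
    histograms: pd.DataFrame
    segments: pd.DataFrame
    hla: HlaTyping
    truth: GroundTruth


@dataclass
class Cohort:
    config: CohortConfig
    reference: Reference
    samples: list[TumorSample]
    expression: pd.DataFrame  # genes x samples


def _write_gene(genome: np.ndarray, start0: int, sense: str, strand: str) -> None:
    seq = sense if strand == "+" else str(Seq(sense).reverse_complement())
    genome[start0 : start0 + len(seq)] = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _plant_run(
    genome: np.ndarray, start0: int, base: str, length: int
) -> None:
    b = ord(base)
    genome[start0 : start0 + length] = b
    # fix flanks so the planted run is maximal
    for flank in (start0 - 1, start0 + length):
        if 0 <= flank < len(genome) and genome[flank] == b:
            genome[flank] = ord("C" if base != "C" else "T")


def _remove_internal_stops(genome: np.ndarray, annotation: pd.DataFrame) -> None:
    """Rewrite internal stop codons (middle base -> C keeps runs intact)."""
    for row in annotation.itertuples(index=False):
        s, e = row.cds_start - 1, row.cds_end
        raw = genome[s:e].tobytes().decode("ascii")
        sense = raw if row.strand == "+" else str(Seq(raw).reverse_complement())
        n_codons = len(sense) // 3
        for ci in range(n_codons - 1):  # final stop codon is legitimate
            codon = sense[ci * 3 : ci * 3 + 3]
            if codon in _STOPS:
                mid = ci * 3 + 1  # sense index of the middle base
                if row.strand == "+":
                    genome[s + mid] = ord("C")
                else:
                    genome[e - 1 - mid] = ord("G")  # complement of C


def build_reference(config: CohortConfig, rng: np.random.Generator | None = None) -> Reference:
    """Build the reference: sequence, transcripts, planted microsatellites.

    Deterministic for a fixed config seed.  Genes are intron-less
    single-CDS transcripts built from sense codons (no internal stops) so
    that every wild-type protein is well defined; homopolymers are
    planted at the configured density ('C' runs inside CDS so no stop
    codon can arise, 'A' runs intergenically) and recorded with exact
    coordinates.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.genome_length
    if L < 10_000:
        raise ValueError("genome_length must be at least 10 kb")
    base_codes = np.frombuffer(_BASES.encode("ascii"), dtype=np.uint8)
    genome = base_codes[rng.integers(0, 4, size=L)].copy()

    # lay out genes
    records = []
    cursor = int(rng.integers(100, 300))
    for g in range(config.n_genes):
        n_codons = int(rng.integers(240, 520))
        cds_len = 3 * (n_codons + 1)  # body + stop codon
        if cursor + cds_len + 100 > L:
            break
        codons = rng.choice(len(_SENSE_CODONS), size=n_codons)
        sense = "".join(_SENSE_CODONS[c] for c in codons) + _STOPS[int(rng.integers(3))]
        strand = "+" if rng.random() < 0.7 else "-"
        _write_gene(genome, cursor, sense, strand)
        records.append(
            {
                "gene": f"GENE{g + 1:04d}",
                "transcript": f"T{g + 1:04d}",
                "chrom": "chr1",
                "cds_start": cursor + 1,
                "cds_end": cursor + cds_len,
                "strand": strand,
            }
        )
        cursor += cds_len + int(rng.integers(150, 450))
    annotation = pd.DataFrame(records)
    if annotation.empty:
        raise ValueError("genome too short to place any gene")

    # plant homopolymers
    gene_iv = annotation[["cds_start", "cds_end"]].to_numpy()
    planted: list[tuple[int, str, int]] = []
    n_plant = int(round(config.microsatellite_density * L / 1000.0))
    run_lengths = np.arange(5, 13)
    run_weights = np.array([0.30, 0.20, 0.15, 0.12, 0.09, 0.06, 0.05, 0.03])
    attempts = 0
    while len(planted) < n_plant and attempts < 20 * max(n_plant, 1):
        attempts += 1
        length = int(rng.choice(run_lengths, p=run_weights))
        pos0 = int(rng.integers(50, L - 50 - length))
        inside = (gene_iv[:, 0] <= pos0 + 1) & (gene_iv[:, 1] >= pos0 + length)
        partial = ((gene_iv[:, 0] <= pos0 + length) & (gene_iv[:, 1] >= pos0 + 1)).any()
        genic = bool(inside.any())
        if partial and not genic:
            continue  # straddles a CDS boundary
        if any(abs(p - (pos0 + 1)) < 30 for p, _, _ in planted):
            continue
        base = "C" if genic else "A"
        _plant_run(genome, pos0, base, length)
        planted.append((pos0 + 1, base, length))
    for pos, base, length in config.explicit_homopolymers:
        _plant_run(genome, pos - 1, base, length)
        planted.append((pos, base, length))

    _remove_internal_stops(genome, annotation)
    seq = genome.tobytes().decode("ascii")
    seqs = {"chr1": seq}
    catalogue = catalogue_microsatellites(seqs)
    proteome = {}
    for row in annotation.itertuples(index=False):
        raw = seq[row.cds_start - 1 : row.cds_end]
        sense = raw if row.strand == "+" else str(Seq(raw).reverse_complement())
        proteome[row.gene] = str(Seq(sense).translate()).rstrip("*")
    return Reference(seqs, annotation, catalogue, planted, proteome)


def _draw_prevalences(n_clones: int, rng: np.random.Generator) -> list[float]:
    """Linear-chain clone prevalences: truncal 1.0, nested subclones."""
    prevs = [1.0]
    for _ in range(n_clones - 1):
        for _ in range(50):
            cand = float(rng.uniform(0.10, 0.85))
            if all(abs(cand - p) >= 0.12 for p in prevs):
                prevs.append(cand)
                break
        else:  # no well-separated value found; stop adding clones
            break
    return sorted(prevs, reverse=True)


def _build_segments(
    L: int, purity: float, rng: np.random.Generator, loh_range: tuple[int, int]
) -> pd.DataFrame:
    events = []
    n_events = int(rng.integers(loh_range[0], loh_range[1] + 1))
    for _ in range(n_events):
        length = int(rng.uniform(0.02, 0.06) * L)
        start = int(rng.integers(1, L - length))
        if any(not (start + length < s or start > s + le) for s, le, _ in events):
            continue
        r = rng.random()
        cn = (2, 0) if r < 0.5 else (1, 0) if r < 0.8 else (2, 1)
        events.append((start, length, cn))
    events.sort()
    rows = []
    cursor = 1
    for start, length, (maj, mino) in events:
        if start > cursor:
            rows.append((cursor, start - 1, 1, 1))
        rows.append((start, start + length - 1, maj, mino))
        cursor = start + length
    if cursor <= L:
        rows.append((cursor, L, 1, 1))
    df = pd.DataFrame(rows, columns=["start", "end", "n_major", "n_minor"])
    df.insert(0, "chrom", "chr1")
    lengths = df["end"] - df["start"] + 1
    ploidy = float(((df["n_major"] + df["n_minor"]) * lengths).sum() / lengths.sum())
    df["ploidy"] = ploidy
    df["purity"] = purity
    return df


def _segment_of(segments: pd.DataFrame, pos: int) -> pd.Series:
    idx = segments["start"].searchsorted(pos, side="right") - 1
    return segments.iloc[int(idx)]


def _class_pools(reference: Reference) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-96-class candidate positions (1-based) and alt bases."""
    comp = str.maketrans("ACGT", "TGCA")
    pools = reference.context_pools()
    out = []
    for label in CONTEXTS_96:
        five, ref, alt, three = label[0], label[2], label[4], label[6]
        tri = five + ref + three
        tri_rc = tri.translate(comp)[::-1]
        pos_pyr = pools.get(tri, np.empty(0, dtype=np.int64))
        pos_pur = pools.get(tri_rc, np.empty(0, dtype=np.int64))
        positions = np.concatenate([pos_pyr + 1, pos_pur + 1])
        alts = np.array([alt] * len(pos_pyr) + [alt.translate(comp)] * len(pos_pur))
        out.append((positions, alts))
    return out


def _true_vaf(
    segment: pd.Series, purity: float, prevalence: float, rng: np.random.Generator
) -> tuple[float, str]:
    """Expected VAF and zygosity of a mutation on one parental allele."""
    maj, mino = int(segment["n_major"]), int(segment["n_minor"])
    copies = maj if rng.random() < 0.5 else mino
    total_avg = 2.0 * (1.0 - purity) + (maj + mino) * purity
    if copies == 0 or total_avg == 0:
        return 0.0, "lost"
    vaf = copies * purity * prevalence / total_avg
    zygosity = "hom" if copies == maj + mino else "het"
    return float(vaf), zygosity


def _stutter_probs(
    ref_len: int, mutant_len: int | None, mutant_frac: float, stutter: float
) -> tuple[list[int], list[float]]:
    base = {ref_len: 1.0 - mutant_frac}
    if mutant_len is not None and mutant_frac > 0:
        base[mutant_len] = mutant_frac
    probs: dict[int, float] = {}
    for length, p in base.items():
        probs[length] = probs.get(length, 0.0) + p * (1.0 - stutter)
        probs[length - 1] = probs.get(length - 1, 0.0) + p * stutter * (2.0 / 3.0)
        probs[length + 1] = probs.get(length + 1, 0.0) + p * stutter / 3.0
    lengths = sorted(probs)
    return lengths, [probs[k] for k in lengths]


def simulate_tumor(
    config: CohortConfig,
    reference: Reference,
    sample_id: str,
    rng: np.random.Generator,
    class_pools: list[tuple[np.ndarray, np.ndarray]] | None = None,
    mixture96: np.ndarray | None = None,
    catalogue: SignatureCatalogue | None = None,
) -> TumorSample:
    """Simulate one paired tumor-normal sample against a built reference."""
    if catalogue is None:
        catalogue = synthetic_catalogue()
    if mixture96 is None:
        mixture96 = np.zeros(96)
        for name, w in config.signature_exposures.items():
            mixture96 += w * catalogue[name].to_numpy()
        mixture96 /= mixture96.sum()
    if class_pools is None:
        class_pools = _class_pools(reference)
    seq = reference.seqs["chr1"]
    L = len(seq)

    purity = float(rng.uniform(*config.purity_range))
    n_clones = int(rng.integers(config.n_clones_range[0], config.n_clones_range[1] + 1))
    prevalences = _draw_prevalences(n_clones, rng)
    msi_intensity = float(rng.uniform(*config.msi_intensity_range))
    clone_weights = np.array(
        [0.7] + [0.3 / (len(prevalences) - 1)] * (len(prevalences) - 1)
        if len(prevalences) > 1
        else [1.0]
    )
    segments = _build_segments(L, purity, rng, config.loh_segments_range)

    # --- SNVs from the signature mixture ------------------------------
    n_snv = int(rng.poisson(config.snv_rate * np.exp(rng.normal(0.0, config.load_dispersion))))
    classes = rng.choice(96, size=n_snv, p=mixture96)
    taken: set[int] = set()
    records = []
    for cls in classes:
        positions, alts = class_pools[cls]
        if len(positions) == 0:
            continue
        j = int(rng.integers(len(positions)))
        pos = int(positions[j])
        if pos in taken:
            continue
        taken.add(pos)
        records.append((pos, seq[pos - 1], str(alts[j])))

    # --- slippage indels at microsatellite loci -----------------------
    slip = config.indel_rate_per_runlength
    slip_keys = sorted(slip)
    scale = msi_intensity / 0.2
    unstable: list[tuple[MicrosatelliteLocus, int]] = []  # (locus, delta units)
    histogram_loci = [m for m in reference.microsatellites if m.n_units >= min(slip_keys)]
    p_del = config.deletion_insertion_odds / (config.deletion_insertion_odds + 1.0)
    for locus in histogram_loci:
        if config.uniform_instability_fraction is not None:
            p = config.uniform_instability_fraction
        else:
            key = min(max(locus.n_units, slip_keys[0]), slip_keys[-1])
            p = min(slip[key] * scale, 0.95)
        if rng.random() < p:
            delta = -1 if rng.random() < p_del else 1
            unstable.append((locus, delta))

    # --- assemble the variant table with truth ------------------------
    rows, truth_rows = [], []
    for pos, ref_base, alt_base in records:
        clone = int(rng.choice(len(prevalences), p=clone_weights))
        segment = _segment_of(segments, pos)
        vaf, zyg = _true_vaf(segment, purity, prevalences[clone], rng)
        if vaf <= 0:
            continue
        rows.append(("chr1", pos, ref_base, alt_base))
        truth_rows.append((clone, prevalences[clone], zyg, vaf, ""))
    for locus, delta in unstable:
        anchor = locus.start - 1
        if anchor < 1:
            continue
        unit = locus.repeat_unit
        anchor_base = seq[anchor - 1]
        if delta < 0:
            ref_a = anchor_base + seq[anchor : anchor + len(unit)]
            alt_a = anchor_base
        else:
            ref_a = anchor_base
            alt_a = anchor_base + unit
        if rng.random() < config.truncal_instability_prob or len(prevalences) == 1:
            clone = 0
        else:
            clone = 1
        segment = _segment_of(segments, locus.start)
        vaf, zyg = _true_vaf(segment, purity, prevalences[clone], rng)
        if vaf <= 0:
            continue
        rows.append(("chr1", anchor, ref_a, alt_a))
        truth_rows.append((clone, prevalences[clone], zyg, vaf, locus.locus_id))

    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    truth = pd.DataFrame(
        truth_rows, columns=["clone", "prevalence", "zygosity", "true_vaf", "locus_id"]
    )
    variants["variant_class"] = [variant_class(r, a) for r, a in zip(variants["ref"], variants["alt"])]
    variants["gene"] = ""

    # --- binomial read sampling ---------------------------------------
    n = len(variants)
    t_depth = rng.poisson(config.tumor_depth_mean, size=n)
    t_alt = rng.binomial(t_depth, np.clip(truth["true_vaf"].to_numpy(), 0, 1))
    n_depth = rng.poisson(config.normal_depth_mean, size=n)
    n_alt = rng.binomial(n_depth, config.contamination_rate)
    variants["tumor_ref_reads"] = t_depth - t_alt
    variants["tumor_alt_reads"] = t_alt
    variants["normal_ref_reads"] = n_depth - n_alt
    variants["normal_alt_reads"] = n_alt
    observed = t_alt > 0
    variants = variants[observed].reset_index(drop=True)
    truth = truth[observed].reset_index(drop=True)

    # --- paired repeat-length histograms ------------------------------
    unstable_map = {loc.locus_id: delta for loc, delta in unstable}
    vaf_map = dict(zip(truth["locus_id"], truth["true_vaf"]))
    hist_rows = []
    for locus in histogram_loci:
        lid = locus.locus_id
        ref_len = locus.n_units
        for tissue, depth_mean in (("tumor", config.tumor_depth_mean), ("normal", config.normal_depth_mean)):
            depth = int(rng.poisson(depth_mean))
            if tissue == "tumor" and lid in unstable_map:
                mutant_len = ref_len + unstable_map[lid]
                frac = float(vaf_map.get(lid, 0.0))
            else:
                mutant_len, frac = None, 0.0
            lengths, probs = _stutter_probs(ref_len, mutant_len, frac, config.stutter_rate)
            counts = rng.multinomial(depth, probs)
            for length, c in zip(lengths, counts):
                if c > 0:
                    hist_rows.append((lid, locus.start, locus.repeat_unit, locus.n_units, tissue, length, int(c)))
    histograms = pd.DataFrame(
        hist_rows,
        columns=["locus_id", "start", "unit", "n_units", "tissue", "length", "reads"],
    )
    histograms.insert(1, "chrom", "chr1")
    histograms.insert(0, "sample", sample_id)

    # --- HLA typing ---------------------------------------------------
    by_locus = {
        "A": [a for a in HLA_ALLELES if a.startswith("HLA-A")],
        "B": [a for a in HLA_ALLELES if a.startswith("HLA-B")],
        "C": [a for a in HLA_ALLELES if a.startswith("HLA-C")],
    }
    alleles = []
    for locus_name in "ABC":
        alleles.extend(rng.choice(by_locus[locus_name], size=2, replace=True))
    hla = HlaTyping(sample_id, tuple(str(a) for a in alleles))

    segments = segments.copy()
    segments.insert(0, "sample", sample_id)
    ground_truth = GroundTruth(
        clones=[(i, p) for i, p in enumerate(prevalences)],
        aberrant_cell_fraction=purity,
        msi_intensity=msi_intensity,
        variant_truth=truth,
        unstable_loci={loc.locus_id for loc, _ in unstable if loc.locus_id in set(vaf_map) and vaf_map[loc.locus_id] > 0},
        expression=pd.Series(dtype=float),
    )
    return TumorSample(sample_id, variants, histograms, segments, hla, ground_truth)


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Simulate the full cohort: reference plus paired samples.

    Bit-identical for a fixed config seed (independent child seeds per
    tumor, so per-sample streams do not interfere).
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_tumors + 2)
    reference = build_reference(config, np.random.default_rng(children[0]))
    catalogue = synthetic_catalogue()
    mixture96 = np.zeros(96)
    for name, w in config.signature_exposures.items():
        mixture96 += w * catalogue[name].to_numpy()
    mixture96 /= mixture96.sum()
    class_pools = _class_pools(reference)

    expr_rng = np.random.default_rng(children[1])
    genes = reference.annotation["gene"].tolist()
    base_level = expr_rng.normal(6.0, 1.0, size=len(genes))
    sample_ids = [f"T{i + 1:03d}" for i in range(config.n_tumors)]
    expression = pd.DataFrame(
        {
            sid: 2.0 ** (base_level + expr_rng.normal(0.0, 0.5, size=len(genes)))
            for sid in sample_ids
        },
        index=genes,
    )

    samples = []
    for i, sid in enumerate(sample_ids):
        rng = np.random.default_rng(children[i + 2])
        sample = simulate_tumor(
            config, reference, sid, rng, class_pools=class_pools,
            mixture96=mixture96, catalogue=catalogue,
        )
        sample.truth.expression = expression[sid]
        samples.append(sample)
    return Cohort(config, reference, samples, expression)


def simulate_vaf_clusters(
    prevalences: Sequence[float],
    aberrant_cell_fraction: float,
    depth_mean: float,
    n_per_clone: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Read counts for planted diploid heterozygous VAF clusters.

    Each clone contributes ``n_per_clone`` variants at expected VAF
    0.5 x ACF x prevalence with Poisson depths and binomial alt counts;
    used for clonality parameter-recovery experiments.
    """
    rows = []
    for clone, prev in enumerate(prevalences):
        vaf = 0.5 * aberrant_cell_fraction * prev
        depth = rng.poisson(depth_mean, size=n_per_clone)
        alt = rng.binomial(depth, vaf)
        for d, a in zip(depth, alt):
            rows.append((clone, prev, vaf, int(d), int(a)))
    return pd.DataFrame(rows, columns=["clone", "prevalence", "true_vaf", "depth", "alt"])
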