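"""File formats: FASTA, VCF v4.2 with AD fields, and the TSV exchange tables.

The pipeline's on-disk formats are deliberately plain: FASTA for
reference and proteome, VCF v4.2 with per-sample allelic depths (AD) for
somatic calls, tab-delimited tables for annotation, histograms, segments
and expression, a text HLA file, and a JSON ground-truth sidecar for
synthetic cohorts.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .neoantigen import HlaTyping
from .variants import VARIANT_COLUMNS, left_align_indel, variant_class

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_vcf",
    "read_vcf",
    "read_annotation",
    "write_annotation",
    "read_hla",
    "write_hla",
    "catalogue_to_bed",
    "write_cohort",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_vcf(variants: pd.DataFrame, path, contigs: Mapping[str, int] | None = None) -> None:
    """Write the variant table as a paired-sample VCF (TUMOR, NORMAL)."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL\n")
        ordered = variants.sort_values(["chrom", "pos"], kind="stable")
        for row in ordered.itertuples(index=False):
            t = f"{row.tumor_ref_reads},{row.tumor_alt_reads}:{row.tumor_ref_reads + row.tumor_alt_reads}"
            n = f"{row.normal_ref_reads},{row.normal_alt_reads}:{row.normal_ref_reads + row.normal_alt_reads}"
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tAD:DP\t{t}\t{n}\n"
            )


def read_vcf(
    path,
    tumor: str = "TUMOR",
    normal: str = "NORMAL",
    refseqs: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a paired-sample VCF into the canonical variant table.

    Multi-allelic records are decomposed into bi-allelic variants (each
    keeps its own AD and the shared reference depth) and indels are
    left-aligned when reference sequences are supplied.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    try:
        it, in_ = samples.index(tumor), samples.index(normal)
    except ValueError:  # fall back to positional tumor-first convention
        it, in_ = 0, 1
    rows = []
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            continue
        ad = np.maximum(ad, 0)
        for k, alt in enumerate(rec.ALT):
            pos, ref_a, alt_a = rec.POS, rec.REF, alt
            if refseqs is not None and len(ref_a) != len(alt_a):
                pos, ref_a, alt_a = left_align_indel(pos, ref_a, alt_a, refseqs[rec.CHROM])
            rows.append(
                (
                    rec.CHROM,
                    pos,
                    ref_a,
                    alt_a,
                    variant_class(ref_a, alt_a),
                    "",
                    int(ad[it][0]),
                    int(ad[it][k + 1]),
                    int(ad[in_][0]),
                    int(ad[in_][k + 1]),
                )
            )
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_hla(path) -> dict[str, HlaTyping]:
    typings = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) == 7:
                typings[parts[0]] = HlaTyping(parts[0], tuple(parts[1:]))
    return typings


def write_hla(typings: Mapping[str, HlaTyping], path) -> None:
    with open(path, "w") as fh:
        for patient, typing in typings.items():
            fh.write(patient + "\t" + "\t".join(typing.alleles) + "\n")


def catalogue_to_bed(loci, path=None) -> pd.DataFrame:
    """Microsatellite catalogue as BED (0-based half-open)."""
    df = pd.DataFrame(
        [(l.chrom, l.start - 1, l.end, l.repeat_unit, l.n_units) for l in loci],
        columns=["chrom", "start", "end", "unit", "n_units"],
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False, header=False)
    return df


def write_cohort(cohort, outdir) -> Path:
    """Persist a synthetic cohort: FASTA, VCFs, TSV tables, ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = cohort.reference
    write_fasta(ref.seqs, outdir / "reference.fa")
    write_fasta(ref.proteome, outdir / "proteome.fa")
    write_annotation(ref.annotation, outdir / "annotation.tsv")
    catalogue_to_bed(ref.microsatellites, outdir / "microsatellites.bed")

    contigs = {name: len(seq) for name, seq in ref.seqs.items()}
    segment_frames, histogram_frames = [], []
    typings = {}
    truth: dict[str, dict] = {}
    for sample in cohort.samples:
        write_vcf(sample.variants, outdir / f"{sample.sample_id}.vcf", contigs)
        segment_frames.append(sample.segments)
        histogram_frames.append(sample.histograms)
        typings[sample.sample_id] = sample.hla
        truth[sample.sample_id] = {
            "clones": [[int(c), float(p)] for c, p in sample.truth.clones],
            "aberrant_cell_fraction": sample.truth.aberrant_cell_fraction,
            "msi_intensity": sample.truth.msi_intensity,
            "unstable_loci": sorted(sample.truth.unstable_loci),
            "variant_truth": sample.truth.variant_truth.to_dict(orient="list"),
        }
    pd.concat(segment_frames).to_csv(outdir / "segments.tsv", sep="\t", index=False)
    pd.concat(histogram_frames).to_csv(outdir / "histograms.tsv", sep="\t", index=False)
    cohort.expression.rename_axis("gene").to_csv(outdir / "expression.tsv", sep="\t")
    write_hla(typings, outdir / "hla.txt")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return outdir
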