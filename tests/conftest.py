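import numpy as np
import pandas as pd
import pytest

from msikit.simulate import CohortConfig, simulate_cohort

# --- tiny hand-built reference for effect/peptide tests -----------------

PAD1 = "TTGACCAGTC"  # 10 bp, run-free
# gene A, '+' strand: M A G C K F P D R L E H *
CDS_A = "ATG" "GCT" "GGA" "TGC" "AAA" "TTT" "CCA" "GAT" "CGA" "CTG" "GAA" "CAT" "TAA"
PAD2 = "GTTACGCTAC"
# gene B, '-' strand: M P E H L *
CDS_B_SENSE = "ATG" "CCT" "GAA" "CAT" "CTG" "TGA"
_COMP = str.maketrans("ACGT", "TGCA")
CDS_B_GENOMIC = CDS_B_SENSE.translate(_COMP)[::-1]
PAD3 = "ACGTGATCCA"

GENOME = PAD1 + CDS_A + PAD2 + CDS_B_GENOMIC + PAD3
A_START = len(PAD1) + 1
A_END = A_START + len(CDS_A) - 1
B_START = A_END + len(PAD2) + 1
B_END = B_START + len(CDS_B_GENOMIC) - 1


@pytest.fixture(scope="session")
def tiny_reference():
    refseqs = {"chr1": GENOME}
    annotation = pd.DataFrame(
        [
            {"gene": "GENEA", "transcript": "TA", "chrom": "chr1",
             "cds_start": A_START, "cds_end": A_END, "strand": "+"},
            {"gene": "GENEB", "transcript": "TB", "chrom": "chr1",
             "cds_start": B_START, "cds_end": B_END, "strand": "-"},
        ]
    )
    return refseqs, annotation


def make_variant(
    chrom="chr1", pos=100, ref="A", alt="T",
    tumor_ref=60, tumor_alt=40, normal_ref=50, normal_alt=0, gene="",
):
    from msikit.variants import variant_class

    return {
        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
        "variant_class": variant_class(ref, alt), "gene": gene,
        "tumor_ref_reads": tumor_ref, "tumor_alt_reads": tumor_alt,
        "normal_ref_reads": normal_ref, "normal_alt_reads": normal_alt,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20170524)


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-tumor cohort on a 60 kb exome, shared across unit tests."""
    config = CohortConfig(n_tumors=4, genome_length=60_000, n_genes=35, seed=11)
    return simulate_cohort(config)
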