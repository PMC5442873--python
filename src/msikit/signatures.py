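"""Trinucleotide mutation-context spectra and signature exposure fitting.

SNVs are tabulated into the standard 96 classes: six pyrimidine-frame
substitution types (C>A, C>G, C>T, T>A, T>C, T>G) by the immediately
flanking 5' and 3' nucleotides; purine-reference substitutions are
reverse-complemented into the pyrimidine frame.  Per-sample exposures to
a supplied signature catalogue are obtained by non-negative least squares
on the normalised spectrum, with nearest-signature cosine assignment as a
secondary mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "SUBSTITUTIONS",
    "CONTEXTS_96",
    "SignatureCatalogue",
    "ExposureFit",
    "tabulate_contexts",
    "fit_exposures",
    "synthetic_catalogue",
]

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: canonical row order: substitution class, then 5' flank, then 3' flank
CONTEXTS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)
_CONTEXT_INDEX = {label: i for i, label in enumerate(CONTEXTS_96)}


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def context_label(trinuc: str, alt: str) -> str | None:
    """96-class label for a ref trinucleotide and alt base, or None.

    Purine-reference changes are folded into the pyrimidine frame, so
    G>A with flanks T_C is recorded as G[C>T]A.
    """
    trinuc, alt = trinuc.upper(), alt.upper()
    if len(trinuc) != 3 or any(b not in _BASES for b in trinuc) or alt not in _BASES:
        return None
    ref = trinuc[1]
    if ref in "GA":
        trinuc, ref, alt = _revcomp(trinuc), _COMPLEMENT_MAP[ref], _COMPLEMENT_MAP[alt]
    if alt == ref:
        return None
    return f"{trinuc[0]}[{ref}>{alt}]{trinuc[2]}"


_COMPLEMENT_MAP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def tabulate_contexts(
    snvs: pd.DataFrame, refseqs: Mapping[str, str], sample: str = ""
) -> pd.Series:
    """Count SNVs into the 96 trinucleotide classes.

    ``snvs`` needs columns ``chrom, pos, ref, alt`` (1-based positions,
    single-base alleles).  SNVs at a sequence boundary, lacking a flank,
    are excluded with a warning; otherwise the vector sum equals the
    number of input SNVs.
    """
    counts = np.zeros(96, dtype=int)
    n_boundary = 0
    for row in snvs.itertuples(index=False):
        if len(row.ref) != 1 or len(row.alt) != 1:
            raise ValueError("tabulate_contexts accepts single-base SNVs only")
        seq = refseqs[row.chrom]
        if row.pos < 2 or row.pos > len(seq) - 1:
            n_boundary += 1
            continue
        trinuc = seq[row.pos - 2 : row.pos + 1]
        label = context_label(trinuc, row.alt)
        if label is None:  # ambiguous base in the reference context
            n_boundary += 1
            continue
        counts[_CONTEXT_INDEX[label]] += 1
    if n_boundary:
        warnings.warn(
            f"excluded {n_boundary} SNV(s) without a full flanking context",
            stacklevel=2,
        )
    return pd.Series(counts, index=list(CONTEXTS_96), name=sample or "spectrum")


class SignatureCatalogue:
    """Named mutation signatures, each a probability vector over 96 classes."""

    def __init__(self, profiles: pd.DataFrame):
        profiles = profiles.reindex(list(CONTEXTS_96))
        if profiles.isna().any().any():
            raise ValueError("catalogue must cover all 96 contexts")
        sums = profiles.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each signature must sum to 1 within 1e-6")
        self.profiles = profiles.astype(float)

    @property
    def names(self) -> list[str]:
        return list(self.profiles.columns)

    def __getitem__(self, name: str) -> pd.Series:
        return self.profiles[name]

    @classmethod
    def from_tsv(cls, path) -> "SignatureCatalogue":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.profiles.to_csv(path, sep="\t")


@dataclass
class ExposureFit:
    sample: str
    exposures: pd.Series  # non-negative fractions per signature
    cosine: float  # reconstruction cosine similarity
    dominant_signature: str


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    return float(a @ b / (na * nb))


def fit_exposures(
    spectrum: pd.Series,
    catalogue: SignatureCatalogue,
    method: str = "nnls",
    sample: str | None = None,
) -> ExposureFit | None:
    """Fit non-negative signature exposures to a 96-context spectrum.

    The spectrum is normalised to fractions and regressed onto the
    catalogue (``nnls``), or assigned wholly to the nearest signature by
    cosine similarity (``cosine``).  Exposures are renormalised to sum
    to 1.  Returns None (with a warning) for an all-zero spectrum.
    """
    y = spectrum.reindex(list(CONTEXTS_96)).to_numpy(dtype=float)
    total = y.sum()
    if total == 0:
        warnings.warn("zero-count spectrum; no exposure fit", stacklevel=2)
        return None
    y = y / total
    A = catalogue.profiles.to_numpy()
    if method == "nnls":
        w, _ = nnls(A, y)
    elif method == "cosine":
        sims = [_cosine(A[:, j], y) for j in range(A.shape[1])]
        w = np.zeros(A.shape[1])
        w[int(np.argmax(sims))] = 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    recon = A @ w
    if w.sum() > 0:
        w = w / w.sum()
    exposures = pd.Series(w, index=catalogue.names)
    dominant = str(exposures.idxmax())
    return ExposureFit(sample or str(spectrum.name), exposures, _cosine(recon, y), dominant)


def synthetic_catalogue() -> SignatureCatalogue:
    """A small deterministic catalogue for simulation and testing.

    Entries are synthetic stand-ins, not COSMIC profiles: ``mmr_like``
    mimics the shape of the MMR-deficiency signature (C>T dominated, 5'-G
    enriched), ``clock_like`` concentrates C>T at NpCpG, ``flat`` is
    uniform, and ``transversion`` is C>A-rich.
    """
    idx = list(CONTEXTS_96)

    def build(weight_fn) -> np.ndarray:
        w = np.array([weight_fn(lbl) for lbl in idx], dtype=float)
        return w / w.sum()

    def parse(lbl):
        five, sub, three = lbl[0], lbl[2:5], lbl[6]
        return five, sub, three

    def mmr_like(lbl):
        five, sub, three = parse(lbl)
        if sub == "C>T":
            return 12.0 * (3.0 if five == "G" else 1.0)
        if sub in ("C>A", "T>C"):
            return 1.0
        return 0.4

    def clock_like(lbl):
        five, sub, three = parse(lbl)
        if sub == "C>T":
            return 10.0 * (4.0 if three == "G" else 0.5)
        return 0.5

    def flat(lbl):
        return 1.0

    def transversion(lbl):
        _, sub, _ = parse(lbl)
        return 8.0 if sub == "C>A" else 0.6

    profiles = pd.DataFrame(
        {
            "mmr_like": build(mmr_like),
            "clock_like": build(clock_like),
            "flat": build(flat),
            "transversion": build(transversion),
        },
        index=idx,
    )
    return SignatureCatalogue(profiles)
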