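"""Patient-specific neoantigen enumeration and the filter cascade.

Mutant peptides of length 8-11 are enumerated from expressed somatic
mutations (single novel residue for nonsynonymous SNVs; the novel stretch
to the first stop codon for frameshift indels), scored against the
patient's six class-I HLA alleles by a pluggable binding predictor, and
passed through the study cascade: IC50 < 500 nM and a percentile rank
< 2 of predicted IC50s pooled over all peptide x allele interactions per
tumor, exclusion of peptides occurring verbatim in the self proteome,
and a predicted C-terminal proteasomal cleavage site.  Peptides binding
several alleles are counted once.

The bundled predictors are deterministic position-weight surrogates so
that the cascade is fully testable offline; they are not biological
models, and adapters for external predictors can implement the same
two-method contract (``ic50(peptide, allele)`` / ``predict(batch)``).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "AMINO_ACIDS",
    "HlaTyping",
    "MutantProteinContext",
    "SurrogateBindingPredictor",
    "SurrogateCleavagePredictor",
    "build_protein_contexts",
    "enumerate_mutant_peptides",
    "expression_filter",
    "binding_filter",
    "self_proteome_filter",
    "cleavage_filter",
    "count_neoantigens",
    "run_cascade",
    "CascadeResult",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
PEPTIDE_LENGTHS = (8, 9, 10, 11)


@dataclass(frozen=True)
class HlaTyping:
    """Six class-I alleles (HLA-A/B/C, two each) at four-digit resolution."""

    patient: str
    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) != 6:
            raise ValueError("a class-I typing has exactly six alleles")

    @property
    def unique_alleles(self) -> tuple[str, ...]:
        """Distinct alleles (homozygous loci contribute one entry)."""
        return tuple(dict.fromkeys(self.alleles))


@dataclass
class MutantProteinContext:
    """The mutant-protein neighbourhood of one mutation.

    ``stretch`` is the mutant amino-acid string containing every residue
    that differs from wild type, padded with up to ``flank`` wild-type
    residues on each side (clipped at the protein termini and, for
    frameshifts, at the new stop codon).  ``novel_start``/``novel_end``
    delimit the novel residues within the stretch (half-open).
    """

    mutation_id: str
    gene: str
    is_frameshift: bool
    stretch: str
    novel_start: int
    novel_end: int
    protein_offset: int  # 0-based residue index of stretch[0] in the protein
    terminated_by_stop: bool = False


def _apply_indel_to_cds(
    cds: str, strand: str, cds_start: int, cds_end: int, pos: int, ref: str, alt: str
) -> str:
    """Apply a VCF-style anchored indel to the sense CDS sequence."""
    if len(ref) > len(alt):  # deletion of ref[1:] after the anchor
        d = len(ref) - len(alt)
        if strand == "+":
            i = pos - cds_start  # anchor index in sense coordinates
            return cds[: i + 1] + cds[i + 1 + d :]
        # '-' strand: genomic bases pos+1 .. pos+d map to sense indices
        # cds_end - (pos+d) .. cds_end - (pos+1)
        lo = max(cds_end - (pos + d), 0)
        hi = cds_end - pos  # exclusive
        return cds[:lo] + cds[hi:]
    if len(alt) > len(ref):  # insertion after the anchor
        ins = alt[len(ref) :]
        if strand == "+":
            i = pos - cds_start
            return cds[: i + 1] + ins + cds[i + 1 :]
        j = cds_end - pos  # insert before this sense index
        rc = str(Seq(ins).reverse_complement())
        return cds[:j] + rc + cds[j:]
    raise ValueError("not an indel")


def _translate(seq: str) -> str:
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def build_protein_contexts(
    variants: pd.DataFrame,
    annotation: pd.DataFrame,
    refseqs: Mapping[str, str],
    flank: int = 10,
) -> list[MutantProteinContext]:
    """Mutant-protein contexts for nonsynonymous SNVs and frameshift indels.

    Other effects carry no novel residues (synonymous), truncate without
    creating them (stopgain), or are outside the enumerated classes
    (in-frame indels) and are skipped.  Variant rows need ``chrom, pos,
    ref, alt, effect`` and an index usable as mutation id.
    """
    tx_by_gene = {row["gene"]: row for _, row in annotation.iterrows()}
    cds_cache: dict[str, str] = {}
    contexts: list[MutantProteinContext] = []
    for mutation_id, row in variants.iterrows():
        effect = row.get("effect", "")
        if effect not in ("nonsynonymous_SNV", "frameshift_indel"):
            continue
        tx = tx_by_gene.get(row["gene"])
        if tx is None:
            continue
        gene = tx["gene"]
        if gene not in cds_cache:
            raw = refseqs[tx["chrom"]][tx["cds_start"] - 1 : tx["cds_end"]]
            cds_cache[gene] = (
                str(Seq(raw).reverse_complement()) if tx["strand"] == "-" else raw
            )
        cds = cds_cache[gene]
        wild = _translate(cds)
        if effect == "nonsynonymous_SNV":
            if tx["strand"] == "+":
                i = row["pos"] - tx["cds_start"]
                alt_base = row["alt"]
            else:
                i = tx["cds_end"] - row["pos"]
                alt_base = str(Seq(row["alt"]).reverse_complement())
            mut_cds = cds[:i] + alt_base + cds[i + 1 :]
        else:
            mut_cds = _apply_indel_to_cds(
                cds, tx["strand"], tx["cds_start"], tx["cds_end"], row["pos"], row["ref"], row["alt"]
            )
        mutant = _translate(mut_cds)
        stop = mutant.find("*")
        terminated = stop >= 0
        if terminated:
            mutant = mutant[:stop]
        wild_cmp = wild.split("*", 1)[0]
        # first differing residue
        limit = min(len(wild_cmp), len(mutant))
        first = next((k for k in range(limit) if wild_cmp[k] != mutant[k]), limit)
        if effect == "nonsynonymous_SNV":
            if first >= len(mutant):
                continue  # mutation fell in the stop codon or past it
            last = first + 1
        else:
            if first >= len(mutant):
                continue  # frameshift immediately hit a stop: no novel residue
            last = len(mutant)
        lo = max(0, first - flank)
        hi = min(len(mutant), last + flank)
        contexts.append(
            MutantProteinContext(
                mutation_id=str(mutation_id),
                gene=gene,
                is_frameshift=effect == "frameshift_indel",
                stretch=mutant[lo:hi],
                novel_start=first - lo,
                novel_end=last - lo,
                protein_offset=lo,
                terminated_by_stop=terminated,
            )
        )
    return contexts


def enumerate_mutant_peptides(
    context: MutantProteinContext, lengths: Sequence[int] = PEPTIDE_LENGTHS
) -> pd.DataFrame:
    """All 8-11mer windows of the mutant stretch containing a novel residue.

    Windows are clipped at the protein termini and at the frameshift stop
    (both already reflected in the stretch).  Peptides containing
    ambiguous residues are dropped with a warning.  Returns columns
    ``peptide, mutation_id, gene, is_frameshift``.
    """
    s = context.stretch
    rows = []
    n_ambiguous = 0
    for L in lengths:
        # window [i, i+L) must intersect [novel_start, novel_end)
        lo = max(0, context.novel_start - L + 1)
        hi = min(len(s) - L, context.novel_end - 1)
        for i in range(lo, hi + 1):
            pep = s[i : i + L]
            if any(a not in _AA_INDEX for a in pep):
                n_ambiguous += 1
                continue
            rows.append((pep, context.mutation_id, context.gene, context.is_frameshift))
    if n_ambiguous:
        warnings.warn(
            f"dropped {n_ambiguous} window(s) with ambiguous residues "
            f"for mutation {context.mutation_id}",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=["peptide", "mutation_id", "gene", "is_frameshift"])


def expression_filter(
    variants: pd.DataFrame, expression: pd.Series, warn_missing: bool = True
) -> pd.DataFrame:
    """Keep mutations whose gene is expressed above the per-tumor median.

    ``expression`` is the sample's column of the genes x samples matrix;
    the median is taken across all genes of the sample and the comparison
    is strict (a gene exactly at the median is dropped).  Mutations in
    genes absent from the matrix are dropped with a warning.
    """
    if expression.empty:
        raise ValueError("expression vector is empty")
    median = float(expression.median())
    known = variants["gene"].isin(expression.index) & (variants["gene"] != "")
    n_missing = int((~known & (variants["gene"] != "")).sum())
    if n_missing and warn_missing:
        warnings.warn(
            f"dropped {n_missing} mutation(s) in genes absent from the expression matrix",
            stacklevel=2,
        )
    expressed = variants.loc[known, "gene"].map(expression) > median
    return variants.loc[known].loc[expressed.to_numpy()]


def _encode_peptides(peptides: Sequence[str], max_len: int = 11) -> tuple[np.ndarray, np.ndarray]:
    """Integer-encode peptides into a padded (n, max_len) index matrix."""
    n = len(peptides)
    enc = np.zeros((n, max_len), dtype=np.int64)
    length = np.zeros(n, dtype=np.int64)
    for i, p in enumerate(peptides):
        length[i] = len(p)
        for j, a in enumerate(p):
            enc[i, j] = _AA_INDEX[a]
    return enc, length


class SurrogateBindingPredictor:
    """Deterministic position-weight binding surrogate.

    Each allele's 11 x 20 weight matrix is seeded from a hash of the
    allele name, so a given (peptide, allele) pair always scores the same
    IC50 in nM.  Scores are spread over roughly 1-50000 nM with a
    minority of strong binders; the surrogate carries no immunological
    meaning and exists to exercise the cascade deterministically.
    """

    def __init__(self) -> None:
        self._pwm: dict[str, np.ndarray] = {}

    def _matrix(self, allele: str) -> np.ndarray:
        if allele not in self._pwm:
            digest = hashlib.md5(allele.encode()).digest()
            rng = np.random.default_rng(int.from_bytes(digest[:4], "little"))
            self._pwm[allele] = rng.random((11, 20))
        return self._pwm[allele]

    def predict(self, peptides: Sequence[str], allele: str) -> np.ndarray:
        """IC50 (nM) for a batch of 8-11mers against one allele."""
        if len(peptides) == 0:
            return np.zeros(0)
        pwm = self._matrix(allele)
        enc, length = _encode_peptides(peptides)
        scores = np.zeros(len(peptides))
        for j in range(11):
            active = length > j
            scores[active] += pwm[j, enc[active, j]]
        scores /= length
        exponent = np.clip(0.25 + 1.4 * (scores - 0.5), 0.0, 1.0)
        return 50000.0 ** (1.0 - exponent)

    def ic50(self, peptide: str, allele: str) -> float:
        return float(self.predict([peptide], allele)[0])


class SurrogateCleavagePredictor:
    """Deterministic C-terminal cleavage surrogate.

    Scores the peptide's C-terminal residue with a fixed per-residue
    propensity table (seeded once); a peptide is predicted cleavable when
    its score reaches the threshold (inclusive).
    """

    threshold: float = 0.5

    def __init__(self) -> None:
        rng = np.random.default_rng(20170524)
        self.propensity = dict(zip(AMINO_ACIDS, rng.random(20)))

    def score(self, peptide: str) -> float:
        return float(self.propensity[peptide[-1]])

    def is_cleaved(self, peptide: str) -> bool:
        return self.score(peptide) >= self.threshold


def pooled_percentile_ranks(ic50: np.ndarray) -> np.ndarray:
    """Percentile rank of each prediction within the pooled set.

    Defined as 100 x (number of pooled predictions with strictly lower
    IC50) / pool size; ties share the lower rank.
    """
    ic50 = np.asarray(ic50, dtype=float)
    order = np.sort(ic50)
    lower = np.searchsorted(order, ic50, side="left")
    return 100.0 * lower / len(ic50)


def binding_filter(
    candidates: pd.DataFrame,
    typing: HlaTyping,
    predictor,
    ic50_max: float = 500.0,
    rank_max: float = 2.0,
    per_allele_rank: bool = False,
) -> pd.DataFrame:
    """Score candidates against the patient alleles and apply both rules.

    All (unique peptide) x (distinct allele) interactions of the tumor
    form the prediction pool; the percentile rank is computed over that
    pool (or within each allele when ``per_allele_rank``).  A candidate
    survives when at least one allele gives IC50 < ``ic50_max`` and rank
    < ``rank_max``; its best allele is the qualifying one with lowest
    IC50.  Returns the surviving candidate rows with ``best_allele,
    ic50, percentile_rank`` added.
    """
    if candidates.empty:
        return candidates.assign(best_allele="", ic50=np.nan, percentile_rank=np.nan)
    peptides = pd.Index(candidates["peptide"].unique())
    alleles = typing.unique_alleles
    preds = []
    for allele in alleles:
        ic50 = predictor.predict(list(peptides), allele)
        preds.append(pd.DataFrame({"peptide": peptides, "allele": allele, "ic50": ic50}))
    pool = pd.concat(preds, ignore_index=True)
    if per_allele_rank:
        pool["percentile_rank"] = pool.groupby("allele")["ic50"].transform(
            lambda s: pooled_percentile_ranks(s.to_numpy())
        )
    else:
        pool["percentile_rank"] = pooled_percentile_ranks(pool["ic50"].to_numpy())
    pool["qualifies"] = (pool["ic50"] < ic50_max) & (pool["percentile_rank"] < rank_max)
    qualifying = pool[pool["qualifies"]].sort_values("ic50").drop_duplicates("peptide")
    best = qualifying.set_index("peptide")[["allele", "ic50", "percentile_rank"]]
    out = candidates[candidates["peptide"].isin(best.index)].copy()
    out["best_allele"] = out["peptide"].map(best["allele"])
    out["ic50"] = out["peptide"].map(best["ic50"])
    out["percentile_rank"] = out["peptide"].map(best["percentile_rank"])
    return out


def self_proteome_filter(
    candidates: pd.DataFrame, proteome: Iterable[str]
) -> pd.DataFrame:
    """Drop candidates occurring verbatim anywhere in the self proteome."""
    proteins = [str(p) for p in proteome]
    if not proteins:
        warnings.warn("empty proteome; self filter passes everything", stacklevel=2)
        return candidates.copy()
    haystack = "|".join(proteins)
    keep = [pep not in haystack for pep in candidates["peptide"]]
    return candidates[np.asarray(keep, dtype=bool)]


def cleavage_filter(candidates: pd.DataFrame, predictor=None) -> pd.DataFrame:
    """Keep candidates with a predicted C-terminal cleavage site."""
    if predictor is None:
        predictor = SurrogateCleavagePredictor()
    keep = [predictor.is_cleaved(p) for p in candidates["peptide"]]
    return candidates[np.asarray(keep, dtype=bool)]


def count_neoantigens(survivors: pd.DataFrame) -> tuple[int, pd.DataFrame]:
    """Unique surviving peptides, with per-mutation yields.

    Peptides binding several alleles (or produced by several windows)
    count once.  The yield table has one row per source mutation with its
    distinct peptide count and frameshift flag.
    """
    n_unique = int(survivors["peptide"].nunique())
    if survivors.empty:
        yields = pd.DataFrame(columns=["mutation_id", "is_frameshift", "n_peptides"])
    else:
        yields = (
            survivors.groupby(["mutation_id", "is_frameshift"])["peptide"]
            .nunique()
            .rename("n_peptides")
            .reset_index()
        )
    return n_unique, yields


@dataclass
class CascadeResult:
    sample: str
    n_candidates: int
    n_after_binding: int
    n_after_self: int
    n_after_cleavage: int
    n_neoantigens: int
    survivors: pd.DataFrame = field(repr=False)
    per_mutation: pd.DataFrame = field(repr=False)


def run_cascade(
    variants: pd.DataFrame,
    expression: pd.Series,
    typing: HlaTyping,
    annotation: pd.DataFrame,
    refseqs: Mapping[str, str],
    proteome: Iterable[str],
    binding_predictor=None,
    cleavage_predictor=None,
    sample: str = "",
    ic50_max: float = 500.0,
    rank_max: float = 2.0,
    per_allele_rank: bool = False,
) -> CascadeResult:
    """Run the full neoantigen filter cascade for one tumor.

    Order follows the study: expression filter, 8-11mer enumeration,
    binding/rank filter, self-proteome exclusion, cleavage filter, then
    counted-once summarisation.  Self and cleavage act on independent
    predicates, so their order does not change the survivors.
    """
    if binding_predictor is None:
        binding_predictor = SurrogateBindingPredictor()
    if cleavage_predictor is None:
        cleavage_predictor = SurrogateCleavagePredictor()
    expressed = expression_filter(variants, expression, warn_missing=False)
    contexts = build_protein_contexts(expressed, annotation, refseqs)
    frames = [enumerate_mutant_peptides(c) for c in contexts]
    candidates = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["peptide", "mutation_id", "gene", "is_frameshift"])
    )
    bound = binding_filter(
        candidates, typing, binding_predictor, ic50_max, rank_max, per_allele_rank
    )
    non_self = self_proteome_filter(bound, proteome)
    cleaved = cleavage_filter(non_self, cleavage_predictor)
    n_unique, yields = count_neoantigens(cleaved)
    return CascadeResult(
        sample=sample,
        n_candidates=int(candidates["peptide"].nunique()) if len(candidates) else 0,
        n_after_binding=int(bound["peptide"].nunique()) if len(bound) else 0,
        n_after_self=int(non_self["peptide"].nunique()) if len(non_self) else 0,
        n_after_cleavage=int(cleaved["peptide"].nunique()) if len(cleaved) else 0,
        n_neoantigens=n_unique,
        survivors=cleaved.reset_index(drop=True),
        per_mutation=yields,
    )
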