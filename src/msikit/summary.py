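"""End-to-end pipeline orchestration and cohort descriptive statistics.

Runs every stage in dependency order on a (synthetic or ingested)
cohort and assembles the per-tumor result table the study figures are
built from -- mutation load, MSI score, clone count, truncal fraction,
neoantigen count, hotspot genotypes -- plus the cohort-level rank
correlations.  Survival modeling is deliberately not computed here; the
per-tumor table doubles as a covariate table for standard survival
tooling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__ as _version
from . import clonality as clonality_mod
from . import cna, hotspots, msi, neoantigen, signatures, variants
from .simulate import Cohort, CohortConfig, simulate_cohort

__all__ = ["spearman", "welch_t", "CohortReport", "run_pipeline"]


def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with a t-approximation p.

    Requires at least four complete paired observations; a constant
    vector yields (NaN, NaN) with a warning rather than an error.
    """
    x = pd.Series(x, dtype=float)
    y = pd.Series(y, dtype=float)
    ok = x.notna() & y.notna()
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("spearman needs at least 4 complete paired observations")
    if x.nunique() < 2 or y.nunique() < 2:
        warnings.warn("constant vector; Spearman correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def welch_t(x, y) -> tuple[float, float]:
    """Welch's two-sample t-test with the same missing-value policy."""
    x = pd.Series(x, dtype=float).dropna()
    y = pd.Series(y, dtype=float).dropna()
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t needs at least 2 observations per group")
    if x.nunique() < 2 and y.nunique() < 2:
        warnings.warn("both groups constant; t-test undefined", stacklevel=2)
        return float("nan"), float("nan")
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


@dataclass
class CohortReport:
    per_tumor: pd.DataFrame
    correlations: dict[str, tuple[float, float]]
    hotspot_frequencies: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.per_tumor.to_csv(outdir / "per_tumor.tsv", sep="\t", index=False)
        self.hotspot_frequencies.to_csv(outdir / "hotspot_frequencies.tsv", sep="\t")
        payload = {
            "correlations": {k: list(v) for k, v in self.correlations.items()},
            "provenance": self.provenance,
        }
        with open(outdir / "report.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        return outdir


def _hotspot_sites(reference):
    """Coding homopolymer sites (>= 6 bp) with genomic coordinates."""
    sites = []
    for row in reference.annotation.itertuples(index=False):
        cds = reference.seqs[row.chrom][row.cds_start - 1 : row.cds_end]
        if row.strand == "-":
            from Bio.Seq import Seq

            cds = str(Seq(cds).reverse_complement())
        for site in hotspots.scan_homopolymers(cds, min_len=6, gene=row.gene, transcript=row.transcript):
            if row.strand == "+":
                g_start = row.cds_start + site.cds_start - 1
            else:
                g_start = row.cds_end - site.cds_start - site.run_length + 2
            sites.append((site, row.chrom, g_start, g_start + site.run_length - 1))
    return sites


def _genotype_hotspots(sites, sample, depth_mean, rng):
    """Per-sample hotspot genotypes from call-backed read support.

    Indel-supporting reads come from the sample's called indels that hit
    the run; sites without a call get a Poisson-sampled spanning depth
    with zero indel reads.
    """
    calls = sample.variants
    is_indel = calls["variant_class"] != "SNV"
    indels = calls[is_indel]
    genos = []
    for site, chrom, g_start, g_end in sites:
        hit = indels[
            (indels["chrom"] == chrom)
            & (indels["pos"] >= g_start - 1)
            & (indels["pos"] <= g_end)
        ]
        if len(hit):
            n_indel = int(hit["tumor_alt_reads"].sum())
            n_reads = int(hit["tumor_alt_reads"].sum() + hit["tumor_ref_reads"].max())
        else:
            n_indel = 0
            n_reads = int(rng.poisson(depth_mean))
        genos.append(hotspots.genotype_hotspot(site, sample.sample_id, n_reads, n_indel))
    return genos


def run_pipeline(
    config: CohortConfig | None = None,
    cohort: Cohort | None = None,
    outdir=None,
    catalogue: signatures.SignatureCatalogue | None = None,
    thresholds: variants.FilterThresholds | None = None,
) -> CohortReport:
    """Execute all stages on a cohort and assemble the report.

    Either a config (a synthetic cohort is generated) or a pre-built
    cohort may be passed.  Deterministic: the same config and seed give a
    byte-identical report.  Any stage failure propagates with the
    failing stage named.
    """
    if cohort is None:
        if config is None:
            raise ValueError("pass a config or a cohort")
        cohort = simulate_cohort(config)
    config = cohort.config
    if catalogue is None:
        catalogue = signatures.synthetic_catalogue()
    reference = cohort.reference
    sites = _hotspot_sites(reference)
    proteome = list(reference.proteome.values())
    binding = neoantigen.SurrogateBindingPredictor()
    cleavage = neoantigen.SurrogateCleavagePredictor()

    rows = []
    all_genotypes = []
    stage = "start"
    try:
        for i, sample in enumerate(cohort.samples):
            stage = f"variant_qc[{sample.sample_id}]"
            filtered = variants.filter_somatic_calls(sample.variants, thresholds)
            retained = filtered[filtered["filter_status"] == "PASS"].reset_index(drop=True)
            classified = variants.classify_effects(retained, reference.annotation, reference.seqs)
            load = variants.mutation_load(classified)

            stage = f"signatures[{sample.sample_id}]"
            snvs = classified[classified["variant_class"] == "SNV"]
            spectrum = signatures.tabulate_contexts(snvs, reference.seqs, sample.sample_id)
            fit = signatures.fit_exposures(spectrum, catalogue)

            stage = f"msi[{sample.sample_id}]"
            msi_result = msi.score_sample(sample.histograms, sample.sample_id)

            stage = f"cna[{sample.sample_id}]"
            ploidy = float(sample.segments["ploidy"].iloc[0])
            loh_segments = cna.call_loh_segments(sample.segments)
            fga = cna.fraction_genome_altered(sample.segments, ploidy)

            stage = f"clonality[{sample.sample_id}]"
            acf = float(sample.segments["purity"].iloc[0])
            model, statuses = clonality_mod.model_clonality(
                classified, sample.segments, acf, seed=config.seed + 101 + i
            )
            clustered = statuses[statuses != "unclustered"]
            truncal_fraction = (
                float((clustered == "truncal").mean()) if len(clustered) else float("nan")
            )

            stage = f"neoantigens[{sample.sample_id}]"
            cascade = neoantigen.run_cascade(
                classified,
                cohort.expression[sample.sample_id],
                sample.hla,
                reference.annotation,
                reference.seqs,
                proteome,
                binding_predictor=binding,
                cleavage_predictor=cleavage,
                sample=sample.sample_id,
            )
            yields = cascade.per_mutation
            fs_yield = (
                float(yields.loc[yields["is_frameshift"], "n_peptides"].mean())
                if yields["is_frameshift"].any()
                else float("nan")
            )
            snv_yield = (
                float(yields.loc[~yields["is_frameshift"], "n_peptides"].mean())
                if (~yields["is_frameshift"]).any()
                else float("nan")
            )

            stage = f"hotspots[{sample.sample_id}]"
            rng = np.random.default_rng([config.seed, 777, i])
            genotypes = _genotype_hotspots(sites, sample, config.tumor_depth_mean, rng)
            all_genotypes.extend(genotypes)

            rows.append(
                {
                    "sample": sample.sample_id,
                    "n_total": load.n_total,
                    "n_affecting": load.n_affecting,
                    "n_silent": load.n_silent,
                    "n_snv": load.n_snv,
                    "n_indel": load.n_indel,
                    "ratio_affecting_silent": load.ratio_affecting_silent,
                    "msi_score": msi_result.msi_score,
                    "n_loci_scored": msi_result.n_scored,
                    "dominant_signature": fit.dominant_signature if fit else "",
                    "exposure_mmr_like": float(fit.exposures.get("mmr_like", np.nan)) if fit else np.nan,
                    "fraction_genome_altered": fga,
                    "n_loh_segments": int((loh_segments["loh"] != "none").sum()),
                    "n_clones": model.n_clones,
                    "truncal_fraction": truncal_fraction,
                    "n_neoantigens": cascade.n_neoantigens,
                    "peptides_per_frameshift": fs_yield,
                    "peptides_per_snv": snv_yield,
                    "acf": acf,
                    "true_n_clones": len(sample.truth.clones),
                }
            )
    except Exception as exc:  # noqa: BLE001 - name the failing stage
        raise RuntimeError(f"pipeline failed at stage {stage}") from exc

    per_tumor = pd.DataFrame(rows)
    correlations = {
        "msi_vs_indels": spearman(per_tumor["msi_score"], per_tumor["n_indel"]),
        "msi_vs_snvs": spearman(per_tumor["msi_score"], per_tumor["n_snv"]),
        "load_vs_neoantigens": spearman(per_tumor["n_total"], per_tumor["n_neoantigens"]),
    } if len(per_tumor) >= 4 else {}
    freq = hotspots.cohort_frequency(all_genotypes) if all_genotypes else pd.DataFrame()
    provenance = {
        "package_version": _version,
        "seed": config.seed,
        "n_tumors": config.n_tumors,
        "genome_length": config.genome_length,
        "thresholds": vars(thresholds or variants.FilterThresholds()),
    }
    report = CohortReport(per_tumor, correlations, freq, provenance)
    if outdir is not None:
        report.write(outdir)
    return report
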