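"""VAF-based clonality modeling: mixture clustering and clone labels.

Somatic variants from copy-number-neutral, LOH-free diploid regions with
at least 50 total reads are clustered on the read-count scale with a
binomial mixture (components live on the VAF scale; the number of
components is chosen by BIC).  Against the aberrant cell fraction (ACF,
the tumor purity), a heterozygous mutation present in every tumor cell is
expected at VAF = ACF/2: the cluster whose mean lies within a configured
tolerance of ACF/2 is the truncal clone, clusters below are subclonal,
and clusters above are homozygous (both alleles mutated).  The clone
count is the number of truncal plus subclonal clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "VafClusters",
    "CloneModel",
    "select_clustering_variants",
    "cluster_vafs",
    "classify_clusters",
    "variant_status",
    "model_clonality",
]


@dataclass
class VafClusters:
    """Fitted binomial mixture over (alt reads, depth) pairs."""

    means: np.ndarray  # per-cluster VAF means, ascending
    weights: np.ndarray
    labels: np.ndarray  # cluster index per clustered variant
    n_components: int
    bic: float
    loglik: float


@dataclass
class CloneModel:
    """Cluster-level clone classification for one tumor."""

    aberrant_cell_fraction: float
    clusters: VafClusters
    cluster_status: list[str]  # truncal | subclonal | homozygous, per cluster
    n_clones: int  # truncal + subclonal clusters
    truncal_index: int | None
    truncal_flagged: bool = False  # True when no cluster fell within tolerance
    variant_index: pd.Index | None = field(default=None, repr=False)


def select_clustering_variants(
    variants: pd.DataFrame, segments: pd.DataFrame, min_depth: int = 50
) -> pd.DataFrame:
    """Variants eligible for clustering: deep, diploid, LOH-free loci.

    Keeps variants with tumor depth >= ``min_depth`` lying in segments
    with total copy number 2 and a non-zero minor allele (the diploid
    heterozygous baseline, unaffected by CNAs and LOH).
    """
    depth = variants["tumor_ref_reads"] + variants["tumor_alt_reads"]
    keep = depth >= min_depth
    seg_ok = pd.Series(False, index=variants.index)
    for chrom, segs in segments.groupby("chrom"):
        segs = segs.sort_values("start")
        in_chrom = variants["chrom"] == chrom
        if not in_chrom.any():
            continue
        pos = variants.loc[in_chrom, "pos"].to_numpy()
        idx = np.searchsorted(segs["start"].to_numpy(), pos, side="right") - 1
        ok = np.zeros(len(pos), dtype=bool)
        valid = idx >= 0
        if valid.any():
            seg_rows = segs.iloc[idx[valid]]
            total = (seg_rows["n_major"] + seg_rows["n_minor"]).to_numpy()
            minor = seg_rows["n_minor"].to_numpy()
            covered = seg_rows["end"].to_numpy() >= pos[valid]
            ok[valid] = covered & (total == 2) & (minor > 0)
        seg_ok.loc[in_chrom] = ok
    return variants[keep & seg_ok]


def _binom_loglik_matrix(alt: np.ndarray, depth: np.ndarray, p: np.ndarray) -> np.ndarray:
    """log P(alt | depth, p_k) for each variant x component (constant dropped)."""
    p = np.clip(p, 1e-6, 1 - 1e-6)
    return alt[:, None] * np.log(p)[None, :] + (depth - alt)[:, None] * np.log1p(-p)[None, :]


def _em_fit(alt, depth, p0, w0, max_iter=300, tol=1e-7):
    const = gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1)
    p, w = p0.copy(), w0.copy()
    prev = -np.inf
    for _ in range(max_iter):
        log_resp = _binom_loglik_matrix(alt, depth, p) + np.log(np.clip(w, 1e-12, None))
        m = log_resp.max(axis=1)
        norm = m + np.log(np.exp(log_resp - m[:, None]).sum(axis=1))
        ll = float(np.sum(norm + const))
        resp = np.exp(log_resp - norm[:, None])
        nk = resp.sum(axis=0)
        w = nk / nk.sum()
        p = (resp * alt[:, None]).sum(axis=0) / np.clip((resp * depth[:, None]).sum(axis=0), 1e-12, None)
        if abs(ll - prev) < tol * (1 + abs(ll)):
            prev = ll
            break
        prev = ll
    return p, w, prev


def cluster_vafs(
    alt: np.ndarray,
    depth: np.ndarray,
    max_clusters: int = 10,
    seed: int = 0,
    min_cluster_frac: float = 0.05,
    min_variants: int = 20,
) -> VafClusters:
    """Cluster alt/depth read counts with a BIC-selected binomial mixture.

    Deterministic for a fixed seed: each component count is fitted from a
    quantile-based initialisation plus one seeded random restart, and the
    best fit by BIC is kept.  Clusters holding fewer than
    ``min_cluster_frac`` of the variants are merged into their nearest
    neighbour (a stabiliser against spurious small components).
    """
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if alt.shape != depth.shape or alt.ndim != 1:
        raise ValueError("alt and depth must be 1-d arrays of equal length")
    n = len(alt)
    if n == 0:
        raise ValueError("no variants to cluster")
    vaf = alt / np.clip(depth, 1, None)
    if n < min_variants or np.ptp(vaf) < 1e-12:
        mean = float(alt.sum() / depth.sum())
        return VafClusters(
            np.array([mean]), np.array([1.0]), np.zeros(n, dtype=int), 1, np.nan, np.nan
        )
    rng = np.random.default_rng(seed)
    best = None
    for k in range(1, max_clusters + 1):
        inits = [np.quantile(vaf, (np.arange(k) + 0.5) / k)]
        inits.append(np.sort(rng.uniform(vaf.min(), vaf.max(), size=k)))
        w0 = np.full(k, 1.0 / k)
        best_k = None
        for p0 in inits:
            p, w, ll = _em_fit(alt, depth, np.asarray(p0, dtype=float), w0)
            if best_k is None or ll > best_k[2]:
                best_k = (p, w, ll)
        p, w, ll = best_k
        n_params = 2 * k - 1
        bic = -2.0 * ll + n_params * np.log(n)
        if best is None or bic < best[3]:
            best = (p, w, ll, bic, k)
    p, w, ll, bic, k = best

    # merge under-populated clusters into their nearest neighbour
    while len(p) > 1 and w.min() < min_cluster_frac:
        j = int(np.argmin(w))
        others = np.delete(np.arange(len(p)), j)
        tgt = others[np.argmin(np.abs(p[others] - p[j]))]
        w[tgt] += w[j]
        p = np.delete(p, j)
        w = np.delete(w, j)
    order = np.argsort(p)
    p, w = p[order], w[order]
    log_resp = _binom_loglik_matrix(alt, depth, p) + np.log(np.clip(w, 1e-12, None))
    labels = np.argmax(log_resp, axis=1)
    return VafClusters(p, w / w.sum(), labels, len(p), bic, ll)


def classify_clusters(
    clusters: VafClusters, aberrant_cell_fraction: float, tolerance_factor: float = 0.1
) -> CloneModel:
    """Label clusters truncal / subclonal / homozygous against the ACF.

    The expected truncal mean is ACF/2; a cluster within
    ``tolerance_factor * ACF`` of it qualifies as truncal (the closest
    such cluster wins if several qualify), clusters below the target are
    subclonal and clusters above are homozygous.  If no cluster
    qualifies, the nearest cluster below the target is flagged as the
    truncal candidate with a warning.
    """
    acf = float(aberrant_cell_fraction)
    if not (0 < acf <= 1):
        raise ValueError("aberrant cell fraction must be in (0, 1]")
    target = acf / 2.0
    tol = tolerance_factor * acf
    means = clusters.means
    dist = np.abs(means - target)
    within = dist <= tol
    truncal_flagged = False
    if within.any():
        truncal_idx = int(np.flatnonzero(within)[np.argmin(dist[within])])
    else:
        below = np.flatnonzero(means <= target)
        if len(below):
            truncal_idx = int(below[np.argmin(target - means[below])])
        else:
            truncal_idx = int(np.argmin(dist))
        truncal_flagged = True
        warnings.warn(
            f"no cluster mean within {tol:.3f} of ACF/2 = {target:.3f}; "
            f"flagging cluster at {means[truncal_idx]:.3f} as truncal candidate",
            stacklevel=2,
        )
    status = []
    for i, m in enumerate(means):
        if i == truncal_idx:
            status.append("truncal")
        elif m < target:
            status.append("subclonal")
        else:
            status.append("homozygous")
    n_clones = sum(s in ("truncal", "subclonal") for s in status)
    return CloneModel(acf, clusters, status, n_clones, truncal_idx, truncal_flagged)


def variant_status(model: CloneModel, variant_index: pd.Index) -> pd.Series:
    """Per-variant status over an arbitrary variant index.

    Clustered variants inherit their cluster's status; all others are
    ``unclustered``.  ``model.variant_index`` must hold the index of the
    clustered subset (set by :func:`model_clonality`).
    """
    if model.variant_index is None:
        raise ValueError("model carries no variant index; fit via model_clonality")
    status = pd.Series("unclustered", index=variant_index, dtype=object)
    clustered = model.variant_index.intersection(variant_index)
    lab = pd.Series(model.clusters.labels, index=model.variant_index)
    status.loc[clustered] = [model.cluster_status[k] for k in lab.loc[clustered]]
    return status


def model_clonality(
    variants: pd.DataFrame,
    segments: pd.DataFrame,
    aberrant_cell_fraction: float,
    min_depth: int = 50,
    max_clusters: int = 10,
    seed: int = 0,
    tolerance_factor: float = 0.1,
) -> tuple[CloneModel, pd.Series]:
    """End-to-end clonality call: select, cluster, classify, label.

    Returns the fitted :class:`CloneModel` and a per-variant status
    series aligned to ``variants.index`` (excluded variants are
    ``unclustered``).
    """
    eligible = select_clustering_variants(variants, segments, min_depth=min_depth)
    if eligible.empty:
        raise ValueError("no variants eligible for clustering")
    clusters = cluster_vafs(
        eligible["tumor_alt_reads"].to_numpy(),
        (eligible["tumor_ref_reads"] + eligible["tumor_alt_reads"]).to_numpy(),
        max_clusters=max_clusters,
        seed=seed,
    )
    model = classify_clusters(clusters, aberrant_cell_fraction, tolerance_factor)
    model.variant_index = eligible.index
    return model, variant_status(model, variants.index)
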