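"""Population-stratification statistics: FST, permutation tests, PCA, k-means.

FST between collection-site groups is computed from identity-by-state (IBS)
probabilities:

    FST = (GS - GT) / (1 - GT)

where GT is the probability that two alleles drawn at random from the
pooled population are identical by state (p̄² + q̄² at a biallelic site) and
GS the same probability for draws within a group, averaged over groups.
This plug-in estimator is upwardly biased at finite sample size and, with K
groups, recovers only (K-1)/K of the model divergence as K is small; the
Weir–Cockerham variance-components estimator (``method="wc"``) is provided
for unbiased parameter recovery and is the one validated against nominal
simulated divergence.

Statistical significance of the genome-wide mean FST and of each per-SNP
FST is assessed by permuting group labels across samples (default 10,000
permutations) with the add-one p-value convention p = (1 + #{perm >= obs})
/ (1 + N), giving a floor of ~1e-4 at 10,000 permutations.  Per-SNP p-values
are corrected by Benjamini–Hochberg FDR; SNPs with q <= 0.05 form the
"stratification-informative" subset used for PCA and k-means clustering.
The optimal cluster count follows an elbow rule on the total within-cluster
sum of squares (TWSS), and the cluster-by-site contingency is tested with a
Pearson chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .gwas import fdr_bh
from .panel import MISSING, GenotypePanel


@dataclass
class FstResult:
    per_snp_fst: np.ndarray
    mean_fst: float
    perm_p_global: float
    perm_p_per_snp: np.ndarray
    q_per_snp: np.ndarray
    informative_snps: np.ndarray  # indices with q <= alpha

    def to_frame(self, variants: pd.DataFrame) -> pd.DataFrame:
        informative = np.zeros(len(self.per_snp_fst), dtype=bool)
        informative[self.informative_snps] = True
        return pd.DataFrame(
            {
                "chrom": variants["chrom"],
                "pos": variants["pos"],
                "fst": self.per_snp_fst,
                "p": self.perm_p_per_snp,
                "q": self.q_per_snp,
                "informative": informative,
            }
        )


@dataclass
class ClusterResult:
    pc_coords: np.ndarray
    eigenvalues: np.ndarray
    twss_by_k: np.ndarray
    optimal_k: int
    assignments: np.ndarray  # 1-based cluster labels
    chi2: float | None = None
    df: int | None = None
    chi2_p: float | None = None


# ---------------------------------------------------------------------------
# FST estimators


def snp_fst(
    group_allele_counts: list[tuple[float, float]], weights: str = "size"
) -> float:
    """IBS-based FST from per-group (ref_count, alt_count) allele counts.

    GS is the within-group IBS probability averaged over groups; by default
    groups are weighted by allele count so that GS is commensurate with GT,
    whose pooled frequency is count-weighted by construction (with an
    unweighted GS and unequal group sizes the two probabilities are
    mismatched and the statistic loses its signal; ``weights="uniform"``
    remains available and is identical for equal-size groups).  Returns
    ``nan`` for a pooled-monomorphic site (GT = 1).
    """
    if len(group_allele_counts) < 2:
        raise ValueError("need at least two groups")
    refs = np.array([c[0] for c in group_allele_counts], dtype=float)
    alts = np.array([c[1] for c in group_allele_counts], dtype=float)
    totals = refs + alts
    for g, t in enumerate(totals):
        if t <= 0:
            raise ValueError(f"group {g} has no observed alleles")
    p = alts / totals
    gs_terms = p**2 + (1 - p) ** 2
    if weights == "uniform":
        gs = float(gs_terms.mean())
    elif weights == "size":
        gs = float(np.average(gs_terms, weights=totals))
    else:
        raise ValueError("weights must be 'uniform' or 'size'")
    p_bar = alts.sum() / totals.sum()
    gt = p_bar**2 + (1 - p_bar) ** 2
    if gt == 1.0:
        return float("nan")
    return float((gs - gt) / (1.0 - gt))


def _group_allele_counts(
    calls: np.ndarray, group_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(alt_count, total_count) per SNP for samples selected by group_mask."""
    sub = calls[group_mask]
    missing = sub == MISSING
    alt = np.where(missing, 0, sub).sum(axis=0)
    tot = 2 * (~missing).sum(axis=0)
    return alt.astype(float), tot.astype(float)


def _per_snp_fst_from_counts(
    alts: np.ndarray, tots: np.ndarray, weights: str = "size"
) -> np.ndarray:
    """Vectorized IBS FST; ``alts``/``tots`` are (n_groups, n_snps)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alts / tots
        gs_terms = p**2 + (1 - p) ** 2
        if weights == "uniform":
            gs = gs_terms.mean(axis=0)
        else:
            gs = (gs_terms * tots).sum(axis=0) / tots.sum(axis=0)
        p_bar = alts.sum(axis=0) / tots.sum(axis=0)
        gt = p_bar**2 + (1 - p_bar) ** 2
        fst = (gs - gt) / (1.0 - gt)
    fst[np.any(tots == 0, axis=0)] = np.nan
    return fst


def _wc_components(
    panel: GenotypePanel, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weir–Cockerham variance components per SNP, vectorized over SNPs.

    Returns (a, a + b + c): the among-group component and the total, from
    which theta is a / (a+b+c) per SNP or sum(a) / sum(a+b+c) genome-wide.
    Groups with no calls at a SNP drop out of that SNP's computation; SNPs
    with fewer than two usable groups yield nan components.
    """
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    n_list, p_list, h_list = [], [], []
    for lab in labels:
        sub = panel.calls[groups == lab]
        miss = sub == MISSING
        n_j = (~miss).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_j = np.where(miss, 0, sub).sum(axis=0) / (2.0 * n_j)
            h_j = (sub == 1).sum(axis=0) / n_j
        n_list.append(n_j)
        p_list.append(p_j)
        h_list.append(h_j)
    n = np.array(n_list)  # (G, S)
    p = np.array(p_list)
    h = np.array(h_list)
    usable = n > 0
    r = usable.sum(axis=0).astype(float)
    n = np.where(usable, n, 0.0)
    p = np.where(usable, p, 0.0)
    h = np.where(usable, h, 0.0)
    n_sum = n.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = n_sum / r
        n_c = (n_sum - (n**2).sum(axis=0) / n_sum) / (r - 1)
        p_bar = (n * p).sum(axis=0) / n_sum
        s2 = (n * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n * h).sum(axis=0) / n_sum
        a = (n_bar / n_c) * (
            s2
            - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2.0
    total = a + b + c
    bad = (r < 2) | ~np.isfinite(total)
    a = np.where(bad, np.nan, a)
    total = np.where(bad, np.nan, total)
    return a, total


def snp_fst_wc(calls_by_group: list[np.ndarray]) -> float:
    """Weir–Cockerham theta for one biallelic SNP.

    ``calls_by_group`` holds dosage vectors (missing = -1) per group.  The
    estimator combines the among-group (a) and within-group (b + c)
    variance components from sample frequencies and observed
    heterozygosity; unlike the IBS plug-in it is designed to estimate the
    model divergence on its nominal scale.  Returns ``nan`` when undefined.
    """
    calls = np.concatenate(calls_by_group)[:, None]
    labels = np.concatenate(
        [np.full(len(g), i) for i, g in enumerate(calls_by_group)]
    )
    panel_like = _FakePanel(calls)
    a, total = _wc_components(panel_like, labels)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a[0] / total[0]
    return float(theta) if np.isfinite(theta) and total[0] != 0 else float("nan")


class _FakePanel:
    """Minimal duck-typed panel wrapper for component computations."""

    def __init__(self, calls: np.ndarray) -> None:
        self.calls = calls


def per_snp_fst(
    panel: GenotypePanel,
    groups: np.ndarray,
    method: str = "ibs",
    weights: str = "size",
) -> np.ndarray:
    """Per-SNP FST across the groups in ``groups`` (per-sample labels)."""
    labels = pd.unique(np.asarray(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if method == "ibs":
        alts, tots = [], []
        for lab in labels:
            a, t = _group_allele_counts(panel.calls, np.asarray(groups) == lab)
            alts.append(a)
            tots.append(t)
        return _per_snp_fst_from_counts(
            np.array(alts), np.array(tots), weights=weights
        )
    if method == "wc":
        a, total = _wc_components(panel, groups)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total != 0, a / total, np.nan)
    raise ValueError("method must be 'ibs' or 'wc'")


def mean_fst(
    panel: GenotypePanel,
    groups: np.ndarray,
    method: str = "ibs",
    weights: str = "size",
    aggregate: str = "mean",
) -> tuple[float, int]:
    """Genome-wide FST and the number of contributing SNPs.

    ``aggregate="mean"`` is the unweighted mean of defined per-SNP values
    (negative values retained, not clamped); ``aggregate="ratio"`` is the
    ratio-of-sums form — sum of numerators over sum of denominators — which
    is the preferred aggregation for the Weir–Cockerham estimator at weak
    divergence.
    """
    if aggregate not in ("mean", "ratio"):
        raise ValueError("aggregate must be 'mean' or 'ratio'")
    if aggregate == "ratio":
        if method == "wc":
            a, total = _wc_components(panel, groups)
            ok = ~np.isnan(total)
            if not ok.any():
                raise ValueError("no SNP with defined FST")
            return float(np.nansum(a) / np.nansum(total)), int(ok.sum())
        # IBS ratio of sums: sum(GS - GT) / sum(1 - GT)
        labels = pd.unique(np.asarray(groups))
        alts, tots = [], []
        for lab in labels:
            al, t = _group_allele_counts(panel.calls, np.asarray(groups) == lab)
            alts.append(al)
            tots.append(t)
        alts, tots = np.array(alts), np.array(tots)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alts / tots
            gs_terms = p**2 + (1 - p) ** 2
            if weights == "uniform":
                gs = gs_terms.mean(axis=0)
            else:
                gs = (gs_terms * tots).sum(axis=0) / tots.sum(axis=0)
            p_bar = alts.sum(axis=0) / tots.sum(axis=0)
            gt = p_bar**2 + (1 - p_bar) ** 2
        ok = ~np.any(tots == 0, axis=0) & np.isfinite(gs) & (gt < 1)
        if not ok.any():
            raise ValueError("no SNP with defined FST")
        return (
            float((gs[ok] - gt[ok]).sum() / (1.0 - gt[ok]).sum()),
            int(ok.sum()),
        )
    fst = per_snp_fst(panel, groups, method=method, weights=weights)
    ok = ~np.isnan(fst)
    if not ok.any():
        raise ValueError("no SNP with defined FST")
    return float(fst[ok].mean()), int(ok.sum())


def fst_permutation(
    panel: GenotypePanel,
    groups: np.ndarray,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    weights: str = "size",
    chunk: int = 500,
) -> FstResult:
    """Permutation test of genome-wide mean and per-SNP IBS FST.

    Group labels are shuffled across samples ``n_perm`` times; p-values use
    the add-one convention (1 + #{perm >= obs}) / (1 + n_perm).  Per-SNP
    p-values are BH-FDR corrected and SNPs with q <= ``alpha`` are flagged
    informative.  Vectorized over permutation chunks: alt and non-missing
    counts per group are linear in the 0/1 group-membership matrix, so each
    chunk is two matrix products per group.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if panel.n_variants == 0:
        raise ValueError("panel has no variants")
    groups = np.asarray(groups)
    codes, labels = pd.factorize(groups)
    rng = np.random.default_rng(seed)

    alt_mat = np.where(panel.calls == MISSING, 0, panel.calls).astype(float)
    nonmiss = (panel.calls != MISSING).astype(float)

    def mean_and_per_snp(membership: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        """membership: per group a (B, n_samples) 0/1 matrix."""
        B = membership[0].shape[0]
        alts = np.stack([m @ alt_mat for m in membership])  # (G, B, n_snps)
        tots = np.stack([2.0 * (m @ nonmiss) for m in membership])
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alts / tots
            gs_terms = p**2 + (1 - p) ** 2
            if weights == "uniform":
                gs = gs_terms.mean(axis=0)
            else:
                gs = (gs_terms * tots).sum(axis=0) / tots.sum(axis=0)
            p_bar = alts.sum(axis=0) / tots.sum(axis=0)
            gt = p_bar**2 + (1 - p_bar) ** 2
            fst = (gs - gt) / (1.0 - gt)  # (B, n_snps)
        fst[np.any(tots == 0, axis=0)] = np.nan
        means = np.nanmean(fst, axis=1)
        return means, fst

    obs_membership = [
        (codes == c).astype(float)[None, :] for c in range(len(labels))
    ]
    obs_mean, obs_fst = mean_and_per_snp(obs_membership)
    obs_mean = float(obs_mean[0])
    obs_fst = obs_fst[0]

    ge_global = 0
    ge_snp = np.zeros(panel.n_variants, dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = np.empty((b, codes.size), dtype=codes.dtype)
        for i in range(b):
            perms[i] = rng.permutation(codes)
        membership = [(perms == c).astype(float) for c in range(len(labels))]
        means, fsts = mean_and_per_snp(membership)
        ge_global += int((means >= obs_mean).sum())
        with np.errstate(invalid="ignore"):
            ge_snp += np.nansum(fsts >= obs_fst, axis=0).astype(np.int64)
        done += b

    p_global = (1 + ge_global) / (1 + n_perm)
    p_snp = (1 + ge_snp) / (1 + n_perm)
    p_snp = np.where(np.isnan(obs_fst), np.nan, p_snp)
    ok = ~np.isnan(p_snp)
    q = np.full_like(p_snp, np.nan)
    q[ok] = fdr_bh(p_snp[ok])
    informative = np.flatnonzero(ok & (q <= alpha))
    return FstResult(
        per_snp_fst=obs_fst,
        mean_fst=obs_mean,
        perm_p_global=float(p_global),
        perm_p_per_snp=p_snp,
        q_per_snp=q,
        informative_snps=informative,
    )


# ---------------------------------------------------------------------------
# PCA / clustering


def pca(
    panel: GenotypePanel, snp_subset: np.ndarray | None = None, n_components: int = 10
) -> tuple[np.ndarray, np.ndarray, int]:
    """PCA of the dosage matrix on a SNP subset.

    Missing dosages are mean-imputed per SNP; columns are centered and
    scaled to unit variance; zero-variance columns are dropped (their count
    is returned).  Returns (coords, eigenvalues, n_dropped): coordinates are
    projections onto the top components, eigenvalues are those of the sample
    covariance matrix in non-increasing order.
    """
    if panel.n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    calls = panel.calls if snp_subset is None else panel.calls[:, snp_subset]
    if calls.shape[1] == 0:
        raise ValueError("empty SNP subset")
    x = calls.astype(float)
    x[x == MISSING] = np.nan
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_mean, inds[1])
    x -= x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    x = x[:, keep] / sd[keep]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eigvals = s**2 / (x.shape[0] - 1)
    k = min(n_components, s.size)
    coords = u[:, :k] * s[:k]
    return coords, eigvals, n_dropped


def optimal_k_twss(
    coords: np.ndarray,
    k_max: int = 10,
    n_restarts: int = 10,
    seed: int = 0,
    plateau: float = 0.10,
) -> ClusterResult:
    """k-means over k = 1..k_max with an elbow rule on TWSS.

    The relative improvement at k is (TWSS[k-1] - TWSS[k]) / TWSS[k-1]; the
    optimal k is the smallest k whose improvement from k-1 is >= ``plateau``
    (always true for k = 1) while the improvement from k to k+1 is below it.
    """
    n = coords.shape[0]
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if n < k_max:
        raise ValueError("fewer samples than k_max")
    twss = np.empty(k_max)
    labels_by_k = []
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        km.fit(coords)
        twss[k - 1] = km.inertia_
        labels_by_k.append(km.labels_)

    def improvement(k: int) -> float:  # improvement of k over k-1
        prev = twss[k - 2]
        return 0.0 if prev <= 0 else (prev - twss[k - 1]) / prev

    optimal = k_max
    for k in range(1, k_max):
        gain_here = True if k == 1 else improvement(k) >= plateau
        if gain_here and improvement(k + 1) < plateau:
            optimal = k
            break
    return ClusterResult(
        pc_coords=coords,
        eigenvalues=np.array([]),
        twss_by_k=twss,
        optimal_k=optimal,
        assignments=labels_by_k[optimal - 1] + 1,
    )


def contingency_chi2(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square of independence (no continuity correction)."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(t < 0) or t.sum() <= 0:
        raise ValueError("counts must be non-negative with positive total")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)
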