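"""Stratified allelic genome-wide association: the CMH test with annotation.

Association between a binary behavioral phenotype (indoor vs outdoor
capture, or dusk vs dawn blood-seeking) and each SNP is tested with the
Cochran–Mantel–Haenszel chi-square on 2x2xK allele-count tables, one 2x2
table per collection-site stratum.  With a_i, b_i the counts of allele A and
B among case alleles, c_i, d_i among control alleles, and
n_i = a_i + b_i + c_i + d_i:

    chi2_MH = ( |sum_i [a_i - (a_i+b_i)(a_i+c_i)/n_i]| - 1/2 )^2
              / sum_i (a_i+b_i)(a_i+c_i)(b_i+d_i)(c_i+d_i) / (n_i^3 - n_i^2)

referred to a chi-square with one degree of freedom.  The 1/2 continuity
correction is applied by default and can be disabled.  P-values are
corrected by Benjamini–Hochberg FDR, and FDR-significant SNPs are annotated
with genes within a physical window (default 10 kb) taken from a GFF3 file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from statsmodels.stats.multitest import multipletests

from .panel import MISSING, GenotypePanel


@dataclass
class StratifiedAlleleTable:
    """Per-stratum 2x2 allele-count tables for one SNP.

    ``counts`` has shape (K, 4) with columns (a, b, c, d): allele A / allele
    B counts in cases then controls.  Allele "A" is the reference allele;
    the CMH statistic is symmetric in this choice.
    """

    counts: np.ndarray
    strata: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float).reshape(-1, 4)
        if np.any(self.counts < 0):
            raise ValueError("allele counts must be non-negative")


@dataclass
class CMHResult:
    chrom: str
    pos: int
    chi2: float
    p: float
    p_fdr: float = float("nan")
    adjacent_genes: list[tuple[str, int, int, int]] = field(default_factory=list)


def build_tables(
    panel: GenotypePanel, phenotype: np.ndarray, strata: np.ndarray
) -> list[StratifiedAlleleTable]:
    """Per-SNP stratified allele-count tables.

    ``phenotype`` is a per-sample boolean (True = case) and ``strata`` the
    per-sample stratum labels.  Each non-missing genotype contributes two
    alleles; a heterozygote contributes one to each allele column.  Strata
    with no observed alleles at a SNP are dropped for that SNP.
    """
    phenotype = np.asarray(phenotype, dtype=bool)
    strata = np.asarray(strata)
    if phenotype.size != panel.n_samples or strata.size != panel.n_samples:
        raise ValueError("phenotype/strata length must match sample count")
    labels = pd.unique(strata)
    # per stratum x case/control: alt counts and non-missing counts per SNP
    tables_counts = np.zeros((len(labels), panel.n_variants, 4))
    for s_i, lab in enumerate(labels):
        for case, (col_a, col_b) in ((True, (0, 1)), (False, (2, 3))):
            sel = (strata == lab) & (phenotype == case)
            calls = panel.calls[sel]
            miss = calls == MISSING
            alt = np.where(miss, 0, calls).sum(axis=0)
            tot = 2 * (~miss).sum(axis=0)
            ref = tot - alt
            tables_counts[s_i, :, col_a] = ref  # allele A = reference
            tables_counts[s_i, :, col_b] = alt
    out = []
    for j in range(panel.n_variants):
        counts = tables_counts[:, j, :]
        nonzero = counts.sum(axis=1) > 0
        out.append(
            StratifiedAlleleTable(
                counts=counts[nonzero], strata=list(np.asarray(labels)[nonzero])
            )
        )
    return out


def cmh_test(
    table: StratifiedAlleleTable, continuity: bool = True
) -> tuple[float, float]:
    """Cochran–Mantel–Haenszel chi-square and p-value for one SNP.

    Strata with n <= 1 or a zero variance term contribute nothing to either
    sum.  Returns ``(nan, nan)`` when every stratum is degenerate.
    """
    c = table.counts
    if c.shape[0] == 0:
        return float("nan"), float("nan")
    a, b, cc, d = c[:, 0], c[:, 1], c[:, 2], c[:, 3]
    n = a + b + cc + d
    with np.errstate(invalid="ignore", divide="ignore"):
        num_i = a - (a + b) * (a + cc) / n
        var_i = (a + b) * (a + cc) * (b + d) * (cc + d) / (n**3 - n**2)
    usable = (n > 1) & np.isfinite(var_i) & (var_i > 0)
    if not usable.any():
        return float("nan"), float("nan")
    dev = float(num_i[usable].sum())
    var = float(var_i[usable].sum())
    corr = 0.5 if continuity else 0.0
    # the correction is not clamped at zero: a deviation smaller than 1/2
    # still yields a positive statistic (|dev| - 1/2)^2, as the formula reads
    chi2 = (abs(dev) - corr) ** 2 / var
    return float(chi2), float(chi2_dist.sf(chi2, df=1))


def fdr_bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def read_gff3_genes(path: str | Path, feature_types: tuple[str, ...] = ("gene",)) -> pd.DataFrame:
    """Gene records (chrom, start, end, name) from a GFF3 file.

    Malformed intervals (start > end or non-numeric) are skipped; their
    count is attached as ``DataFrame.attrs["n_skipped"]``.
    """
    rows = []
    n_skipped = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] not in feature_types:
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                n_skipped += 1
                continue
            if start > end:
                n_skipped += 1
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID") or f"gene_{len(rows)}"
            rows.append((parts[0], start, end, name))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    df.attrs["n_skipped"] = n_skipped
    return df


def annotate_adjacent_genes(
    snps: list[tuple[str, int]], genes: pd.DataFrame, max_dist: int = 10_000
) -> list[list[tuple[str, int, int, int]]]:
    """Genes within ``max_dist`` bp of each SNP, sorted by distance.

    Distance is 0 for a SNP inside the gene interval (1-based inclusive),
    otherwise the gap to the nearer end.  Each entry is
    (name, start, end, distance).
    """
    by_chrom = {c: g for c, g in genes.groupby("chrom")}
    out = []
    for chrom, pos in snps:
        hits: list[tuple[str, int, int, int]] = []
        g = by_chrom.get(chrom)
        if g is not None:
            inside = (g["start"] <= pos) & (pos <= g["end"])
            dist = np.where(
                inside,
                0,
                np.minimum(np.abs(pos - g["start"]), np.abs(pos - g["end"])),
            )
            for (_, row), d in zip(g.iterrows(), dist):
                if d <= max_dist:
                    hits.append((row["name"], int(row["start"]), int(row["end"]), int(d)))
        hits.sort(key=lambda h: h[3])
        out.append(hits)
    return out


def run_gwas(
    panel: GenotypePanel,
    phenotype_column: str,
    case_label: str,
    strata_column: str = "site",
    continuity: bool = True,
    fdr_alpha: float = 0.05,
    genes: pd.DataFrame | None = None,
    gene_window: int = 10_000,
) -> pd.DataFrame:
    """End-to-end stratified association scan.

    Returns a per-SNP DataFrame (chrom, pos, ref, alt, chi2, p, p_fdr,
    significant, adjacent_genes, neg_log10_p).  SNPs whose CMH statistic is
    undefined carry NaN and are excluded from the FDR correction.
    """
    if panel.metadata is None:
        raise ValueError("panel has no sample metadata")
    pheno = panel.metadata.loc[panel.sample_ids, phenotype_column].to_numpy()
    strata = panel.metadata.loc[panel.sample_ids, strata_column].to_numpy()
    tables = build_tables(panel, pheno == case_label, strata)
    chi2s = np.empty(panel.n_variants)
    ps = np.empty(panel.n_variants)
    for j, tab in enumerate(tables):
        chi2s[j], ps[j] = cmh_test(tab, continuity=continuity)
    ok = ~np.isnan(ps)
    p_fdr = np.full_like(ps, np.nan)
    if ok.any():
        p_fdr[ok] = fdr_bh(ps[ok])
    res = panel.variants[["chrom", "pos", "ref", "alt"]].copy()
    res["chi2"] = chi2s
    res["p"] = ps
    res["p_fdr"] = p_fdr
    res["significant"] = p_fdr < fdr_alpha
    with np.errstate(divide="ignore"):
        res["neg_log10_p"] = -np.log10(ps)
    if genes is not None:
        gene_lists = [[] for _ in range(len(res))]
        sig_idx = np.flatnonzero(res["significant"].to_numpy())
        snps = [
            (res["chrom"].iat[i], int(res["pos"].iat[i])) for i in sig_idx
        ]
        for i, hits in zip(sig_idx, annotate_adjacent_genes(snps, genes, gene_window)):
            gene_lists[i] = hits
        res["adjacent_genes"] = gene_lists
    return res
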