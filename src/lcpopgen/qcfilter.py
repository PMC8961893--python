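"""Species-identification filtering and genotype/site-level panel QC.

Implements three layers of quality control used when genotyping mosquitoes
from extreme low-coverage sequencing:

* **BLAST hit screening** — each specimen's COI consensus is identified by
  its single best BLAST hit; a specimen is kept only when the hit is strong
  (e-value <= 1e-100, >= 200 identical positions, >= 90% identity) and the
  subject taxon matches the target species.

* **Genotype masking** — genotypes with read depth DP < 5 or genotype
  quality GQ < 20 are flagged as low-confidence candidates for imputation.

* **Site filters** — minor-allele-frequency, missing-data and within-stratum
  Hardy–Weinberg exact-test filters, with the three rule sets used for the
  pre-imputation, post-imputation and raw (never-imputed) panels.  Boundary
  semantics deliberately follow the strict inequalities of each rule set:
  pre-imputation removes MAF < 0.1 and MD > 0.5 (a site at exactly 0.1 / 0.5
  survives), whereas post-imputation keeps MAF > 0.1 and MD < 0.3 (a site at
  exactly 0.1 / 0.3 is removed).

The Hardy–Weinberg test is the conditional exact test (Wigginton-style
two-sided enumeration of heterozygote counts given the allele counts, no
mid-p); a chi-square variant is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist

from .panel import MISSING, GenotypePanel


@dataclass(frozen=True)
class BlastHit:
    """Best BLAST hit for one specimen."""

    query_id: str
    subject_taxon: str
    evalue: float
    identities: int
    identity_pct: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"{self.query_id}: negative e-value")
        if not 0 <= self.identity_pct <= 100:
            raise ValueError(f"{self.query_id}: identity% outside [0, 100]")
        if self.identities < 0:
            raise ValueError(f"{self.query_id}: negative identities")


@dataclass
class FilterConfig:
    """Thresholds for the site filters; defaults are the study values."""

    mode: Literal["pre_imputation", "post_imputation", "raw"] = "post_imputation"
    maf_min: float = 0.1
    md_max: float = 0.5  # pre-imputation bound; post uses 0.3, raw 0.8
    dp_min: int = 5
    gq_min: int = 20
    gp_min: float = 0.95
    hwe_alpha: float = 0.001
    min_nonmissing_per_stratum: int = 15
    hwe_method: Literal["exact", "chi2"] = "exact"

    @classmethod
    def for_mode(cls, mode: str) -> "FilterConfig":
        md = {"pre_imputation": 0.5, "post_imputation": 0.3, "raw": 0.8}[mode]
        return cls(mode=mode, md_max=md)


def filter_blast_hits(
    hits: list[BlastHit], target_taxon: str
) -> tuple[list[BlastHit], list[BlastHit]]:
    """Partition best hits into kept and discarded specimens.

    Kept iff e-value <= 1e-100 AND identities >= 200 AND identity >= 90%
    AND the subject taxon equals the target.
    """
    kept, discarded = [], []
    for h in hits:
        ok = (
            h.evalue <= 1e-100
            and h.identities >= 200
            and h.identity_pct >= 90.0
            and h.subject_taxon == target_taxon
        )
        (kept if ok else discarded).append(h)
    return kept, discarded


def read_blast_tabular(
    path,
    columns: tuple[str, ...] = (
        "query_id",
        "subject_taxon",
        "identity_pct",
        "identities",
        "evalue",
    ),
) -> list[BlastHit]:
    """Read outfmt-6-style BLAST tabular output (column mapping configurable).

    Only the listed columns are consumed; extra columns are ignored by
    position.  One row per specimen (the best hit) is expected.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(columns)]
    df.columns = list(columns)
    return [
        BlastHit(
            query_id=str(r.query_id),
            subject_taxon=str(r.subject_taxon),
            evalue=float(r.evalue),
            identities=int(r.identities),
            identity_pct=float(r.identity_pct),
        )
        for r in df.itertuples(index=False)
    ]


def mask_low_confidence(
    panel: GenotypePanel, dp_min: int = 5, gq_min: int = 20
) -> tuple[GenotypePanel, int]:
    """Flag genotypes with DP < dp_min or GQ < gq_min for imputation.

    Returns a panel copy carrying the mask and the number of genotypes
    flagged.  Calls are not altered here; imputation decides their fate.
    """
    out = panel.copy()
    mask = (out.dp < dp_min) | (out.gq < gq_min)
    out.mask = mask
    return out, int(mask.sum())


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided conditional exact Hardy–Weinberg test.

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one (no mid-p correction).  Monomorphic samples return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotype required")
    n_a = n_Aa + 2 * n_aa  # minor-allele count by convention below
    n_A = n_Aa + 2 * n_AA
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0
    # P(het = h | allele counts) ∝ n! / (nAA! nAa! naa!) * 2^h
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    logp = (
        hets * np.log(2.0)
        - gammaln(homr + 1)
        - gammaln(hets + 1)
        - gammaln(homc + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    p_obs = prob[hets == n_Aa][0]
    # tolerance guards against float ties in the enumeration
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def hwe_chi2_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-df chi-square Hardy–Weinberg test (no continuity correction)."""
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotype required")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if np.any(exp == 0):
        return 1.0
    stat = float(((obs - exp) ** 2 / exp).sum())
    return float(chi2_dist.sf(stat, df=1))


def _site_maf(panel: GenotypePanel) -> np.ndarray:
    freq = panel.alt_allele_freq()
    maf = np.minimum(freq, 1.0 - freq)
    return np.where(np.isnan(freq), 0.0, maf)  # all-missing -> MAF 0


def _stratum_hwe_pass(
    panel: GenotypePanel, alpha: float, method: str
) -> np.ndarray:
    """Sites passing the within-stratum HWE filter in every stratum."""
    test = hwe_exact_test if method == "exact" else hwe_chi2_test
    strata = panel.strata()
    ok = np.ones(panel.n_variants, dtype=bool)
    for s in pd.unique(strata):
        sub = panel.calls[strata == s]
        for j in range(panel.n_variants):
            col = sub[:, j]
            col = col[col != MISSING]
            if col.size == 0:
                continue
            counts = np.bincount(col, minlength=3)
            # filter removes sites with HWE p below alpha in any stratum
            if test(int(counts[0]), int(counts[1]), int(counts[2])) < alpha:
                ok[j] = False
    return ok


def site_filters(
    panel: GenotypePanel, config: FilterConfig
) -> tuple[GenotypePanel, dict[str, int]]:
    """Apply the mode's site-level filters; return the kept panel and
    per-rule removal counts.

    Each removed site is attributed to the first rule it fails, in the
    fixed order MAF, MD, per-stratum non-missing, HWE.
    """
    maf = _site_maf(panel)
    md = panel.missing.mean(axis=0)
    mode = config.mode

    if mode == "pre_imputation":
        fail_maf = maf < config.maf_min
        fail_md = md > config.md_max
        fail_strat = np.zeros_like(fail_maf)
        fail_hwe = np.zeros_like(fail_maf)
    elif mode == "post_imputation":
        fail_maf = ~(maf > config.maf_min)
        fail_md = ~(md < config.md_max)
        fail_strat = np.zeros(panel.n_variants, dtype=bool)
        fail_hwe = ~_stratum_hwe_pass(panel, config.hwe_alpha, config.hwe_method)
    elif mode == "raw":
        fail_maf = ~(maf > config.maf_min)
        fail_md = ~(md < config.md_max)
        strata = panel.strata()
        nonmiss = ~panel.missing
        fail_strat = np.zeros(panel.n_variants, dtype=bool)
        for s in pd.unique(strata):
            n_ok = nonmiss[strata == s].sum(axis=0)
            fail_strat |= n_ok < config.min_nonmissing_per_stratum
        fail_hwe = ~_stratum_hwe_pass(panel, config.hwe_alpha, config.hwe_method)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    counts = {
        "maf": int(fail_maf.sum()),
        "md": int((fail_md & ~fail_maf).sum()),
        "stratum_nonmissing": int((fail_strat & ~fail_maf & ~fail_md).sum()),
        "hwe": int((fail_hwe & ~fail_maf & ~fail_md & ~fail_strat).sum()),
    }
    keep = ~(fail_maf | fail_md | fail_strat | fail_hwe)
    counts["kept"] = int(keep.sum())
    return panel.take_variants(keep), counts


def genotyping_rate(panel: GenotypePanel) -> float:
    """Fraction of non-missing genotype calls over samples x variants."""
    if panel.n_samples == 0 or panel.n_variants == 0:
        raise ValueError("empty panel")
    return float(1.0 - panel.missing.mean())


def sample_accounting(
    captured: dict[str, int], discarded: dict[str, int]
) -> tuple[dict[str, int], int]:
    """Retained sample counts per origin and overall total."""
    retained = {}
    for origin, n_cap in captured.items():
        n_disc = discarded.get(origin, 0)
        if n_disc > n_cap:
            raise ValueError(f"{origin}: discarded {n_disc} exceeds captured {n_cap}")
        retained[origin] = n_cap - n_disc
    return retained, sum(retained.values())
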