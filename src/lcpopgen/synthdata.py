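"""Synthetic stratified low-coverage genotype panels with a truth sidecar.

Emulates, at the statistical level, the inputs of a microgeographic
population study of *Nyssorhynchus darlingi*: K collection-site
subpopulations whose allele frequencies diverge under the Balding–Nichols
model, Hardy–Weinberg genotypes within each subpopulation, and shallow
Poisson-distributed read depth from which phred genotype likelihoods (PL),
depth (DP) and genotype quality (GQ) are derived exactly as a genotype-
likelihood caller would.  Two binary behavioral phenotypes are attached per
sample (indoor/outdoor capture location and dusk/dawn capture window); a
configurable number of causal SNPs receive a within-stratum case/control
allele-frequency shift so that downstream stratified association tests have
planted signal to find.

The Balding–Nichols model draws subpopulation frequency p_i for a SNP with
ancestral frequency p from

    p_i ~ Beta( p (1-F)/F,  (1-p)(1-F)/F )

which has mean p and variance F p (1-p); F is therefore the expected
fixation index between the subpopulations and the ancestral pool, directly
matching the magnitude of differentiation being emulated (on the order of
0.001 for houses 2-3 km apart, 0.04 for populations hundreds of km apart).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel, write_metadata, write_vcf

SITE_NAMES = "ABCDEFGH"


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults describe the emulated field study: three microgeographic
    collection sites, shallow mean depth of 3 reads per genotype, Illumina-like
    base error, and a handful of planted behavioral-association SNPs.
    """

    #: number of collection-site subpopulations and their sample sizes
    n_subpops: int = 3
    samples_per_subpop: tuple[int, ...] = (60, 60, 60)
    n_snps: int = 1000
    divergence_F: float = 0.002
    ancestral_maf_range: tuple[float, float] = (0.1, 0.5)
    mean_depth: float = 3.0
    depth_dispersion: float = 0.5
    base_error: float = 0.001
    n_causal: int = 0
    causal_effect: float = 0.2
    phenotype_balance: float = 0.5
    n_scaffolds: int = 25
    scaffold_length: int = 50_000
    ld_decay_rate: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subpops < 1 or self.n_snps < 1:
            raise ValueError("n_subpops and n_snps must be >= 1")
        if len(self.samples_per_subpop) != self.n_subpops:
            raise ValueError("samples_per_subpop length must equal n_subpops")
        if any(n < 1 for n in self.samples_per_subpop):
            raise ValueError("each subpopulation needs >= 1 sample")
        if not 0.0 <= self.divergence_F < 1.0:
            raise ValueError("divergence_F must be in [0, 1)")
        if not 0.0 < self.base_error < 0.5:
            raise ValueError("base_error must be in (0, 0.5)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be non-negative")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must lie within (0, 0.5]")
        if self.n_causal < 0 or self.n_causal > self.n_snps:
            raise ValueError("n_causal must be in [0, n_snps]")
        if self.n_subpops > len(SITE_NAMES):
            raise ValueError(f"at most {len(SITE_NAMES)} subpopulations supported")


@dataclass
class TruthSet:
    """Ground truth accompanying a simulated panel."""

    ancestral_freqs: np.ndarray
    subpop_freqs: np.ndarray  # (n_subpops, n_snps)
    true_genotypes: np.ndarray  # (n_samples, n_snps) dosages
    causal_snps: dict[str, np.ndarray]  # phenotype name -> SNP indices
    phenotypes: pd.DataFrame  # per-sample binary labels per dichotomy


def draw_subpop_frequencies(
    ancestral_freqs: np.ndarray,
    F: float,
    n_subpops: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw per-subpopulation allele frequencies under Balding–Nichols.

    For ``F = 0`` the Beta degenerates to a point mass and each subpopulation
    frequency equals the ancestral frequency exactly.
    """
    p = np.asarray(ancestral_freqs, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("ancestral frequencies must lie in (0, 1)")
    if not 0.0 <= F < 1.0:
        raise ValueError("F must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if F == 0.0:
        return np.tile(p, (n_subpops, 1))
    scale = (1.0 - F) / F
    return rng.beta(p * scale, (1.0 - p) * scale, size=(n_subpops, p.size))


def _phred_likelihoods(
    n_alt: np.ndarray, depth: np.ndarray, eps: float
) -> np.ndarray:
    """Phred-scaled normalized genotype log-likelihoods (…, 3).

    Per-read alt probability is eps / 0.5 / 1-eps for dosages 0/1/2; the
    likelihood of a (ref, alt) read-count pair is binomial up to a constant
    that cancels in the normalization.
    """
    n_ref = depth - n_alt
    with np.errstate(divide="ignore"):
        l0 = n_alt * np.log10(eps) + n_ref * np.log10(1.0 - eps)
        l1 = depth * np.log10(0.5)
        l2 = n_alt * np.log10(1.0 - eps) + n_ref * np.log10(eps)
    ll = np.stack([l0, l1, l2], axis=-1)
    pl = -10.0 * (ll - ll.max(axis=-1, keepdims=True))
    return np.rint(np.minimum(pl, 10_000.0)).astype(np.int32)


def _simulate_genotype_fields(
    true_geno: np.ndarray,
    mean_depth: float | np.ndarray,
    eps: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Reads, likelihoods and calls for a matrix of true genotypes.

    ``mean_depth`` may be a scalar or a per-site vector of Poisson rates.
    """
    depth = rng.poisson(
        np.broadcast_to(np.asarray(mean_depth, dtype=float), true_geno.shape),
    ).astype(np.int32)
    p_alt = np.choose(true_geno, [eps, 0.5, 1.0 - eps])
    n_alt = rng.binomial(depth, p_alt).astype(np.int32)
    pl = _phred_likelihoods(n_alt, depth, eps)
    calls = np.argmin(pl, axis=-1).astype(np.int8)
    calls[depth == 0] = MISSING  # no reads: no call
    part = np.partition(pl, 1, axis=-1)
    gq = (part[..., 1] - part[..., 0]).astype(np.int32)
    gq[depth == 0] = 0
    return calls, depth, gq, pl


def _place_variants(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Uniform random SNP positions on synthetic scaffolds, sorted."""
    scaf = rng.integers(0, cfg.n_scaffolds, size=cfg.n_snps)
    pos = rng.integers(1, cfg.scaffold_length + 1, size=cfg.n_snps)
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=cfg.n_snps)
    alt = (ref + rng.integers(1, 4, size=cfg.n_snps)) % 4
    df = pd.DataFrame(
        {
            "chrom": [f"scaffold_{s:04d}" for s in scaf],
            "pos": pos,
            "ref": bases[ref],
            "alt": bases[alt],
        }
    )
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    # collisions at identical positions are harmless for every downstream
    # statistic except distance binning; nudge duplicates apart
    dup = df.duplicated(["chrom", "pos"])
    while dup.any():
        df.loc[dup, "pos"] += 1
        dup = df.duplicated(["chrom", "pos"])
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def _haplotypes_with_ld(
    freqs: np.ndarray,
    variants: pd.DataFrame,
    n_hap: int,
    rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """First-order copying process along each scaffold.

    A haplotype copies its allele state from the previous SNP with
    probability exp(-rate * distance_bp), producing r² that decays
    approximately exponentially with distance; otherwise it draws fresh from
    the site frequency.  ``freqs`` is (n_snps,) for one subpopulation.
    """
    n_snps = len(freqs)
    hap = np.empty((n_hap, n_snps), dtype=np.int8)
    chrom = variants["chrom"].to_numpy()
    pos = variants["pos"].to_numpy()
    fresh = (rng.random((n_hap, n_snps)) < freqs[None, :]).astype(np.int8)
    hap[:, 0] = fresh[:, 0]
    for j in range(1, n_snps):
        if chrom[j] != chrom[j - 1]:
            hap[:, j] = fresh[:, j]
            continue
        p_copy = np.exp(-rate * (pos[j] - pos[j - 1]))
        copy = rng.random(n_hap) < p_copy
        hap[:, j] = np.where(copy, hap[:, j - 1], fresh[:, j])
    return hap


def simulate_panel(cfg: SimulationConfig) -> tuple[GenotypePanel, TruthSet]:
    """Simulate a low-coverage genotype panel and its truth sidecar.

    Genotypes are Hardy–Weinberg draws from Balding–Nichols subpopulation
    frequencies; reads, PL, GQ, DP and the likelihood-maximizing call are
    layered on top.  Causal SNPs are planted for the indoor/outdoor
    dichotomy by shifting the alt-allele frequency by ``±causal_effect/2``
    between cases and controls within every stratum.
    """
    rng = np.random.default_rng(cfg.seed)
    n_total = int(sum(cfg.samples_per_subpop))

    lo, hi = cfg.ancestral_maf_range
    anc = rng.uniform(lo, hi, size=cfg.n_snps)
    variants = _place_variants(cfg, rng)
    subpop_freqs = draw_subpop_frequencies(anc, cfg.divergence_F, cfg.n_subpops, rng)

    sites = np.repeat(
        [SITE_NAMES[k] for k in range(cfg.n_subpops)], cfg.samples_per_subpop
    )
    sample_ids = [f"S{i:04d}" for i in range(n_total)]

    # two behavioral dichotomies, balanced within each stratum
    pheno = {}
    for name, labels in (("location", ("indoor", "outdoor")),
                         ("window", ("dusk", "dawn"))):
        lab = np.empty(n_total, dtype=object)
        for k in range(cfg.n_subpops):
            idx = np.flatnonzero(sites == SITE_NAMES[k])
            n_case = int(round(cfg.phenotype_balance * idx.size))
            perm = rng.permutation(idx)
            lab[perm[:n_case]] = labels[0]
            lab[perm[n_case:]] = labels[1]
        pheno[name] = lab
    phenotypes = pd.DataFrame(pheno, index=sample_ids)
    is_case = phenotypes["location"].to_numpy() == "indoor"

    causal = rng.choice(cfg.n_snps, size=cfg.n_causal, replace=False)
    causal.sort()

    # per-sample per-SNP sampling frequency, with the causal shift applied
    # within stratum between phenotype groups
    sample_freqs = subpop_freqs[
        np.repeat(np.arange(cfg.n_subpops), cfg.samples_per_subpop)
    ].copy()
    if cfg.n_causal:
        shift = cfg.causal_effect / 2.0
        sample_freqs[np.ix_(is_case, causal)] += shift
        sample_freqs[np.ix_(~is_case, causal)] -= shift
        np.clip(sample_freqs, 0.01, 0.99, out=sample_freqs)

    if cfg.ld_decay_rate is not None:
        # haplotype copying needs per-subpop frequency tracks; phenotype
        # shifts are not combined with LD mode (LD mode exists to exercise
        # decay-curve estimation, not association)
        hap_a = np.empty((n_total, cfg.n_snps), dtype=np.int8)
        hap_b = np.empty((n_total, cfg.n_snps), dtype=np.int8)
        start = 0
        for k, n_k in enumerate(cfg.samples_per_subpop):
            sl = slice(start, start + n_k)
            hap_a[sl] = _haplotypes_with_ld(
                subpop_freqs[k], variants, n_k, cfg.ld_decay_rate, rng
            )
            hap_b[sl] = _haplotypes_with_ld(
                subpop_freqs[k], variants, n_k, cfg.ld_decay_rate, rng
            )
            start += n_k
        true_geno = (hap_a + hap_b).astype(np.int8)
    else:
        true_geno = rng.binomial(2, sample_freqs).astype(np.int8)

    # per-site coverage multiplier emulating mappability/copy-number driven
    # depth heterogeneity; lognormal with mean 1 so mean_depth is preserved
    site_rates = np.full(cfg.n_snps, cfg.mean_depth)
    if cfg.depth_dispersion > 0:
        sigma = cfg.depth_dispersion
        site_rates = cfg.mean_depth * rng.lognormal(
            -(sigma**2) / 2.0, sigma, size=cfg.n_snps
        )
    calls, depth, gq, pl = _simulate_genotype_fields(
        true_geno, site_rates, cfg.base_error, rng
    )

    metadata = pd.DataFrame(
        {
            "site": sites,
            "stage": np.where(sites == "D", "larva", "adult"),
            "location": phenotypes["location"].to_numpy(),
            "window": phenotypes["window"].to_numpy(),
        },
        index=pd.Index(sample_ids, name="sample"),
    )

    panel = GenotypePanel(
        sample_ids=sample_ids,
        variants=variants,
        calls=calls,
        dp=depth,
        gq=gq,
        pl=pl,
        metadata=metadata,
    )
    truth = TruthSet(
        ancestral_freqs=anc,
        subpop_freqs=subpop_freqs,
        true_genotypes=true_geno,
        causal_snps={"location": causal, "window": np.array([], dtype=int)},
        phenotypes=phenotypes,
    )
    return panel, truth


def write_truth(truth: TruthSet, panel: GenotypePanel, path: str | Path) -> None:
    """Truth sidecar TSV: one row per SNP with subpop freqs and causal flag."""
    df = panel.variants[["chrom", "pos"]].copy()
    for k in range(truth.subpop_freqs.shape[0]):
        df[f"freq_{SITE_NAMES[k]}"] = truth.subpop_freqs[k]
    causal_flag = np.zeros(len(df), dtype=int)
    causal_flag[truth.causal_snps["location"]] = 1
    df["causal"] = causal_flag
    df.to_csv(path, sep="\t", index=False)


def simulate_to_files(cfg: SimulationConfig, prefix: str | Path) -> GenotypePanel:
    """Simulate and write <prefix>.vcf, <prefix>.samples.tsv, <prefix>.truth.tsv."""
    prefix = Path(prefix)
    panel, truth = simulate_panel(cfg)
    write_vcf(panel, prefix.with_suffix(".vcf"))
    write_metadata(panel.metadata, f"{prefix}.samples.tsv")
    write_truth(truth, panel, f"{prefix}.truth.tsv")
    return panel
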