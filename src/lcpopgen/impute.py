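"""Frequency-prior EM genotype refinement and the GP >= 0.95 gate.

Low-confidence genotypes (flagged by :func:`lcpopgen.qcfilter.mask_low_confidence`)
are refined site-by-site: an EM iteration estimates the maximum-likelihood
alternative-allele frequency from every sample's genotype likelihoods, a
Hardy–Weinberg prior built from that frequency is combined with each
sample's likelihoods into a genotype posterior (GP), and a flagged genotype
is replaced by its posterior-maximizing dosage only when that posterior
reaches the acceptance gate (default GP >= 0.95) — otherwise it becomes
missing.  Unflagged genotypes keep their original calls.

The refiner treats sites independently (no haplotype model).  Panels imputed
externally by a haplotype-aware tool can be ingested instead: a VCF that
already carries GP bypasses the EM entirely and flows through the same gate.
"""

from __future__ import annotations

import numpy as np

from .panel import MISSING, GenotypePanel

_EM_TOL = 1e-8
_EM_MAX_ITER = 100


def _likelihoods_from_pl(pls: np.ndarray) -> np.ndarray:
    """Genotype likelihoods 10^(-PL/10), shape (..., 3)."""
    return np.power(10.0, -np.asarray(pls, dtype=float) / 10.0)


def em_site_frequency(
    pls: np.ndarray, init: float | None = None
) -> tuple[float, bool]:
    """Maximum-likelihood alt-allele frequency at one site by EM.

    Parameters
    ----------
    pls : (n_samples, 3) phred likelihood triples in ref-hom/het/alt-hom order.
    init : starting frequency; defaults to the likelihood-best-genotype
        frequency, falling back to 0.5 when uninformative.

    Returns
    -------
    (frequency, flat_warning) — ``flat_warning`` is True when every sample's
    likelihood triple is flat, in which case 0.5 is returned.
    """
    lik = _likelihoods_from_pl(pls)
    if lik.ndim != 2 or lik.shape[1] != 3 or lik.shape[0] < 1:
        raise ValueError("pls must be a non-empty (n_samples, 3) array")
    informative = ~np.all(lik == lik[:, :1], axis=1)
    if not informative.any():
        return 0.5, True

    if init is None:
        best = np.argmax(lik, axis=1)
        init = float(best[informative].mean() / 2.0)
        init = min(max(init, 1e-6), 1 - 1e-6)

    q = init  # alt-allele frequency
    for _ in range(_EM_MAX_ITER):
        p = 1.0 - q
        prior = np.array([p * p, 2 * p * q, q * q])
        post = lik * prior
        post /= post.sum(axis=1, keepdims=True)
        q_new = float(post[:, 1].sum() * 0.5 + post[:, 2].sum()) / lik.shape[0]
        if abs(q_new - q) < _EM_TOL:
            q = q_new
            break
        q = q_new
    return q, False


def genotype_posteriors(pls: np.ndarray, freq: float) -> np.ndarray:
    """Posterior genotype probabilities from PL and a Hardy–Weinberg prior.

    ``freq`` is the alternative-allele frequency; the prior over
    (ref-hom, het, alt-hom) is ((1-q)^2, 2q(1-q), q^2).  Accepts a single
    triple or an array of triples; the result is normalized to sum to 1.
    """
    if not 0.0 <= freq <= 1.0:
        raise ValueError("freq must be in [0, 1]")
    lik = _likelihoods_from_pl(pls)
    q = freq
    p = 1.0 - q
    prior = np.array([p * p, 2 * p * q, q * q])
    post = lik * prior
    total = post.sum(axis=-1, keepdims=True)
    # degenerate prior (freq 0 or 1) can zero out the whole product when the
    # likelihood is zero on the supported genotype; resolve to the prior
    flat = total.squeeze(-1) == 0
    if np.any(flat):
        post = np.where(flat[..., None], prior, post)
        total = post.sum(axis=-1, keepdims=True)
    return post / total


def apply_imputation(
    panel: GenotypePanel, gp_min: float = 0.95
) -> tuple[GenotypePanel, dict[str, int]]:
    """Refine flagged genotypes and apply the GP acceptance gate.

    Requires ``panel.mask`` (from :func:`qcfilter.mask_low_confidence`).  If
    the panel already carries GP (externally imputed), those posteriors are
    used unchanged; otherwise GP is computed by the per-site EM refiner.
    Flagged genotypes become the posterior-argmax dosage when max GP >=
    ``gp_min`` and missing otherwise; unflagged genotypes are untouched.

    Returns the refined panel and counts
    ``{"imputed": ..., "set_missing": ...}``.
    """
    if panel.mask is None:
        raise ValueError("panel has no low-confidence mask; run mask_low_confidence")
    if not 0.0 < gp_min <= 1.0:
        raise ValueError("gp_min must be in (0, 1]")
    out = panel.copy()

    if out.gp is None:
        gp = np.empty(out.pl.shape, dtype=float)
        for j in range(out.n_variants):
            freq, _ = em_site_frequency(out.pl[:, j])
            gp[:, j] = genotype_posteriors(out.pl[:, j], freq)
        out.gp = gp

    best = np.argmax(out.gp, axis=2).astype(np.int8)
    best_p = np.take_along_axis(out.gp, best[..., None].astype(int), axis=2)[..., 0]
    accept = out.mask & (best_p >= gp_min)
    reject = out.mask & ~accept
    out.calls = np.where(accept, best, out.calls).astype(np.int8)
    out.calls[reject] = MISSING
    out.mask = np.zeros_like(out.mask)
    return out, {"imputed": int(accept.sum()), "set_missing": int(reject.sum())}
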