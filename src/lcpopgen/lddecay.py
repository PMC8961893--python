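"""Linkage-disequilibrium decay profiling, curve fitting and marker pruning.

Pairwise r² (squared Pearson correlation of genotype dosages) is averaged in
500-bp distance bins over 20 kb (40 bins) and the decay of the bin means
with physical distance x is modelled as

    Y_hat = beta0 + beta1 * 1/ln(x)

which is linear in the transformed predictor 1/ln(x) and is fitted by
ordinary least squares.  The distance at which the fitted (or its lower 95%
confidence) curve crosses a target r² — the point where markers become
effectively independent — determines the window used for LD pruning: a
greedy left-to-right scan that drops any SNP whose r² with an already
retained SNP within the window exceeds a threshold (default 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq

from .panel import MISSING, GenotypePanel

DEFAULT_BIN_WIDTH = 500
DEFAULT_N_BINS = 40


@dataclass
class LDProfile:
    """Mean r² per physical-distance bin."""

    bin_midpoints: np.ndarray  # bp
    mean_r2: np.ndarray  # nan where bin empty
    se_r2: np.ndarray
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(1, len(self.bin_midpoints) + 1),
                "midpoint_bp": self.bin_midpoints,
                "mean_r2": self.mean_r2,
                "se_r2": self.se_r2,
                "n_pairs": self.n_pairs,
            }
        )


@dataclass
class LDDecayFit:
    """OLS fit of mean r² on 1/ln(distance)."""

    beta0: float
    beta1: float
    r_squared: float
    residual_se: float
    bin_midpoints: np.ndarray
    lower_band: np.ndarray  # pointwise lower 95% CI of the mean response
    cov_params: np.ndarray  # 2x2 covariance of (beta0, beta1)
    df_resid: float
    t_crit: float

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.beta0 + self.beta1 / np.log(x)

    def lower_curve(self, x: np.ndarray | float) -> np.ndarray | float:
        """Lower 95% confidence curve for the mean response at distance x."""
        z = 1.0 / np.log(x)
        design = np.stack([np.ones_like(np.atleast_1d(z)), np.atleast_1d(z)], axis=1)
        var = np.einsum("ij,jk,ik->i", design, self.cov_params, design)
        se = np.sqrt(var)
        out = self.predict(np.atleast_1d(x)) - self.t_crit * se
        return out if np.ndim(x) else float(out[0])


def pairwise_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over complete pairs.

    Returns ``nan`` when fewer than two complete pairs remain or either
    vector is constant on the complete-pair subset.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    ok = (a != MISSING) & (b != MISSING) & ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _pairwise_r2_matrix(calls: np.ndarray) -> np.ndarray:
    """All-pairs r² for a (n_samples, n_snps) dosage block.

    Complete blocks go through a single correlation-matrix call; blocks with
    missing calls fall back to exact pairwise-complete computation.
    """
    n_snps = calls.shape[1]
    if not np.any(calls == MISSING):
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(calls.astype(float), rowvar=False)
        return r**2
    out = np.full((n_snps, n_snps), np.nan)
    for i in range(n_snps - 1):
        for j in range(i + 1, n_snps):
            out[i, j] = out[j, i] = pairwise_r2(calls[:, i], calls[:, j])
    return out


def bin_ld_by_distance(
    panel: GenotypePanel,
    bin_width: int = DEFAULT_BIN_WIDTH,
    n_bins: int = DEFAULT_N_BINS,
) -> LDProfile:
    """Average pairwise r² in half-open distance bins ((b-1)w, bw].

    Every intra-scaffold pair at distance <= n_bins*bin_width contributes to
    the bin containing its distance; cross-scaffold pairs are excluded, as
    are pairs whose r² is undefined (constant dosage vector).
    """
    max_dist = bin_width * n_bins
    sums = np.zeros(n_bins)
    sqsums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)

    chroms = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy()
    order = np.lexsort((pos, chroms))
    for chrom in pd.unique(chroms):
        idx = order[chroms[order] == chrom]
        if idx.size < 2:
            continue
        p = pos[idx]
        r2 = _pairwise_r2_matrix(panel.calls[:, idx])
        for i in range(idx.size - 1):
            for j in range(i + 1, idx.size):
                d = p[j] - p[i]
                if d > max_dist:
                    break
                if d <= 0:
                    continue
                v = r2[i, j]
                if np.isnan(v):
                    continue
                b = int(np.ceil(d / bin_width)) - 1
                sums[b] += v
                sqsums[b] += v * v
                counts[b] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = np.where(
            counts > 1,
            (sqsums - counts * mean**2) / np.maximum(counts - 1, 1),
            np.nan,
        )
        se = np.sqrt(np.maximum(var, 0.0) / np.maximum(counts, 1))
    midpoints = bin_width * (np.arange(1, n_bins + 1) - 0.5)
    return LDProfile(
        bin_midpoints=midpoints, mean_r2=mean, se_r2=se, n_pairs=counts
    )


def fit_decay(profile: LDProfile, conf_level: float = 0.95) -> LDDecayFit:
    """OLS fit of the decay model to the binned means.

    Bins with undefined means are dropped; at least three defined bins are
    required.  The lower confidence band is the pointwise lower bound of the
    mean-response CI from the linear fit in the transformed predictor.
    """
    ok = ~np.isnan(profile.mean_r2)
    if ok.sum() < 3:
        raise ValueError("need at least 3 bins with defined mean r2")
    x = profile.bin_midpoints[ok]
    y = profile.mean_r2[ok]
    z = 1.0 / np.log(x)
    if np.ptp(z) == 0:
        raise ValueError("all bin midpoints equal; fit is singular")
    design = sm.add_constant(z)
    res = sm.OLS(y, design).fit()
    pred = res.get_prediction(
        sm.add_constant(1.0 / np.log(profile.bin_midpoints))
    )
    lower = pred.conf_int(alpha=1 - conf_level)[:, 0]
    from scipy.stats import t as t_dist

    with np.errstate(invalid="ignore"):
        rsq = float(res.rsquared)
    if not np.isfinite(rsq):  # zero-variance response: constant fitted exactly
        rsq = 1.0 if res.ssr < 1e-24 else 0.0
    return LDDecayFit(
        beta0=float(res.params[0]),
        beta1=float(res.params[1]),
        r_squared=rsq,
        residual_se=float(np.sqrt(res.mse_resid)),
        bin_midpoints=profile.bin_midpoints.copy(),
        lower_band=lower,
        cov_params=np.asarray(res.cov_params()),
        df_resid=float(res.df_resid),
        t_crit=float(t_dist.ppf(0.5 + conf_level / 2.0, res.df_resid)),
    )


def solve_crossing(
    fit: LDDecayFit, threshold: float = 0.1, use_lower_band: bool = False
) -> float:
    """Distance (bp) at which the decay curve crosses ``threshold``.

    Point-estimate mode inverts the model in closed form,
    x* = exp(beta1 / (threshold - beta0)); lower-band mode root-finds the
    crossing of the pointwise lower confidence curve.  The threshold must
    exceed the asymptote beta0.
    """
    if threshold <= fit.beta0:
        raise ValueError(
            f"threshold {threshold} is at or below the asymptote beta0={fit.beta0}"
        )
    point = float(np.exp(fit.beta1 / (threshold - fit.beta0)))
    if not use_lower_band:
        return point
    f = lambda x: fit.lower_curve(x) - threshold
    # the band sits below the point curve, so its crossing is at or left of x*
    lo, hi = 1.0 + 1e-9, point
    if f(hi) > 0:  # band still above threshold at the point crossing
        while f(hi) > 0 and hi < point * 1e6:
            hi *= 2.0
    if f(lo) <= 0:
        raise ValueError("lower band is below the threshold everywhere")
    return float(brentq(f, lo, hi))


def prune(
    panel: GenotypePanel, window: int = 14_000, r2_max: float = 0.1
) -> np.ndarray:
    """Greedy left-to-right LD pruning.

    Scanning each scaffold in position order, a SNP is removed when its r²
    with any already-retained SNP within ``window`` bp upstream exceeds
    ``r2_max``; undefined r² (constant dosages) never triggers removal.
    Returns the integer indices (into ``panel.variants``) of retained SNPs,
    in position order per scaffold.
    """
    if window <= 0 or not 0.0 < r2_max <= 1.0:
        raise ValueError("window must be positive and r2_max in (0, 1]")
    chroms = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy()
    order = np.lexsort((pos, chroms))
    retained: list[int] = []
    for chrom in pd.unique(chroms):
        idx = order[chroms[order] == chrom]
        kept_here: list[int] = []
        for i in idx:
            drop = False
            for k in reversed(kept_here):
                if pos[i] - pos[k] > window:
                    break
                r2 = pairwise_r2(panel.calls[:, k], panel.calls[:, i])
                if not np.isnan(r2) and r2 > r2_max:
                    drop = True
                    break
            if not drop:
                kept_here.append(int(i))
        retained.extend(kept_here)
    return np.array(retained, dtype=int)
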