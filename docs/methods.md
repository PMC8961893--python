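# Methods

This note documents the models, estimators and numerical choices behind
`lcpopgen`, and what the synthetic-data generator does and does not
emulate.

## Synthetic low-coverage panels

### Population model

Subpopulation allele frequencies follow the **Balding–Nichols model**: for
a SNP with ancestral frequency p and divergence parameter F ∈ [0, 1), each
subpopulation draws

p_i ~ Beta( p(1−F)/F , (1−p)(1−F)/F ),

with mean p and variance F·p(1−p).  F is therefore the expected fixation
index between a subpopulation and the ancestral pool.  Defaults emulate a
three-site microgeographic study: `divergence_F = 0.002` (sites a few km
apart); long-range comparisons use `F = 0.04`.  Ancestral frequencies are
uniform on (0.1, 0.5) — panels are conditioned on common variants, as
low-coverage genotyping of rare alleles is unreliable and real pipelines
filter on MAF anyway.  Genotypes are Hardy–Weinberg draws within each
subpopulation, so within-stratum HWE holds by construction and the
Wahlund-effect filter has a clean null.

### Sequencing model

Per-genotype read depth is Poisson with rate λ = `mean_depth` × a per-site
lognormal multiplier (σ = `depth_dispersion`, mean 1).  The default
λ = 3 represents the extreme low-coverage regime; the dispersion
(default 0.5) emulates mappability- and copy-number-driven coverage
heterogeneity between sites, without which every site in a panel has
essentially the same missingness and the raw-panel MD filter becomes
all-or-nothing — real panels retain their high-coverage tail.  Reads carry
a symmetric base error ε (default 0.001); allele counts at a genotype are
binomial with alt-read probability ε, ½, 1−ε for dosages 0/1/2.  From the
read counts we compute phred-scaled genotype likelihoods, normalize to a
minimum PL of 0, call the likelihood-maximizing genotype, set DP to the
read total and GQ to the gap between the two smallest PL entries.
Zero-depth genotypes are emitted as missing with flat PL.

### Phenotypes and planted effects

Each sample carries two binary behavioral labels (indoor/outdoor capture
location; dusk/dawn capture window), balanced within each stratum
(`phenotype_balance`, default 0.5).  `n_causal` SNPs are planted for the
indoor/outdoor dichotomy by shifting the alt-allele sampling frequency by
±`causal_effect`/2 between cases and controls *within every stratum*
(clipped to [0.01, 0.99]) — an allele-frequency displacement is exactly the
alternative the allelic CMH test is powered against.  The dusk/dawn labels
never receive planted effects and serve as a permanent negative control.

### Linkage disequilibrium mode

By default SNPs are independent given subpopulation frequencies (clean
null for pruning and association).  With `ld_decay_rate` set, haplotypes
are built by a first-order copying process along each scaffold: the allele
at a SNP copies the previous SNP's allele with probability
exp(−rate·distance) and is drawn fresh otherwise, producing r² that decays
approximately exponentially with distance.  This exercises the decay-curve
machinery; it is not a coalescent and makes no claim about haplotype block
realism.

### What the generator does not emulate

Read-level artifacts (duplicates, indels, reference bias), rare variants,
demographic history, isolation by distance, kinship, and genuine
haplotype-scale LD.  Tests passing on these panels demonstrate the
correctness and calibration of the statistics, not their behavior under
every pathology of real sequencing data.

## QC filters

Boundary semantics follow each rule set's strict inequalities literally:

* **pre-imputation**: remove MAF < 0.1 or MD > 0.5 (a site at exactly
  MAF 0.1 or MD 0.5 survives);
* **post-imputation**: keep MAF > 0.1, MD < 0.3 and within-stratum HWE
  exact p ≥ 0.001 in every stratum (a site at exactly MAF 0.1 is removed);
* **raw**: keep MAF > 0.1, MD < 0.8, ≥ 15 non-missing genotypes in every
  stratum, and the same HWE rule.

The asymmetry between pre- and post-imputation at MAF = 0.1 is
deliberate: both rule sets are applied exactly as specified for their
stage.  Removed sites are attributed to the first failed rule in the fixed
order MAF → MD → per-stratum non-missing → HWE, so per-rule counts sum to
total removals and reports are deterministic.  MAF is min(p̂, 1−p̂) of the
alt-allele frequency over non-missing calls; an all-missing or monomorphic
site has MAF 0 and is removed under the MAF rule.  Multi-allelic VCF
records are dropped on read with a count — every statistic here is
defined for biallelic sites.

The Hardy–Weinberg test is the **conditional exact test**: enumeration of
all heterozygote counts compatible with the observed allele counts, with
P(h) ∝ 2^h / (n_homR! · h! · n_homC!), summing configurations no more
probable than the observed one.  No mid-p correction.  Computed in log
space with a 1+1e−12 relative tolerance on probability ties; it matches an
exact-rational enumeration to 1e−12 for n ≤ 100.  A chi-square variant is
available (`hwe_method="chi2"`).

## Genotype refinement and the GP gate

Genotypes flagged DP < 5 or GQ < 20 are candidates for imputation.  The
internal refiner is deliberately **site-independent**: per site, an EM
iteration finds the maximum-likelihood alt-allele frequency q under
Hardy–Weinberg from all samples' genotype likelihoods 10^(−PL/10)
(initialized at the best-genotype frequency, converged at |Δq| < 1e−8 or
100 iterations), and each sample's posterior is its likelihood triple
times the prior ((1−q)², 2q(1−q), q²), normalized.  A flagged genotype is
replaced by the posterior-argmax dosage when max GP ≥ 0.95 and set missing
otherwise; genotypes failing the gate count as missing in downstream MD
filters.  This recovers far less information than a haplotype-aware
imputer — that is expected and documented, not a defect; panels imputed
externally can be ingested through the same gate via their VCF GP field.
Flat-likelihood sites return q = 0.5 with a warning flag.  At a degenerate
prior (q = 0 or 1) the prior dominates regardless of likelihood, which is
the correct limit of the model.

## LD decay and pruning

Pairwise r² is the squared Pearson correlation of dosage vectors over
pairwise-complete samples; pairs with a constant vector are undefined and
excluded.  Distances bin half-open, (b−1)·500 < d ≤ b·500, over 40 bins
(20 kb); cross-scaffold pairs are excluded.  The decay model
Ŷ = β₀ + β₁/ln(x) uses the **natural logarithm**: with the reference
coefficient magnitudes (β₀ ≈ −0.40, β₁ ≈ 4.76) a base-10 logarithm would
put the r² = 0.1 crossing near 10^9.5 bp, while natural log gives
~13.6 kb, consistent with the 14-kb window such analyses adopt.  The fit
is OLS in the transformed predictor z = 1/ln(x); the lower confidence
curve is the pointwise 95% CI of the mean response,
Ŷ(x) − t₀.₉₇₅,df · se(x) with se from the coefficient covariance, and
lower-band crossings are found by Brent root-finding (the point-estimate
crossing has the closed form x* = exp(β₁/(r²* − β₀))).  R² of a
zero-variance (flat) profile is reported as 1 when the constant fits
exactly.

Pruning is the windowed greedy rule: scanning each scaffold
left-to-right, a SNP is dropped if its r² with any already-retained SNP
within the window (default 14 kb) exceeds the threshold (default 0.1,
taken from the "mean r² between 0.1 and 0.05" window-selection
criterion).  Deterministic given input order; undefined r² never removes
a SNP.

## FST

`snp_fst` implements the identity-by-state form FST = (GS − GT)/(1 − GT).
GT is computed from pooled allele counts, which weights groups by their
allele counts **by construction**; GS therefore defaults to the same
count-weighted average of within-group IBS probabilities.  An unweighted
GS (`weights="uniform"`) is available but mismatches GT when group sizes
differ — at 160-vs-39 samples the mismatch cancels nearly the entire
divergence signal, which is why it is not the default.  Pooled-monomorphic
sites (GT = 1) are undefined and excluded.  Negative per-SNP values are
retained, never clamped.

The plug-in IBS estimator has two systematic properties worth knowing:
with K groups its infinite-sample limit is ≈ F·(K−1)/K of the
Balding–Nichols divergence (for K = 2, about F/2), and finite samples add
an O(1/n) positive bias.  Permutation p-values are unaffected (the null
distribution carries the same bias), but for estimating divergence on its
nominal scale use the **Weir–Cockerham** estimator (`method="wc"`),
implemented from the standard two-allele variance components a, b, c with
θ = a/(a+b+c) per SNP; its ratio-of-sums aggregation
(`aggregate="ratio"`) is preferred at weak divergence, while the default
genome-wide aggregation is the unweighted mean of defined per-SNP values.

Permutation tests shuffle group labels across samples without restriction
(a stage-restricted mode is a straightforward caller-side subset).  The
**add-one convention** p = (1 + #{perm ≥ obs})/(1 + N) gives a floor of
≈1.0 × 10⁻⁴ at N = 10,000, matching the convention under which such
analyses report their smallest p.  Pooled counts are invariant under
label permutation, so only GS is recomputed per permutation; memberships
are 0/1 matrices and the per-group allele counts are two matrix products
per chunk (default 500 permutations per chunk, bounding memory).
Per-SNP p-values receive BH-FDR; SNPs with q ≤ 0.05 form the
stratification-informative subset.

## PCA, k-means, optimal k

PCA mean-imputes missing dosages per SNP, centers and unit-variance
scales columns (dropping zero-variance columns with a count), and takes
the SVD; eigenvalues are of the sample covariance.  k-means (scikit-learn,
`n_init` restarts, seeded) runs for k = 1..k_max; the elbow rule takes the
smallest k whose relative TWSS improvement over k−1 is ≥ δ (trivially true
for k = 1) while the improvement at k+1 falls below δ = 0.10.

A geometric caveat drove one design choice: in one or two dimensions,
k-means on *unstructured* data keeps reducing TWSS by more than 10% per
added cluster almost indefinitely (splitting a 2-D Gaussian cuts TWSS by
~30%), so an elbow at δ = 0.10 only exists when the clustering space has
enough background dimensions to flatten the tail.  Clustering therefore
defaults to the top 10 PCs rather than the 2 that are plotted; with ~10
background dimensions a single Gaussian cloud correctly yields k = 1 and
three separated clouds yield k = 3.

The cluster×site association is the Pearson chi-square without continuity
correction, df = (rows−1)(cols−1); zero margins are rejected.

## Stratified association (CMH)

Each non-missing genotype contributes two alleles to its stratum's 2×2
table (heterozygotes one to each allele column); allele "A" is the
reference allele, a choice the statistic is symmetric in.  The statistic
is computed exactly as written, including squaring (|Σdev| − ½)² even
when |Σdev| < ½ — the correction is not clamped at zero (the zero-signal
value is 0.25/Var, matching the reference implementation in
statsmodels).  Strata with n ≤ 1 or a zero variance term contribute to
neither sum; if all strata are degenerate the SNP's result is missing and
excluded from FDR.  The ½ correction makes the test conservative at
α = 0.05 by roughly P(|Z| > 1.96 + 0.5/SD) — visible as a null rejection
rate slightly under 0.05 — which is the intended behavior of the
corrected statistic; `continuity=False` recovers the asymptotically exact
calibration.

The dusk capture window is 18:00–22:00 and dawn 02:00–06:00 when deriving
labels from capture times; gene adjacency uses distance 0 inside the gene
interval (1-based inclusive) and the gap to the nearer end otherwise, with
a default window of 10 kb on each side (5 kb available by flag).

BH-FDR is the step-up procedure via `statsmodels.stats.multitest`,
validated in tests against exhaustive evaluation of the step-up
definition.

## Problem sizes and determinism

All simulation-based checks run at desk scale, chosen so each statistic is
in its identifiable regime: permutation tests use 5,000 SNPs and ~200
samples with 10,000 permutations; estimator-recovery checks use 5,000
SNPs at 50 samples per subpopulation; calibration checks use 2,000 SNPs
at 100 samples per stratum.  Every stochastic component takes an explicit
seed and a single `numpy.random.Generator` stream per run, so fixtures
and acceptance outputs are bit-reproducible.  The acceptance script
derives its simulation and permutation seeds from the single `--seed`
argument.

## Known limitations

* The EM refiner cannot approach haplotype-imputer accuracy; its role is
  to provide a correct, documented GP field and gate, with external
  imputation as the fidelity path.
* The IBS FST default reports the printed-formula statistic, not nominal
  divergence; use `method="wc"` for parameter estimation.
* The LD copying process is first-order and cannot represent long-range
  or block-structured LD.
* Allelic (rather than genotypic) association assumes within-stratum HWE,
  which the simulator guarantees but real data may violate; the HWE site
  filter is the guard.
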