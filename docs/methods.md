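# Methods

## Overview

`immunosig` implements a two-stage study design: (1) unsupervised
representation learning of gene expression signatures from single-cell
RNA-seq, and (2) association of a selected signature with immune-checkpoint-
blockade response and survival in bulk clinical cohorts. This note records
the models, the defaults and why they were chosen, what the synthetic data
does and does not emulate, and the numerical conventions.

## Signature model

The representation learner is an autoencoder
`x → h = f(W_e x + b_e) → x̂ = W_d h + b_d` over gene-centred, normalized
expression, trained by Adam on mean-squared reconstruction error. Defaults:

| parameter | default | notes |
|---|---|---|
| activation `f` | linear | ReLU available via `TrainingConfig(activation="relu")` |
| K (signatures) | caller-supplied | library-scale analyses use K in the hundreds; desk-scale tests use K ∈ [1, 16] |
| epochs | 300 | full-batch; 1200–1500 for near-machine-precision convergence on small noiseless toys |
| learning rate | 1e-2 | Adam (β₁=0.9, β₂=0.999) |
| batch size | full batch | mini-batches supported; order reshuffled per epoch from the training seed |
| weight decay | 0 | nonzero shrinks loadings; off by default so the linear limit is exactly PCA-like |

Why an autoencoder rather than plain PCA: the architecture extends to
nonlinear bottlenecks and to iterative/streaming training, while its linear,
unregularized limit is fully understood — the decoder rows span the top-K
principal subspace of the centred data at the loss minimum. That limit is
enforced by test: on a rank-K noiseless matrix the principal angles between
the decoder span and the top-K right-singular subspace are required to be
< 5° (in practice they are < 1e-4°).

Conventions:

- **Normalization.** Library-size scaling to 10,000 counts per observation
  followed by log1p, the field-standard recipe for UMI-like counts. The
  spec of the transform is stored with the model and re-applied verbatim
  when projecting new (e.g. bulk) data, so single-cell and bulk matrices
  travel through the identical transform.
- **Gene alignment.** `encode` aligns by gene identifier, drops extra genes,
  imputes missing model genes at the normalized-zero value, and refuses to
  project when fewer than 50% of model genes are present (configurable).
- **Decoder normalization.** After training, each decoder row is rescaled to
  unit L2 norm with the compensating scale folded into the encoder (valid
  because both supported activations are positively homogeneous), making
  loading magnitudes comparable across signatures.
- **Sign.** Latent factors are sign-indeterminate. `orient_signatures` flips
  each signature so its mean loading over a reference set (the
  immunomodulator set, in the pipeline) is non-negative, giving downstream
  odds ratios a fixed direction.
- **Divergence.** A non-finite loss raises immediately, reporting the last
  finite epoch; the training log keeps the per-epoch loss so the
  monotone-trend contract (final ≤ initial; decreasing on a 5-epoch
  smoothed curve) is checkable.

## Ranking signatures against immunomodulators

Each signature's |loading| vector is compared between member and non-member
genes with a two-sided Wilcoxon rank-sum test (exact for small tie-free
groups, normal approximation with tie correction otherwise). A rank test is
used because it is invariant to the loading scale — multiplying a
signature's loadings by any positive constant cannot change its rank — and
because no parametric form for loading distributions is assumed. The
signed standardized statistic is positive when member genes carry larger
loadings. Benjamini–Hochberg adjustment runs across the K signature-level
tests; significance is adjusted p < 0.05 by default. Signatures whose
member/non-member split is degenerate (fewer than 2 genes on either side)
are flagged untestable and excluded from the significance denominator, so
the reported fraction (e.g. 164/258 = 63.6%) is always well defined.
Subcategory profiles re-run the same test per subcategory for the top-k
signatures, with BH within that table.

## Clinical association battery

- **Wilcoxon (score vs response).** Two-sided Mann–Whitney per signature in
  the top-k family, BH across the family; group medians with 2000-draw
  percentile-bootstrap 95% CIs (seeded).
- **Fisher's exact test.** The 2×2 table is high/low group × response. The
  odds ratio is the conditional maximum-likelihood estimate (noncentral
  hypergeometric), with exact 95% CI; the two-sided p sums hypergeometric
  probabilities of tables no more likely than the observed (the
  "probability ≤ observed" rule, the most common implementation
  convention). Zero-margin tables return a flagged, undefined OR — no
  silent continuity correction. Both p and OR are pinned to brute-force
  enumeration for every 2×2 table with n ≤ 30.
- **Logistic regression.** Response on the continuous score plus TMB, CTL
  and *PD-1*/*PD-L1*/*CTLA-4* expression; listwise deletion, Wald 95% CIs.
  The per-unit OR is reported alongside the per-SD OR, since either scaling
  appears in the literature. Perfect or quasi-separation (|β| > 20 or
  SE > 1e3) raises rather than reporting an absurd finite OR. A warning
  fires below 10 events per fitted coefficient.
- **Kaplan–Meier / log-rank.** Product-limit curves per group; two-group
  log-rank chi-square. Zero events yields a flagged undefined result.
- **Cox regression.** High/low group as the default exposure (per-group HR,
  matching the convention of reporting group-wise survival contrasts) with
  sex, subtype/stage (dummy-encoded, first level reference) and TMB as
  covariates; continuous-score exposure is one argument away. Ties are
  handled by Efron's method. Note one consequence: exact duplication of a
  cohort leaves the HR only approximately unchanged (relative shifts
  ~1e-3), because duplication manufactures ties.

Missingness policy throughout: listwise deletion within each model on the
columns that model uses, with `n_used` always reported — mirroring how trial
analyses report different n for unadjusted and TMB-adjusted models.

## Preranked GSEA

Genes are ranked by the difference of group means of normalized expression
(signal-to-noise optional, with the conventional floor of 0.2·|mean| on each
group SD); ties are broken lexicographically by gene id so the order is
total. The enrichment score is the classic weighted Kolmogorov–Smirnov
running sum with weight exponent 1: members add |metric|/Σ_member|metric|,
non-members subtract 1/(N−m), so the sum starts and ends at zero and the ES
is its signed extremum (ties in extremum magnitude within 1e-12 resolve to
the positive side, a deterministic convention). If all member metrics are
zero the member steps fall back to 1/m. The null permutes gene labels —
valid at small cohort sizes where phenotype permutation runs out of
relabellings; this is a documented divergence from phenotype-permutation
GSEA and the reason set-to-set correlations are not modelled. The two-sided
p is (1 + #{|ES_perm| ≥ |ES|})/(n_perm + 1); NES divides ES by the mean
|permutation ES|; BH runs across sets and adjusted p < 0.10 is the
reporting threshold. Sets intersecting the ranked list in fewer than 3
genes are skipped and logged.

## Synthetic data: what it emulates and what it does not

`simulate_single_cells` draws counts from a negative binomial (gamma–Poisson,
shared dispersion θ, variance μ + μ²/θ) whose log-mean combines a gene
abundance offset, a cell-type baseline (five types by default: tumor,
stroma, dendritic, CD4+ and CD8+ T cells), and Σ_p activity×loading over
planted latent programs; per-cell means are renormalized to a lognormal
library size. Exactly one program's loadings are positive and concentrated
on the designated immunomodulator set (member loadings |N(scale, 0.25·scale)|,
so `program_loading_scale` is their mean and a scale of 0 yields a pure
cell-type mixture). `simulate_cohort` builds each patient's bulk profile as
a Dirichlet-weighted mixture of the cell-type profiles evaluated at the
patient's own program activities, then draws response from
Bernoulli(logistic(α + β_sig·s + β_confᵀx)) and survival from an
exponential with hazard ∝ exp(log(HR)·s); censoring strikes independently
with probability `censor_rate` and replaces the event time with a uniform
draw below it.

Default study conditions: 500 genes, 3000 cells, 3 programs, a 50-gene
immunomodulator set, loading scale 1.0, dispersion 2.0, 298 patients
(a trial-sized cohort), planted per-unit OR 1.3 and HR 0.61 — the effect
sizes a well-powered ICB biomarker would show — response intercept −1.2
(≈23% responders), baseline hazard 1/12 per month, 30% censoring. TMB is
stored on a linear mutations/Mb-like scale (10 + 4z, floored at 0.1) so
that a model adjusting for the stored column is correctly specified; the
five confounders are generated independent of the planted score, which
makes the adjusted and unadjusted signature effects share one estimand and
keeps null calibration clean.

Deliberately not emulated: batch effects, doublets, ambient RNA,
cell-type-specific program activity, confounder–signature correlation, and
non-proportional hazards. Exponential survival means proportional hazards
hold exactly, so Cox recovery is well-posed; passing tests therefore show
the estimators recover what was planted under their own assumptions, not
that real trial data satisfies those assumptions.

Reproducibility: every operation derives its RNG stream from the config
seed plus a fixed per-operation offset, so identical configs give
bit-identical outputs and stages rerun independently reproduce themselves;
`simulate_cohort` accepts a seed override for replicate cohorts sharing one
single-cell truth.

## Stratification

Median split with ties going low is the default high/low stratifier — the
conventional cut when no activation threshold is externally defined — with
a fixed-threshold alternative exposed. Constant score vectors and splits
that empty a group raise rather than degrade into undefined group tests.

## Problem sizes used by the tests and acceptance script

Unit tests run on 30–150-gene, 50–700-cell simulations. The acceptance
script uses the default 500×3000 single-cell conditions for ten training
seeds (top-5 recovery of the planted signature), n = 5000 cohorts for
effect recovery, 1000 replicate n = 100 cohorts for Fisher null
calibration, 200 replicate n = 150 cohorts for Cox CI coverage, and the
exhaustive n ≤ 30 table sweep for Fisher oracle equivalence. These sizes
give stable Monte-Carlo margins for every threshold tested while keeping a
full run in the minutes range on one CPU.

## Known limitations

- The autoencoder default is linear; nonlinear signatures exist only behind
  the ReLU config switch and are not exercised by the recovery tests.
- Gene-label permutation GSEA ignores inter-gene correlation; its p-values
  are anti-conservative for strongly co-expressed sets.
- The conditional-MLE OR and its exact CI come from SciPy's implementation;
  the package pins them to enumeration rather than reimplementing them.
- Bulk profiles are mixtures over simulated cell-type means, not sums over
  resampled single cells; statistically equivalent at these scales but
  without single-cell sampling noise in the mixture weights.
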