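# Methods

This note documents the statistical model behind `normodi`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## The normobiotic reference model

The core object is a PCA model of healthy-control ("normobiotic") microbiome
composition. Raw counts are closed to relative abundances per sample,
optionally prevalence-filtered, and mapped into an approximately Euclidean
space by the centred log-ratio (CLR) transform,
`clr(x)ᵢ = log(xᵢ + c) − mean_j log(xⱼ + c)`. PCA with elliptical confidence
regions presumes approximately multivariate-normal geometry; CLR is the
standard compositional choice for that purpose, and `log-relative`
(elementwise `log(x + c)`) is available as an alternative. The pseudocount
`c` defaults to half the smallest nonzero relative abundance in the
reference table (the common multiplicative-replacement heuristic) and is
**locked at fit time**: scored samples are always transformed with the
reference's pseudocount so they live in exactly the space the model was fit
in.

The model itself: with reference matrix `X` (n × d, transformed), the
per-feature mean (and, if autoscaling, the n−1 standard deviation) is
computed on the reference only; the SVD of the centred matrix gives
orthonormal loadings `P` and eigenvalues `λᵢ = sᵢ²/(n−1)` for all d
components (zero-padded past the rank). The retained count `k` is the
smallest number of components reaching the cumulative-variance target
(default 0.90), capped at `n − 2`; an explicit `n_components` can force any
`k` up to the matrix rank. Ties at exactly the target resolve to the smaller
`k`; sign indeterminacy of the SVD is fixed by making each loading column's
largest-magnitude entry positive, so fits are bit-reproducible.

### Scoring and confidence limits

For a sample `x`, with `x̃` the centred (/scaled) vector and `t = Pᵀx̃`:

* `T² = Σ_{i≤k} tᵢ²/λᵢ` — distance within the retained score space;
* `Q = ‖x̃ − P t‖²` — squared reconstruction residual outside it.

The T² limit uses the F form for a *new* observation,
`T²_lim = k(n−1)(n+1)/(n(n−k)) · F₁₋α(k, n−k)`; the Q limit is the
Jackson–Mudholkar approximation built on the discarded eigenvalues
(θᵢ = Σ_{j>k} λⱼⁱ, h₀ = 1 − 2θ₁θ₃/(3θ₂²)). When `k` equals the rank there is
no residual space (θ₁ = 0): the Q limit is reported as 0, Q scoring is
disabled with a logged warning, and the DI falls back to the T² component
alone.

### The Dysbiosis Index

The DI combines both exceedance ratios symmetrically:

    DI = ( T²/T²_lim + Q/Q_lim ) / 2

so DI > 1 means the sample is outside the normobiotic confidence range on
average. This combination is a design choice, not an established identity:
T²-only, Q-only or max combinations are equally defensible, which is why the
score set reports `T2`, `Q`, both limits and both out-of-limit flags
alongside `DI`, and the model file stores everything needed to recompute any
alternative. The limits use the training-data F form rather than
leave-one-out, so calibration statements are made for *fresh* samples;
training-sample coverage is only approximate.

Default α = 0.05, variance target 0.90, autoscaling off — conventional
settings in multivariate statistical process control.

## Group statistics

Kruskal–Wallis uses mid-ranks with the standard tie correction and the
chi-square approximation on g−1 degrees of freedom (group sizes in the
intended use are ≥ 21, so no exact small-sample tables); an all-identical
pooled sample is reported as H = 0, p = 1 rather than an error. Dunn's
post-hoc z statistics are computed on pooled mid-ranks with the same tie
term, two-sided normal p-values, and an explicit adjustment argument
(Bonferroni, BH, or none) — the adjustment is deliberately not defaulted
away, since study reports differ in whether pairwise p-values were
corrected. Benjamini–Hochberg adjustment delegates to statsmodels'
step-up implementation.

## Discriminatory features (LEfSe-style)

Features are first gated per-feature by Kruskal–Wallis across all groups at
`kw_alpha` (default 0.05). Survivors are rescaled to the per-million axis
(× 10⁶, floored at 1, the LEfSe convention) and, for each enriched group, a
one-against-all linear discriminant is fit on `n_boot = 30` bootstrap rounds
that subsample 2/3 of each class; the pooled within-class covariance is
regularised by adding 10⁻⁶ of its mean eigenvalue to the diagonal so
small-sample LDA is well-posed. A feature's effect size is
`log10(1 + e)` with `e` the bootstrap average of the mean of (i) the
absolute raw class-mean difference and (ii) the feature's
coefficient-weighted share `|w_f| · |wᵀ(m₁−m₀)|` of the discriminant
separation (unit-norm `w`). This per-feature attribution follows the LEfSe
convention and puts scores on the familiar 2–6 scale, where the default
pass threshold of 2 corresponds to roughly hundredfold-scale separation on
the per-million axis. The enriched group is the argmax of group mean
relative abundance. There is no subclass (within-class) stage: the intended
design is four flat arms. Determinism is guaranteed given `(seed, n_boot)`,
and results are invariant to sample order (samples are canonicalised by
sorted identifier before any resampling).

## Correlations

Spearman's rho is computed on mid-ranks for every cross pair of two tables
(or the upper triangle of one table — no self-pairs), with two-sided
p-values from the t approximation on n−2 degrees of freedom (intended n
≥ 10; the approximation is standard at cohort sizes). BH adjustment across
all pairs is the default filter; filtering on unadjusted p < 0.05 is
available because study figures are often thresholded that way. Constant
features have undefined rank correlation: their pairs are reported with
missing rho/p, excluded from the BH family, and never kept.

## The synthetic trial generator

The generator emulates the *statistical structure* the analysis assumes, at
the four-arm trial's sample sizes: a healthy reference cohort (n=50) for
model fitting, a held-out healthy test cohort (n=30), two dysbiotic arms
(NIP n=57, Placebo n=21), and an intervention arm (Synbiotic n=29). Each
taxon has a baseline log-mean drawn from N(0, 2²) — a long-tailed
rank-abundance profile spanning several orders of magnitude — and per-sample
latent values add N(0, 0.5²) noise. Dysbiosis adds a signed shift δ
(default 1.0) to a fraction (default 0.2) of taxa, half upward
("opportunist-like") and half downward ("beneficial-like"); the Synbiotic
arm receives `(1−ρ)·δ` with reversion ρ = 0.7 by default. Counts are
multinomial draws (depth 50,000) from the softmax of the latent vector, so
compositional closure and count overdispersion emerge naturally rather than
being imposed.

Metabolite tables for correlation testing are Gaussian-copula generated:
a linked pair at target Spearman ρ_s uses latent Pearson correlation
`2·sin(πρ_s/6)` (the exact Gaussian-copula inversion), so realised rank
correlations match their targets without tuning; positivity comes from
exponentiation.

What the generator does **not** emulate: real taxonomies or phylogenetic
structure, strain-level variation, sequencing error, batch effects,
covariate structure (age, BMI, medication), or the heavy zero-inflation of
low-biomass samples. Passing tests therefore demonstrate that the pipeline
recovers the *kind* of signal it targets at realistic sizes and noise — not
that it would reproduce any particular clinical dataset.

## Numerical choices and degenerate inputs

* Standard deviations use the n−1 convention throughout, for consistency
  with the F-based limits.
* Rank computation for a fitted model uses a relative threshold
  (`s > s₁·max(n,d)·ε`); eigenvalues past the rank are exactly zero.
* Zero-variance features: an error under autoscaling, under `log2_zscore`
  and under Pareto scaling (named in the message); tolerated by the
  unscaled PCA.
* All-zero samples are an error at closure time, named in the message.
* Missing cells are NaN from the moment of reading (empty cell or `NA`);
  only `min_impute` removes them, and it never alters an observed value.
* Model files are plain text and store floats with `repr`, so a saved and
  reloaded model scores bit-identically.
* A pathological Jackson–Mudholkar evaluation (non-positive inner term,
  possible for extreme discarded spectra) falls back to θ₁, the mean
  residual power.

## Benchmark problem sizes

The statistical benchmarks in `tests/test_acceptance.py` and
`scripts/acceptance.py` use: limit calibration pooled over 10 independent
reference fits of 200 samples × 20 features (k forced to 5) with 10,000
fresh null draws each — pooling over fits removes the reference-sampling
noise that otherwise dominates a single exceedance estimate; DI separation
over 100 trial replicates at generator defaults; reversion monotonicity at
ρ ∈ {0, 0.5, 1} × 50 replicates; 10,000 null Kruskal–Wallis simulations;
50 spiked-feature runs (200 features, two groups of 30); and 60
copula-recovery replicates at 100 samples. These sizes put Monte-Carlo error
comfortably inside each asserted band while keeping the whole suite in the
tens of seconds on one CPU.

## Known limitations

* **High-dimensional miscalibration.** With d (taxa) comparable to or above
  n_ref — the trial regime, d=100 vs n_ref=50 — sample eigenvalues are
  biased and both limits are anti-conservative for fresh samples: the
  held-out healthy cohort's median DI sits near 2 rather than below 1.
  Group *contrasts* (the quantity the analysis reports) remain valid, which
  is why acceptance asserts calibration only at n ≫ d and asserts ordering
  and rejection — not absolute DI levels — on the trial.
* **Ordering resolution at weak residual signal.** Because T² and Q grow
  quadratically in a mean shift, an arm retaining 30% of the dysbiotic
  shift is elevated above healthy by only ~9% of the untreated arm's
  elevation; at n ≈ 29 per arm this margin is comparable to the sampling
  error of a median, so the full three-way median ordering
  HC_test < Synbiotic < NIP reproduces in roughly 80–85% of replicates,
  not near-certainly. The Synbiotic < NIP contrast, and the Kruskal–Wallis
  rejection of NIP vs healthy, are essentially always recovered.
* Rarefaction is not implemented; closure to relative abundance is used
  instead, which is sufficient for every downstream statistic here.
* The DI combination rule is one defensible choice among several (see
  above); all ingredients are exported so alternatives can be computed.
* LDA effect sizes follow this package's bootstrap/regularisation
  conventions; numerical agreement with other LEfSe implementations should
  not be expected beyond rank-level concordance.
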