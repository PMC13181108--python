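# Methods

`closcreen` scores pooled CRISPR knockout screens in which cells are sorted
into fluorescence bins (e.g. the top and bottom 30% of a surface-receptor
immunostain) and guide abundances are read out by sequencing. This note
documents the statistical model, the defaults and why they were chosen, the
synthetic-data generator, and known limitations.

## The CLO score

For each guide *g* and compared sample *s*, the number of sequencing reads
*n<sub>gs</sub>* is modelled as negative binomial, parametrized by its mean
and variance. Under the **observed** model, the guide's true frequency in
sample *s* equals its observed frequency, so the mean is the observed read
count itself. Under the **null** model, the guide's frequency is the same
in every compared sample — the pooled frequency across samples — so the
mean is *f<sub>pool</sub>(g) · T<sub>s</sub>*, with *T<sub>s</sub>* the
sample's effective total reads. The guide score is

CLO<sub>guide</sub> = sign(effect) × Σ<sub>s</sub> log₁₀ [ P(n<sub>gs</sub> | f<sub>obs</sub>, var) / P(n<sub>gs</sub> | f<sub>pool</sub>, var) ]

where the sign is that of the high-bin minus low-bin observed frequency.
Gene scores are the sums of their guides' scores. Log base 10 is used
throughout.

Because the modelled variance is a function of the mean, the variance is
evaluated at each model's own mean (a shared variance would be undefined
when one mean is zero). A consequence is that the numerator is not exactly
the pmf-maximizing mean: per-sample log-LR terms can dip on the order of
10⁻³ below zero when a guide sits exactly at its null expectation. Zero
mean is treated as a point mass at zero reads; the log-probability of an
impossible outcome is clamped at −10⁶ to keep sums finite.

## Normalization: effective total reads

Sorting enriches or depletes guides with real phenotypes, so raw column
totals misstate sequencing effort. For each sample the scaling factor is
the median, over control guides (non-targeting and safe-targeting), of the
guide's observed frequency divided by its frequency in the data pooled over
the compared samples (pooled with *actual* totals; controls with zero
pooled counts are excluded, since 0/0 carries no information). The
effective total is the actual total times this factor.

The factors are then rescaled by one global constant so the effective
totals sum to the actual grand total. This constant cancels out of every
frequency ratio and every read-count expectation downstream; it only pins
the absolute frequency scale so that the median control-guide
observed/pooled frequency ratio is exactly 1 in every sample. It can be
disabled (`rescale=False`).

## The empirical variance model

Measurement variance is estimated from control guides only, to avoid
inflating it with real phenotypes. Deviations (observed − expected reads,
expectation = pooled frequency × effective total) are pooled into bins of
expected read number on a fixed grid, 10^1.2 through 10^3 in steps of
10^0.05 (36 bins); each guide is binned once by its expected reads averaged
over the compared samples and contributes one deviation per sample. The
per-bin variance is the mean squared deviation times
n<sub>samples</sub>/(n<sub>samples</sub>−1), correcting for the degree of
freedom spent estimating the expectation. A line is fitted to
log₁₀(variance) against log₁₀(bin center), weighted by bin occupancy —
the sampling variance of a log bin-variance scales as 1/n, and unweighted
fitting lets near-empty edge bins swing the slope by ±20% between
replicate screens. Guides outside the grid do not enter the fit but still
receive predictions by extrapolation. Predicted variance is floored at
1.01 × mean, so the negative binomial is always strictly overdispersed.

Known limitation: binning by *estimated* expected reads induces selection
effects in the edge bins (low bins attenuated, high bins inflated), which
biases the fitted slope slightly upward and the intercept — an
extrapolation to mean 1 — down by roughly 2.2× any slope error. Fitted
variance inside the data range is accurate to a few percent; the intercept
in isolation is not a faithful estimate of the generating constant.

## Empirical p-values and hits

A guide's negative-direction p-value is (0.5 + number of control guides
with a strictly lower CLO score) / (number of controls); the positive
p-value is its exact complement. Ties count as "not lower". A guide above
every control is treated as having N−1 controls lower, keeping both
directional p-values inside (0, 1) with floor 0.5/N — the resolution limit
of the control set.

Gene p-values combine the per-guide directional p-values under a uniform
null: Fisher's method (−2 Σ ln p ~ χ²₂ₖ) by default, or an empirical
alternative that ranks the gene CLO against pseudo-genes built by summing k
resampled control-guide scores. The log P-score used for ranking and
plotting is sign(effect) × (−log₁₀ p), so decreases in surface signal give
negative scores.

Hits are called one-tailed per direction at a positive false discovery
rate below 0.05. q-values use Storey's pFDR with the smoother π₀ estimate
(cubic spline over a λ grid, read off at λ = 0.95, floored at 1/m);
Benjamini–Hochberg is available as an alternative. A gene is reported in
the direction with the smaller p and can be a hit in only one direction.

## Effect sizes

The raw effect is log₂(f_high/f_low) of observed frequencies. Guides with
a zero count in either bin get a Haldane-style 0.5-read pseudocount in both
bins and are flagged; double-zero guides are reported as 0.

Shrunken estimates use an empirical-Bayes grid search. The prior is a
kernel-density estimate of the raw effects of guides with ≥ 100 mean
reads/sample, using a standard t kernel with 3 degrees of freedom — close
to Gaussian in the body but heavy-tailed, so effects beyond the
well-measured range keep prior mass. The bandwidth is Silverman's rule of
thumb on the qualifying effects (exposed as a knob; the kernel scale is
otherwise arbitrary). For each sample a grid of 21 candidate frequencies
runs from the observed frequency to the null expectation, endpoints
included — a 21 × 21 posterior matrix for a two-sample comparison. The
estimate is the log₂ ratio at the posterior maximum; ties break toward the
null. By construction the estimate lies between 0 and the raw effect and
approaches the raw effect as depth grows. Gene effects are the median of
the gene's guide estimates (mean available).

## Four-sample differential analysis

The paired design sorts low/high bins with and without ligand stimulation.
The differential score isolates stimulation-specific (internalization /
recycling) phenotypes by comparing each guide's observed post-stimulation
bin split against a null in which (i) the unstimulated bin frequencies are
free (set to observed), (ii) the guide's total stimulated abundance is free
(set to the observed pooled stimulated frequency), and (iii) the
stimulated high/low split is fixed by a trend fitted to e_stim ~ e_unstim
over guides passing a mean-read floor of 10, where e is the pseudocounted
log₂ high/low enrichment of a condition. Because (i) and (ii) are free,
the likelihood-ratio sum runs over the two stimulated samples only. The
sign is that of the observed stimulated enrichment minus its trend
prediction. Guide p-values come from the control-guide CLO_diff null,
exactly parallel to the two-sample case, and the pipeline also emits the
two plain two-sample analyses (basal pair, stimulated pair) so every gene
carries three score blocks.

Two design choices here were genuinely open and were settled by simulation:

* **Trend family.** The default is LOWESS, which estimates the conditional
  expectation E[e_stim | e_unstim]: flat inside the noise cloud, tracking
  the real relation where basal effects dominate. A single global robust
  line (Huber, available as `family="huber"`) is attenuated by measurement
  noise in e_unstim (fitted slope ~0.84 when the generating relation is
  the identity) and hands strong basal-only guides systematic spurious
  residuals. Total least squares was evaluated and rejected: its principal
  direction is captured by the genuine differential genes' vertical spread.
* **Trend-input noise.** The trend prediction is made from the *measured*
  basal enrichment. For guides strongly depleted from the low bins the
  input is noisy, and that noise propagates into the null's stimulated bin
  split — their differential scores would otherwise be far more dispersed
  than the control null they are ranked against, producing false
  differential calls on purely basal genes. Each stimulated sample's
  log-LR term is therefore weighted by the reliability
  v_read / (v_read + v_trend), where v_trend is the delta-method variance
  of the null bin mean: (N_stim · s(1−s) · ln2)² · g′(e_u)² · var(e_u),
  with s the null high-bin share and var(e_u) from the variance model.
  Guides in the flat part of the trend have weight 1, so the two-sample
  behaviour and the control null are untouched. The unweighted score is
  kept in the per-guide output (`clo_unweighted`); it is the quantity that
  is exactly invariant to rescaling a guide's unstimulated counts.

The differential effect size is the residual e_stim − g(e_unstim) (raw),
shrunk on the stimulated pair with the null frequencies allocated by the
trend and the prior fitted to the residuals of well-read guides.

## The synthetic-data generator

The simulator emulates the screen design it is used to validate: 10
guides/gene, 5644 non-targeting + 6750 safe-targeting controls, 1000
cells/guide, 30% sort gates, and overdispersed sequencing counts
(variance = 2 × mean by default). Per guide, cells draw a latent log
surface level from Normal(effect × efficacy, 1) — one unit is the
cell-to-cell SD; sort gates are population quantiles of the pooled
mixture, bin membership is multinomial, and bin tallies become reads via a
negative binomial at the configured depth (default 300 reads/guide per
sorted sample; the study's sequencing depth is not stated, and 300 places
typical guides near the middle of the variance-model grid). Guide
efficacy is Beta(5, 1) — most guides effective, a weak tail — and each
guide carries a fixed lognormal abundance weight (σ = 0.5 in natural log,
shared between conditions), emulating the order-of-magnitude representation
spread of real libraries; without it all guides sit in one variance bin
and the mean–variance trend cannot be estimated. In four-sample mode the
stimulated condition shifts the latent mean by basal + stim shift,
recomputes gates on the stimulated population and re-bins independently
drawn cells.

What the generator does **not** model: PCR jackpotting, guide dropout
during passaging, fitness effects coupled to the phenotype, cell-cycle
structure, doublets, or sort impurity. Passing recovery and calibration
tests therefore demonstrates correctness of the statistics under the
declared noise model, not robustness to those artefacts.

Evaluation metrics (`truth_evaluation`) are ROC AUC of |log P| against
genes with non-zero true shift, realized false-discovery proportion among
called hits, and the Spearman correlation between estimated gene effects
and true shifts computed over affected genes only — the nulls are one big
tied group in the truth, and including them measures nothing but rank
noise among genes whose true rank is undefined.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run screens of 100–200 genes
with the full control complement (12 394) for single-screen checks, and
100 genes × 5 guides with 1000 controls for the replicated calibration
loops (100–200 replicates). These sizes put thousands of control guides in
the variance bins and give the empirical null a resolution of ~10⁻³ while
keeping every check fast enough for routine runs.

## Numerical conventions

* NB pmf through log-gamma; shape r = m²/(v−m), success fraction p = m/v.
* Exact tie in high/low frequencies → sign 0 → CLO 0.
* p = 0 inputs to the log P-score are clamped to the smallest positive
  float (cannot arise from the empirical formula).
* Grid ties in the effect search break toward the null (conservative).
* One root seed; every stage derives child seeds deterministically.
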