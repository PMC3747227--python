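# Methods

## Data model and conversions

A qPCR trial reports a quantification cycle Cq, proportional to the
negative base-E logarithm of the number of target molecules that entered
the reaction, with E the per-cycle amplification factor (E = 2 is perfect
doubling; values are validated to (1, 2.2]).  Three cell states are kept
distinct end to end: a numeric Cq, *no amplification* (the reaction ran
and detected nothing — an informative zero) and *not measured* (no
information; dropped and tallied).  In input CSVs an empty cell means not
measured and a configurable token (default `ND`) means no amplification;
conflating the two would either discard the strongest evidence of low
abundance or fabricate zeros from missing wells.

**Counts.** `count = round(E^(Cq1 - Cq))`, clamped to ≥ 1 for detected
trials, since any amplification implies at least one template molecule;
without the clamp, high-Cq detections would alias with true zeros.  Cq1 —
the cycle at which a single molecule is detected — can be per-gene
(measured), from the empirical linear relation `Cq1 = 79 - 21.5 E`
(anchored at Cq1 = 36 for E = 2, the same anchor the single-efficiency
model `Cq1(E) = 36 ln 2 / ln E` passes through), or uniform (default 37).
Relative quantification is insensitive to the choice because a wrong Cq1
multiplies a gene's counts by a constant, which the gene intercept
absorbs; only zero-bounded (lowest-abundance) genes react noticeably.

**Log abundances.** `la = -Cq ln E`, plus the efficiency-corrected cycle
`cq_corrected = Cq log2 E` (the Cq that would have been observed at E = 2
exactly).  `la` is defined up to a per-gene additive constant
(`Cq1 ln E`); every downstream quantity — treatment contrasts,
normalization, predictions differences — is invariant to per-gene
constants, so the constant is dropped.

## The joint mixed model

Per-trial log rate: gene intercept `I_g` + gene-specific treatment effects
`B_ig` (treatment-contrast coding; one column per gene × non-reference
factor level or declared interaction cell; reference level = first
lexicographic level unless overridden) + sample loading `t_k` (shared
across genes, single variance) + gene-specific grouping effects `a_jg`
(per-gene variances) + gene-specific sample effects `s_kg` (per-gene
variances; included only when technical replicates make it separable from
the residual) + gene-specific trial residual with log-variance `v_g`.
Counts are conditionally Poisson given the log rate, i.e. marginally
Poisson-lognormal — overdispersed with variance
`mean + mean^2 (e^v - 1)`, Poisson in the `v -> 0` limit.

The loading block uses a single scalar variance: loading reflects template
quantity/quality and acts on all genes of a sample equally, so there is
nothing gene-specific to estimate there.  Grouping and sample blocks are
gene-specific because genes genuinely differ in biological variability.

## Priors and control-gene regimes

* Fixed effects: diffuse `N(0, 1e8)` (naive regime).
* Informed regime: designated control genes' *effect* columns (never their
  intercepts) get `N(0, s^2)` with `s = ln(m) sqrt(pi/2)`, so the prior
  mean absolute log fold-change is exactly `ln m` — the reading we adopt
  of "allowed to vary m-fold on average", with default m = 1.2.  The
  cruder `s = ln m` is selectable (`stability_scale="sd"`); at m near 1
  the two differ by ~25% in s and not measurably in inference.
* Fixed regime: control-gene effect variance pinned at 1e-6 (also the
  m = 1 limit).  Optionally the control genes' grouping and sample
  variance components are fixed at a user value.
* Variance components: near-flat inverse-gamma(1e-3, 1e-3) with a hard
  floor of 1e-6 on sampled variances, approximating maximum-likelihood
  behaviour while keeping the posterior proper; truly improper flat priors
  are not offered.

## Sampler

Metropolis-within-Gibbs on the augmented latent log-rates `psi = eta + e`:

1. per-observation random-walk Metropolis on `psi` against
   `Poisson(y | e^psi) × N(psi | eta, v_g)`; proposals are per-gene scaled,
   tuned to ~44% acceptance by Robbins-Monro (`gamma_t = t^-0.6`) during
   burn-in only, preserving detailed balance afterwards;
2. one joint conjugate multivariate-normal draw of all location effects
   (β and every random block) given `psi` — a weighted Gaussian regression
   of `psi` on the stacked sparse design, solved by dense Cholesky of the
   posterior precision (a few hundred columns at realistic panel sizes);
3. conjugate inverse-gamma draws for the loading variance, the per-gene
   block variances and the per-gene residual `v_g`.

For log-abundance responses step 1 disappears and the sampler is fully
conjugate Gibbs.  Initialisation: β from sparse least squares on
`log(count + 1)` (or `la`), latents at `log(count + 0.5)`, random effects
at 0, variances at 1.  Defaults 13000 iterations / 3000 burn-in /
thinning 10 give M = 1000 retained draws; a fixed seed yields bitwise
identical chains.  Per-parameter effective sample sizes (arviz) are
exposed, with a warning list under ESS 100.

## Reported quantities

Posterior means, HPD intervals by default (equal-tailed quantile intervals
selectable; at M = 1000 the two estimates differ by a few percent in
width, within Monte-Carlo noise).  `p_mcmc` = twice the fraction of draws
crossing zero relative to the posterior mean, floored at 2/M — the
smallest non-zero value a finite chain can resolve; `p_z` = two-sided
normal tail of mean/SD, which extends below that floor when the posterior
is approximately normal.  BH-FDR adjustment runs over all fixed-effect
rows of a model jointly; contrast families are adjusted separately.
Contrasts and abundance predictions are computed draw-wise from the fixed
effects (random effects integrate out at their zero prior mean).

## The classic pipeline

Normalization subtracts, per (sample, technical replicate), the mean log
abundance of the control genes — division by their geometric mean on the
natural scale; with one control gene this is the classic ΔCt.
Normalization is per trial group rather than per sample so that
technical-replicate loading noise is removed as well.  The normalized data
are fitted with the same model minus the loading term.  Control genes stay
in the fit; their near-zero estimates act as a sanity indicator and they
are flagged in the output rather than excluded from the FDR family.  On a
balanced one-factor design the posterior means reproduce hand-computed
efficiency-corrected ΔΔCt values (the joint fit adds power, not bias).
The classic route drops no-amplification trials (log of zero) — the
count-based model is the right tool when those matter — but it is the only
regime that stays unbiased when loading varies systematically with
condition.

## Identifiability of loading: what "self-normalizing" means exactly

Within each design cell, sample loading deviations are fully absorbed by
`t_k`.  The *mean* loading of a cell, however, is exactly confounded with
the gene-shared component of that cell's fixed effects: with diffuse
effect priors the flat mode resolves in favour of the fixed effects, so
naive-regime estimates carry cell-mean loading noise with standard
deviation `sigma_t sqrt(sum 1/n_cell)` over the cells entering a contrast.
This is a property of the model class, not of the sampler.  Three visible
consequences, each verified by the test suite: naive credible intervals
are wider than informed ones by exactly this component (the power ordering
fixed < informed < naive); point estimates across regimes agree up to the
naive model's own reported extra uncertainty; and an x-fold change of one
sample's template moves each fixed effect by at most `ln(x)/n_cell`
(vanishing with replication), the rest going into `t_k`.  Control genes —
or classic normalization — are what pin this mode down.

## Synthetic data and nulls

The generator draws from the model's own generative process and
back-converts counts to Cq (zero counts become no-amplification trials).
The default preset mirrors a realistic stress study: 8 genotype groups ×
2 conditions × 2 timepoints, one biological sample per (group, cell),
duplicate technical replicates, gene intercepts log-spaced over ~5–5000
starting molecules so zero-bounded genes occur.  Default noise scales,
chosen once as realistic bench values: loading SD 0.7 (~2-fold template
variation — the magnitude loading correction exists for), grouping SD 0.3,
sample SD 0.3, residual log-variance 0.05 (~0.3-cycle technical
replicate scatter), efficiency 2.0 unless specified.  What the simulator
does **not** emulate: inhibition and efficiency drift across samples,
plate/batch effects, probe cross-reactivity, Cq-calling artifacts near the
detection threshold.  Passing tests therefore demonstrate correctness of
the inference machinery under the model's assumptions, not robustness to
assay pathologies.

Null datasets follow the subtract-and-shuffle recipe: fitted fixed effects
(posterior means, divided by ln 2 to convert to cycles) are added back
onto the efficiency-corrected Cq values, then whole samples are permuted
across fixed-factor combinations, preserving per-cell counts; grouping
labels travel with their samples.  The result lives on the corrected scale
and is analyzed with E = 2 for every gene.  Note a finite-sample subtlety:
subtracting fitted per-gene cell means deflates null variance by roughly
(#cells)/(#samples), so null calibration is assessed at the study's own
sample count (32), where the deflation is ~12%; at much smaller sample
counts the shuffle test measures the deflation, not the calibration.

## Diagnostics

Four per-observation checks from a fitted posterior: (1) lognormal
residuals (log-scale observation minus linear predictor) against predicted
values; (2) scale-location (sqrt |standardized residual| against
predicted); (3) normal QQ of standardized residuals; (4) randomized
probability-integral-transform values of each count under its sampled
Poisson rate `exp(psi)` from one retained draw, paired with uniform order
statistics.  For count fits the observation proxy is `log(y + 0.5)`
(zero-safe) and the standardization variance is `v_g + 1/(rate)` — the
shot-noise term is included because the log-count proxy carries Poisson
noise on top of the lognormal residual; without it the scale-location plot
shows a spurious trend for low-abundance genes even under the true model.
The PIT construction is our concrete rendering of "probabilities of
Poisson residuals"; it reproduces the intended behaviour (uniform under a
correct model, detectably non-uniform when rates ignore the lognormal
noise) but may differ in detail from older residual-probability recipes.

## Problem sizes and numerical choices

Tests and the acceptance suite run scaled-down studies — 4–6 genes, the
32-sample layout, chains of 5200/1200/4 (still M = 1000) — chosen so the
full suite completes in a few minutes on one core while every check keeps
its statistical teeth; the package defaults remain 13000/3000/10.
Tie-breaks and guards: counts clamped to ≥ 1 for detected trials; sampled
variances floored at 1e-6; variance draws capped implicitly by a gamma
floor; log-rate overflow (> 700) rejected in the simulator; a simulated
Cq outside (0, 100) is an error instructing lower intercepts.

## Known limitations

* No amplification-curve-based efficiency estimation and no absolute
  quantification against external calibration curves.
* No automatic control-gene discovery; circular selection (picking
  controls from the dataset being analyzed) is the user's responsibility
  to avoid.
* No full Bayesian model selection with multiplicity control; the z-test
  p-values are asymptotically, not exactly, classical.
* Variance-component interval estimates are only as good as the number of
  levels feeding them (e.g. per-gene grouping variances from 8 groups are
  shrinkage estimates, not precise measurements).
* Single chain; ESS flags, not R-hat across chains, are the convergence
  signal.
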