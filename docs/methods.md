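# Methods

## Model

phylonb estimates associations between a single food-item score and the
abundances of many OTUs jointly, using a three-level Bayesian
hierarchical negative-binomial model.

**Level 1 — counts.** For subject *i* and OTU *j*,

    Y_ij ~ NB(mu_ij, phi_j),        log mu_ij = alpha_j + x_i beta_j + log z_i

with the mean–dispersion parameterization Var(Y) = mu + mu²/phi, so
phi → ∞ recovers the Poisson. The offset log z_i is the log library
size and accounts for uneven sequencing depth; x_i is the (usually
standardized) food-item score, so beta_j is a log-fold change in
relative abundance per SD of intake.

**Level 2 — phylogenetic-family shrinkage.** Within a family *f*,

    (alpha_j, beta_j) ~ N2( (mu_alpha_f, mu_beta_f), Sigma_f ),
    Sigma_f = [[sigma_alpha_f²,  omega sigma_alpha_f sigma_beta_f],
               [omega sigma_alpha_f sigma_beta_f,  sigma_beta_f²]].

The correlation omega between intercepts and slopes is shared across
families because small families cannot identify their own.

**Level 3 — hyperpriors.**

    mu_alpha_f ~ N(mu_alpha, sigma_alpha²),   mu_beta_f ~ N(mu_beta, sigma_beta²)
    (mu_alpha, mu_beta) ~ N(0, 1),            (sigma_alpha, sigma_beta) ~ Exp(1)

**Mean–dispersion regularization.** Dispersion estimates from sparse
counts are unstable; phylonb shares information across OTUs of similar
abundance by

    phi_j ~ lognormal(mu_phi_j, sigma_phi²),   mu_phi_j = a1 * mean_i(mu_ij) + a0
    (a1, a0) ~ N(0, 1),                        sigma_phi ~ Exp(1)

The trend location depends on the *current* fitted means, so it is
recomputed inside every density evaluation rather than plugged in from
a preliminary fit.

Priors that the model leaves genuinely open were fixed as follows and
are package choices, not estimates: Exp(1) on the family-level SDs
sigma_alpha_f, sigma_beta_f (mirroring the global-SD priors), and a
uniform prior on omega over (−1, 1), the least informative proper
choice for a single correlation.

## Posterior computation

The joint density and its analytic gradient are implemented over an
unconstrained vector (log transforms for scales and dispersions,
atanh for omega, with Jacobian corrections) and sampled with a
self-contained No-U-Turn sampler (multinomial variant): dual-averaging
step-size adaptation toward acceptance 0.8, diagonal inverse-metric
estimation in expanding warmup windows, divergence flagged at an energy
error of 1000. Defaults are 4 chains, 1,000 warmup and 1,000 retained
iterations per chain, thinning 2 (so 500 stored draws per chain).
Split R-hat and effective sample sizes come from arviz; any R-hat above
1.05 or post-warmup divergence is recorded as a warning on the fit, not
an exception.

Three numerical choices matter for wall-clock behavior and are worth
stating:

* **Parameterization.** Both the centered and the non-centered form of
  the normal hierarchy are implemented and mathematically identical
  (a unit test asserts equality of the two densities through the
  change of variables). Centered coordinates mix far better when every
  OTU is well informed by the data; non-centered coordinates avoid the
  funnel when shrinkage groups are small. The default picks centered
  when every family has at least 20 members, and either can be forced.
* **Initialization and starting metric.** Chains start at the prior
  center jittered by U(−0.1, 0.1), with intercepts (and one Newton
  step of per-OTU Poisson slopes) seeded from observed mean rates; the
  initial diagonal metric comes from a finite-difference curvature
  probe at the start point, shared across chains. Both remove a long
  adaptation transient; neither changes the target distribution.
* **Warmup trajectory cap.** During warmup only, tree depth is capped
  at 6 to bound the cost of the early, badly scaled phase; sampling
  after warmup uses the full cap of 10.
* **Intercept shear.** When the covariate is not centered, intercepts
  and slopes are strongly negatively correlated a posteriori. In the
  centered parameterization the sampled vector therefore stores
  ``a' = a + mean(x) * b`` at every level of the hierarchy — a
  unit-Jacobian change of coordinates equivalent to centering the
  covariate — and natural parameters are recovered on output.

The likelihood exploits the integer structure of counts: gamma-function
terms are evaluated on the unique (count, OTU) pairs only and weighted
by multiplicity, which is the dominant cost saving at cohort sizes.
The linear predictor is clipped at |eta| = 40 purely as an overflow
guard.

## Comparators

* **Per-OTU ML NB regression** (the glm.nb analogue): statsmodels'
  NB-2 maximum likelihood with the same offset, Wald tests for slopes.
  When the dispersion runs to the Poisson boundary the optimizer cannot
  formally converge; the fit is then replaced by the Poisson GLM limit
  with the dispersion capped at 1e8. All-zero OTUs are flagged
  non-estimable, failed fits non-converged; neither is dropped
  silently.
* **Hierarchy without phylogeny**: exactly the same model with all
  OTUs in a single family (the code literally collapses the family
  map, and a test checks draw-for-draw equality with that special
  case).

## Synthetic data

The generator emulates a two-family cohort: OTUs assigned uniformly to
two families; intercept means 2, slope means 0 (family 1) and ±1
(family 2, sign per dataset), family means drawn with SD 0.1; per-OTU
effects bivariate normal around the family means with SD 0.1 and
correlation −0.7; food scores N(mu_x, 1) with mu_x drawn from
{0, +1, −1}, squared in the skewed configuration. Over-dispersed counts
are NB with phi_j ~ lognormal(0.1/alpha_j, 0.1) (log-scale location and
SD); under-dispersed counts are Poisson with the top 20% of counts per
OTU replaced by the rounded per-OTU mean or by zero (mode per dataset).
The full grid crosses {10, 100, 200} OTUs × {50, 250, 500} subjects ×
{over, under}: 18 scenarios; at 100 replicates each, 1,800 datasets
with 50 skewed per scenario.

Where the generative description left choices open: the SD of x is 1
(only the mean is varied); library sizes are z_i = 1 in simulation so
slopes are directly comparable to their generating values (no depth
process is simulated); "0.1/intercept" is read on the log scale of the
lognormal; the top-20% replacement uses the per-OTU (not global)
average and one replacement mode per dataset. A
`fix_family_means` switch pins the family means exactly at (2, 0) and
(2, +1) for parameter-recovery checks, removing family-level draw
noise from the comparison.

What the generator does **not** emulate: realistic library-size
variation, taxonomic structure deeper than one family level,
compositionality constraints, or the zero patterns of real 16S data.
Passing tests therefore demonstrate correctness of the inference
machinery under the stated generative process, not performance on any
real cohort.

## Evaluation measures

MSE, bias (estimated − true), 95%-interval coverage, and FDR computed
per (scenario, method). "Truly null" means membership in the
slope-mean-zero family: realized null slopes are N(0, 0.1) around zero,
so a strict-zero definition would be empty. FDR is the standard ratio
false discoveries / max(1, discoveries); a literal "all nulls / false
positives" ratio is available as a debug column because that quantity
is sometimes reported instead, although it is not a rate. For Bayesian
fits a discovery is a 95% credible interval excluding 0; for the GLM,
p < 0.05. Non-converged GLM fits are excluded from aggregation and
counted.

## Cohort pipeline

Filtering keeps OTUs present in at least 20% of subjects, then OTUs
whose identified (non-unclassified) family retains at least 5 members,
in that order. Families are ranked by mean relative abundance and
packed greedily into batches of at most 200 OTUs — the practical limit
for whole-posterior fitting on a laptop-class machine — splitting a
family only when it alone exceeds the cap. Per batch the model is fit
with the library-size offset (pre-filter totals by default, since the
offset represents sequencing depth rather than the filtered subtotal),
and per-OTU z = posterior mean / posterior SD is thresholded at the
Bonferroni level for the number of batches; no within-batch correction
is applied because the hierarchical prior already shrinks estimates.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` exercise the
(100 OTU × 250 subject) over-dispersed scenario with 4–10 replicates
and 1–4 chains of 250–300 warmup / 250–300 retained iterations, plus
one 200-OTU fit for the correlation parameter; these sizes were chosen
as the smallest at which the calibration and ordering claims are
stable across seeds. Statistical tolerances follow from the scale: pooled
coverage over ≥400 intervals is asserted within [0.90, 0.99], and
posterior recovery within 3 posterior SDs.

## Known limitations

* Univariate only: one food item per fit; no multi-food regression and
  no covariate adjustment (ethnicity, age, ...).
* The family level is the only phylogenetic information used; genus or
  deeper structure and tree uncertainty are ignored.
* The mean–dispersion link worsens interval calibration when counts
  are under-dispersed — visible in the simulation grid — and the model
  has no zero-inflation component.
* MCMC cost grows with subjects × OTUs; a few hundred OTUs per batch
  is the practical ceiling, hence the batching pipeline.
* Divergent transitions (typically a handful per fit in the harder
  regimes) are reported on the fit; they slightly bias the deepest
  hierarchy scales while leaving slope inference essentially intact in
  our checks.
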