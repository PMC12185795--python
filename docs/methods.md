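# Methods

## Estimand and likelihood

The estimand is the relative risk (RR) of 30-day mortality for nonagenarian
(≥ 90 y) versus octogenarian (80–89 y) ICU admissions.  The binary death
indicator is fitted by Poisson regression with a log link, the standard
"modified Poisson" device for estimating RRs directly when the outcome is
common (here ~42–45%), where odds ratios would overstate the effect.  For a
binary outcome the Poisson likelihood overstates the residual variance
(`mu` instead of `mu(1-mu)`), with two deliberate consequences:

* The frequentist fit reports both the model-based covariance
  `(X'WX)^-1` and the sandwich covariance `A^-1 B A^-1`
  (`A = Σ mu_i x_i x_i'`, `B = Σ (y_i - mu_i)^2 x_i x_i'`); the sandwich SE
  is the honest frequentist uncertainty (0.041 vs 0.055 on the published
  two-group counts).
* The Bayesian posterior uses the Poisson likelihood itself.  Its spread is
  the model-based one, which is what reproduces the published posterior
  probabilities and HPD intervals; the cost is conservative (over-wide)
  credible intervals relative to the true sampling variability of a binary
  outcome.  See "Known limitations".

The unadjusted model (Model-1) contains intercept and exposure only; since
the Poisson likelihood then depends on the data only through the per-group
death/total counts, the implementation works on an aggregated four-row
weighted design, and the sufficiency (aggregated = expanded records) is
asserted by test.  In the two-group model the exposure MLE is exactly the
log crude RR, `ln((d1/n1)/(d0/n0)) = 0.0658` on the published counts.

The adjusted model (Model-2) adds sex, SOFA, CFS, NIV, mechanical
ventilation, RRT, admission diagnosis and the two treatment-limitation flags.
Continuous scores enter linearly and uncentred; categoricals are
reference-coded with the most frequent level as reference.

Maximisation is plain Newton/IRLS with step halving, initialised at the
log mean outcome.  Convergence is declared when the score norm falls below
1e-10 *relative* to `||X'Wy||`; an absolute 1e-10 is below double-precision
rounding noise for cohort-sized sums with SOFA-scale columns.

## Priors

All priors are normal on the log-RR scale.  Tail elicitation solves
`SD = |ln t - ln m| / z(1-p)` for the unique normal with mass `p` beyond
threshold `t`; both published constraints (5% below RR = 1 around mean
ln 1.1; 5% above RR = 1.1 around mean 0) give SD = 0.0579 (printed 0.058).
Elicited SDs are kept at full precision internally and rounded only for
display.  "No effect" is read as RR ≤ 1.  No optimistic prior is offered:
lower mortality in the older group was considered clinically implausible.
Nuisance coefficients (intercept, covariates) receive independent N(0, 10²)
priors, configurable via `nuisance_sd`.

## MCMC

Gaussian random-walk Metropolis, 4 chains × 12,500 iterations with 2,500
burn-in (the `analysis` preset; a `diagnostic` preset runs 4 × 10,000 for
convergence checks).  Proposal scales adapt only during burn-in by
Robbins–Monro on the log scale with step `t^-0.6`, then freeze, so the
sampling-phase kernel is a fixed, valid Metropolis kernel.  Chains
initialise at the MLE plus one-SE jitter and use independent substreams
spawned from the master seed; extending a run cannot perturb earlier draws.

Two proposal modes:

* `componentwise` (default): univariate updates, target acceptance 0.44.
  Used for the two-parameter Model-1 posterior, where each likelihood
  evaluation is O(1) on the aggregated design.
* `joint`: one multivariate proposal per iteration with the MLE covariance
  as shape matrix and a single adapted scale targeting 0.234.  Used by the
  Model-2 simulation driver, where a likelihood pass is O(n·p) and the
  joint kernel needs one pass per iteration instead of one per coordinate —
  the difference between minutes and hours for a replicated study.

Diagnostics: the classic (non-split, no degrees-of-freedom correction)
Gelman–Rubin PSRF `Rc = sqrt(((n-1)/n W + B/n)/W)` with a split-chain
variant by flag, pass threshold 1.1; effective sample size by Geyer's
initial-positive-sequence autocorrelation estimator (FFT autocovariances,
paired sums truncated at the first negative pair), capped at the draw count
and summed over chains.  Summaries refuse to run on a failed PSRF gate
unless forced.  A burn-in acceptance rate below 1% raises a mixing-failure
error rather than returning garbage draws.

## Posterior summaries

All reported quantities use pooled post-burn-in draws exponentiated to the
RR scale.  The 95% HPD interval is the shortest contiguous window of the
sorted draws containing ⌈0.95 n⌉ of them, ties broken toward the lowest
lower bound; computing it on the RR scale (not exponentiating a log-scale
interval) matches the leftward shift of the published intervals for the
right-skewed RR posterior.  Threshold probabilities are the fractions of
draws strictly above 1.0 / 1.1 / 1.2, with MCSE from the binomial formula
using the ESS of the exceedance indicator.  The tail-area "AUC" integrates
the exported density curve above a threshold and equals the draw fraction
within quadrature error (cross-checked by test).  Density exports use a
histogram smoothed by a monotone PCHIP interpolant on a 512-point grid over
the central 99.9% of posterior mass, renormalised to unit area; the prior
curve is the pointwise lognormal density (a wide prior has essentially no
mass on a posterior-centred grid, so only the posterior curve is
normalised).

## Synthetic cohort generator

The generator stands in for the non-public registry data.  It emulates:
the 807/7601 group split (exact sizes via a seeded permutation by default;
Bernoulli assignment by flag), per-group covariate marginals equal to the
published prevalences, and discrete age/SOFA/CFS distributions whose
distribution quartiles reproduce the published median (IQR) exactly —
SOFA from a truncated negative binomial on 0–24 calibrated by grid search
(with a cdf safety margin so empirical quartiles are stable), CFS and age
from hand-calibrated categoricals.  Admission diagnosis is 8 generic
categories with fixed weights (the registries publish none).  Mortality
follows `P(death) = min(1, exp(beta0 + theta·nona + gamma'z))`; the log
link makes the generator's `theta` exactly the Poisson-model estimand.
`beta0` is set so the expected reference-group risk is 42% using the exact
closed form `E[exp(gamma'z)]` (product of per-covariate MGFs under
within-group independence).  Default covariate effects are modest
(e.g. 0.04/SOFA point, 0.25–0.30 for treatment-limitation flags), keeping
risk truncation below 0.5% of records; truncation is always counted and a
warning fires above 1%.

What the generator does **not** emulate: covariate correlations (only
marginals are published; a rank-correlation hook exists for sensitivity
work), time-to-event structure, length of stay, and informative
treatment-limitation dynamics ("self-fulfilling prophecy" effects).
Passing tests therefore validate the estimation machinery under the stated
model, not the clinical realism of any particular synthetic cohort.

Randomness: one master seed; each generated column has its own
SeedSequence-spawned substream in a fixed order, so identical
(config, seed) give byte-identical CSVs.

## Descriptive statistics

Medians and IQRs use numpy's linear-interpolation quantile convention
(pinned in tests; the median of an odd-length sample is its middle order
statistic).  Group comparisons use the tie-corrected normal-approximation
Mann–Whitney U (U counts first-sample wins plus half-ties) for continuous
variables and the Pearson chi-square for categoricals.  The chi-square
default is uncorrected; Yates continuity correction is available by flag.
On the published counts the uncorrected p is 0.116 and the Yates p is
0.125; the published 0.120 lies between the two and its convention is not
stated, so tests assert consistency, not equality.

## Problem sizes and numerical choices

The reproduction runs the full published settings (3 priors × 4 × 12,500
iterations, ~40,000 pooled draws per prior; a few seconds on one core
thanks to the aggregated design).  The adjusted-model simulation study uses
100 replicates of n = 8,408 with true RR = 1.1 and, per replicate, 2 joint
chains × 4,000 iterations (1,000 burn-in) — enough for stable posterior
means and HPD endpoints at the precision the coverage summary needs.
Exceedance probabilities are reported to 3 decimals.  Non-finite linear
predictors yield a -inf log-posterior (a rejected proposal), never an
exception.

## Known limitations

* **Conservative credible intervals.**  Because the Poisson likelihood
  overstates binary-outcome variance, the posterior SD of the log RR equals
  the model-based SE (0.055 on the published counts) rather than the
  sandwich SE (0.041).  Nominal 95% HPD intervals therefore cover the true
  log RR in ~99% of synthetic replicates, not 95% — verified empirically
  by the simulation study.  This mirrors the published analysis; a
  binomial-likelihood posterior would be better calibrated but would *not*
  reproduce the published posterior probabilities.
* The published P(RR > 1) under the pessimistic prior differs between the
  original report's table (0.979) and text (0.980); comparisons use the
  table.
* The exact two-group posterior places P(RR > 1 | skeptical prior) at
  0.800 (by numerical quadrature); the published 0.811 carries its own
  Monte-Carlo error, so agreement there is at the ~0.01 level, coarser
  than for the other cells.
* Adjusted-model covariate codings in the original analysis (diagnosis
  categories, CFS linear vs categorical) are unpublished; the package's
  choices (linear scores, reference-coded categoricals) are its own.
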