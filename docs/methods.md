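# Methods

This note documents the model, priors, sampler, synthetic-data design and
numerical choices behind `srbtrans`, in the spirit of the methods
documentation of packages like statsmodels or msprime: enough detail to
re-derive every computation, with the design decisions and their
rationale made explicit.

## Model

For province $p$ and integer calendar year $t$ on the estimation grid
(default 1976–2016), the sex ratio at birth is

$$\Theta_{p,t} = b\,\Phi_{p,t} + \delta_p\,\alpha_{p,t}.$$

**Baseline and fluctuation.** $b$ is the national baseline SRB, a fixed
constant (default 1.049) taken from national-level evidence rather than
estimated: with at most a couple of dozen noisy observations per
province, jointly estimating the national level and the provincial
deviations from it leaves both hopelessly uncertain. $\log\Phi_{p,t}$ is
a stationary AR(1) process, $\log\Phi_{p,t} \sim \mathcal N(\rho
\log\Phi_{p,t-1}, \sigma_\varepsilon^2)$ with stationary initial
distribution $\mathcal N(0, \sigma_\varepsilon^2/(1-\rho^2))$. The AR(1)
constants are likewise fixed configuration (defaults $\rho = 0.9$,
$\sigma_\varepsilon = 0.004$, giving a stationary log-scale spread of
about 0.9%): they describe the *natural* fluctuation scale of the SRB and
are not identifiable per province from this kind of data. Both appear in
`GlobalParams` and are recorded in fit metadata.

**The sex ratio transition.** $\alpha_{p,t}$ is the trapezoid

* 0 for $t \le \gamma_p$ (start year);
* linear rise to $\xi_p$ over $\lambda_{1p}$ years;
* constant $\xi_p$ for $\lambda_{2p}$ years;
* linear fall to 0 over $\lambda_{3p}$ years; 0 afterwards,

implemented as $\xi\,\mathrm{clip}(\min(\mathrm{up},\mathrm{down}),0,1)$
which is exact, continuous and vectorizes. Inflation is constrained
non-negative: the setting is son preference; ratio deflation (girl
preference) is deliberately out of scope. $\delta_p$ switches the whole
transition on or off; it is Bernoulli with a province-specific mean
$\pi_p$ that carries a Uniform(0,1) hyperprior — the least informative
choice that still lets provinces differ. The reported *inflation
probability* is the exact posterior frequency of $\delta_p = 1$.

**Priors on the shape.** $\lambda_{1p},\lambda_{2p},\lambda_{3p},\xi_p$
are truncated-normal ($\ge 0$) around across-province means and sds,
which are themselves sampled: means carry normal hyperpriors, sds
half-normal hyperpriors. The hyperprior constants are informative and
centred on the national transition experience: a total span of
$\lambda_1+\lambda_2+\lambda_3 \approx 36$ years split evenly (12/12/12,
sd 2 each on the means, half-normal scale 4 on the sds), and a maximum
inflation of 0.05 (sd 0.02; half-normal scale 0.03). These defaults are
declared package choices, exposed in `ModelConfig`.

**Start year and the fertility squeeze.** $\gamma_p$ has a Student-$t_3$
prior with scale $s_0 = 8$ years, located at the first year the
province's total fertility rate (TFR) falls to the reference level
$f^\* $ — the mechanism by which fertility decline squeezes families into
sex selection. $f^\*$ defaults to 3.5 children per woman, the midpoint of
the TFR-at-start-year range the reference analysis reports across
provinces (2.6–4.4); it is a configuration value, not an estimate. The
three degrees of freedom are deliberate (heavy tails let a province with
an outlying fertility path start its transition far from the located
year) and the code refuses other values unless overridden explicitly in
config. $\gamma_p$ is restricted to a window (default 1970–2049); the
window's truncation constant is omitted from the log prior since it is
fixed per province and cancels in every ratio the sampler forms. A
config switch (`require_end_by_horizon`) additionally truncates the
prior to transitions that finish by the projection horizon; the default
leaves transitions free to extend past it.

**Observations.** $\log r_{p,t} \mid \Theta \sim \mathcal
N(\log\Theta_{p,t}, \sigma_{p,t}^2)$ with $\sigma_{p,t}$ precomputed (see
preprocessing). Multi-year reference periods are evaluated at their
midpoint year, rounded down — this keeps the likelihood a single normal
term per record; evaluating at the period-averaged $\Theta$ instead is
available behind `average_theta_over_period` in the density functions
(the difference is second-order because the trapezoid is piecewise
linear and the fluctuation is nearly flat within a period).

## Preprocessing

* **Period merging.** Retrospective surveys yield one-year counts too
  noisy to use singly. Consecutive one-year records of one
  province-source block are pooled greedily left-to-right until the
  delta-method coefficient of variation of the pooled ratio,
  $\mathrm{CV} = \sqrt{1/m + 1/f}$, reaches the threshold `cv_max`
  (default 0.1, i.e. log-scale error at most ~0.1; configurable). The
  pooled ratio is recomputed from pooled counts; male and female totals
  are conserved exactly; an un-mergeable terminal remainder is emitted
  with a warning.
* **Jackknife errors.** $\sigma$ is the delete-one-cluster jackknife
  standard error of $\log(\text{SRB})$: with $k$ clusters and replicate
  ratios $\hat\theta_{(i)}$, $\sigma^2 = \frac{k-1}{k}\sum_i
  (\hat\theta_{(i)} - \bar\theta)^2$ — the standard survey-ratio
  estimator, invariant to cluster order and uniform weight rescaling.
* **Recall window.** Survey records whose period starts more than 25
  years (configurable) before the survey year are dropped; the boundary
  year is kept; censuses pass through.
* **Census district weighting.** District birth counts sampled at
  fraction $q$ are inverse-probability weighted by $1/q$ before
  aggregation to provinces.

## Posterior computation

The sampler is Metropolis-within-Gibbs, chosen over gradient-based
samplers because the posterior mixes a discrete indicator with
conditionally weakly-identified shape parameters:

1. **Fluctuation paths** are proposed jointly per province by
   forward-filter backward-sampling (FFBS) a linear-Gaussian surrogate:
   each observation is replaced by a pseudo-observation of $x = \log\phi$
   with precision $w^2/\sigma^2$, where $w = b\phi/\Theta$ linearizes
   $\log\Theta$ in $x$ around the current path. A Metropolis-Hastings
   correction with the exact surrogate density (evaluated via the
   backward conditionals) makes the update exact; without inflation at
   the observed years the surrogate is the true full conditional and the
   draw is exact Gibbs. Acceptance is near 1 because the linearization
   error is quadratic in a quantity of order 1%.
2. **Indicators** $\delta_p$ use exact two-point Gibbs: conditional odds
   = (province likelihood with the trapezoid on / off) × prior odds
   $\pi_p/(1-\pi_p)$. No reversible jump is needed because the shape
   parameters are retained while $\delta_p = 0$.
3. **Shape parameters** with $\delta_p = 1$ move by per-parameter
   adaptive random-walk Metropolis plus a joint independence proposal
   from the hierarchical prior (prior terms cancel; acceptance is the
   likelihood ratio), which provides large decorrelating jumps. With
   $\delta_p = 0$ they have no likelihood and are redrawn exactly from
   the prior, keeping the chain irreducible — standard spike-and-slab
   practice.
4. **Bernoulli means** $\pi_p$ are conjugate Beta(1+δ, 2−δ) draws.
5. **Hyperparameters** move by random walks — additive for means,
   multiplicative (log-scale, with Jacobian) for sds, whose conditionals
   are right-skewed. The update is *partially collapsed*: conditionals
   include only the $\delta = 1$ provinces' shapes (the $\delta = 0$
   prior factors integrate to one), after which the $\delta = 0$ shapes
   are refreshed from the updated prior. Collapsing removes a slow
   feedback loop in which the sds were informed by their own prior
   draws.

Proposal scales adapt toward 0.44 acceptance during warmup (Robbins–
Monro on the log scale, every 20 iterations) and are frozen afterwards,
so the post-warmup chain is a fixed Markov kernel. Defaults: 2 chains,
500 warmup, 1500 retained draws per chain; diagnostics (split-$\hat R$
and bulk ESS via arviz, computed on the fluctuation paths, Bernoulli
means and hyperparameters) are attached to every fit, with thresholds
$\hat R \le 1.05$ and ESS $\ge 200$; exceeding them produces a prominent
warning, never silent success. Identical seeds give identical draws;
chain seeds are spawned from one `SeedSequence`.

Two numerical details were load-bearing. Truncated-normal draws use the
inverse CDF only while the bound is within five proposal sds of the
mean, and Robert's exponential rejection sampler in the deep-tail
regime: a naive inverse CDF there collapses to the bound *exactly*, and
a point atom at zero makes the hierarchical sd updates degenerate (the
truncated-normal density is unbounded as the mean drifts negative with
the values pinned at the bound). Second, inflation terms are gated by
`np.where` on $\delta$ rather than multiplied by it, so a non-finite
shape value in a $\delta = 0$ draw can never propagate.

## Projection

Each retained draw is extended forward: $\log\Phi$ by simulating the
AR(1) recursion from the last estimation year to the horizon (default
2050), $\alpha$ by evaluating the draw's trapezoid through the horizon.
Draws whose start year lies in the future inflate *during* the
projection, which is how "the province may yet inflate, with a
probability" is realized. Summaries are per-year quantiles; the peak
year is the argmax of the median trajectory (ties to the earliest
year), and the convergence year is the first post-peak year with
$|\mathrm{median} - b| < 0.002$ (configurable). Projection appends to,
and never alters, estimation-period summaries. A `transition_data_coverage`
report gives, per draw, the share of integer years in
$[\gamma_p, \gamma_p + \lambda_1 + \lambda_2 + \lambda_3)$ overlapped by
any observation period — the honest statement of how much of the
transition the data actually see.

## Synthetic data

The generator emulates the real inputs' statistical structure so the
whole pipeline is testable offline:

* **Truth** follows the model identically: stationary AR(1) fluctuation,
  configured trapezoids, $\Theta = b\Phi + \delta\alpha$ exactly.
* **Observations** are generated at the *birth-count* level: each
  scheduled record's total births (default 1,200, matching the order of
  magnitude of a pooled provincial survey period) are spread uniformly
  over the reference-period years and multinomially over clusters
  (default 25); each birth is male with probability
  $\Theta_t/(1+\Theta_t)$. The reported ratio and jackknife $\sigma$ are
  then computed by the same `data_io` routines used on real data, so the
  stated errors are automatically consistent with the generated design.
  Sex counts are binomial given totals (totals are fixed by survey
  design, not Poisson), and clusters have equal expected size — the
  simplest design with a non-trivial jackknife.
* **Schedule** mirrors the reference setting: four retrospective surveys
  (2001/2006/2011/2016), each contributing three 5-year periods per
  province within the recall window, plus one single-year census record —
  91 records across seven provinces.
* **Fertility** declines along a logistic from 6.0 to 1.9 children per
  woman (the national span of the reference setting), staggered across
  provinces so start-year prior locations differ.

Two named scenarios standardize study conditions:
`strong_signal_scenario` (maximum inflation 0.10, ~5,000 births per
record) for indicator-classification checks, and
`prior_predictive_scenario`, which draws indicators and shapes from the
model's own prior — the regime in which Bayesian interval coverage is
nominal *by construction*, hence the right condition for calibration
checks of the predictive machinery. Fixed-truth scenarios probe recovery
on specific parameter slices instead, where mild under-coverage from
spike-and-slab shrinkage is expected behaviour, not a defect.

What the generator does **not** emulate: stratification, non-response,
intra-cluster correlation of sex outcomes, recall errors, or
heterogeneous district coverage beyond a per-district sampled fraction.
Passing tests therefore demonstrate correctness of the estimation
machinery under the model's own assumptions, not robustness to the
messiness of real microdata.

## Validation machinery

* **Out-of-sample.** The split is deterministic and mirrors the data's
  retrospective structure: all records collected (survey year) at or
  after the cutoff (default 2016 — the latest survey wave, ≈20% of
  records) form the test set; censuses and earlier waves train. The
  predictive for a held-out record is the posterior of $\log\Theta$ at
  its midpoint year plus $\mathcal N(0,\sigma^2)$ noise with its own
  jackknife error. Reported: empirical 80%/95% interval coverage,
  median/mean/absolute log-scale errors, per-province breakdown.
* **Simulation study.** Replicates of simulate → fit → score, reporting
  bias/RMSE and 95% interval coverage of $\Theta$, interval coverage of
  $\xi$ and $\gamma$ for truly inflated provinces (conditional on
  $\delta = 1$ draws), and an indicator classification table (posterior
  probability vs 0.5). Replicates exceeding the $\hat R$ threshold are
  excluded and counted, never silently averaged.

## Problem sizes

Default test and acceptance runs use desk-scale settings chosen to keep
the statistical checks meaningful at interactive cost: fits of 2 chains
× (400 warmup + 1,000 retained draws) on the 91-record scenarios
(~10–15 s each), 20 recovery replicates at 2,000 retained draws, and
three held-out-wave refits pooling ~63 held-out records for the
calibration check. Start-year summaries round draws to integer years and
break median ties to the earlier year.

## Known limitations

* Inflation is non-negative by construction; populations with girl
  preference need a signed formulation.
* The fertility squeeze enters only through the start-year prior
  location; fertility does not modulate the transition's length or
  height.
* Global constants ($b$, $\rho$, $\sigma_\varepsilon$) are fixed, so
  their uncertainty is not propagated.
* The midpoint-year convention slightly misplaces multi-year records
  that straddle a trapezoid kink.
* With ~13 records per province, indicator probabilities react to
  2σ-level flukes in individual surveys (see the worked example's
  Province 6); this is faithful uncertainty reporting, but it means
  single-fit classifications should be read as probabilities, not calls.
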