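"""The sex-ratio-transition model.

The SRB of province ``p`` in year ``t`` is

    Theta_{p,t} = b * Phi_{p,t} + delta_p * alpha_{p,t}

where ``b`` is the fixed national baseline, ``Phi`` an AR(1) process on the
log scale capturing natural fluctuation around the baseline, ``delta_p`` a
binary indicator of whether the province undergoes a sex ratio transition,
and ``alpha`` a non-negative trapezoid inflation curve (linear increase,
stagnation, linear convergence back to baseline). Observed log ratios are
normal around ``log Theta`` with known, precomputed sampling errors:

    log(r_{p,t}) | Theta_{p,t} ~ N(log(Theta_{p,t}), sigma_{p,t}^2).

Trapezoid shape parameters are province-specific with hierarchical
(truncated-normal) distributions across provinces; the start year has a
heavy-tailed Student-t(3) prior whose location is tied to the province's
fertility decline: the year its total fertility rate first falls to the
reference level ``f_star`` (the "fertility squeeze").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import log_ndtr

from .structures import (
    ContractError,
    GlobalParams,
    ObservationSet,
    ProvinceState,
    TFRSeries,
    TransitionShape,
)

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class HierarchicalHypers:
    """Across-province means and sds of the trapezoid shape parameters."""

    mu_len_increase: float = 12.0
    sd_len_increase: float = 4.0
    mu_len_stagnation: float = 12.0
    sd_len_stagnation: float = 4.0
    mu_len_decrease: float = 12.0
    sd_len_decrease: float = 4.0
    mu_max_inflation: float = 0.05
    sd_max_inflation: float = 0.02

    def as_array(self) -> np.ndarray:
        return np.array([
            self.mu_len_increase, self.sd_len_increase,
            self.mu_len_stagnation, self.sd_len_stagnation,
            self.mu_len_decrease, self.sd_len_decrease,
            self.mu_max_inflation, self.sd_max_inflation,
        ])

    @staticmethod
    def from_array(a) -> "HierarchicalHypers":
        return HierarchicalHypers(*[float(x) for x in a])


@dataclass(frozen=True)
class ModelConfig:
    """Model constants, priors and hyperpriors.

    The AR(1) parameters and the baseline are fixed (taken from national-level
    experience rather than estimated, which would leave the provincial trends
    too uncertain). The hierarchical shape hyperpriors are informative,
    centred on a 36-year national transition span split evenly across the
    three stages and a 0.05 maximum inflation.
    """

    globals_: GlobalParams = field(default_factory=GlobalParams)
    # hyperpriors on the across-province means: Normal(mu0, mu0_sd)
    mu0_len_increase: float = 12.0
    mu0_len_stagnation: float = 12.0
    mu0_len_decrease: float = 12.0
    mu0_max_inflation: float = 0.05
    mu0_sd_lengths: float = 2.0
    mu0_sd_max_inflation: float = 0.02
    # hyperpriors on the across-province sds: HalfNormal(scale)
    sd_scale_lengths: float = 4.0
    sd_scale_max_inflation: float = 0.03
    # start-year prior: Student-t(df) located by the fertility squeeze
    start_year_scale: float = 8.0
    start_year_df: float = 3.0
    f_star: float = 3.5
    t0_window: tuple[float, float] = (1970.0, 2049.0)
    # model grid
    year_start: int = 1976
    year_end: int = 2016
    horizon_year: int = 2050
    allow_inflation: bool = True
    average_theta_over_period: bool = False
    # if True, the shape prior forbids transitions ending after horizon_year
    require_end_by_horizon: bool = False

    @property
    def years(self) -> np.ndarray:
        """Estimation-period model grid (integer calendar years)."""
        return np.arange(self.year_start, self.year_end + 1)


def alpha_trapezoid(t, shape: TransitionShape):
    """Trapezoid inflation alpha(t): 0 before the start year, linear rise to
    the maximum over the increase stage, flat through stagnation, linear fall
    to 0 over the decrease stage, 0 afterwards. Continuous and >= 0.

    Accepts scalar or array ``t``; vectorized.
    """
    t = np.asarray(t, dtype=float)
    up = (t - shape.t0) / shape.len_increase
    down = (shape.end_year - t) / shape.len_decrease
    frac = np.clip(np.minimum(up, down), 0.0, 1.0)
    out = shape.max_inflation * frac
    return float(out) if out.ndim == 0 else out


def srb_mean(b: float, phi_t, delta: int, alpha_t):
    """Assemble Theta = b*phi + delta*alpha (elementwise)."""
    return b * np.asarray(phi_t) + delta * np.asarray(alpha_t)


def _norm_logpdf(x, mean, sd):
    z = (np.asarray(x) - mean) / sd
    return -0.5 * _LOG_2PI - np.log(sd) - 0.5 * z * z


def ar1_logdensity(phi_path, rho: float, sigma_ar: float) -> float:
    """Log density of a positive fluctuation path under the stationary
    log-scale AR(1): log phi_0 ~ N(0, sigma^2/(1-rho^2)),
    log phi_t ~ N(rho * log phi_{t-1}, sigma^2).

    This is the density of the log path (the sampler operates on log phi).
    """
    if not 0 < rho < 1:
        raise ContractError("rho must lie in (0, 1)")
    x = np.log(np.asarray(phi_path, dtype=float))
    stat_sd = sigma_ar / math.sqrt(1.0 - rho * rho)
    total = float(_norm_logpdf(x[0], 0.0, stat_sd))
    if x.size > 1:
        total += float(np.sum(_norm_logpdf(x[1:], rho * x[:-1], sigma_ar)))
    return total


def start_year_location(tfr: TFRSeries, f_star: float) -> int:
    """First year the province's TFR falls to or below ``f_star``.

    Locates the start-year prior at the onset of the fertility squeeze. If
    the TFR never reaches ``f_star`` on the grid, the last grid year is
    returned with a warning.
    """
    for year, value in zip(tfr.years, tfr.tfr):
        if value <= f_star:
            return int(year)
    logger.warning("TFR for %s never falls to f*=%.2f; using last year %d",
                   tfr.province, f_star, tfr.years[-1])
    return int(tfr.years[-1])


def student_t_logpdf(z, df: float):
    """Standard Student-t log density, hand-assembled from the gamma function."""
    return (math.lgamma((df + 1) / 2) - math.lgamma(df / 2)
            - 0.5 * math.log(df * math.pi)
            - (df + 1) / 2 * np.log1p(np.asarray(z, dtype=float) ** 2 / df))


def start_year_logprior(t0, location: float, scale: float, df: float = 3.0) -> float:
    """Student-t(3) log prior for the transition start year.

    The heavy tails allow provinces whose fertility decline is an outlier to
    start their transition far from the located year. ``df`` other than 3 is
    rejected; pass through :class:`ModelConfig` only deliberately.
    """
    if not scale > 0:
        raise ContractError("start-year prior scale must be positive")
    if df != 3.0:
        raise ContractError("start-year prior uses 3 degrees of freedom; "
                            "override via ModelConfig.start_year_df deliberately")
    z = (np.asarray(t0, dtype=float) - location) / scale
    out = student_t_logpdf(z, df) - math.log(scale)
    return float(out) if out.ndim == 0 else out


def obs_loglik(r: float, sigma: float, theta: float) -> float:
    """Normal log likelihood of an observed ratio: log r ~ N(log theta, sigma^2)."""
    if sigma <= 0:
        raise ContractError("observations must carry positive sampling error")
    if r <= 0 or theta <= 0:
        raise ContractError("r and theta must be positive")
    return float(_norm_logpdf(math.log(r), math.log(theta), sigma))


def truncnorm_logpdf(x, mean, sd, lower: float = 0.0):
    """Log density of a normal truncated below at ``lower`` (default 0)."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        x >= lower,
        _norm_logpdf(x, mean, sd) - log_ndtr((np.asarray(mean) - lower) / sd),
        -np.inf,
    )
    return float(out) if out.ndim == 0 else out


def halfnormal_logpdf(x, scale):
    x = np.asarray(x, dtype=float)
    out = np.where(x > 0, math.log(2.0) + _norm_logpdf(x, 0.0, scale), -np.inf)
    return float(out) if out.ndim == 0 else out


def shape_logprior(shape: TransitionShape, hypers: HierarchicalHypers,
                   location: float, config: ModelConfig) -> float:
    """Hierarchical log prior of one province's trapezoid shape.

    Stage lengths and the maximum inflation are truncated-normal (>= 0)
    around the across-province means; the start year is Student-t(3) located
    at the fertility-squeeze year, restricted to the allowed window. The
    window truncation constant is omitted (fixed per province, so it cancels
    in every posterior ratio the sampler forms).
    """
    lo, hi = config.t0_window
    if not lo <= shape.t0 <= hi:
        return -np.inf
    if config.require_end_by_horizon and shape.end_year > config.horizon_year:
        return -np.inf
    total = start_year_logprior(shape.t0, location, config.start_year_scale,
                                config.start_year_df)
    total += truncnorm_logpdf(shape.len_increase, hypers.mu_len_increase,
                              hypers.sd_len_increase)
    total += truncnorm_logpdf(shape.len_stagnation, hypers.mu_len_stagnation,
                              hypers.sd_len_stagnation)
    total += truncnorm_logpdf(shape.len_decrease, hypers.mu_len_decrease,
                              hypers.sd_len_decrease)
    total += truncnorm_logpdf(shape.max_inflation, hypers.mu_max_inflation,
                              hypers.sd_max_inflation)
    return float(total)


def hyper_logprior(hypers: HierarchicalHypers, config: ModelConfig) -> float:
    """Informative hyperpriors on the across-province shape distributions."""
    total = 0.0
    for mu, mu0, mu0_sd in (
        (hypers.mu_len_increase, config.mu0_len_increase, config.mu0_sd_lengths),
        (hypers.mu_len_stagnation, config.mu0_len_stagnation, config.mu0_sd_lengths),
        (hypers.mu_len_decrease, config.mu0_len_decrease, config.mu0_sd_lengths),
        (hypers.mu_max_inflation, config.mu0_max_inflation,
         config.mu0_sd_max_inflation),
    ):
        total += float(_norm_logpdf(mu, mu0, mu0_sd))
    for sd, scale in (
        (hypers.sd_len_increase, config.sd_scale_lengths),
        (hypers.sd_len_stagnation, config.sd_scale_lengths),
        (hypers.sd_len_decrease, config.sd_scale_lengths),
        (hypers.sd_max_inflation, config.sd_scale_max_inflation),
    ):
        total += float(halfnormal_logpdf(sd, scale))
    return total


def province_obs_loglik(state: ProvinceState, config: ModelConfig,
                        observations, years: np.ndarray) -> float:
    """Sum of observation log likelihoods for one province.

    Multi-year observations are evaluated at their midpoint reference year
    (or, behind a config flag, at the period-averaged Theta).
    """
    g = config.globals_
    total = 0.0
    year0 = int(years[0])
    for o in observations:
        if config.average_theta_over_period:
            ts = np.arange(o.period_start, o.period_end + 1)
            idx = ts - year0
            if idx.min() < 0 or idx.max() >= len(years):
                raise ContractError(
                    f"observation period {o.period_start}-{o.period_end} "
                    "extends beyond the model grid")
            theta = float(np.mean(srb_mean(
                g.b, state.phi[idx], state.delta,
                alpha_trapezoid(ts, state.shape))))
        else:
            t = o.reference_year
            idx = t - year0
            if idx < 0 or idx >= len(years):
                raise ContractError(
                    f"observation reference year {t} outside the model grid")
            theta = float(srb_mean(g.b, state.phi[idx], state.delta,
                                   alpha_trapezoid(t, state.shape)))
        total += obs_loglik(o.srb, o.log_se, theta)
    return total


def log_posterior(
    states: Mapping[str, ProvinceState],
    hypers: HierarchicalHypers,
    config: ModelConfig,
    data: ObservationSet,
    tfr: Mapping[str, TFRSeries],
) -> float:
    """Full unnormalized log posterior over all provinces.

    Sum of observation likelihoods, per-province AR(1) path densities,
    hierarchical shape priors, start-year priors, Bernoulli mass for the
    inflation indicators (with Uniform(0,1) hyperpriors on their means,
    contributing zero), and the shape hyperpriors. Invariant to observation
    order.
    """
    g = config.globals_
    years = config.years
    total = hyper_logprior(hypers, config)
    by_province: dict[str, list] = {p: [] for p in states}
    for o in data:
        if o.province not in states:
            raise ContractError(f"no state for province {o.province!r}")
        by_province[o.province].append(o)
    for prov, state in states.items():
        if len(state.phi) != len(years):
            raise ContractError("phi path length must match the model grid")
        total += province_obs_loglik(state, config, by_province[prov], years)
        total += ar1_logdensity(state.phi, g.rho, g.sigma_ar)
        loc = start_year_location(tfr[prov], config.f_star)
        total += shape_logprior(state.shape, hypers, loc, config)
        p = state.prob_delta
        if not 0 < p < 1:
            return -np.inf
        total += state.delta * math.log(p) + (1 - state.delta) * math.log1p(-p)
    if not np.isfinite(total):
        _diagnose_nonfinite(states, hypers, config, data, tfr)
    return float(total)


def _diagnose_nonfinite(states, hypers, config, data, tfr) -> None:
    g = config.globals_
    years = config.years
    by_province: dict[str, list] = {p: [] for p in states}
    for o in data:
        by_province[o.province].append(o)
    if not np.isfinite(hyper_logprior(hypers, config)):
        raise ContractError("non-finite posterior term: hyperprior")
    for prov, state in states.items():
        terms = {
            "likelihood": province_obs_loglik(state, config, by_province[prov], years),
            "ar1": ar1_logdensity(state.phi, g.rho, g.sigma_ar),
            "shape prior": shape_logprior(
                state.shape, hypers,
                start_year_location(tfr[prov], config.f_star), config),
        }
        for name, value in terms.items():
            if not np.isfinite(value):
                raise ContractError(
                    f"non-finite posterior term: {name} for province {prov!r}")
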