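"""Synthetic province-level SRB data with survey-style sampling structure.

Generates ground-truth SRB trajectories from the same generative model the
estimator assumes (baseline x log-scale AR(1) fluctuation, plus an optional
trapezoid inflation per province) and then survey-style observations on top:
clustered binomial birth counts over multi-year retrospective reference
periods, with delete-one-cluster jackknife sampling errors. This stands in
for the Demographic and Health Survey / census inputs, so the whole
estimation-projection-validation pipeline is testable offline.

Default scenario constants emulate the Nepal setting: seven provinces,
a 1976-2016 observation grid, total fertility declining from around 6 to
below 2 children per woman, four retrospective surveys (2001, 2006, 2011,
2016) each contributing three pooled multi-year observations per province
of roughly 1,200 births each, plus one single-year census observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import data_io
from .structures import (
    ClusterBirths,
    ContractError,
    ObservationSet,
    SRBObservation,
    TFRSeries,
    TransitionShape,
    ValidationError,
)


@dataclass(frozen=True)
class ObsSpec:
    """Schedule entry: one observation to synthesize for every province."""

    source: str
    period_start: int
    period_end: int
    survey_year: int | None


def ndhs_like_schedule(
    survey_years: Sequence[int] = (2001, 2006, 2011, 2016),
    census_year: int | None = 2010,
) -> tuple[ObsSpec, ...]:
    """Retrospective schedule: each survey yields three 5-year periods
    covering the 15 years before it; an optional census adds one
    single-year record."""
    specs = []
    for sy in survey_years:
        for start in (sy - 15, sy - 10, sy - 5):
            specs.append(ObsSpec(f"survey_{sy}", start, start + 4, sy))
    if census_year is not None:
        specs.append(ObsSpec(f"census_{census_year}", census_year, census_year, None))
    return tuple(specs)


def _default_shapes(n: int) -> tuple[TransitionShape, ...]:
    # staggered start years and moderate inflations, national-span-like lengths
    base = []
    for p in range(n):
        base.append(TransitionShape(
            t0=1998.0 + 3.0 * (p % 4),
            len_increase=10.0 + (p % 3),
            len_stagnation=12.0,
            len_decrease=13.0,
            max_inflation=0.05 + 0.01 * (p % 3),
        ))
    return tuple(base)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic scenario."""

    n_provinces: int = 7
    year_start: int = 1976
    year_end: int = 2016
    baseline_b: float = 1.049
    ar1_rho: float = 0.9
    ar1_sd: float = 0.004
    deltas: tuple[int, ...] | None = None        # default: alternating 1,0,...
    shapes: tuple[TransitionShape, ...] | None = None
    tfr_start: float = 6.0
    tfr_end: float = 1.9
    tfr_midpoint_year: float = 1998.0
    tfr_steepness: float = 0.12
    births_per_obs: int = 1200
    n_clusters: int = 25
    obs_schedule: tuple[ObsSpec, ...] = field(default_factory=ndhs_like_schedule)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ar1_sd <= 0 or not 0 < self.ar1_rho < 1:
            raise ValidationError("AR(1) parameters out of range")
        if self.births_per_obs < self.n_clusters or self.n_clusters < 2:
            raise ValidationError("need births_per_obs >= n_clusters >= 2")
        if self.deltas is not None and len(self.deltas) != self.n_provinces:
            raise ValidationError("deltas length must equal n_provinces")
        if self.shapes is not None and len(self.shapes) != self.n_provinces:
            raise ValidationError("shapes length must equal n_provinces")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def provinces(self) -> tuple[str, ...]:
        return tuple(f"Province {i + 1}" for i in range(self.n_provinces))

    def resolved_deltas(self) -> tuple[int, ...]:
        if self.deltas is not None:
            return self.deltas
        return tuple((p + 1) % 2 for p in range(self.n_provinces))

    def resolved_shapes(self) -> tuple[TransitionShape, ...]:
        if self.shapes is not None:
            return self.shapes
        return _default_shapes(self.n_provinces)


@dataclass(frozen=True)
class SyntheticDataset:
    """Ground truth plus survey-style observations for one scenario."""

    config: ScenarioConfig
    phi: np.ndarray          # (provinces, years) natural fluctuation
    alpha: np.ndarray        # (provinces, years) trapezoid inflation
    theta: np.ndarray        # (provinces, years) true SRB
    deltas: tuple[int, ...]
    shapes: tuple[TransitionShape, ...]
    tfr: Mapping[str, TFRSeries]
    observations: ObservationSet | None = None


def simulate_tfr_series(
    province: str,
    tfr_start: float,
    tfr_end: float,
    years: Sequence[int],
    midpoint_year: float,
    steepness: float,
    seed: int | None = None,
) -> TFRSeries:
    """Smooth monotone-declining logistic TFR curve from tfr_start to tfr_end.

    Deterministic; ``seed`` is accepted for interface symmetry with the
    stochastic generators and ignored.
    """
    if tfr_start < tfr_end:
        raise ContractError("tfr_start must be >= tfr_end (monotone decline)")
    if tfr_end <= 0:
        raise ContractError("tfr_end must be positive")
    t = np.asarray(years, dtype=float)
    with np.errstate(over="ignore"):
        frac = 1.0 / (1.0 + np.exp(steepness * (t - midpoint_year)))
    tfr = tfr_end + (tfr_start - tfr_end) * frac
    return TFRSeries(province=province, years=tuple(int(y) for y in years),
                     tfr=tuple(float(v) for v in tfr))


def simulate_truth(config: ScenarioConfig, horizon_year: int | None = None) -> SyntheticDataset:
    """Draw ground-truth SRB trajectories for every province.

    log Phi starts from its stationary distribution
    (N(0, ar1_sd^2 / (1 - ar1_rho^2))) and evolves by the AR(1) recursion;
    alpha is the configured trapezoid; Theta = b*Phi + delta*alpha exactly.
    Reproducible: the same config (including seed) yields a byte-identical
    dataset.
    """
    from .model import alpha_trapezoid, srb_mean

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    years = config.years
    P, T = config.n_provinces, len(years)
    deltas = config.resolved_deltas()
    shapes = config.resolved_shapes()

    stat_sd = config.ar1_sd / np.sqrt(1.0 - config.ar1_rho**2)
    log_phi = np.empty((P, T))
    log_phi[:, 0] = rng.normal(0.0, stat_sd, size=P)
    innov = rng.normal(0.0, config.ar1_sd, size=(P, T - 1))
    for t in range(1, T):
        log_phi[:, t] = config.ar1_rho * log_phi[:, t - 1] + innov[:, t - 1]
    phi = np.exp(log_phi)

    alpha = np.stack([alpha_trapezoid(years, s) for s in shapes])
    theta = srb_mean(config.baseline_b, phi, 1, alpha * np.array(deltas)[:, None])

    tfr_end_year = horizon_year if horizon_year is not None else config.year_end
    tfr_years = range(config.year_start, tfr_end_year + 1)
    tfr = {}
    for p, prov in enumerate(config.provinces):
        # stagger the fertility decline so start-year prior locations differ
        tfr[prov] = simulate_tfr_series(
            prov, config.tfr_start, config.tfr_end, tfr_years,
            config.tfr_midpoint_year + 2.0 * (p % 4), config.tfr_steepness)
    return SyntheticDataset(config=config, phi=phi, alpha=alpha, theta=theta,
                            deltas=deltas, shapes=shapes, tfr=tfr)


def simulate_observations(
    truth: SyntheticDataset,
    births_per_obs: int | None = None,
    n_clusters: int | None = None,
    obs_schedule: Sequence[ObsSpec] | None = None,
    seed: int | None = None,
) -> SyntheticDataset:
    """Synthesize survey-style observations on top of a truth dataset.

    For each scheduled observation the total births are spread uniformly
    over the reference-period years and multinomially across clusters; each
    birth is male with probability Theta_t / (1 + Theta_t). The reported
    ratio and its jackknife log-scale standard error are then computed with
    the same routines used on real data. Degenerate draws (zero female
    births overall, or a jackknife replicate with zero of either sex —
    possible only at tiny counts) are redrawn and counted.
    """
    cfg = truth.config
    births = births_per_obs if births_per_obs is not None else cfg.births_per_obs
    k = n_clusters if n_clusters is not None else cfg.n_clusters
    schedule = obs_schedule if obs_schedule is not None else cfg.obs_schedule
    base_seed = seed if seed is not None else cfg.seed
    rng = np.random.default_rng(np.random.SeedSequence([base_seed, 202]))
    if births < k or k < 2:
        raise ContractError("need births_per_obs >= n_clusters >= 2")

    years = cfg.years
    year0 = int(years[0])
    observations = []
    redraws = 0
    for p, prov in enumerate(cfg.provinces):
        for spec in schedule:
            period = np.arange(spec.period_start, spec.period_end + 1)
            idx = period - year0
            if idx.min() < 0 or idx.max() >= len(years):
                raise ContractError(
                    f"scheduled period {spec.period_start}-{spec.period_end} "
                    "outside the truth grid")
            p_male = truth.theta[p, idx] / (1.0 + truth.theta[p, idx])
            for _attempt in range(100):
                per_year = rng.multinomial(births, np.full(len(period), 1.0 / len(period)))
                # split each year's births across clusters, then sex by year
                male_by_cluster = np.zeros(k)
                female_by_cluster = np.zeros(k)
                for j, n_t in enumerate(per_year):
                    if n_t == 0:
                        continue
                    cluster_counts = rng.multinomial(n_t, np.full(k, 1.0 / k))
                    males = rng.binomial(cluster_counts, p_male[j])
                    male_by_cluster += males
                    female_by_cluster += cluster_counts - males
                m_tot, f_tot = male_by_cluster.sum(), female_by_cluster.sum()
                if m_tot == 0 or f_tot == 0:
                    redraws += 1
                    continue
                clusters = [ClusterBirths(str(i), m, f) for i, (m, f)
                            in enumerate(zip(male_by_cluster, female_by_cluster))]
                try:
                    sigma = data_io.jackknife_log_se(clusters)
                except ContractError:
                    redraws += 1
                    continue
                if sigma == 0.0:
                    redraws += 1  # all replicates identical; not survey-like
                    continue
                break
            else:
                raise ContractError("could not draw a non-degenerate observation")
            observations.append(SRBObservation(
                province=prov, source=spec.source,
                period_start=spec.period_start, period_end=spec.period_end,
                male_births=float(m_tot), female_births=float(f_tot),
                srb=float(m_tot / f_tot), log_se=sigma,
                survey_year=spec.survey_year,
            ))
    if redraws:
        import logging
        logging.getLogger(__name__).info("redrew %d degenerate observations", redraws)
    obs_set = ObservationSet(tuple(observations), cfg.provinces)
    return SyntheticDataset(
        config=cfg, phi=truth.phi, alpha=truth.alpha, theta=truth.theta,
        deltas=truth.deltas, shapes=truth.shapes, tfr=truth.tfr,
        observations=obs_set)


def simulate_dataset(config: ScenarioConfig, horizon_year: int | None = None) -> SyntheticDataset:
    """Convenience: truth plus observations in one call."""
    return simulate_observations(simulate_truth(config, horizon_year=horizon_year))


def prior_predictive_scenario(seed: int = 0, model_config=None,
                              base: ScenarioConfig | None = None) -> ScenarioConfig:
    """Scenario whose inflation indicators and trapezoid shapes are drawn
    from the estimation model's own prior.

    This makes the generative process exactly the model's prior predictive,
    which is the setting in which Bayesian interval coverage is nominal by
    construction — the right study condition for calibration checks of the
    predictive machinery. Fixed-truth scenarios (specific deltas and shape
    values) instead probe recovery on particular slices of parameter space.
    """
    from .inference import _truncnorm_draw
    from .model import ModelConfig, start_year_location

    mc = model_config or ModelConfig()
    cfg = base or ScenarioConfig(seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 606]))
    # hyperparameters from their hyperpriors
    mu_l = rng.normal([mc.mu0_len_increase, mc.mu0_len_stagnation,
                       mc.mu0_len_decrease], mc.mu0_sd_lengths)
    sd_l = np.abs(rng.normal(0.0, mc.sd_scale_lengths, 3))
    mu_xi = rng.normal(mc.mu0_max_inflation, mc.mu0_sd_max_inflation)
    sd_xi = abs(rng.normal(0.0, mc.sd_scale_max_inflation))
    # start-year prior locations need the fertility curves of the scenario
    tfr = {
        prov: simulate_tfr_series(
            prov, cfg.tfr_start, cfg.tfr_end,
            range(cfg.year_start, cfg.year_end + 1),
            cfg.tfr_midpoint_year + 2.0 * (p % 4), cfg.tfr_steepness)
        for p, prov in enumerate(cfg.provinces)
    }
    deltas, shapes = [], []
    from scipy.stats import t as student_t

    lo, hi = mc.t0_window
    for prov in cfg.provinces:
        pi = rng.uniform()
        deltas.append(int(rng.uniform() < pi))
        loc = start_year_location(tfr[prov], mc.f_star)
        u = rng.uniform(student_t.cdf((lo - loc) / mc.start_year_scale, mc.start_year_df),
                        student_t.cdf((hi - loc) / mc.start_year_scale, mc.start_year_df))
        t0 = loc + mc.start_year_scale * float(student_t.ppf(u, mc.start_year_df))
        while True:
            l1 = float(_truncnorm_draw(rng, mu_l[0], sd_l[0]))
            l2 = float(_truncnorm_draw(rng, mu_l[1], sd_l[1]))
            l3 = float(_truncnorm_draw(rng, mu_l[2], sd_l[2]))
            xi = float(_truncnorm_draw(rng, mu_xi, sd_xi))
            if l1 > 0 and l3 > 0:
                break
        shapes.append(TransitionShape(t0, l1, l2, l3, xi))
    import dataclasses

    return dataclasses.replace(cfg, deltas=tuple(deltas), shapes=tuple(shapes),
                               seed=seed)


def strong_signal_scenario(seed: int = 0) -> ScenarioConfig:
    """Scenario with unambiguous inflations: 0.10 maximum inflation in the
    odd-numbered provinces and surveys of about 5,000 births, so the
    inflation indicator is statistically identifiable from a single fit.
    Used for indicator-classification checks."""
    shapes = tuple(
        TransitionShape(
            t0=1998.0 + 3.0 * (p % 4),
            len_increase=10.0 + (p % 3),
            len_stagnation=12.0,
            len_decrease=13.0,
            max_inflation=0.10 if (p + 1) % 2 else 0.0)
        for p in range(7))
    return ScenarioConfig(deltas=(1, 0, 1, 0, 1, 0, 1), shapes=shapes,
                          births_per_obs=5000, seed=seed)
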