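"""Model assessment: out-of-sample validation and parameter-recovery study.

Out-of-sample validation mirrors the retrospective structure of the data:
rather than a random split, all observations collected by the most recent
survey wave (survey year at or after a cutoff) are held out, the model is
refit on the remainder, and the held-out points are scored against their
posterior predictive distributions. The simulation study generates data
with known ground truth, refits, and scores recovery of the SRB
trajectories, trapezoid parameters and inflation indicators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .inference import MCMCConfig, PosteriorSamples, fit_mcmc
from .model import ModelConfig
from .structures import ContractError, ObservationSet, SRBObservation
from .synthetic import ScenarioConfig, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictiveDistribution:
    """Posterior predictive of one held-out observation's log ratio."""

    observation: SRBObservation
    log_pred_draws: np.ndarray  # draws of log Theta at the midpoint year + noise

    def interval(self, level: float) -> tuple[float, float]:
        tail = (1.0 - level) / 2.0
        return (float(np.quantile(self.log_pred_draws, tail)),
                float(np.quantile(self.log_pred_draws, 1.0 - tail)))

    @property
    def median(self) -> float:
        return float(np.median(self.log_pred_draws))


@dataclass(frozen=True)
class ValidationReport:
    n_heldout: int
    heldout_share: float
    median_error: float          # log scale: observed - predictive median
    mean_error: float
    mean_abs_error: float
    coverage80: float
    coverage95: float
    by_province: dict = field(default_factory=dict)


@dataclass(frozen=True)
class RecoveryReport:
    n_replicates: int
    n_excluded: int
    theta_bias: float
    theta_rmse: float
    theta_coverage95: float
    xi_coverage95: float | None
    t0_coverage95: float | None
    delta_classification: dict      # counts keyed "true<d>_pred<d>"
    delta_accuracy: float


def holdout_split(
    data: ObservationSet, cutoff_year: int = 2016
) -> tuple[ObservationSet, ObservationSet]:
    """Deterministic rule-based split: observations collected (survey year)
    in or after the cutoff form the test set; everything else — earlier
    surveys and censuses — trains the model."""
    test = [o for o in data
            if o.survey_year is not None and o.survey_year >= cutoff_year]
    train = [o for o in data
             if not (o.survey_year is not None and o.survey_year >= cutoff_year)]
    if not test:
        raise ContractError(
            f"holdout cutoff {cutoff_year} leaves an empty test set")
    return (data.replace_observations(train), data.replace_observations(test))


def predictive_distributions(
    samples: PosteriorSamples,
    test: ObservationSet,
    seed: int = 0,
) -> list[PredictiveDistribution]:
    """Posterior predictive draws for each held-out observation.

    The predictive for a held-out ratio is the posterior of log Theta at
    the observation's midpoint year plus N(0, sigma^2) sampling noise with
    the observation's own precomputed standard error.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    theta = samples.theta_draws()   # (n, P, T)
    year0 = int(samples.years[0])
    out = []
    for o in test:
        p = samples.province_index(o.province)
        t = o.reference_year - year0
        if t < 0 or t >= theta.shape[2]:
            raise ContractError(
                f"held-out observation at {o.reference_year} outside the grid")
        draws = np.log(theta[:, p, t]) + rng.normal(0.0, o.log_se, theta.shape[0])
        out.append(PredictiveDistribution(o, draws))
    return out


def coverage_metrics(
    test: ObservationSet,
    predictive: Sequence[PredictiveDistribution],
    levels: Sequence[float] = (0.8, 0.95),
    total_n: int | None = None,
) -> ValidationReport:
    """Score held-out observations against their predictive distributions.

    Errors are on the log scale (observed log ratio minus predictive
    median); empirical coverage is the share of held-out log ratios inside
    each nominal predictive interval. A well-calibrated but conservative
    model shows empirical coverage at or above nominal.
    """
    if len(predictive) != len(test):
        raise ContractError("each held-out observation needs a predictive "
                            "distribution (length mismatch)")
    keyed = {id(pd_.observation): pd_ for pd_ in predictive}
    for o in test:
        if id(o) not in keyed:
            raise ContractError(
                f"no predictive distribution matches observation {o.province!r} "
                f"{o.period_start}-{o.period_end}")
    errors, inside = [], {lv: [] for lv in levels}
    by_prov: dict[str, list[float]] = {}
    for o in test:
        pd_ = keyed[id(o)]
        lr = float(np.log(o.srb))
        err = lr - pd_.median
        errors.append(err)
        by_prov.setdefault(o.province, []).append(err)
        for lv in levels:
            lo, hi = pd_.interval(lv)
            inside[lv].append(lo <= lr <= hi)
    errors = np.asarray(errors)
    share = len(test) / total_n if total_n else float("nan")
    return ValidationReport(
        n_heldout=len(test),
        heldout_share=share,
        median_error=float(np.median(errors)),
        mean_error=float(np.mean(errors)),
        mean_abs_error=float(np.mean(np.abs(errors))),
        coverage80=float(np.mean(inside[0.8])) if 0.8 in inside else float("nan"),
        coverage95=float(np.mean(inside[0.95])) if 0.95 in inside else float("nan"),
        by_province={p: {"n": len(v), "mean_error": float(np.mean(v))}
                     for p, v in by_prov.items()},
    )


def simulation_study(
    scenario: ScenarioConfig,
    n_replicates: int,
    mcmc_config: MCMCConfig | None = None,
    seed: int = 0,
    model_config: ModelConfig | None = None,
) -> RecoveryReport:
    """Parameter-recovery study: simulate, fit, score, repeat.

    Each replicate draws a fresh dataset from the scenario (fresh seed),
    fits the model, and scores: bias/RMSE and 95% credible-interval
    coverage of the true SRB over the estimation grid, interval coverage of
    the trapezoid maximum and start year for truly-inflated provinces
    (conditional on delta=1 draws), and classification of the inflation
    indicator by whether the posterior probability falls on the correct
    side of 0.5. Replicates whose worst split-R-hat exceeds the configured
    threshold are excluded and counted, never silently averaged.
    """
    import dataclasses

    mc = mcmc_config or MCMCConfig(n_warmup=300, n_samples=700)
    root = np.random.SeedSequence([seed, 505])
    rep_seeds = root.generate_state(2 * n_replicates)[:n_replicates] % (2**31 - 1)

    theta_err, theta_cover = [], []
    xi_cover, t0_cover = [], []
    cls = {"true0_pred0": 0, "true0_pred1": 0, "true1_pred0": 0, "true1_pred1": 0}
    excluded = 0
    for r in range(n_replicates):
        sc = dataclasses.replace(scenario, seed=int(rep_seeds[r]))
        ds = simulate_dataset(sc)
        mcfg = model_config or ModelConfig(
            year_start=sc.year_start, year_end=sc.year_end)
        mcr = dataclasses.replace(mc, seed=int(rep_seeds[r]) + 1)
        samples = fit_mcmc(ds.observations, ds.tfr, mcfg, mcr)
        if samples.diagnostics.get("max_rhat", 1.0) > mcr.rhat_threshold:
            excluded += 1
            logger.warning("replicate %d excluded: max R-hat %.3f", r,
                           samples.diagnostics["max_rhat"])
            continue
        theta = samples.theta_draws()                      # (n, P, T)
        med = np.median(theta, axis=0)
        lo = np.quantile(theta, 0.025, axis=0)
        hi = np.quantile(theta, 0.975, axis=0)
        theta_err.append(med - ds.theta)
        theta_cover.append((lo <= ds.theta) & (ds.theta <= hi))
        delta_flat = samples._flat(samples.delta)
        sh = samples.shapes_flat()
        for p, prov in enumerate(samples.provinces):
            prob = float(delta_flat[:, p].mean())
            true_d = ds.deltas[p]
            pred_d = int(prob > 0.5)
            cls[f"true{true_d}_pred{pred_d}"] += 1
            if true_d == 1:
                on = delta_flat[:, p].astype(bool)
                if on.any():
                    xi_draws = sh["max_inflation"][on, p]
                    t0_draws = sh["t0"][on, p]
                    xi_cover.append(
                        np.quantile(xi_draws, 0.025) <= ds.shapes[p].max_inflation
                        <= np.quantile(xi_draws, 0.975))
                    t0_cover.append(
                        np.quantile(t0_draws, 0.025) <= ds.shapes[p].t0
                        <= np.quantile(t0_draws, 0.975))
    if not theta_err:
        raise ContractError("all replicates excluded; nothing to report")
    err = np.concatenate([e.ravel() for e in theta_err])
    cov = np.concatenate([c.ravel() for c in theta_cover])
    total = sum(cls.values())
    correct = cls["true0_pred0"] + cls["true1_pred1"]
    return RecoveryReport(
        n_replicates=n_replicates,
        n_excluded=excluded,
        theta_bias=float(np.mean(err)),
        theta_rmse=float(np.sqrt(np.mean(err**2))),
        theta_coverage95=float(np.mean(cov)),
        xi_coverage95=float(np.mean(xi_cover)) if xi_cover else None,
        t0_coverage95=float(np.mean(t0_cover)) if t0_cover else None,
        delta_classification=cls,
        delta_accuracy=correct / total if total else float("nan"),
    )
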