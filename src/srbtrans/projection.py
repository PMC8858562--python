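"""Probabilistic SRB projection by forward-simulating posterior draws.

Each retained posterior draw carries a fluctuation path, an inflation
indicator and a trapezoid shape; projection extends the log-scale AR(1)
fluctuation forward by simulation and evaluates the draw's trapezoid
through the horizon, so draws whose transition starts in the future
realize the "may yet inflate, with a probability" part of the posterior.
The estimation-period summaries are never altered: projection appends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .inference import PosteriorSamples
from .structures import ContractError, ObservationSet, TFRSeries


@dataclass(frozen=True)
class ProjectionResult:
    """Trajectory quantiles by province-year plus peak/convergence summaries.

    The trajectory starts at the fit's last estimation year (repeated from
    the estimation summary, for continuity) and runs to the horizon.
    """

    table: pd.DataFrame  # columns: province, year, quantile_0.025/0.5/0.975
    baseline: float
    first_projection_year: int
    horizon_year: int
    convergence_tolerance: float

    def for_province(self, province: str) -> pd.DataFrame:
        out = self.table[self.table["province"] == province]
        if out.empty:
            raise KeyError(f"unknown province {province!r}")
        return out.reset_index(drop=True)

    def convergence_year(self, province: str) -> int | None:
        """First year after the median peak with |median - b| within tolerance."""
        df = self.for_province(province)
        med = df["quantile_0.5"].to_numpy()
        years = df["year"].to_numpy()
        peak = int(np.argmax(med))
        for j in range(peak, len(years)):
            if abs(med[j] - self.baseline) < self.convergence_tolerance:
                return int(years[j])
        return None


def project_srb(
    samples: PosteriorSamples,
    horizon_year: int = 2050,
    tfr_projection: Mapping[str, TFRSeries] | None = None,
    seed: int = 0,
    quantiles: Sequence[float] = (0.025, 0.5, 0.975),
    convergence_tolerance: float = 0.002,
) -> ProjectionResult:
    """Project the SRB of every province from the last estimation year to
    ``horizon_year``.

    ``tfr_projection``, when given, must cover the projection horizon for
    every province; it is validated and recorded but the projection itself
    needs no further fertility input (the fertility squeeze enters through
    the already-sampled start years). Reproducible for a fixed seed.
    """
    cfg = samples.model_config
    last_year = int(samples.years[-1])
    if horizon_year <= last_year:
        raise ContractError(
            f"horizon {horizon_year} must lie after the last estimation "
            f"year {last_year}")
    if tfr_projection is not None:
        future = range(last_year + 1, horizon_year + 1)
        missing = [p for p in samples.provinces
                   if p not in tfr_projection
                   or not tfr_projection[p].covers(future)]
        if missing:
            raise ContractError(
                "TFR projection does not cover the horizon for: "
                + ", ".join(missing))

    g = cfg.globals_
    H = horizon_year - last_year
    phi_last = samples._flat(samples.phi)[:, :, -1]      # (n, P)
    n, P = phi_last.shape
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    log_phi = np.empty((n, P, H + 1))
    log_phi[:, :, 0] = np.log(phi_last)
    innov = rng.normal(0.0, g.sigma_ar, size=(n, P, H))
    for h in range(1, H + 1):
        log_phi[:, :, h] = g.rho * log_phi[:, :, h - 1] + innov[:, :, h - 1]

    years = np.arange(last_year, horizon_year + 1)
    alpha = samples.alpha_draws(years)                   # (n, P, H+1)
    delta = samples._flat(samples.delta)[:, :, None]
    theta = g.b * np.exp(log_phi) + np.where(delta.astype(bool), alpha, 0.0)
    qs = np.quantile(theta, quantiles, axis=0)           # (Q, P, H+1)

    rows = []
    for p, prov in enumerate(samples.provinces):
        for j, y in enumerate(years):
            row = {"province": prov, "year": int(y)}
            for qi, q in enumerate(quantiles):
                row[f"quantile_{q}"] = float(qs[qi, p, j])
            rows.append(row)
    return ProjectionResult(
        table=pd.DataFrame(rows), baseline=g.b,
        first_projection_year=last_year + 1, horizon_year=horizon_year,
        convergence_tolerance=convergence_tolerance)


def max_inflation_year(result: ProjectionResult, province: str) -> tuple[int, float]:
    """Year the projected median SRB peaks (ties break to the earliest year)
    and the median SRB in that year."""
    df = result.for_province(province)
    med = df["quantile_0.5"].to_numpy()
    j = int(np.argmax(med))  # argmax returns the first maximum
    return int(df["year"].iloc[j]), float(med[j])


@dataclass(frozen=True)
class TransitionCoverage:
    """How much of each province's sex ratio transition is seen by data."""

    fraction_by_province: dict[str, float]   # posterior median fractions
    years_covered_by_province: dict[str, float]
    length_by_province: dict[str, float]
    mean_years_covered: float
    mean_length: float

    @property
    def mean_fraction(self) -> float:
        return self.mean_years_covered / self.mean_length


def transition_data_coverage(
    samples: PosteriorSamples,
    data: ObservationSet,
) -> TransitionCoverage:
    """Share of the transition period covered by observation periods.

    For each posterior draw and province, counts the integer years inside
    [t0, t0 + total transition length] whose year is overlapped by at least
    one of the province's observation periods, divided by the transition
    length. Reports posterior medians per province plus across-province
    averages of years covered and transition length.
    """
    y_min, y_max = 1900, 2200
    n_years = y_max - y_min + 1
    covered = np.zeros((len(samples.provinces), n_years), dtype=bool)
    for o in data:
        p = samples.province_index(o.province)
        covered[p, o.period_start - y_min:o.period_end - y_min + 1] = True
    # cumulative count of covered years up to and including each year
    cum = np.concatenate([np.zeros((covered.shape[0], 1)),
                          np.cumsum(covered, axis=1)], axis=1)

    sh = samples.shapes_flat()
    t0 = sh["t0"]
    length = sh["len_increase"] + sh["len_stagnation"] + sh["len_decrease"]
    end = t0 + length
    # integer years in the half-open interval [t0, end)
    a = np.clip(np.ceil(t0).astype(int) - y_min, 0, n_years)
    b = np.clip(np.ceil(end).astype(int) - y_min, 0, n_years)
    n, P = t0.shape
    rows = np.repeat(np.arange(P)[None, :], n, axis=0)
    years_covered = cum[rows, b] - cum[rows, a]          # (n, P)
    fraction = years_covered / length

    frac_med = np.median(fraction, axis=0)
    yrs_med = np.median(years_covered, axis=0)
    len_med = np.median(length, axis=0)
    provs = samples.provinces
    return TransitionCoverage(
        fraction_by_province={p: float(f) for p, f in zip(provs, frac_med)},
        years_covered_by_province={p: float(v) for p, v in zip(provs, yrs_med)},
        length_by_province={p: float(v) for p, v in zip(provs, len_med)},
        mean_years_covered=float(np.mean(yrs_med)),
        mean_length=float(np.mean(len_med)),
    )
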