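"""Core containers for subnational sex-ratio-at-birth (SRB) analysis.

The spatial unit throughout is the *province*; the temporal unit is the
integer calendar year. Observed SRB values ``r`` are dimensionless
male/female birth ratios with a precomputed sampling error ``log_se``
on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np


class ValidationError(ValueError):
    """An input record violates a domain invariant."""


class ContractError(ValueError):
    """A precondition of an operation was violated by the caller."""


@dataclass(frozen=True)
class SRBObservation:
    """One survey or census SRB data point for a province.

    ``period_start``..``period_end`` (inclusive) is the reference period the
    births fall in; retrospective surveys carry ``survey_year`` (the year the
    data were collected), censuses leave it ``None``. ``srb`` is the
    male/female ratio and ``log_se`` its sampling standard error on the log
    scale, typically from a delete-one-cluster jackknife.
    """

    province: str
    source: str
    period_start: int
    period_end: int
    srb: float
    log_se: float
    male_births: float | None = None
    female_births: float | None = None
    survey_year: int | None = None

    def __post_init__(self) -> None:
        if self.period_start > self.period_end:
            raise ValidationError(
                f"period_start {self.period_start} > period_end {self.period_end}"
            )
        if not self.srb > 0:
            raise ValidationError(f"srb must be positive, got {self.srb}")
        if not self.log_se > 0:
            raise ValidationError(f"log_se must be positive, got {self.log_se}")
        if self.male_births is not None:
            if self.male_births < 0:
                raise ValidationError("male_births must be >= 0")
            if self.female_births is None or not self.female_births > 0:
                raise ValidationError("female_births must be > 0 when counts present")
            if not np.isclose(self.srb, self.male_births / self.female_births,
                              rtol=1e-6, atol=1e-9):
                raise ValidationError(
                    "srb inconsistent with male_births/female_births "
                    f"({self.srb} vs {self.male_births / self.female_births})"
                )

    @property
    def reference_year(self) -> int:
        """Midpoint of the reference period, rounded down to a model year."""
        return (self.period_start + self.period_end) // 2

    @property
    def total_births(self) -> float | None:
        if self.male_births is None or self.female_births is None:
            return None
        return self.male_births + self.female_births

    @property
    def is_census(self) -> bool:
        return self.survey_year is None


@dataclass(frozen=True)
class ClusterBirths:
    """Weighted sex-specific birth counts for one sampling cluster."""

    cluster_id: str
    male_births: float
    female_births: float

    def __post_init__(self) -> None:
        if self.male_births < 0 or self.female_births < 0:
            raise ValidationError("cluster birth counts must be >= 0")


@dataclass(frozen=True)
class TFRSeries:
    """Annual total fertility rate (children per woman) for one province."""

    province: str
    years: tuple[int, ...]
    tfr: tuple[float, ...]

    def __post_init__(self) -> None:
        years = np.asarray(self.years)
        tfr = np.asarray(self.tfr, dtype=float)
        if years.size != tfr.size:
            raise ValidationError("years and tfr must have equal length")
        if years.size and np.any(np.diff(years) != 1):
            raise ValidationError("years must be contiguous")
        if np.any(tfr <= 0):
            raise ValidationError("tfr must be positive")

    def at(self, year: int) -> float:
        idx = year - self.years[0]
        if idx < 0 or idx >= len(self.years):
            raise KeyError(f"year {year} outside TFR series for {self.province}")
        return self.tfr[idx]

    def covers(self, years: Iterable[int]) -> bool:
        ys = set(self.years)
        return all(y in ys for y in years)


@dataclass(frozen=True)
class ObservationSet:
    """A validated collection of SRB observations over an ordered province set."""

    observations: tuple[SRBObservation, ...]
    provinces: tuple[str, ...]

    def __post_init__(self) -> None:
        known = set(self.provinces)
        for i, obs in enumerate(self.observations):
            if obs.province not in known:
                raise ValidationError(
                    f"observation {i}: province {obs.province!r} not in province set"
                )

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self) -> Iterator[SRBObservation]:
        return iter(self.observations)

    def for_province(self, province: str) -> tuple[SRBObservation, ...]:
        return tuple(o for o in self.observations if o.province == province)

    def total_births(self) -> float:
        """Sum of male+female births over records that carry counts."""
        return float(sum(o.total_births or 0.0 for o in self.observations))

    def births_by_source(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for o in self.observations:
            out[o.source] = out.get(o.source, 0.0) + (o.total_births or 0.0)
        return out

    def counts_by_source(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for o in self.observations:
            out[o.source] = out.get(o.source, 0) + 1
        return out

    def replace_observations(self, observations: Sequence[SRBObservation]) -> "ObservationSet":
        return ObservationSet(tuple(observations), self.provinces)


@dataclass(frozen=True)
class TransitionShape:
    """Trapezoid sex-ratio-transition shape for one province.

    The inflation rises linearly from 0 at ``t0`` (the start year) to
    ``max_inflation`` over ``len_increase`` years, stays flat for
    ``len_stagnation`` years, and declines linearly back to 0 over
    ``len_decrease`` years.
    """

    t0: float
    len_increase: float
    len_stagnation: float
    len_decrease: float
    max_inflation: float

    def __post_init__(self) -> None:
        if not self.len_increase > 0 or not self.len_decrease > 0:
            raise ValidationError("len_increase and len_decrease must be > 0")
        if self.len_stagnation < 0:
            raise ValidationError("len_stagnation must be >= 0")
        if self.max_inflation < 0:
            raise ValidationError("max_inflation must be >= 0 (no deflation)")

    @property
    def total_length(self) -> float:
        return self.len_increase + self.len_stagnation + self.len_decrease

    @property
    def end_year(self) -> float:
        return self.t0 + self.total_length


@dataclass(frozen=True)
class GlobalParams:
    """National-level constants of the SRB model.

    ``b`` is the national SRB baseline (fixed, not estimated); ``rho`` and
    ``sigma_ar`` are the AR(1) autocorrelation and innovation standard
    deviation of the log-scale natural-fluctuation process.
    """

    b: float = 1.049
    rho: float = 0.9
    sigma_ar: float = 0.004

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValidationError("baseline b must be positive")
        if not 0 < self.rho < 1:
            raise ValidationError("rho must lie in (0, 1)")
        if not self.sigma_ar > 0:
            raise ValidationError("sigma_ar must be positive")

    @property
    def stationary_sd(self) -> float:
        return self.sigma_ar / np.sqrt(1.0 - self.rho**2)


@dataclass(frozen=True)
class ProvinceState:
    """Latent state of one province at one MCMC draw."""

    phi: np.ndarray            # per-year natural fluctuation, > 0
    delta: int                 # inflation indicator in {0, 1}
    shape: TransitionShape
    prob_delta: float          # province-specific Bernoulli mean

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.phi) <= 0):
            raise ValidationError("phi must be positive for all years")
        if self.delta not in (0, 1):
            raise ValidationError("delta must be 0 or 1")
        if not 0.0 <= self.prob_delta <= 1.0:
            raise ValidationError("prob_delta must lie in [0, 1]")
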