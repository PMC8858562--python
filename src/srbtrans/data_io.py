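"""Reading, writing and preprocessing of the provincial SRB database.

Implements the survey-data preprocessing pipeline: pooling of one-year
observations into multi-year periods until the coefficient of variation of
the pooled ratio is acceptable, delete-one-cluster jackknife sampling
errors, a recall-window filter for retrospective birth histories, and
inverse-probability weighting of partially sampled census districts.

CSV schema for the observation database (one header row, comma separated):

    province,source,period_start,period_end,male_births,female_births,srb,log_se,survey_year

``male_births``/``female_births``/``survey_year`` may be empty. TFR series
use the schema ``province,year,tfr``.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .structures import (
    ClusterBirths,
    ContractError,
    ObservationSet,
    SRBObservation,
    TFRSeries,
    ValidationError,
)

logger = logging.getLogger(__name__)

SRB_COLUMNS = [
    "province", "source", "period_start", "period_end",
    "male_births", "female_births", "srb", "log_se", "survey_year",
]
TFR_COLUMNS = ["province", "year", "tfr"]


class SchemaError(ValueError):
    """The input file does not match the documented CSV schema."""


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def _opt_int(v) -> int | None:
    f = _opt_float(v)
    return None if f is None else int(f)


def load_srb_database(path) -> ObservationSet:
    """Read an SRB observation database CSV into a validated ObservationSet.

    Provinces are ordered by first appearance. Per-source record and birth
    totals are logged (queryable via :meth:`ObservationSet.counts_by_source`
    and :meth:`ObservationSet.births_by_source`) but no particular totals
    are enforced.
    """
    df = pd.read_csv(path)
    missing = [c for c in SRB_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    observations = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            observations.append(SRBObservation(
                province=str(row.province),
                source=str(row.source),
                period_start=int(row.period_start),
                period_end=int(row.period_end),
                male_births=_opt_float(row.male_births),
                female_births=_opt_float(row.female_births),
                srb=float(row.srb),
                log_se=float(row.log_se),
                survey_year=_opt_int(row.survey_year),
            ))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    provinces = tuple(dict.fromkeys(o.province for o in observations))
    obs_set = ObservationSet(tuple(observations), provinces)
    logger.info("loaded %d observations, %.0f births, sources: %s",
                len(obs_set), obs_set.total_births(), obs_set.counts_by_source())
    return obs_set


def write_srb_database(obs_set: ObservationSet, path) -> None:
    """Write an ObservationSet back to the documented CSV schema."""
    rows = [{
        "province": o.province, "source": o.source,
        "period_start": o.period_start, "period_end": o.period_end,
        "male_births": o.male_births, "female_births": o.female_births,
        "srb": o.srb, "log_se": o.log_se, "survey_year": o.survey_year,
    } for o in obs_set]
    pd.DataFrame(rows, columns=SRB_COLUMNS).to_csv(path, index=False)


def load_tfr(path) -> dict[str, TFRSeries]:
    """Read per-province annual TFR series from CSV."""
    df = pd.read_csv(path)
    missing = [c for c in TFR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    out: dict[str, TFRSeries] = {}
    for prov, grp in df.groupby("province", sort=False):
        grp = grp.sort_values("year")
        out[str(prov)] = TFRSeries(
            province=str(prov),
            years=tuple(int(y) for y in grp["year"]),
            tfr=tuple(float(v) for v in grp["tfr"]),
        )
    return out


def write_tfr(series: Mapping[str, TFRSeries], path) -> None:
    rows = [{"province": s.province, "year": y, "tfr": v}
            for s in series.values() for y, v in zip(s.years, s.tfr)]
    pd.DataFrame(rows, columns=TFR_COLUMNS).to_csv(path, index=False)


def ratio_cv(male: float, female: float) -> float:
    """Delta-method coefficient of variation of a ratio of counts.

    For a ratio r = m/f of independent count totals the relative variance is
    approximately 1/m + 1/f, so CV = sqrt(1/m + 1/f); on the log scale this
    equals the approximate standard error of log r.
    """
    if male <= 0 or female <= 0:
        raise ContractError("ratio_cv requires positive counts")
    return math.sqrt(1.0 / male + 1.0 / female)


def merge_observation_periods(
    annual_obs: Sequence[SRBObservation], cv_max: float
) -> list[SRBObservation]:
    """Pool consecutive one-year observations until the ratio CV is acceptable.

    Walks the sorted annual records of one province-source block left to
    right, accumulating male and female births until the pooled
    CV = sqrt(1/m + 1/f) drops to ``cv_max`` or below, then emits a
    multi-year record with the pooled counts, recomputed SRB and log-scale
    standard error set to the pooled CV. A terminal remainder that cannot
    reach ``cv_max`` is emitted as-is with a warning. Total births are
    conserved.
    """
    if not annual_obs:
        return []
    provinces = {o.province for o in annual_obs}
    sources = {o.source for o in annual_obs}
    if len(provinces) > 1 or len(sources) > 1:
        raise ContractError("merge requires a single province-source block")
    years = [o.period_start for o in annual_obs]
    if any(o.period_start != o.period_end for o in annual_obs):
        raise ContractError("merge expects one-year input periods")
    if years != sorted(years):
        raise ContractError("annual observations must be sorted by year")
    if any(o.male_births is None or o.female_births is None for o in annual_obs):
        raise ContractError("merge requires birth counts on every record")

    merged: list[SRBObservation] = []
    buf: list[SRBObservation] = []
    m = f = 0.0
    for obs in annual_obs:
        buf.append(obs)
        m += obs.male_births
        f += obs.female_births
        if m > 0 and f > 0 and ratio_cv(m, f) <= cv_max:
            merged.append(_pooled(buf, m, f))
            buf, m, f = [], 0.0, 0.0
    if buf:
        if m <= 0 or f <= 0:
            raise ContractError("terminal remainder has zero male or female births")
        logger.warning(
            "terminal remainder %d-%d has CV %.4f > cv_max %.4f; emitted as-is",
            buf[0].period_start, buf[-1].period_end, ratio_cv(m, f), cv_max)
        merged.append(_pooled(buf, m, f))
    return merged


def _pooled(buf: list[SRBObservation], m: float, f: float) -> SRBObservation:
    first, last = buf[0], buf[-1]
    return SRBObservation(
        province=first.province, source=first.source,
        period_start=first.period_start, period_end=last.period_end,
        male_births=m, female_births=f, srb=m / f, log_se=ratio_cv(m, f),
        survey_year=first.survey_year,
    )


def jackknife_log_se(clusters: Sequence[ClusterBirths]) -> float:
    """Delete-one-cluster jackknife standard error of log(SRB).

    With k clusters, let theta_hat_(i) be log of the male/female ratio
    computed from all clusters except i, and theta_bar their mean. The
    jackknife variance is ((k-1)/k) * sum_i (theta_hat_(i) - theta_bar)^2.
    Invariant to cluster order and to uniform rescaling of all weights.
    """
    k = len(clusters)
    if k < 2:
        raise ContractError("jackknife requires at least 2 clusters")
    male = np.array([c.male_births for c in clusters], dtype=float)
    female = np.array([c.female_births for c in clusters], dtype=float)
    m_tot, f_tot = male.sum(), female.sum()
    m_del, f_del = m_tot - male, f_tot - female
    bad = np.nonzero((m_del <= 0) | (f_del <= 0))[0]
    if bad.size:
        raise ContractError(
            "degenerate jackknife replicate: deleting cluster "
            f"{clusters[bad[0]].cluster_id!r} leaves zero male or female births")
    theta = np.log(m_del / f_del)
    var = (k - 1) / k * np.sum((theta - theta.mean()) ** 2)
    return float(np.sqrt(var))


def filter_recall_window(obs_set: ObservationSet, max_lag: int = 25) -> ObservationSet:
    """Drop survey observations recalled from too far before the survey year.

    A survey record is dropped when its period starts more than ``max_lag``
    years before the survey year (``period_start < survey_year - max_lag``);
    the boundary year is retained. Census records (no survey year) pass
    through untouched. Idempotent.
    """
    kept, dropped = [], 0
    for o in obs_set:
        if o.survey_year is not None and o.period_start < o.survey_year - max_lag:
            dropped += 1
        else:
            kept.append(o)
    if dropped:
        logger.info("recall filter dropped %d of %d observations (max_lag=%d)",
                    dropped, len(obs_set), max_lag)
    return obs_set.replace_observations(kept)


def aggregate_census_districts(
    district_births: pd.DataFrame,
    district_to_province: Mapping[str, str],
    source: str = "census",
    period_start: int = 0,
    period_end: int | None = None,
) -> list[SRBObservation]:
    """Aggregate district census birth counts to weighted provincial SRBs.

    ``district_births`` needs columns district, male, female,
    sampled_fraction. Each district's counts are inverse-probability
    weighted (divided by its sampled fraction) before summing within the
    province, correcting for districts where the census microdata sample
    covers only part of the population.
    """
    for col in ("district", "male", "female", "sampled_fraction"):
        if col not in district_births.columns:
            raise SchemaError(f"missing column(s): {col}")
    totals: dict[str, list[float]] = {}
    for row in district_births.itertuples(index=False):
        frac = float(row.sampled_fraction)
        if not 0 < frac <= 1:
            raise ValidationError(
                f"district {row.district!r}: sampled_fraction must be in (0, 1], got {frac}")
        if row.district not in district_to_province:
            raise KeyError(f"district {row.district!r} has no province mapping")
        prov = district_to_province[row.district]
        m, f = totals.setdefault(prov, [0.0, 0.0])
        totals[prov][0] = m + float(row.male) / frac
        totals[prov][1] = f + float(row.female) / frac
    out = []
    for prov, (m, f) in totals.items():
        out.append(SRBObservation(
            province=prov, source=source,
            period_start=period_start,
            period_end=period_end if period_end is not None else period_start,
            male_births=m, female_births=f, srb=m / f, log_se=ratio_cv(m, f),
            survey_year=None,
        ))
    return out
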