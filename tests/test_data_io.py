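import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hyp

import srbtrans.data_io as dio
from srbtrans.structures import (
    ClusterBirths,
    ContractError,
    ObservationSet,
    SRBObservation,
    ValidationError,
)


def _obs(province="Province 1", source="survey_2001", start=1990, end=1990,
         male=105.0, female=100.0, survey_year=2001, log_se=None):
    return SRBObservation(
        province=province, source=source, period_start=start, period_end=end,
        male_births=male, female_births=female, srb=male / female,
        log_se=log_se or dio.ratio_cv(male, female), survey_year=survey_year)


class TestLoadWrite:
    def test_loads_validated_rows_and_computes_totals(self, tmp_path):
        path = tmp_path / "db.csv"
        df = pd.DataFrame([
            {"province": "Province 1", "source": "survey_2001",
             "period_start": 1990, "period_end": 1994, "male_births": 105,
             "female_births": 100, "srb": 1.05, "log_se": 0.14,
             "survey_year": 2001},
            {"province": "Province 2", "source": "census_2011",
             "period_start": 2011, "period_end": 2011, "male_births": 520,
             "female_births": 500, "srb": 1.04, "log_se": 0.063,
             "survey_year": None},
        ])
        df.to_csv(path, index=False)
        obs = dio.load_srb_database(path)
        assert len(obs) == 2
        assert obs.observations[0].srb == pytest.approx(1.05)
        assert obs.total_births() == pytest.approx(1225)
        assert obs.counts_by_source() == {"survey_2001": 1, "census_2011": 1}
        assert obs.observations[1].is_census

    def test_empty_file_with_valid_header_gives_empty_set(self, tmp_path):
        path = tmp_path / "empty.csv"
        pd.DataFrame(columns=dio.SRB_COLUMNS).to_csv(path, index=False)
        obs = dio.load_srb_database(path)
        assert len(obs) == 0

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame(columns=[c for c in dio.SRB_COLUMNS if c != "log_se"]
                     ).to_csv(path, index=False)
        with pytest.raises(dio.SchemaError, match="log_se"):
            dio.load_srb_database(path)

    def test_nonpositive_sigma_reports_row_index(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame([{"province": "P", "source": "s", "period_start": 2000,
                       "period_end": 2000, "male_births": None,
                       "female_births": None, "srb": 1.05, "log_se": 0.0,
                       "survey_year": 2001}]).to_csv(path, index=False)
        with pytest.raises(ValidationError, match="row 0"):
            dio.load_srb_database(path)

    def test_round_trip_preserves_fields(self, tmp_path):
        original = ObservationSet(
            (_obs(), _obs(province="Province 2", source="census_2011",
                          start=2011, end=2011, survey_year=None)),
            ("Province 1", "Province 2"))
        path = tmp_path / "rt.csv"
        dio.write_srb_database(original, path)
        loaded = dio.load_srb_database(path)
        assert loaded.observations == original.observations
        # write again: byte-stable round trip
        path2 = tmp_path / "rt2.csv"
        dio.write_srb_database(loaded, path2)
        assert path.read_text() == path2.read_text()


class TestPeriodMerging:
    def test_precise_single_year_is_left_alone(self):
        obs = [_obs(start=2000, end=2000, male=20000, female=20000)]
        out = dio.merge_observation_periods(obs, cv_max=0.05)
        assert len(out) == 1
        assert out[0].period_start == out[0].period_end == 2000
        assert out[0].log_se == pytest.approx(math.sqrt(2 / 20000), abs=1e-12)

    def test_two_noisy_years_pool_into_one_period(self):
        obs = [_obs(start=y, end=y, male=500, female=500) for y in (2000, 2001)]
        out = dio.merge_observation_periods(obs, cv_max=0.05)
        assert len(out) == 1
        merged = out[0]
        assert (merged.period_start, merged.period_end) == (2000, 2001)
        assert merged.male_births == merged.female_births == 1000
        assert merged.log_se == pytest.approx(math.sqrt(2 / 1000), abs=1e-12)
        assert merged.srb == pytest.approx(1.0)

    def test_infinite_threshold_changes_nothing_but_periods(self):
        obs = [_obs(start=y, end=y, male=50 + y % 3, female=50) for y in range(2000, 2005)]
        out = dio.merge_observation_periods(obs, cv_max=math.inf)
        assert [(o.period_start, o.period_end) for o in out] == \
            [(y, y) for y in range(2000, 2005)]
        assert [o.male_births for o in out] == [o.male_births for o in obs]

    def test_terminal_remainder_emitted_with_warning(self, caplog):
        obs = [_obs(start=y, end=y, male=40, female=40) for y in (2000, 2001)]
        with caplog.at_level("WARNING", logger="srbtrans.data_io"):
            out = dio.merge_observation_periods(obs, cv_max=0.05)
        assert len(out) == 1  # pooled but still above threshold
        assert any("remainder" in r.message for r in caplog.records)

    def test_rejects_mixed_provinces_and_unsorted_years(self):
        mixed = [_obs(), _obs(province="Province 2")]
        with pytest.raises(ContractError):
            dio.merge_observation_periods(mixed, cv_max=0.1)
        unsorted_ = [_obs(start=2001, end=2001), _obs(start=2000, end=2000)]
        with pytest.raises(ContractError):
            dio.merge_observation_periods(unsorted_, cv_max=0.1)

    @settings(max_examples=30, deadline=None)
    @given(counts=hyp.lists(
        hyp.tuples(hyp.integers(5, 2000), hyp.integers(5, 2000)),
        min_size=1, max_size=12),
        cv_max=hyp.floats(0.01, 0.3))
    def test_merging_conserves_total_births(self, counts, cv_max):
        obs = [_obs(start=2000 + i, end=2000 + i, male=float(m), female=float(f))
               for i, (m, f) in enumerate(counts)]
        out = dio.merge_observation_periods(obs, cv_max=cv_max)
        assert sum(o.male_births for o in out) == pytest.approx(
            sum(m for m, _ in counts))
        assert sum(o.female_births for o in out) == pytest.approx(
            sum(f for _, f in counts))
        # periods tile the input range without overlap
        spans = [(o.period_start, o.period_end) for o in out]
        assert spans[0][0] == 2000
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert b0 == a1 + 1


class TestJackknife:
    def test_identical_clusters_have_zero_error(self):
        clusters = [ClusterBirths(str(i), 52, 50) for i in range(10)]
        assert dio.jackknife_log_se(clusters) == pytest.approx(0.0, abs=1e-15)

    def test_two_cluster_value_matches_hand_computation(self):
        clusters = [ClusterBirths("a", 60, 40), ClusterBirths("b", 40, 60)]
        # replicates are log(40/60) and log(60/40); sigma = log(1.5)
        assert dio.jackknife_log_se(clusters) == pytest.approx(
            math.log(1.5), abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(data=hyp.lists(
        hyp.tuples(hyp.floats(1, 500), hyp.floats(1, 500)),
        min_size=2, max_size=15),
        factor=hyp.floats(0.1, 10))
    def test_invariant_to_rescaling_and_order(self, data, factor):
        clusters = [ClusterBirths(str(i), m, f) for i, (m, f) in enumerate(data)]
        base = dio.jackknife_log_se(clusters)
        scaled = [ClusterBirths(c.cluster_id, factor * c.male_births,
                                factor * c.female_births) for c in clusters]
        assert dio.jackknife_log_se(scaled) == pytest.approx(base, rel=1e-9, abs=1e-12)
        assert dio.jackknife_log_se(clusters[::-1]) == pytest.approx(
            base, rel=1e-9, abs=1e-12)

    def test_degenerate_replicate_names_the_cluster(self):
        clusters = [ClusterBirths("a", 10, 10), ClusterBirths("b", 0, 5)]
        # deleting "b" leaves (10, 10); deleting "a" leaves (0, 5) -> bad
        with pytest.raises(ContractError, match="'a'"):
            dio.jackknife_log_se(clusters)

    def test_requires_two_clusters(self):
        with pytest.raises(ContractError):
            dio.jackknife_log_se([ClusterBirths("a", 10, 10)])


class TestRecallFilter:
    def _set(self, starts, survey_year=2016):
        obs = tuple(_obs(start=s, end=s + 1, survey_year=survey_year)
                    for s in starts)
        return ObservationSet(obs, ("Province 1",))

    def test_boundary_year_retained_and_older_dropped(self):
        data = self._set([2016 - 26, 2016 - 25, 2016 - 5])
        out = dio.filter_recall_window(data, max_lag=25)
        assert [o.period_start for o in out] == [1991, 2011]

    def test_zero_lag_keeps_only_the_survey_year(self):
        obs = tuple(_obs(start=s, end=s, survey_year=2016)
                    for s in (2014, 2015, 2016))
        out = dio.filter_recall_window(
            ObservationSet(obs, ("Province 1",)), max_lag=0)
        assert [o.period_start for o in out] == [2016]

    def test_census_passes_through_untouched(self):
        census = _obs(source="census", start=1950, end=1950, survey_year=None)
        out = dio.filter_recall_window(
            ObservationSet((census,), ("Province 1",)), max_lag=25)
        assert len(out) == 1

    def test_idempotent(self):
        data = self._set([1985, 1995, 2010])
        once = dio.filter_recall_window(data)
        twice = dio.filter_recall_window(once)
        assert once.observations == twice.observations


class TestCensusAggregation:
    MAP = {"d1": "Province 1", "d2": "Province 1", "d3": "Province 2"}

    def test_fully_sampled_districts_sum_plainly(self):
        df = pd.DataFrame([
            {"district": "d1", "male": 50, "female": 50, "sampled_fraction": 1.0},
            {"district": "d2", "male": 55, "female": 50, "sampled_fraction": 1.0},
        ])
        out = dio.aggregate_census_districts(df, self.MAP, period_start=2011)
        assert len(out) == 1
        assert out[0].srb == pytest.approx(1.05)

    def test_inverse_probability_weighting(self):
        df = pd.DataFrame([
            {"district": "d1", "male": 10, "female": 10, "sampled_fraction": 0.5},
        ])
        out = dio.aggregate_census_districts(df, self.MAP, period_start=2011)
        assert out[0].male_births == pytest.approx(20)
        assert out[0].female_births == pytest.approx(20)
        assert out[0].srb == pytest.approx(1.0)

    def test_heterogeneous_coverage_weights_applied_before_summation(self):
        df = pd.DataFrame([
            {"district": "d1", "male": 11, "female": 11, "sampled_fraction": 0.11},
            {"district": "d2", "male": 99, "female": 99, "sampled_fraction": 0.99},
        ])
        out = dio.aggregate_census_districts(df, self.MAP, period_start=2011)
        assert out[0].male_births == pytest.approx(11 / 0.11 + 99 / 0.99)

    def test_bad_fraction_and_unmapped_district_raise(self):
        df = pd.DataFrame([
            {"district": "d1", "male": 1, "female": 1, "sampled_fraction": 0.0}])
        with pytest.raises(ValidationError):
            dio.aggregate_census_districts(df, self.MAP)
        df2 = pd.DataFrame([
            {"district": "dX", "male": 1, "female": 1, "sampled_fraction": 1.0}])
        with pytest.raises(KeyError, match="dX"):
            dio.aggregate_census_districts(df2, self.MAP)


class TestTFRRoundTrip:
    def test_tfr_round_trip(self, tmp_path):
        import srbtrans as st

        series = {
            "Province 1": st.simulate_tfr_series(
                "Province 1", 6.0, 1.9, range(1976, 2017), 1998.0, 0.12),
        }
        path = tmp_path / "tfr.csv"
        dio.write_tfr(series, path)
        loaded = dio.load_tfr(path)
        assert loaded["Province 1"].years == series["Province 1"].years
        np.testing.assert_allclose(loaded["Province 1"].tfr,
                                   series["Province 1"].tfr)
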