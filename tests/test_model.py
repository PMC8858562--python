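import math

import numpy as np
import pytest
import scipy.stats as ss
from hypothesis import given, settings
from hypothesis import strategies as hyp

import srbtrans.model as m
from srbtrans.structures import (
    ContractError,
    ObservationSet,
    ProvinceState,
    SRBObservation,
    TFRSeries,
    TransitionShape,
)

SHAPE = TransitionShape(t0=2000.0, len_increase=10.0, len_stagnation=8.0,
                        len_decrease=12.0, max_inflation=0.06)


class TestTrapezoid:
    @pytest.mark.parametrize("t, expected", [
        (1999.0, 0.0),                    # before the start year
        (2000.0, 0.0),                    # exactly at the start
        (2005.0, 0.03),                   # halfway up the increase
        (2010.0, 0.06),                   # top reached
        (2014.0, 0.06),                   # stagnation
        (2024.0, 0.03),                   # halfway down
        (2030.0, 0.0),                    # fully converged
        (2035.0, 0.0),                    # long after
    ])
    def test_piecewise_values(self, t, expected):
        assert m.alpha_trapezoid(t, SHAPE) == pytest.approx(expected, abs=1e-12)

    def test_vectorized_matches_scalar(self):
        ts = np.linspace(1995, 2035, 200)
        vec = m.alpha_trapezoid(ts, SHAPE)
        scalars = np.array([m.alpha_trapezoid(t, SHAPE) for t in ts])
        np.testing.assert_allclose(vec, scalars, atol=1e-15)

    @settings(max_examples=40, deadline=None)
    @given(t0=hyp.floats(1970, 2030), l1=hyp.floats(0.5, 25),
           l2=hyp.floats(0, 25), l3=hyp.floats(0.5, 25),
           xi=hyp.floats(0, 0.3))
    def test_integral_matches_quadrature(self, t0, l1, l2, l3, xi):
        """The trapezoid area is xi*(l1/2 + l2 + l3/2); check against
        numeric quadrature of the curve."""
        shape = TransitionShape(t0, l1, l2, l3, xi)
        grid = np.linspace(t0 - 1, t0 + l1 + l2 + l3 + 1, 4001)
        numeric = np.trapezoid(m.alpha_trapezoid(grid, shape), grid)
        closed = xi * (l1 / 2 + l2 + l3 / 2)
        assert numeric == pytest.approx(closed, abs=1e-3 + 1e-3 * closed)

    @settings(max_examples=40, deadline=None)
    @given(t=hyp.floats(1950, 2100))
    def test_nonnegative_everywhere(self, t):
        assert m.alpha_trapezoid(t, SHAPE) >= 0.0


class TestSRBMean:
    def test_no_inflation_is_baseline(self):
        assert m.srb_mean(1.049, 1.0, 0, 0.5) == pytest.approx(1.049)

    def test_additive_inflation(self):
        assert m.srb_mean(1.049, 1.0, 1, 0.05) == pytest.approx(1.099)

    def test_zero_alpha_makes_delta_irrelevant(self):
        assert m.srb_mean(1.049, 1.01, 1, 0.0) == m.srb_mean(1.049, 1.01, 0, 0.0)

    def test_never_below_baseline_component(self):
        rng = np.random.default_rng(0)
        phi = np.exp(rng.normal(0, 0.01, 100))
        alpha = np.abs(rng.normal(0, 0.05, 100))
        theta = m.srb_mean(1.049, phi, 1, alpha)
        assert np.all(theta >= 1.049 * phi - 1e-15)


class TestAR1Density:
    def test_constant_path_matches_normal_pdf_product(self):
        rho, s = 0.6, 0.01
        path = np.ones(5)
        stat_sd = s / math.sqrt(1 - rho**2)
        expected = ss.norm.logpdf(0.0, 0.0, stat_sd) + \
            4 * ss.norm.logpdf(0.0, 0.0, s)
        assert m.ar1_logdensity(path, rho, s) == pytest.approx(expected, abs=1e-10)

    def test_general_path_matches_scipy_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 0.01, 8)
        rho, s = 0.85, 0.004
        stat_sd = s / math.sqrt(1 - rho**2)
        expected = ss.norm.logpdf(x[0], 0.0, stat_sd) + sum(
            ss.norm.logpdf(x[t], rho * x[t - 1], s) for t in range(1, 8))
        assert m.ar1_logdensity(np.exp(x), rho, s) == pytest.approx(
            expected, abs=1e-10)

    def test_rho_near_zero_gives_independent_terms(self):
        x = np.array([0.003, -0.002, 0.001])
        val = m.ar1_logdensity(np.exp(x), 1e-12, 0.005)
        expected = ss.norm.logpdf(x, 0.0, 0.005).sum()
        assert val == pytest.approx(expected, abs=1e-6)

    def test_rejects_rho_outside_unit_interval(self):
        with pytest.raises(ContractError):
            m.ar1_logdensity([1.0, 1.0], 1.2, 0.01)

    def test_simulated_stationary_variance_matches_closed_form(self):
        rho, s = 0.9, 0.004
        rng = np.random.default_rng(8)
        n = 200_000
        x = np.empty(n)
        x[0] = rng.normal(0, s / math.sqrt(1 - rho**2))
        eps = rng.normal(0, s, n - 1)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + eps[t - 1]
        assert np.var(x) == pytest.approx(s**2 / (1 - rho**2), rel=0.05)


class TestStartYearPrior:
    def _tfr(self, values, start=1990):
        years = tuple(range(start, start + len(values)))
        return TFRSeries("P", years, tuple(values))

    def test_first_crossing_year(self):
        tfr = self._tfr([4.0, 3.5, 3.0, 2.5])
        assert m.start_year_location(tfr, 3.0) == 1992

    def test_exact_crossing_counts(self):
        tfr = self._tfr([4.0, 3.0, 2.0])
        assert m.start_year_location(tfr, 3.0) == 1991

    def test_never_crossing_returns_last_year(self, caplog):
        tfr = self._tfr([6.0, 5.9, 5.8])
        with caplog.at_level("WARNING", logger="srbtrans.model"):
            assert m.start_year_location(tfr, 3.0) == 1992
        assert any("never falls" in r.message for r in caplog.records)

    def test_india_like_high_fertility_reference(self):
        # fertility squeeze can be referenced at high TFR levels too
        tfr = self._tfr(list(np.linspace(6.0, 2.0, 41)), start=1976)
        year = m.start_year_location(tfr, 5.2)
        assert tfr.at(year) <= 5.2 and tfr.at(year - 1) > 5.2

    def test_logpdf_matches_scipy_student_t(self):
        loc, scale = 2001.0, 8.0
        for t0 in (2001.0, 2009.0, 1985.0, 2030.0):
            expected = ss.t.logpdf((t0 - loc) / scale, df=3) - math.log(scale)
            assert m.start_year_logprior(t0, loc, scale) == pytest.approx(
                expected, abs=1e-10)

    def test_symmetric_about_location(self):
        lo = m.start_year_logprior(1995.0, 2000.0, 5.0)
        hi = m.start_year_logprior(2005.0, 2000.0, 5.0)
        assert lo == pytest.approx(hi, abs=1e-12)
        assert m.start_year_logprior(2000.0, 2000.0, 5.0) > lo

    def test_other_degrees_of_freedom_rejected(self):
        with pytest.raises(ContractError):
            m.start_year_logprior(2000.0, 2000.0, 5.0, df=5.0)


class TestObsLoglik:
    def test_maximized_at_theta_equal_r(self):
        sigma = 0.03
        at_mode = m.obs_loglik(1.05, sigma, 1.05)
        assert at_mode == pytest.approx(-math.log(sigma * math.sqrt(2 * math.pi)),
                                        abs=1e-12)
        assert at_mode > m.obs_loglik(1.05, sigma, 1.06)

    def test_halving_sigma_at_mode_adds_log2(self):
        assert m.obs_loglik(1.05, 0.015, 1.05) - m.obs_loglik(1.05, 0.03, 1.05) \
            == pytest.approx(math.log(2), abs=1e-12)

    def test_matches_scipy_normal_oracle(self):
        expected = ss.norm.logpdf(math.log(1.10), math.log(1.05), 0.03)
        assert m.obs_loglik(1.10, 0.03, 1.05) == pytest.approx(expected, abs=1e-10)

    def test_zero_sigma_rejected(self):
        with pytest.raises(ContractError):
            m.obs_loglik(1.05, 0.0, 1.05)


def _fixture_posterior_inputs():
    config = m.ModelConfig(year_start=2000, year_end=2004)
    years = config.years
    tfr = {
        "A": TFRSeries("A", tuple(years), (4.0, 3.6, 3.3, 3.0, 2.8)),
        "B": TFRSeries("B", tuple(years), (3.2, 3.0, 2.8, 2.6, 2.4)),
    }
    rng = np.random.default_rng(5)
    states = {
        "A": ProvinceState(
            phi=np.exp(rng.normal(0, 0.004, 5)), delta=1,
            shape=TransitionShape(2001.0, 9.0, 10.0, 11.0, 0.05),
            prob_delta=0.6),
        "B": ProvinceState(
            phi=np.exp(rng.normal(0, 0.004, 5)), delta=0,
            shape=TransitionShape(2002.0, 10.0, 10.0, 12.0, 0.04),
            prob_delta=0.3),
    }
    obs = (
        SRBObservation("A", "s1", 2000, 2002, srb=1.07, log_se=0.03,
                       survey_year=2006),
        SRBObservation("A", "s1", 2003, 2003, srb=1.05, log_se=0.05,
                       survey_year=2006),
        SRBObservation("B", "s1", 2001, 2003, srb=1.04, log_se=0.04,
                       survey_year=2006),
    )
    data = ObservationSet(obs, ("A", "B"))
    hypers = m.HierarchicalHypers()
    return states, hypers, config, data, tfr


class TestLogPosterior:
    def test_matches_term_by_term_scipy_oracle(self):
        """Independently assemble every term with scipy distributions."""
        states, hypers, config, data, tfr = _fixture_posterior_inputs()
        g = config.globals_
        expected = 0.0
        # observation terms at midpoint years
        for o in data:
            st_ = states[o.province]
            t_mid = (o.period_start + o.period_end) // 2
            idx = t_mid - config.year_start
            alpha = m.alpha_trapezoid(float(t_mid), st_.shape)
            theta = g.b * st_.phi[idx] + st_.delta * alpha
            expected += ss.norm.logpdf(math.log(o.srb), math.log(theta), o.log_se)
        for prov, st_ in states.items():
            x = np.log(st_.phi)
            stat_sd = g.sigma_ar / math.sqrt(1 - g.rho**2)
            expected += ss.norm.logpdf(x[0], 0, stat_sd)
            expected += ss.norm.logpdf(x[1:], g.rho * x[:-1], g.sigma_ar).sum()
            loc = m.start_year_location(tfr[prov], config.f_star)
            expected += ss.t.logpdf((st_.shape.t0 - loc) / config.start_year_scale,
                                    df=3) - math.log(config.start_year_scale)
            for value, mu, sd in (
                (st_.shape.len_increase, hypers.mu_len_increase, hypers.sd_len_increase),
                (st_.shape.len_stagnation, hypers.mu_len_stagnation, hypers.sd_len_stagnation),
                (st_.shape.len_decrease, hypers.mu_len_decrease, hypers.sd_len_decrease),
                (st_.shape.max_inflation, hypers.mu_max_inflation, hypers.sd_max_inflation),
            ):
                expected += ss.truncnorm.logpdf(value, -mu / sd, np.inf,
                                                loc=mu, scale=sd)
            expected += st_.delta * math.log(st_.prob_delta) + \
                (1 - st_.delta) * math.log(1 - st_.prob_delta)
        for mu, mu0, sd0 in (
            (hypers.mu_len_increase, config.mu0_len_increase, config.mu0_sd_lengths),
            (hypers.mu_len_stagnation, config.mu0_len_stagnation, config.mu0_sd_lengths),
            (hypers.mu_len_decrease, config.mu0_len_decrease, config.mu0_sd_lengths),
            (hypers.mu_max_inflation, config.mu0_max_inflation,
             config.mu0_sd_max_inflation),
        ):
            expected += ss.norm.logpdf(mu, mu0, sd0)
        for sd, scale in (
            (hypers.sd_len_increase, config.sd_scale_lengths),
            (hypers.sd_len_stagnation, config.sd_scale_lengths),
            (hypers.sd_len_decrease, config.sd_scale_lengths),
            (hypers.sd_max_inflation, config.sd_scale_max_inflation),
        ):
            expected += ss.halfnorm.logpdf(sd, scale=scale)
        actual = m.log_posterior(states, hypers, config, data, tfr)
        assert actual == pytest.approx(expected, abs=1e-8)

    def test_removing_observations_leaves_prior_only_total(self):
        states, hypers, config, data, tfr = _fixture_posterior_inputs()
        full = m.log_posterior(states, hypers, config, data, tfr)
        empty = ObservationSet((), data.provinces)
        prior_only = m.log_posterior(states, hypers, config, empty, tfr)
        lik = sum(
            m.obs_loglik(o.srb, o.log_se,
                         config.globals_.b * states[o.province].phi[
                             o.reference_year - config.year_start]
                         + states[o.province].delta * m.alpha_trapezoid(
                             float(o.reference_year), states[o.province].shape))
            for o in data)
        assert full == pytest.approx(prior_only + lik, abs=1e-9)

    def test_duplicating_an_observation_adds_its_loglik(self):
        states, hypers, config, data, tfr = _fixture_posterior_inputs()
        base = m.log_posterior(states, hypers, config, data, tfr)
        dup = ObservationSet(data.observations + (data.observations[0],),
                             data.provinces)
        o = data.observations[0]
        st_ = states[o.province]
        theta = config.globals_.b * st_.phi[o.reference_year - config.year_start] \
            + st_.delta * m.alpha_trapezoid(float(o.reference_year), st_.shape)
        assert m.log_posterior(states, hypers, config, dup, tfr) == pytest.approx(
            base + m.obs_loglik(o.srb, o.log_se, theta), abs=1e-9)

    def test_invariant_under_observation_permutation(self):
        states, hypers, config, data, tfr = _fixture_posterior_inputs()
        base = m.log_posterior(states, hypers, config, data, tfr)
        perm = ObservationSet(data.observations[::-1], data.provinces)
        assert m.log_posterior(states, hypers, config, perm, tfr) == \
            pytest.approx(base, abs=1e-12)

    def test_period_averaged_evaluation_differs_but_is_finite(self):
        states, hypers, config, data, tfr = _fixture_posterior_inputs()
        import dataclasses

        avg_config = dataclasses.replace(config, average_theta_over_period=True)
        val = m.log_posterior(states, hypers, avg_config, data, tfr)
        assert np.isfinite(val)

    def test_out_of_window_start_year_diagnosed(self):
        states, hypers, config, data, tfr = _fixture_posterior_inputs()
        bad = dict(states)
        bad["A"] = ProvinceState(
            phi=states["A"].phi, delta=1,
            shape=TransitionShape(1900.0, 9.0, 10.0, 11.0, 0.05),
            prob_delta=0.6)
        with pytest.raises(ContractError, match="shape prior.*'A'"):
            m.log_posterior(bad, hypers, config, data, tfr)
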