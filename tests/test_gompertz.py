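"""Gompertz expectation, closed-form oracle, and the Markov sampler."""
import math

import numpy as np
import pandas as pd
import pytest

from reefres.config import GompertzPriors
from reefres.gompertz import (
    RecoveryEstimate,
    TrajectoryPosterior,
    closed_form_time_to_fraction,
    gompertz_expectation,
    months_to_fraction,
    pooled_recovery,
    simulate_posterior,
    total_recovery_years,
    trajectory_bands,
)
from reefres.rates import GrowthRate, RateParams


def make_rates(g_seabird=0.4032, g_rat=0.1764, r_seabird=0.0, r_rat=0.0):
    return {
        "seabird": RateParams(
            "seabird", GrowthRate(g_seabird * 100, g_seabird), r_seabird
        ),
        "rat": RateParams("rat", GrowthRate(g_rat * 100, g_rat), r_rat),
    }


def endpoints(rows):
    return pd.DataFrame(
        [dict(island_id=f"I{i}", treatment=tr, c1=c1, m_mu=m)
         for i, (tr, c1, m) in enumerate(rows)]
    )


class TestExpectation:
    def test_anchored_at_initial_cover(self):
        assert gompertz_expectation(10, 20, 0.2, 0.0, 0) == pytest.approx(10.0)

    def test_asymptote(self):
        assert gompertz_expectation(10, 20, 0.2, 0.5, 1e6) == pytest.approx(20.5)

    def test_reaches_ninety_percent_at_closed_form_time(self):
        t = closed_form_time_to_fraction(10, 20, 0.2, 0.9)
        assert t == pytest.approx(9.419, abs=2e-3)
        assert gompertz_expectation(10, 20, 0.2, 0.0, t) == pytest.approx(18.0)

    def test_initial_above_final_warns(self):
        with pytest.warns(RuntimeWarning):
            value = gompertz_expectation(30, 20, 0.2, 0.1, 5)
        assert value == pytest.approx(20.1)

    def test_literal_form_differs(self):
        anchored = gompertz_expectation(10, 20, 0.2, 0.0, 5, form="anchored")
        literal = gompertz_expectation(10, 20, 0.2, 0.0, 5, form="literal")
        assert np.isfinite(literal)
        assert anchored != pytest.approx(literal)

    def test_unknown_form(self):
        with pytest.raises(ValueError):
            gompertz_expectation(10, 20, 0.2, 0.0, 5, form="mystery")


class TestClosedForm:
    def test_already_recovered(self):
        assert closed_form_time_to_fraction(18, 19, 0.2, 0.9) == 0.0

    def test_doubling_g_halves_time(self):
        t1 = closed_form_time_to_fraction(10, 20, 0.2, 0.9)
        t2 = closed_form_time_to_fraction(10, 20, 0.4, 0.9)
        assert t1 == pytest.approx(2 * t2)

    def test_monotone_decreasing_in_c1(self):
        times = [
            closed_form_time_to_fraction(c1, 20, 0.2, 0.9)
            for c1 in (1, 2, 5, 10, 15)
        ]
        assert all(a > b for a, b in zip(times, times[1:]))

    @pytest.mark.parametrize("bad", [dict(g=0.0), dict(fraction=1.0)])
    def test_validation(self, bad):
        kwargs = dict(c1=10, m=20, g=0.2, fraction=0.9)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            closed_form_time_to_fraction(**kwargs)


class TestSampler:
    def test_noise_free_limit_matches_expectation(self):
        eps = endpoints([("seabird", 10.0, 20.0)])
        priors = GompertzPriors.degenerate(chains=1, iterations=2, burn_in=1)
        post = simulate_posterior(eps, make_rates(), priors, seed=1)["I0"]
        expected = np.array(
            [
                gompertz_expectation(10.0, 20.0, 0.4032, 0.0, t)
                for t in post.time_grid
            ]
        )
        assert np.max(np.abs(post.draws - expected)) < 1e-9

    def test_determinism(self):
        eps = endpoints([("seabird", 1.1, 18.0), ("rat", 0.25, 13.0)])
        priors = GompertzPriors(chains=2, iterations=200, burn_in=50)
        a = simulate_posterior(eps, make_rates(), priors, seed=5)
        b = simulate_posterior(eps, make_rates(), priors, seed=5)
        for island in a:
            assert np.array_equal(a[island].draws, b[island].draws)

    def test_draw_count_and_truncation(self):
        eps = endpoints([("seabird", 1.1, 18.0), ("rat", 0.25, 13.0)])
        priors = GompertzPriors(chains=2, iterations=300, burn_in=100)
        posts = simulate_posterior(eps, make_rates(r_seabird=0.173, r_rat=0.227),
                                   priors, seed=3)
        for post in posts.values():
            assert post.n_draws == 2 * 200
            assert np.all(post.draws > 0.0)
            assert np.all(post.draws < 100.0)

    def test_burn_in_validated(self):
        eps = endpoints([("seabird", 1.1, 18.0)])
        with pytest.raises(Exception):
            simulate_posterior(
                eps,
                make_rates(),
                GompertzPriors(iterations=100, burn_in=100),
                seed=1,
            )


class TestRecoveryTime:
    def deterministic_posterior(self, c1, m, g, fraction_grid=38):
        t = np.arange(fraction_grid)
        curve = np.array(
            [gompertz_expectation(c1, m, g, 0.0, tt) for tt in t]
        )
        return TrajectoryPosterior(
            island_id="I0",
            treatment="seabird",
            time_grid=t,
            draws=curve[None, :],
            m_mean=np.array([m]),
            g_mean=np.array([g]),
            r_mean=np.array([0.0]),
            ctau=np.array([np.inf]),
        )

    def test_grid_rounding_of_oracle(self):
        post = self.deterministic_posterior(10.0, 20.0, 0.2)
        est = months_to_fraction(post, 0.9)
        assert est.months_to_threshold == 10  # ceil(9.419)

    def test_fraction_zero(self):
        post = self.deterministic_posterior(10.0, 20.0, 0.2)
        assert months_to_fraction(post, 0.0).months_to_threshold == 0

    def test_censored_draws_counted(self):
        t = np.arange(5)
        draws = np.array([[1, 2, 3, 9.5, 9.6], [1, 1, 1, 1, 1.0]])
        post = TrajectoryPosterior(
            island_id="I0",
            treatment="rat",
            time_grid=t,
            draws=draws,
            m_mean=np.array([10.0, 10.0]),
            g_mean=np.zeros(2),
            r_mean=np.zeros(2),
            ctau=np.ones(2),
        )
        est = months_to_fraction(post, 0.9)
        assert est.n_censored == 1
        assert est.months_to_threshold == 3  # first month with cover >= 9.0

    def test_all_censored_raises(self):
        t = np.arange(3)
        post = TrajectoryPosterior(
            island_id="I0",
            treatment="rat",
            time_grid=t,
            draws=np.ones((2, 3)),
            m_mean=np.full(2, 50.0),
            g_mean=np.zeros(2),
            r_mean=np.zeros(2),
            ctau=np.ones(2),
        )
        with pytest.raises(ValueError, match="threshold"):
            months_to_fraction(post, 0.9)

    def test_faster_growth_recovers_sooner(self):
        """With identical endpoints, the higher-G treatment's estimate is
        strictly no later, across a parameter grid."""
        priors = GompertzPriors.degenerate(chains=1, iterations=2, burn_in=1)
        for c1, m in ((1.0, 15.0), (2.0, 20.0), (0.5, 12.0)):
            eps = endpoints([("seabird", c1, m), ("rat", c1, m)])
            posts = simulate_posterior(eps, make_rates(), priors, seed=1)
            est = {p.treatment: months_to_fraction(p) for p in posts.values()}
            assert (
                est["seabird"].months_to_threshold
                <= est["rat"].months_to_threshold
            )

    def test_pooled_recovery_median_of_island_medians(self):
        priors = GompertzPriors.degenerate(chains=1, iterations=2, burn_in=1)
        eps = endpoints(
            [("seabird", 1.0, 15.0), ("seabird", 1.1, 16.5), ("seabird", 0.9, 13.5)]
        )
        posts = simulate_posterior(eps, make_rates(), priors, seed=1)
        pooled = pooled_recovery(posts)["seabird"]
        medians = [months_to_fraction(p).months_to_threshold for p in posts.values()]
        assert pooled.months_to_threshold == np.median(medians)
        assert pooled.total_years == total_recovery_years(
            pooled.months_to_threshold
        )


class TestTotalRecoveryYears:
    @pytest.mark.parametrize(
        "months,expected", [(8, 3.67), (18, 4.50), (0, 3.00)]
    )
    def test_examples(self, months, expected):
        assert total_recovery_years(months, 36) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            total_recovery_years(-1)


def test_trajectory_bands_shape():
    eps = endpoints([("seabird", 1.1, 18.0)])
    priors = GompertzPriors(chains=1, iterations=120, burn_in=20)
    post = simulate_posterior(eps, make_rates(), priors, seed=2)["I0"]
    bands = trajectory_bands(post)
    assert list(bands.columns) == [
        "island_id", "treatment", "month", "median", "lo90", "hi90", "lo70", "hi70",
    ]
    assert (bands["lo90"] <= bands["median"]).all()
    assert (bands["median"] <= bands["hi90"]).all()


def test_recovery_estimate_invariants():
    with pytest.raises(ValueError):
        RecoveryEstimate(months_to_threshold=5, ci_lo=6, ci_hi=7)
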