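"""Width-weight regression and maturity ogive: recovery, priors, summaries."""

import dataclasses

import numpy as np
import pytest

from devilray import (
    LWPriorSet,
    MaturityPriorSet,
    allometric_weight,
    fit_lw,
    fit_maturity,
    x50_summary,
)
from devilray.bayes import SampleResult
from devilray.size_weight_maturity import MaturityPosterior
from devilray.synthetic_data import simulate_ages, simulate_specimens


def test_allometric_point_prediction():
    # a 200 cm ray weighs ~57 kg under the fitted power law
    assert allometric_weight(-9.26, 2.51, 200.0) == pytest.approx(56.8, abs=0.5)


@pytest.fixture(scope="module")
def noisefree_fit(noisefree_thurstoni, fast_mcmc):
    ds = noisefree_thurstoni
    return ds, fit_lw(
        ds.specimens.dw_cm, ds.specimens.weight_kg,
        LWPriorSet.strong(), fast_mcmc, seed=31,
    )


@pytest.fixture(scope="module")
def ogive_fit(fast_mcmc):
    rng = np.random.default_rng(40)
    x = rng.uniform(0, 20, 300)
    p = 1.0 / (1.0 + np.exp(-0.66 * (x - 8.2)))
    status = (rng.random(300) < p).astype(int)
    return fit_maturity(x, status, MaturityPriorSet.strong_age(), fast_mcmc, seed=41)


class TestFitLW:
    def test_recovers_truth_on_noisefree_data(self, noisefree_fit):
        ds, post = noisefree_fit
        b, log_a = post.b_draws, post.log_a_draws
        assert abs(np.mean(b) - ds.profile.lw_b) < 2 * np.std(b) + 1e-3
        assert abs(np.mean(log_a) - ds.profile.lw_log_a) < 2 * np.std(log_a) + 1e-2

    def test_prior_strength_barely_moves_posterior(self, noisefree_thurstoni, fast_mcmc):
        ds = noisefree_thurstoni
        strong = fit_lw(ds.specimens.dw_cm, ds.specimens.weight_kg,
                        LWPriorSet.strong(), fast_mcmc, seed=32)
        weak = fit_lw(ds.specimens.dw_cm, ds.specimens.weight_kg,
                      LWPriorSet.weaker(), fast_mcmc, seed=33)
        assert abs(np.mean(strong.b_draws) - np.mean(weak.b_draws)) < 0.05

    def test_unit_equivariance_of_log_intercept(self, noisefree_thurstoni, fast_mcmc):
        # refitting with DW in mm shifts log_a by -b*ln(10), leaves b unchanged
        ds = noisefree_thurstoni
        cm = fit_lw(ds.specimens.dw_cm, ds.specimens.weight_kg,
                    LWPriorSet.weaker(), fast_mcmc, seed=34)
        mm = fit_lw(ds.specimens.dw_cm * 10.0, ds.specimens.weight_kg,
                    LWPriorSet.weaker(), fast_mcmc, seed=34)
        b_cm = np.mean(cm.b_draws)
        assert abs(np.mean(mm.b_draws) - b_cm) < 0.02
        shift = np.mean(cm.log_a_draws) - np.mean(mm.log_a_draws)
        assert shift == pytest.approx(b_cm * np.log(10.0), abs=0.1)

    def test_rejects_nonpositive_and_short_input(self):
        with pytest.raises(ValueError):
            fit_lw([100, 120, -5, 130, 140], [10, 12, 13, 14, 15])
        with pytest.raises(ValueError):
            fit_lw([100, 120], [10, 12])


class TestFitMaturity:
    def test_x50_credible_interval_covers_truth(self, ogive_fit):
        s = x50_summary(ogive_fit)
        assert s.ci_low < 8.2 < s.ci_high
        assert not s.flagged

    def test_x50_interval_width_is_plausible(self, ogive_fit):
        s = x50_summary(ogive_fit)
        assert 0.3 < (s.ci_high - s.ci_low) < 4.0

    def test_single_class_is_hard_error(self):
        with pytest.raises(ValueError):
            fit_maturity([1, 2, 3, 4], [0, 0, 0, 0])

    def test_sparse_class_flagged_unreliable(self, fast_mcmc):
        rng = np.random.default_rng(42)
        x = np.r_[rng.uniform(0, 6, 40), [15.0, 16.0]]
        status = np.r_[np.zeros(40, int), [1, 1]]
        post = fit_maturity(x, status, MaturityPriorSet.strong_age(), fast_mcmc, seed=43)
        assert post.unreliable

    def test_separated_ogive_x50_between_classes(self, fast_mcmc):
        x = np.r_[np.linspace(0, 6, 25), np.linspace(10, 20, 25)]
        status = np.r_[np.zeros(25, int), np.ones(25, int)]
        post = fit_maturity(x, status, MaturityPriorSet.strong_age(8.0), fast_mcmc, seed=44)
        s = x50_summary(post)
        assert 6.0 < s.mean < 10.0


class TestX50Summary:
    def _posterior(self, a, beta):
        a = np.asarray(a, float).reshape(1, -1)
        beta = np.asarray(beta, float).reshape(1, -1)
        res = SampleResult(
            names=["a", "beta"], chains={"a": a, "beta": beta},
            rhat={"a": 1.0, "beta": 1.0}, ess={"a": 1e4, "beta": 1e4}, converged=True,
        )
        return MaturityPosterior(result=res, unreliable=False)

    def test_constant_draws(self):
        post = self._posterior(np.full(200, -7.0), np.full(200, 1.0))
        s = x50_summary(post)
        assert s.mean == 7.0 and s.ci_low == 7.0 and s.ci_high == 7.0

    def test_uniform_three_values(self):
        a = -np.repeat([6.0, 8.0, 10.0], 100)
        post = self._posterior(a, np.ones(300))
        assert x50_summary(post).mean == pytest.approx(8.0)

    def test_negative_slope_draws_flagged(self):
        beta = np.r_[np.full(90, 1.0), np.full(30, -1.0)]
        post = self._posterior(np.full(120, -7.0), beta)
        assert x50_summary(post).flagged

    def test_requires_enough_draws(self):
        post = self._posterior(np.full(50, -7.0), np.ones(50))
        with pytest.raises(ValueError):
            x50_summary(post)


def test_recovery_against_table_truth(mobular, fast_mcmc):
    """Generator truth (posterior-mean parameter values) is recovered by the
    same Bayesian machinery on a fresh synthetic sample."""
    ages = simulate_ages(mobular, 300, seed=45)
    ds = simulate_specimens(mobular, ages, seed=45)
    post = fit_lw(ds.specimens.dw_cm, ds.specimens.weight_kg,
                  LWPriorSet.strong(), fast_mcmc, seed=46)
    # at n=300 the sampling sd of the slope is ~0.09; allow ~3 sd
    assert abs(np.mean(post.b_draws) - mobular.lw_b) < 0.25
    assert abs(np.mean(post.log_a_draws) - mobular.lw_log_a) < 1.3
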