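"""Growth curves: mean functions, inverses, Bayesian fits, LOO comparison."""

import copy

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from devilray import (
    GrowthPriorSet,
    age_at_size,
    compare_models,
    dwinf_from_dwmax,
    fit_growth,
    growth_mean,
)
from devilray.growth import _lester_t0
from devilray.synthetic_data import simulate_ages, simulate_specimens

MOBULAR_VB = {"k": 0.05, "dw0": 1166.53, "dwinf": 3502.95}
THURSTONI_LOG = {"g": 0.19, "dw0": 870.21, "dwinf": 2022.11}


class TestDwinfFromDwmax:
    @pytest.mark.parametrize(
        "dwmax, ratio", [(350.0, 1.01), (197.0, 1.02)]
    )
    def test_ratio_to_max_size(self, dwmax, ratio):
        assert round(dwinf_from_dwmax(dwmax) / dwmax, 2) == ratio

    def test_hand_value(self):
        assert dwinf_from_dwmax(100.0) == pytest.approx(10 ** (0.044 + 0.9841 * 2), rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            dwinf_from_dwmax(0.0)


class TestGrowthMean:
    def test_vb_at_zero_is_dw0(self):
        assert growth_mean("vb", MOBULAR_VB, 0.0) == pytest.approx(1166.53)

    def test_vb_bounded_by_dwinf(self):
        t = np.linspace(0, 500, 100)
        dw = growth_mean("vb", MOBULAR_VB, t)
        assert np.all(np.diff(dw) > 0) and dw[-1] < MOBULAR_VB["dwinf"]
        assert dw[-1] == pytest.approx(MOBULAR_VB["dwinf"], rel=1e-6)

    def test_logistic_size_at_maturity_age(self):
        assert growth_mean("logistic", THURSTONI_LOG, 10.43) == pytest.approx(1710, abs=2)

    @given(
        model=st.sampled_from(["vb", "gompertz", "logistic"]),
        coef=st.floats(min_value=0.02, max_value=1.0),
        dw0=st.floats(min_value=100, max_value=1500),
        ratio=st.floats(min_value=1.2, max_value=5.0),
    )
    def test_monotone_nondecreasing(self, model, coef, dw0, ratio):
        key = "k" if model == "vb" else "g"
        params = {key: coef, "dw0": dw0, "dwinf": dw0 * ratio}
        t = np.linspace(0, 60, 200)
        dw = growth_mean(model, params, t)
        assert np.all(np.diff(dw) >= -1e-9)

    def test_lester_phases_meet_at_breakpoint(self):
        params = {"h": 250.0, "t1": -1.0, "T": 5.0, "k": 0.15, "dwinf": 3000.0}
        eps = 1e-9
        below = growth_mean("lester", params, 5.0 - eps)
        above = growth_mean("lester", params, 5.0 + eps)
        assert below == pytest.approx(above, abs=1e-3)

    def test_lester_rejects_impossible_geometry(self):
        with pytest.raises(ValueError):
            _lester_t0(h=1000.0, t1=0.0, T=5.0, k=0.1, dwinf=3000.0)

    def test_rejects_nonpositive_dw0_for_sigmoids(self):
        with pytest.raises(ValueError):
            growth_mean("gompertz", {"g": 0.1, "dw0": 0.0, "dwinf": 100.0}, 1.0)


class TestAgeAtSize:
    def test_vb_smallest_mature_mobular(self):
        assert round(age_at_size("vb", MOBULAR_VB, 1930.0), 1) == 7.9

    def test_logistic_smallest_mature_thurstoni(self):
        assert round(age_at_size("logistic", THURSTONI_LOG, 1710.0), 1) == 10.4

    @pytest.mark.parametrize("model", ["vb", "gompertz", "logistic"])
    @pytest.mark.parametrize("t", [1.0, 5.0, 20.0])
    def test_round_trip_identity(self, model, t):
        key = "k" if model == "vb" else "g"
        params = {key: 0.11, "dw0": 900.0, "dwinf": 2500.0}
        dw = growth_mean(model, params, t)
        assert age_at_size(model, params, float(dw)) == pytest.approx(t, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            age_at_size("vb", MOBULAR_VB, 5000.0)
        with pytest.raises(ValueError, match="outside"):
            age_at_size("vb", MOBULAR_VB, 100.0)


@pytest.fixture(scope="module")
def vb_fit(mobular_dataset, fast_mcmc):
    ds = mobular_dataset
    return ds, fit_growth(
        ds.true_ages, ds.specimens.dw_cm.to_numpy() * 10.0,
        "vb", GrowthPriorSet.mobular_strong(), fast_mcmc, seed=51,
    )


class TestFitGrowth:
    def test_recovers_k_and_dwinf(self, vb_fit):
        ds, post = vb_fit
        for name, truth in (("k", 0.05), ("dwinf", 3502.95)):
            lo, hi = np.percentile(post.draws(name), [2.5, 97.5])
            assert lo < truth < hi, name

    def test_kappa_truncation_respected(self, vb_fit):
        kappa = vb_fit[1].draws("kappa")
        assert kappa.min() > 0.7 and kappa.max() < 1.3

    def test_dwinf_exceeds_dw0(self, vb_fit):
        assert vb_fit[1].dwinf_exceeds_dw0_fraction() >= 0.99

    def test_prior_dominates_when_large_animals_missing(self, mobular, fast_mcmc):
        ages = simulate_ages(mobular, 150, seed=52)
        ds = simulate_specimens(mobular, ages, seed=52)
        dw = ds.specimens.dw_cm.to_numpy() * 10.0
        keep = dw < 2000.0
        post = fit_growth(
            ds.true_ages[keep], dw[keep], "vb",
            GrowthPriorSet.mobular_strong(), fast_mcmc, seed=53,
        )
        # with no large animals the DWinf posterior is held near kappa*3500
        assert abs(np.mean(post.draws("dwinf")) - 3500.0) < 400.0

    def test_unit_scale_equivariance_of_k(self, mobular_dataset, fast_mcmc):
        ds = mobular_dataset
        dw_mm = ds.specimens.dw_cm.to_numpy() * 10.0
        priors = GrowthPriorSet.mobular_strong()
        mm = fit_growth(ds.true_ages, dw_mm, "vb", priors, fast_mcmc, seed=54)
        cm = fit_growth(ds.true_ages, dw_mm / 10.0, "vb", priors.rescaled(0.1),
                        fast_mcmc, seed=54)
        assert np.mean(mm.draws("k")) == pytest.approx(np.mean(cm.draws("k")), abs=0.004)

    def test_degenerate_single_age_rejected(self):
        with pytest.raises(ValueError):
            fit_growth(np.full(20, 5.0), np.full(20, 1500.0), "vb",
                       GrowthPriorSet.mobular_strong())

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_growth([1, 2, 3], [1000, 1100, 1200], "vb",
                       GrowthPriorSet.mobular_strong())


class TestCompareModels:
    def test_identical_posteriors_split_weight(self, vb_fit):
        post = vb_fit[1]
        cmp = compare_models([post, post])
        w = cmp.table["weight"].to_numpy()
        assert w == pytest.approx([0.5, 0.5], abs=1e-6)
        assert np.ptp(cmp.table["looic"]) == pytest.approx(0.0, abs=1e-9)

    def test_weights_sum_to_one(self, vb_fit):
        post = vb_fit[1]
        shifted = copy.deepcopy(post)
        shifted.log_lik = shifted.log_lik - 0.5
        cmp = compare_models([post, shifted])
        assert cmp.table["weight"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_dominant_model_wins(self, vb_fit):
        post = vb_fit[1]
        worse = copy.deepcopy(post)
        worse.log_lik = worse.log_lik - 1.0  # uniformly lower pointwise likelihood
        worse.model = "gompertz"
        cmp = compare_models([post, worse])
        tab = cmp.table.set_index("model")
        assert tab.loc["vb", "looic"] < tab.loc["gompertz", "looic"]
        assert tab.loc["vb", "weight"] > tab.loc["gompertz", "weight"]
        assert cmp.best() == "vb"

    def test_mismatched_data_rejected(self, vb_fit):
        post = vb_fit[1]
        other = copy.deepcopy(post)
        other.data_fingerprint = "deadbeef"
        with pytest.raises(ValueError, match="different data"):
            compare_models([post, other])
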