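"""Catch-curve Z estimation and the F/E exploitation Monte Carlo."""

import dataclasses

import numpy as np
import pytest

from devilray import chapman_robson, fe_monte_carlo, sustainability_flags
from devilray.mortality import CatchCurveResult, ages_from_growth, catch_curve_table
from devilray.synthetic_data import simulate_ages, simulate_specimens

MOBULAR_VB = {"k": 0.05, "dw0": 1166.53, "dwinf": 3502.95}


def z215() -> CatchCurveResult:
    """A catch-curve result with the headline Z and CI for the larger species."""
    return CatchCurveResult(
        Z=0.215, Z_se=(0.272 - 0.157) / 3.92, Z_ci95=(0.157, 0.272),
        Z_uncorrected=0.215, S=float(np.exp(-0.215)), recruit_age=3,
        first_used_age=4, annual_mortality_A=float(1 - np.exp(-0.215)), n_used=103,
    )


class TestAgesFromGrowth:
    def test_maturity_size_maps_to_eight_years(self):
        ages = ages_from_growth([1930.0], MOBULAR_VB, "vb")
        assert ages[0] == 8  # 7.91 rounded

    def test_dw0_maps_to_zero(self):
        assert ages_from_growth([MOBULAR_VB["dw0"]], MOBULAR_VB, "vb")[0] == 0

    def test_above_dwinf_assigned_max_class(self):
        ages = ages_from_growth([3600.0, 3490.0], MOBULAR_VB, "vb", max_age_class=30)
        assert ages[0] == 30
        assert ages[1] > 30 and np.isfinite(ages[1])  # just below DWinf: finite, large


class TestChapmanRobson:
    def test_hand_worked_toy_counts(self):
        r = chapman_robson({0: 5, 1: 3, 2: 2}, recruit_age=0,
                           peak_plus_one=False, bias_corrected=False)
        assert r.S == pytest.approx(7 / 16)
        assert r.Z == pytest.approx(0.827, abs=0.001)
        assert r.annual_mortality_A == pytest.approx(1 - np.exp(-r.Z), rel=1e-12)

    def test_bias_correction_shrinks_z(self):
        raw = chapman_robson({0: 5, 1: 3, 2: 2}, 0, peak_plus_one=False,
                             bias_corrected=False)
        bc = chapman_robson({0: 5, 1: 3, 2: 2}, 0, peak_plus_one=False,
                            bias_corrected=True)
        assert bc.Z < raw.Z
        assert bc.Z_uncorrected == pytest.approx(raw.Z)

    def test_exact_geometric_counts_recover_z(self):
        # counts proportional to exp(-0.5 x): estimator consistency check
        x = np.arange(0, 40)
        counts = {int(a): float(1e6 * np.exp(-0.5 * a)) for a in x}
        r = chapman_robson(counts, recruit_age=0, peak_plus_one=False,
                           bias_corrected=False)
        assert r.Z == pytest.approx(0.5, abs=1e-3)

    def test_peak_plus_one_recoding(self):
        counts = {3: 50, 4: 40, 5: 30, 6: 20}
        r = chapman_robson(counts, recruit_age=3)
        assert r.first_used_age == 4
        assert r.n_used == 90  # age-3 class excluded

    def test_degenerate_single_class_is_error(self):
        with pytest.raises(ValueError):
            chapman_robson({4: 100}, recruit_age=3)
        with pytest.raises(ValueError):
            chapman_robson({4: 100, 5: 0}, recruit_age=3)

    def test_catch_curve_table_flags(self):
        tab = catch_curve_table([2, 3, 3, 4, 5], recruit_age=3)
        assert not tab.loc[tab.age == 2, "used_in_fit"].item()
        assert not tab.loc[tab.age == 3, "used_in_fit"].item()
        assert tab.loc[tab.age == 4, "used_in_fit"].item()


class TestFEMonteCarlo:
    def test_identities_hold_per_draw(self):
        d = fe_monte_carlo(z215(), (0.033, 0.070), 5000, seed=70)
        np.testing.assert_array_equal(d.F, d.Z - d.M)
        np.testing.assert_array_equal(d.E, d.F / d.Z)

    def test_degenerate_bounds_give_exact_f_and_e(self):
        z = z215()
        z = dataclasses.replace(z, Z_ci95=(0.215, 0.215), Z_se=0.0)
        d = fe_monte_carlo(z, (0.05, 0.05), 1000, seed=71)
        assert np.allclose(d.F, 0.215 - 0.05)
        assert np.allclose(d.E, 1 - 0.05 / 0.215)

    def test_median_seed_stability(self):
        a = fe_monte_carlo(z215(), (0.033, 0.070), 10_000, seed=72).summary()
        b = fe_monte_carlo(z215(), (0.033, 0.070), 10_000, seed=73).summary()
        assert abs(a["F_median"] - b["F_median"]) < 0.005
        assert abs(a["E_median"] - b["E_median"]) < 0.005

    def test_invalid_m_bounds_rejected(self):
        with pytest.raises(ValueError):
            fe_monte_carlo(z215(), (0.0, 0.07))


class TestSustainability:
    def test_overfishing_flagged(self):
        d = fe_monte_carlo(z215(), (0.033, 0.070), 5000, seed=74)
        rep = sustainability_flags(d, rmax_median=0.109)
        assert rep.median_F_exceeds_rmax
        assert rep.share_E_gt_half > 0.5
        assert "EXCEEDS" in rep.text()

    def test_below_rmax_not_flagged(self):
        d = fe_monte_carlo(z215(), (0.033, 0.070), 5000, seed=75)
        rep = sustainability_flags(d, rmax_median=0.5)
        assert not rep.median_F_exceeds_rmax

    def test_boundary_draws_do_not_count(self):
        d = fe_monte_carlo(z215(), (0.033, 0.070), 100, seed=76)
        d.E = np.full_like(d.E, 0.5)
        rep = sustainability_flags(d, rmax_median=0.109)
        assert rep.share_E_gt_half == 0.0


def test_end_to_end_z_recovery_on_noisefree_sizes(mobular):
    """Noise-free sizes -> growth inversion -> catch curve recovers Z_true."""
    profile = dataclasses.replace(mobular, sigma2_log=0.0, max_age=45)
    true_ages = simulate_ages(profile, 800, seed=77, pre_recruit_fraction=0.0)
    ds = simulate_specimens(profile, true_ages, seed=77)
    est_ages = ages_from_growth(
        ds.specimens.dw_cm.to_numpy() * 10.0, profile.growth_params, "vb"
    )
    np.testing.assert_array_equal(est_ages, true_ages.astype(int))
    vals, counts = np.unique(est_ages, return_counts=True)
    r = chapman_robson(dict(zip(vals, counts)), recruit_age=profile.recruit_age,
                       peak_plus_one=True)
    assert abs(r.Z - profile.z_true) < 2 * r.Z_se
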