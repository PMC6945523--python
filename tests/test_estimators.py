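"""Estimator algebra, invariances, and recovery on simulated data."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from adipomr.estimators import (
    ivw,
    mr_egger,
    mvmr,
    ratio_estimates,
    weighted_median,
    weighted_median_point,
)
from adipomr.simulate import SyntheticConfig

from conftest import build_instruments, random_instruments, simulate_harmonized


class TestRatios:
    def test_direct_arithmetic(self):
        inst = build_instruments([0.2], [0.01], [0.02], [0.01])
        (r,) = ratio_estimates(inst)
        assert r.ratio == pytest.approx(0.10)
        assert r.se_ratio == pytest.approx(0.05)

    def test_sign_flip_of_both_associations_leaves_ratio_unchanged(self):
        a = build_instruments([0.2], [0.01], [0.02], [0.01])
        b = build_instruments([-0.2], [0.01], [-0.02], [0.01])
        assert ratio_estimates(a)[0].ratio == pytest.approx(ratio_estimates(b)[0].ratio)

    def test_elementwise_division_oracle(self, rng):
        inst = random_instruments(rng, 25)
        arr = inst.arrays()
        expected = [g2 / g1 for g1, g2 in zip(arr["gamma"], arr["Gamma"])]
        got = [r.ratio for r in ratio_estimates(inst)]
        assert np.allclose(got, expected)

    def test_zero_gamma_is_hard_error(self):
        inst = build_instruments([0.2, 0.0], [0.01, 0.01], [0.02, 0.01], [0.01, 0.01])
        with pytest.raises(ValueError, match="rs2"):
            ratio_estimates(inst)


class TestIVW:
    def test_single_instrument_collapses_to_ratio(self):
        inst = build_instruments([0.2], [0.01], [0.02], [0.01])
        est = ivw(inst)
        assert est.beta == pytest.approx(0.10)
        assert est.se == pytest.approx(0.05)
        assert est.cochran_q is None and est.q_pval is None

    def test_three_ratio_hand_computation(self):
        # ratios 0.10 (se 0.02), 0.12 (se 0.03), 0.08 (se 0.04) expressed as
        # gamma=1 instruments
        inst = build_instruments([1, 1, 1], [1e-6] * 3, [0.10, 0.12, 0.08], [0.02, 0.03, 0.04])
        w = np.array([1 / 0.02**2, 1 / 0.03**2, 1 / 0.04**2])
        r = np.array([0.10, 0.12, 0.08])
        expected = float(w @ r / w.sum())
        est = ivw(inst, "fixed")
        assert est.beta == pytest.approx(expected, abs=1e-12)
        assert est.se == pytest.approx(w.sum() ** -0.5, abs=1e-12)

    def test_fixed_effect_equals_no_intercept_wls(self, rng):
        import statsmodels.api as sm

        for _ in range(20):
            inst = random_instruments(rng, int(rng.integers(3, 30)))
            arr = inst.arrays()
            fit = sm.WLS(arr["Gamma"], arr["gamma"], weights=1 / arr["se_Gamma"] ** 2).fit()
            est = ivw(inst, "fixed")
            assert est.beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_random_effects_se_never_below_fixed(self, rng):
        for _ in range(20):
            inst = random_instruments(rng, 15)
            assert ivw(inst).se >= ivw(inst, "fixed").se - 1e-15

    def test_or_is_exp_beta_and_ci_order(self, rng):
        est = ivw(random_instruments(rng, 10))
        assert est.odds_ratio == pytest.approx(np.exp(est.beta))
        assert est.ci_low < est.beta < est.ci_high

    def test_reordering_invariance(self, rng):
        inst = random_instruments(rng, 12)
        perm = list(rng.permutation(12))
        shuffled = build_instruments(
            *[
                [getattr(inst.instruments[i], f) for i in perm]
                for f in ("gamma", "se_gamma", "Gamma", "se_Gamma")
            ]
        )
        assert ivw(inst).beta == pytest.approx(ivw(shuffled).beta, abs=1e-14)
        assert mr_egger(inst).beta == pytest.approx(mr_egger(shuffled).beta, abs=1e-12)

    def test_empty_set_is_hard_error(self):
        with pytest.raises(ValueError):
            ivw(build_instruments([], [], [], []))


class TestWeightedMedian:
    def test_equal_weights_odd_j_is_simple_median(self):
        inst = build_instruments([1] * 5, [0.01] * 5, [0.3, 0.1, 0.5, 0.2, 0.4], [0.1] * 5)
        est = weighted_median(inst, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.3)

    def test_equal_weights_even_j_averages_middle_pair(self):
        assert weighted_median_point(
            np.array([0.1, 0.2, 0.4, 0.6]), np.ones(4)
        ) == pytest.approx(0.3)

    def test_dominant_snp_determines_estimate(self):
        # middle-ranked SNP carries >50% of total weight
        inst = build_instruments(
            [1, 1, 1], [0.01] * 3, [0.1, 0.25, 0.4], [1.0, 0.1, 1.0]
        )
        est = weighted_median(inst, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.25)

    def test_estimate_within_ratio_range(self, rng):
        for _ in range(10):
            inst = random_instruments(rng, 9)
            ratios = [r.ratio for r in ratio_estimates(inst)]
            est = weighted_median(inst, n_boot=150, seed=2)
            assert min(ratios) <= est.beta <= max(ratios)

    def test_bootstrap_deterministic_given_seed(self, rng):
        inst = random_instruments(rng, 8)
        assert weighted_median(inst, 300, seed=5).se == weighted_median(inst, 300, seed=5).se

    def test_too_few_instruments_and_low_boot(self, rng):
        with pytest.raises(ValueError):
            weighted_median(random_instruments(rng, 2))
        with pytest.warns(UserWarning, match="n_boot"):
            weighted_median(random_instruments(rng, 5), n_boot=50, seed=0)


class TestEgger:
    def test_exact_fit_with_constant_pleiotropy(self):
        gamma = np.array([0.1, 0.2, 0.3, 0.4])
        c, slope = 0.05, 0.3
        Gamma = c + slope * gamma
        inst = build_instruments(gamma, [0.01] * 4, Gamma, [0.01] * 4)
        est = mr_egger(inst)
        assert est.beta == pytest.approx(slope, abs=1e-10)
        assert est.egger_intercept == pytest.approx(c, abs=1e-10)
        assert est.cochran_q == pytest.approx(0.0, abs=1e-16)

    def test_orientation_invariance_under_allele_representation(self):
        gamma = np.array([0.1, -0.2, 0.3, -0.4, 0.25])
        Gamma = 0.02 + 0.3 * np.abs(gamma) * np.sign(gamma)
        inst = build_instruments(gamma, [0.01] * 5, Gamma, [0.02] * 5)
        flipped = build_instruments(-gamma, [0.01] * 5, -Gamma, [0.02] * 5)
        a, b = mr_egger(inst), mr_egger(flipped)
        assert a.beta == pytest.approx(b.beta)
        assert a.egger_intercept == pytest.approx(b.egger_intercept)

    def test_degenerate_design_rejected(self):
        inst = build_instruments([0.2, 0.2, -0.2], [0.01] * 3, [0.1, 0.1, -0.1], [0.01] * 3)
        with pytest.raises(ValueError, match="spread"):
            mr_egger(inst)
        with pytest.raises(ValueError):
            mr_egger(build_instruments([0.1, 0.2], [0.01] * 2, [0.1, 0.1], [0.01] * 2))


class TestMVMR:
    def test_zero_second_exposure_collapses_to_univariable_ivw(self, rng):
        inst = random_instruments(rng, 10)
        arr = inst.arrays()
        both = build_instruments(
            arr["gamma"], arr["se_gamma"], arr["Gamma"], arr["se_Gamma"],
            gamma2=np.zeros(10), se_gamma2=np.full(10, 0.01),
        )
        with pytest.warns(UserWarning, match="all-zero"):
            mv = mvmr(both, ("e1", "e2"))
        assert mv["e2"] is None
        assert mv["e1"].beta == pytest.approx(ivw(inst).beta, abs=1e-12)

    def test_exact_collinearity_is_hard_error(self, rng):
        inst = random_instruments(rng, 8)
        arr = inst.arrays()
        both = build_instruments(
            arr["gamma"], arr["se_gamma"], arr["Gamma"], arr["se_Gamma"],
            gamma2=2.0 * arr["gamma"], se_gamma2=arr["se_gamma"],
        )
        with pytest.raises(ValueError, match="collinear"):
            mvmr(both)

    def test_recovers_opposite_signed_direct_effects(self):
        # correlated fat / fat-free style exposures with direct effects
        # (+0.3, -0.1); strong instruments so conditional bias is small
        reps, est1, est2, se1 = 25, [], [], []
        for rep in range(reps):
            cfg = SyntheticConfig(
                n_exposure_cohort=200_000, n_outcome_cohort=50_000, n_snps=96,
                exposure_h2=0.016, true_effect=0.3, outcome_prevalence=0.15,
                second_exposure={"h2": 0.014, "effect_correlation": 0.5, "true_effect": -0.1},
                seed=1000 + rep,
            )
            inst, _ = simulate_harmonized(cfg)
            mv = mvmr(inst, ("fat", "ffm"))
            est1.append(mv["fat"].beta)
            est2.append(mv["ffm"].beta)
            se1.append(mv["fat"].se)
        mc_se1 = np.std(est1, ddof=1) / np.sqrt(reps)
        mc_se2 = np.std(est2, ddof=1) / np.sqrt(reps)
        assert np.mean(est1) == pytest.approx(0.3, abs=2.5 * mc_se1)
        assert np.mean(est2) == pytest.approx(-0.1, abs=2.5 * mc_se2)


class TestRobustness:
    def test_weighted_median_resists_directional_contamination(self):
        # 40% of instruments carry large same-direction direct effects; the
        # weighted median stays near the truth while IVW is pulled far away
        cfg = SyntheticConfig(
            n_exposure_cohort=80_000, n_outcome_cohort=80_000, n_snps=15,
            exposure_h2=0.15, true_effect=0.1, outcome_prevalence=0.2,
            effect_distribution="equal",
            pleiotropy_mode="directional", pleiotropy_mean=0.35,
            pleiotropy_sd=0.02, pleiotropy_frac=0.4, seed=77,
        )
        inst, _ = simulate_harmonized(cfg)
        wm = weighted_median(inst, n_boot=500, seed=3)
        iv = ivw(inst)
        # at 40% one-directional contamination the weighted median sits near
        # the 0.5/0.6 quantile of the valid ratios, i.e. within about one
        # per-SNP ratio SE of the truth, while IVW is pulled far outside its CI
        assert abs(wm.beta - 0.1) <= 3.0 * wm.se
        assert abs(iv.beta - 0.1) > 2.0 * iv.se
        assert abs(wm.beta - 0.1) < 0.4 * abs(iv.beta - 0.1)


@given(st.integers(0, 2**31 - 1))
def test_weighted_median_bounds_property(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 12))
    ratios = rng.normal(size=n)
    weights = rng.uniform(0.1, 5.0, n)
    m = weighted_median_point(ratios, weights)
    assert ratios.min() <= m <= ratios.max()
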