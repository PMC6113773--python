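"""The two-sample MR estimator suite and power calculation."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from conftest import make_hset
from osteomr.errors import InputError
from osteomr.mr import (
    PowerParams,
    bonferroni_flag,
    egger,
    ivw,
    mr_power,
    penalized_weighted_median,
    wald_ratio,
    weighted_median,
)
from osteomr.mr import _weighted_median_point
from osteomr.simulate import SimulationTruth, simulate_two_sample
from osteomr.sumstats import harmonize


class TestWaldRatio:
    def test_unit_instrument(self):
        assert wald_ratio(1.0, 0.01, 0.05, 0.01).beta == pytest.approx(0.05)

    def test_null_outcome_effect(self):
        est = wald_ratio(0.2, 0.01, 0.0, 0.01)
        assert est.beta == 0
        assert est.se == pytest.approx(0.05)

    def test_first_order_delta_method(self):
        est = wald_ratio(0.1, 0.01, 0.02, 0.005)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.05)

    def test_second_order_adds_exposure_term(self):
        est = wald_ratio(0.1, 0.01, 0.02, 0.005, second_order=True)
        expected = math.sqrt(0.005**2 / 0.1**2 + 0.02**2 * 0.01**2 / 0.1**4)
        assert est.se == pytest.approx(expected)

    def test_zero_bx_rejected(self):
        with pytest.raises(InputError):
            wald_ratio(0.0, 0.01, 0.02, 0.005)


class TestIVW:
    def test_single_instrument_equals_wald(self):
        h = make_hset([0.1], [0.02], se_by=[0.005])
        w = wald_ratio(0.1, 0.01, 0.02, 0.005)
        r = ivw(h)
        assert r.beta == pytest.approx(w.beta)
        assert r.se == pytest.approx(w.se)

    def test_equal_ratio_toy_is_exact(self):
        r = ivw(make_hset([0.1, 0.2, 0.3], [0.02, 0.04, 0.06]))
        assert r.beta == pytest.approx(0.2, abs=1e-15)

    def test_invariant_to_instrument_orientation(self):
        bx = np.array([0.1, -0.2, 0.3])
        by = np.array([0.02, -0.04, 0.07])
        r1 = ivw(make_hset(bx, by))
        r2 = ivw(make_hset(-bx, -by))
        assert r1.beta == pytest.approx(r2.beta, abs=1e-15)
        assert r1.se == pytest.approx(r2.se, abs=1e-15)

    def test_empty_set_rejected(self):
        import pandas as pd

        from osteomr.sumstats import HarmonizedInstrumentSet

        empty = HarmonizedInstrumentSet(
            "x", "y", "quantitative",
            pd.DataFrame(columns=["snp_id", "bx", "se_bx", "by", "se_by"]),
        )
        with pytest.raises(InputError):
            ivw(empty)


class TestEgger:
    def test_exact_proportionality_gives_zero_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        r = egger(make_hset(bx, 0.5 * bx))
        assert r.intercept == pytest.approx(0, abs=1e-12)
        assert r.beta == pytest.approx(0.5, abs=1e-12)

    def test_pure_directional_pleiotropy_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        r = egger(make_hset(bx, 0.03 + 0.5 * bx))
        assert r.intercept == pytest.approx(0.03, abs=1e-12)
        assert r.beta == pytest.approx(0.5, abs=1e-12)

    def test_matches_hand_solved_weighted_normal_equations(self):
        bx = np.array([0.05, 0.12, 0.20, 0.33])
        by = np.array([0.011, 0.030, 0.041, 0.078])
        se_by = np.array([0.01, 0.02, 0.012, 0.03])
        w = 1 / se_by**2
        # closed-form 2x2 WLS: [sum w, sum w x; sum w x, sum w x^2]
        A = np.array([[w.sum(), (w * bx).sum()], [(w * bx).sum(), (w * bx**2).sum()]])
        rhs = np.array([(w * by).sum(), (w * bx * by).sum()])
        icpt, slope = np.linalg.solve(A, rhs)
        r = egger(make_hset(bx, by, se_by=se_by))
        assert r.intercept == pytest.approx(icpt, abs=1e-10)
        assert r.beta == pytest.approx(slope, abs=1e-10)

    def test_two_instruments_rejected(self):
        with pytest.raises(InputError):
            egger(make_hset([0.1, 0.2], [0.02, 0.04]))

    def test_orientation_flip_leaves_fit_unchanged(self):
        bx = np.array([0.1, -0.2, 0.3, -0.4])
        by = 0.02 + 0.4 * bx * np.sign(bx) * np.sign(bx)  # arbitrary
        r1 = egger(make_hset(bx, by))
        r2 = egger(make_hset(-bx, -by))
        assert r1.beta == pytest.approx(r2.beta, abs=1e-12)
        assert r1.intercept == pytest.approx(r2.intercept, abs=1e-12)


class TestWeightedMedian:
    def test_degenerate_distribution(self):
        bx = np.array([0.1, 0.2, 0.4])
        r = weighted_median(make_hset(bx, 0.3 * bx), n_boot=50, seed=1)
        assert r.beta == pytest.approx(0.3, abs=1e-12)

    def test_midpoint_interpolation_convention(self):
        # ratios (1,2,3), normalised weights (0.5,0.25,0.25):
        # midpoint positions (0.25, 0.625, 0.875); interpolating 0.5
        # between the first two ratios gives 1 + 0.25/0.375 = 5/3
        est = _weighted_median_point(
            np.array([1.0, 2.0, 3.0]), np.array([0.5, 0.25, 0.25])
        )
        assert est[0] == pytest.approx(5 / 3, abs=1e-12)

    def test_robust_to_invalid_minority_where_ivw_breaks(self):
        # 40% of instruments carry a constant pleiotropic effect: the
        # weighted median stays near the truth while IVW is pulled away
        truth = SimulationTruth(
            causal_beta=0.2, frac_invalid=0.4, pleiotropy_mean=0.1,
            pleiotropy_sd=0.0, n_exposure=200_000, seed=0,
        )
        exposure, outcome, _ = simulate_two_sample(truth, 20, positive_bx=True)
        h = harmonize(exposure, outcome)
        wm = weighted_median(h, n_boot=1000, seed=0)
        iv = ivw(h)
        assert abs(wm.beta - 0.2) <= 2 * wm.se
        assert iv.beta - 0.2 > 2 * iv.se  # biased upward

    def test_too_few_instruments_rejected(self):
        with pytest.raises(InputError):
            weighted_median(make_hset([0.1, 0.2], [0.02, 0.04]), 10, 0)

    def test_bootstrap_is_seeded(self):
        h = make_hset([0.1, 0.2, 0.3, 0.4], [0.03, 0.05, 0.05, 0.09])
        r1 = weighted_median(h, n_boot=200, seed=5)
        r2 = weighted_median(h, n_boot=200, seed=5)
        assert r1.se == r2.se


class TestPenalizedWeightedMedian:
    def test_homogeneous_ratios_equal_plain_weighted_median(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        h = make_hset(bx, 0.25 * bx + np.array([1, -1, 1, -1, 0]) * 1e-4)
        wm = weighted_median(h, n_boot=50, seed=2)
        pwm = penalized_weighted_median(h, n_boot=50, seed=2)
        assert pwm.beta == pytest.approx(wm.beta, abs=1e-9)

    def test_gross_outlier_weight_crushed(self):
        bx = np.array([0.1] * 10 + [0.1])
        by = np.array([0.02] * 10 + [0.5])  # outlier ratio 5 vs 0.2
        se_by = np.full(11, 0.01)
        from osteomr.mr import _penalised_weights

        w_raw = bx**2 / se_by**2
        w_pen = _penalised_weights(bx, by, se_by, 20.0)
        assert w_pen[-1] < 0.01 * w_raw[-1]

    def test_single_pleiotropic_snp_never_worse_than_plain_median(self):
        # Monte-Carlo comparison: mean absolute error of the penalised
        # estimator at most that of the plain weighted median
        errs_wm, errs_pwm = [], []
        for rep in range(500):
            truth = SimulationTruth(
                causal_beta=0.2, frac_invalid=0.1, pleiotropy_mean=0.15,
                pleiotropy_sd=0.0, n_exposure=200_000, seed=10_000 + rep,
            )
            exposure, outcome, _ = simulate_two_sample(
                truth, 10, positive_bx=True
            )
            h = harmonize(exposure, outcome)
            bx, _, by, se_by = h.arrays()
            errs_wm.append(abs(
                float(_weighted_median_point(by / bx, bx**2 / se_by**2)[0]) - 0.2
            ))
            from osteomr.mr import _penalised_weights

            w_pen = _penalised_weights(bx, by, se_by, 20.0)
            errs_pwm.append(abs(
                float(_weighted_median_point(by / bx, w_pen)[0]) - 0.2
            ))
        assert np.mean(errs_pwm) <= np.mean(errs_wm)


class TestMrPower:
    def test_null_effect_gives_test_size(self):
        p = PowerParams(alpha=0.05, n_outcome=10_000, case_fraction=0.5,
                        r2_gx=0.05, target_or=1.0)
        assert mr_power(p) == pytest.approx(0.05, abs=1e-12)

    def test_huge_sample_gives_full_power(self):
        p = PowerParams(alpha=3.3e-3, n_outcome=10**9, case_fraction=0.5,
                        r2_gx=0.05, target_or=1.15)
        assert mr_power(p) == pytest.approx(1.0, abs=1e-12)

    def test_against_numerical_integration_oracle(self):
        # oracle: rejection probability of |Z| > z_crit for
        # Z ~ Normal(ncp, 1), integrated numerically
        p = PowerParams(alpha=3.3e-3, n_outcome=100_000, case_fraction=0.5,
                        r2_gx=0.05, target_or=1.15)
        ncp = math.log(1.15) * math.sqrt(100_000 * 0.05 * 0.25)
        z_crit = stats.norm.ppf(1 - 3.3e-3 / 2)

        def density(z):
            return stats.norm.pdf(z, loc=ncp)

        reject, _ = integrate.quad(density, z_crit, 40)
        reject_low, _ = integrate.quad(density, -40, -z_crit)
        assert mr_power(p) == pytest.approx(reject + reject_low, abs=1e-6)


class TestBonferroni:
    def test_strong_signal_flagged(self):
        r = ivw(make_hset([0.1], [0.05], se_by=[0.0001]))
        flagged = bonferroni_flag([r], n_tests=15)
        assert flagged[0].pvalue < 1e-60
        assert flagged[0].significant_after_bonferroni

    def test_nominal_signal_not_flagged_after_correction(self):
        # p = 0.01 is below 0.05 but above 0.05/15 = 3.3e-3
        bx, by, se = 0.1, 0.02577, 0.01  # z = 2.577 -> p ~ 0.00996
        r = wald_ratio(bx, 0.01, by * bx, se * bx)
        flagged = bonferroni_flag([r], n_tests=15)
        assert 0.0033 < flagged[0].pvalue < 0.05
        assert not flagged[0].significant_after_bonferroni

    def test_boundary_is_strict(self):
        import dataclasses

        r = ivw(make_hset([0.1], [0.02]))
        r = dataclasses.replace(r, pvalue=0.05 / 15)
        flagged = bonferroni_flag([r], n_tests=15)
        assert not flagged[0].significant_after_bonferroni
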