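"""The five causal estimators, MR-Egger and the OR_SD transform."""

import math

import numpy as np
import pytest
from scipy import stats

from conftest import make_instruments
from mrscreen import estimators as est
from mrscreen.estimators import (
    EstimationError,
    SingularDesignError,
    egger,
    ivw_fe,
    max_likelihood,
    to_or_scale,
    wald_ratio,
    weighted_median,
    weighted_mode,
)


def one_instrument(bx, sx, by, sy):
    return make_instruments([bx], [sx], [by], [sy])[0]


class TestWaldRatio:
    def test_first_order_formula(self):
        e = wald_ratio(one_instrument(0.2, 0.01, 0.05, 0.02))
        assert e.theta == pytest.approx(0.25)
        assert e.se == pytest.approx(0.10)
        assert e.or_sd == pytest.approx(1.284, abs=5e-4)
        assert e.n_snps == 1

    def test_zero_outcome_effect(self):
        e = wald_ratio(one_instrument(0.2, 0.01, 0.0, 0.02))
        assert e.theta == 0.0
        assert e.or_sd == 1.0
        assert e.pvalue == 1.0

    def test_second_order_se_matches_delta_method(self):
        e = wald_ratio(one_instrument(0.2, 0.01, 0.05, 0.02), se_order="second")
        expected = math.sqrt(0.02**2 / 0.2**2 + 0.05**2 * 0.01**2 / 0.2**4)
        assert e.se == pytest.approx(expected, rel=1e-12)

    def test_zero_exposure_effect_is_error(self):
        with pytest.raises(EstimationError, match="beta_exposure"):
            wald_ratio(one_instrument(0.0, 0.01, 0.05, 0.02))


class TestIVW:
    def test_single_instrument_reduces_to_wald(self):
        inst = one_instrument(0.2, 0.01, 0.05, 0.02)
        w = wald_ratio(inst)
        i = ivw_fe([inst])
        assert (i.theta, i.se, i.pvalue) == (w.theta, w.se, w.pvalue)

    def test_two_ratio_hand_computation(self):
        # ratios 0.2 (se 0.1) and 0.4 (se 0.2): use unit exposure effects
        insts = make_instruments([1.0, 1.0], [1e-9, 1e-9], [0.2, 0.4], [0.1, 0.2])
        e = ivw_fe(insts)
        assert e.theta == pytest.approx((0.2 * 100 + 0.4 * 25) / 125, rel=1e-12)
        assert e.se == pytest.approx(1 / math.sqrt(125), rel=1e-12)

    def test_equals_wls_through_origin(self, rng):
        for _ in range(100):
            k = rng.integers(3, 12)
            bx = rng.uniform(0.02, 0.2, k) * rng.choice([-1, 1], k)
            sx = rng.uniform(0.002, 0.01, k)
            by = rng.normal(0, 0.05, k)
            sy = rng.uniform(0.01, 0.05, k)
            e = ivw_fe(make_instruments(bx, sx, by, sy))
            w = 1 / sy**2
            slope = np.sum(w * bx * by) / np.sum(w * bx**2)
            se = np.sum(w * bx**2) ** -0.5
            assert e.theta == pytest.approx(slope, abs=1e-10)
            assert e.se == pytest.approx(se, abs=1e-10)

    def test_empty_set_is_error(self):
        with pytest.raises(EstimationError):
            ivw_fe([])


class TestMaxLikelihood:
    def test_noiseless_data_recovers_generating_effect(self, rng):
        bx = rng.uniform(0.05, 0.2, 10)
        theta = 0.37
        insts = make_instruments(bx, np.full(10, 0.005), theta * bx, np.full(10, 0.02))
        e = max_likelihood(insts)
        assert e.theta == pytest.approx(theta, abs=1e-7)

    def test_matches_grid_search_of_profile_likelihood(self):
        bx = np.array([0.08, 0.15])
        sx = np.array([0.01, 0.012])
        by = np.array([0.03, 0.02])
        sy = np.array([0.02, 0.025])

        def profile_loglik(t):
            return -0.5 * np.sum((by - t * bx) ** 2 / (sy**2 + t**2 * sx**2))

        grid = np.linspace(-2, 2, 400_001)
        t_grid = grid[np.argmax([profile_loglik(t) for t in grid])]
        e = max_likelihood(make_instruments(bx, sx, by, sy))
        assert e.theta == pytest.approx(t_grid, abs=1e-4)

    def test_close_to_ivw_without_heterogeneity(self, rng):
        hits = 0
        for _ in range(200):
            bx = rng.uniform(0.03, 0.08, 20)
            sx = np.full(20, 0.005)
            sy = np.full(20, 0.02)
            by = 0.2 * bx + rng.normal(0, 1, 20) * sy
            bx_obs = bx + rng.normal(0, 1, 20) * sx
            insts = make_instruments(bx_obs, sx, by, sy)
            m = max_likelihood(insts)
            i = ivw_fe(insts)
            joint_se = math.hypot(m.se, i.se)
            hits += abs(m.theta - i.theta) <= 2 * joint_se
        assert hits >= 195  # both estimate the same quantity

    def test_requires_two_instruments(self):
        with pytest.raises(EstimationError):
            max_likelihood(make_instruments([0.1], [0.01], [0.02], [0.02]))


class TestWeightedMedian:
    def test_all_equal_ratios_return_that_value(self):
        bx = np.array([0.1, 0.2, 0.05])
        insts = make_instruments(bx, [0.01] * 3, 0.4 * bx, [0.02, 0.05, 0.01])
        e = weighted_median(insts, n_boot=50, seed=1)
        assert e.theta == pytest.approx(0.4, rel=1e-12)

    def test_hand_interpolation_with_equal_weights(self):
        # equal first-order ratio variances => equal weights; ratios 0.1/0.2/0.9
        bx = np.ones(3)
        sy = np.ones(3)
        by = np.array([0.1, 0.2, 0.9])
        e = weighted_median(make_instruments(bx, [1e-6] * 3, by, sy), n_boot=50, seed=1)
        # cumulative standardized weights 1/6, 1/2, 5/6 -> interpolates to 0.2
        assert e.theta == pytest.approx(0.2, rel=1e-12)

    def test_seeded_bootstrap_is_bit_reproducible(self, five_instruments):
        a = weighted_median(five_instruments, n_boot=200, seed=7)
        b = weighted_median(five_instruments, n_boot=200, seed=7)
        assert a.se == b.se
        c = weighted_median(five_instruments, n_boot=200, seed=8)
        assert c.se != a.se

    def test_requires_three_instruments(self):
        with pytest.raises(EstimationError):
            weighted_median(make_instruments([0.1, 0.1], [0.01] * 2, [0.02] * 2, [0.02] * 2))


class TestWeightedMode:
    def test_all_equal_ratios_degenerate(self):
        bx = np.array([0.1, 0.2, 0.05])
        insts = make_instruments(bx, [0.01] * 3, 0.25 * bx, [0.02] * 3)
        e = weighted_mode(insts, n_boot=50, seed=1)
        assert e.theta == pytest.approx(0.25, rel=1e-12)

    def test_mode_lands_in_majority_cluster_and_matches_grid(self, rng):
        # 5 ratios near 0.3, 2 outliers near 1.5, equal weights
        ratios = np.array([0.28, 0.29, 0.30, 0.31, 0.32, 1.48, 1.52])
        bx = np.ones(7)
        insts = make_instruments(bx, [1e-6] * 7, ratios, np.ones(7))
        e = weighted_mode(insts, n_boot=50, seed=1)
        assert abs(e.theta - 0.30) < 0.02  # inside the cluster half-width

        # independent dense-grid argmax of the same kernel density
        weights = np.full(7, 1 / 7)
        h = est._mode_bandwidth(ratios, phi=1.0)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 200_001)
        dens = (weights[None, :] * np.exp(
            -0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2
        )).sum(axis=1)
        t_grid = grid[np.argmax(dens)]
        assert e.theta == pytest.approx(t_grid, abs=(grid[1] - grid[0]) * 2)

    def test_seeded_determinism(self, five_instruments):
        a = weighted_mode(five_instruments, n_boot=100, seed=3)
        b = weighted_mode(five_instruments, n_boot=100, seed=3)
        assert (a.theta, a.se) == (b.theta, b.se)

    def test_requires_three_instruments_and_positive_phi(self, five_instruments):
        with pytest.raises(EstimationError):
            weighted_mode(five_instruments[:2])
        with pytest.raises(EstimationError, match="phi"):
            weighted_mode(five_instruments, phi=0.0)


class TestEgger:
    def test_exact_linear_fit_recovered_exactly(self):
        bx = np.array([0.05, 0.08, 0.12, 0.2])
        by = 0.01 + 0.3 * bx
        r = egger(make_instruments(bx, [0.01] * 4, by, [0.02] * 4))
        assert r.intercept == pytest.approx(0.01, abs=1e-12)
        assert r.slope.theta == pytest.approx(0.3, abs=1e-12)

    def test_matches_closed_form_weighted_normal_equations(self):
        bx = np.array([0.05, -0.08, 0.12, 0.2])
        by = np.array([0.021, -0.013, 0.044, 0.051])
        sy = np.array([0.02, 0.03, 0.025, 0.04])
        r = egger(make_instruments(bx, [0.01] * 4, by, sy))
        sign = np.where(bx < 0, -1.0, 1.0)
        bxo, byo = bx * sign, by * sign
        W = np.diag(1 / sy**2)
        X = np.column_stack([np.ones(4), bxo])
        coef = np.linalg.solve(X.T @ W @ X, X.T @ W @ byo)
        assert r.intercept == pytest.approx(coef[0], abs=1e-12)
        assert r.slope.theta == pytest.approx(coef[1], abs=1e-12)

    def test_no_intercept_no_noise_slope_equals_ivw(self):
        bx = np.array([0.05, 0.08, 0.12, 0.2, 0.31])
        sy = np.array([0.02, 0.03, 0.025, 0.04, 0.02])
        by = 0.3 * bx  # alpha = 0, zero residual
        insts = make_instruments(bx, [0.01] * 5, by, sy)
        r = egger(insts)
        i = ivw_fe(insts)
        assert r.slope.theta == pytest.approx(i.theta, abs=1e-10)

    def test_singular_design_rejected(self):
        bx = np.array([0.1, -0.1, 0.1])
        by = np.array([0.02, 0.01, 0.03])
        with pytest.raises(SingularDesignError):
            egger(make_instruments(bx, [0.01] * 3, by, [0.02] * 3))

    def test_intercept_pvalue_is_two_sided_normal(self):
        bx = np.array([0.05, 0.08, 0.12, 0.2])
        by = np.array([0.03, 0.02, 0.05, 0.07])
        r = egger(make_instruments(bx, [0.01] * 4, by, [0.02] * 4))
        expected = 2 * stats.norm.sf(abs(r.intercept) / r.intercept_se)
        assert r.intercept_pvalue == pytest.approx(expected, rel=1e-12)


class TestORScale:
    def test_null_effect(self):
        or_sd, lo, hi, p = to_or_scale(0.0, 0.1)
        assert or_sd == 1.0
        assert p == 1.0
        assert lo * hi == pytest.approx(1.0, rel=1e-12)  # log-symmetric

    def test_reference_values(self):
        or_sd, lo, hi, p = to_or_scale(0.25, 0.10)
        assert or_sd == pytest.approx(1.284, abs=5e-4)
        assert lo == pytest.approx(math.exp(0.25 - 1.959964 * 0.10), abs=1e-5)
        assert hi == pytest.approx(math.exp(0.25 + 1.959964 * 0.10), abs=1e-5)
        assert p == pytest.approx(2 * stats.norm.sf(2.5), rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(EstimationError):
            to_or_scale(0.1, 0.0)
        with pytest.raises(EstimationError):
            to_or_scale(0.1, 0.1, level=1.0)


class TestEquivariance:
    def _estimates(self, insts, seed=11):
        return {
            "ivw_fe": ivw_fe(insts),
            "mle": max_likelihood(insts),
            "weighted_median": weighted_median(insts, n_boot=400, seed=seed),
            "weighted_mode": weighted_mode(insts, n_boot=400, seed=seed),
            "egger_slope": egger(insts).slope,
        }

    def test_negating_outcome_negates_theta(self, five_instruments):
        flipped = make_instruments(
            [i.beta_exposure for i in five_instruments],
            [i.se_exposure for i in five_instruments],
            [-i.beta_outcome for i in five_instruments],
            [i.se_outcome for i in five_instruments],
        )
        a = self._estimates(five_instruments)
        b = self._estimates(flipped)
        for m in a:
            assert b[m].theta == pytest.approx(-a[m].theta, abs=1e-8), m
        for m in ("ivw_fe", "mle", "egger_slope"):
            assert b[m].se == pytest.approx(a[m].se, rel=1e-8), m
        # bootstrap SEs agree in distribution, not bit-for-bit
        for m in ("weighted_median", "weighted_mode"):
            assert b[m].se == pytest.approx(a[m].se, rel=0.2), m

    def test_rescaling_exposure_divides_theta(self, five_instruments):
        c = 2.5
        scaled = make_instruments(
            [c * i.beta_exposure for i in five_instruments],
            [c * i.se_exposure for i in five_instruments],
            [i.beta_outcome for i in five_instruments],
            [i.se_outcome for i in five_instruments],
        )
        for fn in (ivw_fe, max_likelihood, lambda x: egger(x).slope):
            assert fn(scaled).theta == pytest.approx(
                fn(five_instruments).theta / c, rel=1e-6
            )
        w = wald_ratio(scaled[0])
        assert w.theta == pytest.approx(
            wald_ratio(five_instruments[0]).theta / c, rel=1e-12
        )
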