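"""Derivative tests, effect translation, percentile contrasts, asymmetry."""

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from conftest import make_analysis_table, noiseless_table, quadratic_surface
from oracles import cluster_bootstrap_se, finite_difference

from dcar.errors import NotEstimableError, NotTestableError
from dcar.hypothesis_tests import (
    EvalPoint,
    ar_derivative,
    asymmetry_test,
    dc_derivative,
    percentile_contrast,
    relative_to_absolute,
    test_derivative as derivative_test,
)
from dcar.quadratic_model import ModelSpec, build_design, fit_lpm
from dcar.synthetic import SyntheticConfig, simulate_panel


def fitted(gamma, n=120, seed=0, fe="none"):
    table = noiseless_table(gamma, n=n, seed=seed)
    return fit_lpm(build_design(table, ModelSpec(fixed_effect=fe))), table


class TestDerivatives:
    @pytest.mark.parametrize(
        "gamma,point,expected_dc",
        [
            ({}, (0.3, 0.4), 0.0),
            ({"e0": 1.0}, (0.9, 0.1), 1.0),
            ({"e0": 0.5, "e0_sq": 0.2, "e0_x_abs_delta": -0.1}, (0.5, 0.2),
             0.5 + 2 * 0.2 * 0.5 - 0.1 * 0.2),
        ],
    )
    def test_dc_closed_form(self, gamma, point, expected_dc):
        fit, _ = fitted({"intercept": 0.3, **gamma})
        at = EvalPoint(*point)
        assert dc_derivative(fit, at) == pytest.approx(expected_dc, abs=1e-7)

    @pytest.mark.parametrize(
        "gamma,point,expected_ar",
        [
            ({}, (0.5, 0.2), 0.0),
            ({"abs_delta": -0.3}, (0.1, 0.9), -0.3),
            ({"abs_delta": -0.3, "abs_delta_sq": 0.05, "e0_x_abs_delta": 0.1},
             (0.5, 0.2), -0.3 + 2 * 0.05 * 0.2 + 0.1 * 0.5),
        ],
    )
    def test_ar_closed_form(self, gamma, point, expected_ar):
        fit, _ = fitted({"intercept": 0.3, **gamma})
        at = EvalPoint(*point)
        assert ar_derivative(fit, at) == pytest.approx(expected_ar, abs=1e-7)

    @pytest.mark.parametrize("point", [(0.2, 0.1), (0.5, 0.2), (0.8, 0.6)])
    def test_derivatives_match_finite_differences(self, point):
        """Both marginal effects equal central finite differences of the
        fitted quadratic surface."""
        gamma = {"intercept": 0.3, "e0": 0.5, "abs_delta": -0.3, "e0_sq": 0.2,
                 "abs_delta_sq": 0.05, "e0_x_abs_delta": -0.1}
        fit, _ = fitted(gamma)
        g = fit.params

        def surface(e0, d):
            return (g.get("intercept", 0.0) + g["e0"] * e0 + g["abs_delta"] * d
                    + g["e0_sq"] * e0**2 + g["abs_delta_sq"] * d**2
                    + g["e0_x_abs_delta"] * e0 * d)

        e0, d = point
        at = EvalPoint(e0, d)
        fd_dc = finite_difference(lambda x: surface(x, d), e0)
        fd_ar = finite_difference(lambda x: surface(e0, x), d)
        assert dc_derivative(fit, at) == pytest.approx(fd_dc, abs=1e-6)
        assert ar_derivative(fit, at) == pytest.approx(fd_ar, abs=1e-6)

    def test_dc_not_estimable_under_individual_fe(self):
        cfg = SyntheticConfig(n_females=40, obs_per_female=5, seed=3)
        table = simulate_panel(cfg)
        fit = fit_lpm(build_design(table, ModelSpec(fixed_effect="individual")))
        with pytest.raises(NotEstimableError):
            dc_derivative(fit)
        # AR remains estimable within females
        assert np.isfinite(ar_derivative(fit))


class TestTestDerivative:
    def test_null_coefficients_give_p_one(self):
        fit, _ = fitted({"intercept": 0.4, "e0": 0.1})
        fit.params.loc[:] = 0.0  # exactly null coefficients, nonzero variance
        fit.vcov = pd.DataFrame(
            np.eye(len(fit.params)), index=fit.params.index, columns=fit.params.index
        )
        res = derivative_test(fit, hypothesis="DC")
        assert res.estimate == 0.0
        assert res.p_value == pytest.approx(1.0)
        assert not res.consistent_with_theory

    def test_unit_variance_gradient(self):
        """With identity vcov and gradient (1,0,...), the SE is exactly 1."""
        fit, _ = fitted({"intercept": 0.3, "e0": 0.5})
        fit.vcov = pd.DataFrame(
            np.eye(len(fit.params)), index=fit.params.index, columns=fit.params.index
        )
        res = derivative_test(fit, at=EvalPoint(0.0, 0.0), hypothesis="DC")
        assert res.se == pytest.approx(1.0)
        assert res.estimate == pytest.approx(fit.params["e0"], abs=1e-9)

    def test_se_close_to_cluster_bootstrap(self):
        """Delta-method SE within 10% of a 2000-replicate cluster bootstrap."""
        cfg = SyntheticConfig(
            n_females=40, obs_per_female=5, n_groups=3,
            gamma={"intercept": 0.3, "e0": 0.3, "abs_delta": -0.2},
            noise_sd=0.3, female_sd=0.1, group_sd=0.0,
            outcome_link="gaussian", seed=9,
        )
        table = simulate_panel(cfg)
        spec = ModelSpec(fixed_effect="group")
        fit = fit_lpm(build_design(table, spec))
        at = EvalPoint(fit.env_means["e0"], fit.env_means["abs_delta"])
        res = derivative_test(fit, at=at, hypothesis="AR")

        def refit(df):
            t = make_analysis_table(df)
            return fit_lpm(build_design(t, spec))

        boot = cluster_bootstrap_se(
            table.df, refit, lambda f: ar_derivative(f, at), n_boot=2000, seed=1
        )
        assert res.se == pytest.approx(boot, rel=0.10)


class TestEffectTranslation:
    @pytest.mark.parametrize(
        "relative,baseline,expected",
        [(13.18, 73.74, 9.72), (59.19, 73.74, 43.65), (0.0, 50.0, 0.0)],
    )
    def test_relative_to_absolute(self, relative, baseline, expected):
        assert relative_to_absolute(relative, baseline) == expected

    def test_domain_error(self):
        with pytest.raises(ValueError):
            relative_to_absolute(10.0, -5.0)
        with pytest.raises(ValueError):
            relative_to_absolute(10.0, 0.0)


class TestPercentileContrast:
    def test_zero_environment_effects(self):
        fit, table = fitted({"intercept": 0.4})
        res = percentile_contrast(fit, table, "e0")
        assert res.relative_difference_pct == pytest.approx(0.0, abs=1e-6)
        assert res.absolute_difference_pct == pytest.approx(0.0, abs=1e-6)

    def test_equal_percentiles_give_zero(self):
        fit, table = fitted({"intercept": 0.4, "e0": 0.3})
        res = percentile_contrast(fit, table, "e0", lo=50.0, hi=50.0)
        assert res.absolute_difference_pct == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("variable", ["e0", "abs_delta"])
    def test_arithmetic_identity(self, variable):
        gamma = {"intercept": 0.5, "e0": 0.3, "abs_delta": -0.4,
                 "e0_sq": -0.1, "abs_delta_sq": 0.2, "e0_x_abs_delta": 0.05}
        fit, table = fitted(gamma, n=200, seed=2)
        res = percentile_contrast(fit, table, variable)
        assert abs(
            res.absolute_difference_pct
            - res.relative_difference_pct * res.baseline_mean_pct / 100.0
        ) < 0.005
        # the adverse direction follows the variable
        assert res.adverse == ("low" if variable == "e0" else "high")

    def test_percentile_out_of_support(self):
        fit, table = fitted({"intercept": 0.4})
        with pytest.raises(ValueError):
            percentile_contrast(fit, table, "e0", lo=-5.0)


class TestAsymmetry:
    @staticmethod
    def signed_delta_table(seed, n_females=150, obs=6, pos_effect=-0.4,
                           neg_effect=-0.4, noise=0.0):
        r = np.random.default_rng(seed)
        n = n_females * obs
        fid = np.repeat([f"f{i:03d}" for i in range(n_females)], obs)
        e0 = np.repeat(r.uniform(0, 1, n_females), obs)
        delta = r.normal(0, 0.25, n)
        dpos, dneg = np.maximum(delta, 0), np.maximum(-delta, 0)
        y = 0.5 + pos_effect * dpos + neg_effect * dneg + r.normal(0, noise, n)
        df = pd.DataFrame(
            {
                "female_id": fid,
                "group_id": np.repeat([f"g{i % 4}" for i in range(n_females)], obs),
                "e0": e0, "e1": e0 + delta, "delta": delta,
                "abs_delta": np.abs(delta), "outcome": y,
                "age": r.uniform(5, 20, n), "group_size": r.uniform(10, 60, n),
            }
        )
        return make_analysis_table(df)

    def test_forced_symmetry_noiseless(self):
        table = self.signed_delta_table(seed=0, noise=0.0)
        res = asymmetry_test(table, ModelSpec(fixed_effect="group"))
        assert res.statistic == pytest.approx(0.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0)

    def test_one_signed_deltas_not_testable(self):
        table = self.signed_delta_table(seed=1)
        df = table.df.copy()
        df["delta"] = df["delta"].abs()
        df["e1"] = df["e0"] + df["delta"]
        with pytest.raises(NotTestableError):
            asymmetry_test(make_analysis_table(df), ModelSpec(fixed_effect="group"))

    def test_size_under_symmetric_noise(self):
        """Rejection rate ≈ alpha when positive and negative effects coincide.

        The joint cluster-robust Wald statistic needs a healthy cluster count
        (the usual few-cluster over-rejection appears below ~100 females), so
        size is checked at 200 females.
        """
        n_reps, alpha = 300, 0.05
        hits = 0
        for s in range(n_reps):
            table = self.signed_delta_table(seed=s, n_females=200, obs=5, noise=0.3)
            res = asymmetry_test(table, ModelSpec(fixed_effect="group"))
            hits += int(res.p_value < alpha)
        rate = hits / n_reps
        mc_se = np.sqrt(alpha * (1 - alpha) / n_reps)
        assert abs(rate - alpha) < 3 * mc_se + 1e-9

    def test_power_against_twofold_asymmetry(self):
        """Δ⁺ effect twice the Δ⁻ effect is detected at large n."""
        hits = 0
        n_reps = 50
        for s in range(n_reps):
            table = self.signed_delta_table(
                seed=1000 + s, n_females=250, obs=8,
                pos_effect=-0.8, neg_effect=-0.4, noise=0.3,
            )
            res = asymmetry_test(table, ModelSpec(fixed_effect="group"))
            hits += int(res.p_value < 0.05)
        assert hits / n_reps >= 0.90
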