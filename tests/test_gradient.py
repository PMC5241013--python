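"""Robust regression, weighted R^2, bootstrap intervals, group analysis."""

import numpy as np
import pandas as pd
import pytest

import coversad as cs
from coversad.gradient import COMBINED


def make_linear(rng, n=60, slope=-4e-4, intercept=1.0, noise=0.05,
                xlo=129.0, xhi=1437.0):
    x = rng.uniform(xlo, xhi, size=n)
    y = intercept + slope * x + rng.normal(0, noise, size=n)
    return x, y


class TestRobustFit:
    def test_exact_line_recovered_with_unit_weights(self):
        x = np.linspace(100, 1400, 20)
        y = 1.5 - 3e-4 * x
        fit = cs.robust_fit(x, y)
        assert fit.slope == pytest.approx(-3e-4, abs=1e-12)
        assert fit.intercept == pytest.approx(1.5, abs=1e-9)
        np.testing.assert_allclose(fit.weights, 1.0)
        assert fit.converged

    def test_recovers_known_slope_within_monte_carlo_error(self):
        rng = np.random.default_rng(11)
        slopes = [cs.robust_fit(*make_linear(rng)).slope for _ in range(200)]
        se = np.std(slopes) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - (-4e-4)) < 3 * se

    def test_outlier_downweighted_and_slope_closer_than_ols(self):
        x = np.linspace(0, 10, 12)
        y = 2.0 + 0.5 * x
        y_out = y.copy()
        y_out[3] += 25.0
        fit = cs.robust_fit(x, y_out)
        ols_slope = np.polyfit(x, y_out, 1)[0]
        assert fit.weights[3] < 1.0
        assert np.delete(fit.weights, 3).min() > fit.weights[3]
        assert abs(fit.slope - 0.5) < abs(ols_slope - 0.5)

    def test_agrees_with_statsmodels_rlm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        x, y = make_linear(rng, noise=0.1)
        y[5] += 2.0  # give the M-estimator something to downweight
        fit = cs.robust_fit(x, y)
        X = sm.add_constant(x)
        rlm = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=cs.HUBER_C)).fit(scale_est="mad")
        assert fit.slope == pytest.approx(rlm.params[1], rel=1e-4)
        assert fit.intercept == pytest.approx(rlm.params[0], rel=1e-3)

    def test_huber_constant_to_infinity_reduces_to_ols(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            x, y = make_linear(rng, noise=0.2)
            fit = cs.robust_fit(x, y, c=1e12)
            b, a = np.polyfit(x, y, 1)
            assert fit.slope == pytest.approx(b, abs=1e-8)
            assert fit.intercept == pytest.approx(a, abs=1e-8)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cs.robust_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cs.robust_fit([1.0, 2.0], [1.0, 2.0])

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            cs.robust_fit([1.0, 2.0, np.nan], [1.0, 2.0, 3.0])


class TestR2Weighted:
    def test_perfect_fit_is_one(self):
        x = np.linspace(0, 10, 10)
        y = 1 + 2 * x
        fit = cs.robust_fit(x, y)
        assert cs.r2_weighted(fit, x, y) == pytest.approx(1.0)

    def test_null_slope_on_centred_data_is_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([-1.0, 1.0, -1.0, 1.0])
        fit = cs.RobustFit(slope=0.0, intercept=0.0, weights=np.ones(4), scale=1.0,
                           converged=True, n_iter=1)
        assert cs.r2_weighted(fit, x, y) == pytest.approx(0.0)

    def test_equals_ordinary_r2_with_unit_weights(self):
        rng = np.random.default_rng(4)
        x, y = make_linear(rng, noise=0.1)
        b, a = np.polyfit(x, y, 1)
        fit = cs.RobustFit(slope=b, intercept=a, weights=np.ones(len(x)), scale=1.0,
                           converged=True, n_iter=1)
        resid = y - a - b * x
        r2_ols = 1 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)
        assert cs.r2_weighted(fit, x, y) == pytest.approx(r2_ols, abs=1e-12)

    def test_zero_weighted_variance_rejected(self):
        fit = cs.RobustFit(slope=0.0, intercept=1.0, weights=np.ones(3), scale=1.0,
                           converged=True, n_iter=1)
        with pytest.raises(ValueError):
            cs.r2_weighted(fit, np.array([1.0, 2.0, 3.0]), np.array([1.0, 1.0, 1.0]))


class TestBootstrapSlopeCI:
    def test_noiseless_collinear_data_degenerate_interval(self):
        x = np.linspace(0, 10, 15)
        y = 3.0 - 0.25 * x
        lo, hi = cs.bootstrap_slope_ci(x, y, n_replicates=200, seed=0)
        assert lo == pytest.approx(-0.25, abs=1e-10)
        assert hi == pytest.approx(-0.25, abs=1e-10)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        x, y = make_linear(rng)
        a = cs.bootstrap_slope_ci(x, y, n_replicates=300, seed=42)
        b = cs.bootstrap_slope_ci(x, y, n_replicates=300, seed=42)
        assert a == b

    def test_interval_width_shrinks_with_n(self):
        rng = np.random.default_rng(6)
        widths = []
        for n in (30, 120):
            deltas = []
            for _ in range(10):
                x, y = make_linear(rng, n=n, noise=0.1)
                lo, hi = cs.bootstrap_slope_ci(x, y, n_replicates=300, seed=1)
                deltas.append(hi - lo)
            widths.append(np.mean(deltas))
        assert widths[1] < widths[0]

    def test_preconditions(self):
        x = np.linspace(0, 1, 10)
        with pytest.raises(ValueError):
            cs.bootstrap_slope_ci(x, x, n_replicates=50)
        with pytest.raises(ValueError):
            cs.bootstrap_slope_ci(x, x, level=1.5)


class TestRunGradientAnalysis:
    def _tables(self, rng, slopes={"G1": -4e-4, "G2": 0.0}, n=40):
        rows_f, rows_s = [], []
        i = 0
        for grp, slope in slopes.items():
            x, y = make_linear(rng, n=n, slope=slope, noise=0.08)
            for xi, yi in zip(x, y):
                pid = f"P{i:04d}"
                rows_f.append(
                    {"plot_id": pid, "visit_id": "V1", "pareto_alpha": yi,
                     "lognormal_sigma": 1.0 / max(yi, 0.1), "excluded_reason": ""}
                )
                rows_s.append(
                    {"plot_id": pid, "visit_id": "V1", "vegetation_group": grp,
                     "map_mm": xi}
                )
                i += 1
        return pd.DataFrame(rows_f), pd.DataFrame(rows_s)

    def test_combined_equals_concatenation_of_groups(self):
        rng = np.random.default_rng(9)
        fits, sites = self._tables(rng)
        out = cs.run_gradient_analysis(
            fits, sites, responses=("pareto_alpha",), n_replicates=100, seed=1
        )
        combined = out[out.group == COMBINED].iloc[0]
        merged = fits.merge(sites, on=["plot_id", "visit_id"])
        direct = cs.robust_fit(merged.map_mm.to_numpy(), merged.pareto_alpha.to_numpy())
        assert combined.slope == pytest.approx(direct.slope, rel=1e-9)
        assert combined.n_obs == len(merged)

    def test_flags_reflect_signal_vs_null(self):
        rng = np.random.default_rng(10)
        fits, sites = self._tables(rng, n=60)
        out = cs.run_gradient_analysis(
            fits, sites, responses=("pareto_alpha",), n_replicates=500, seed=2
        ).set_index("group")
        assert not out.loc["G1", "overlaps_zero"]
        assert out.loc["G2", "overlaps_zero"]

    def test_small_group_skipped_with_warning(self):
        fits = pd.DataFrame(
            [{"plot_id": "P1", "visit_id": "V1", "pareto_alpha": 1.0,
              "excluded_reason": ""}]
        )
        sites = pd.DataFrame(
            [{"plot_id": "P1", "visit_id": "V1", "vegetation_group": "tiny",
              "map_mm": 500.0}]
        )
        with pytest.warns(UserWarning, match="skipped"):
            out = cs.run_gradient_analysis(
                fits, sites, responses=("pareto_alpha",), n_replicates=100
            )
        assert out.empty

    def test_all_filtered_gives_empty_table_no_crash(self):
        fits = pd.DataFrame(
            [{"plot_id": "P1", "visit_id": "V1", "pareto_alpha": 1.0,
              "excluded_reason": "fewer than 6 species recorded"}]
        )
        sites = pd.DataFrame(
            [{"plot_id": "P1", "visit_id": "V1", "vegetation_group": "G",
              "map_mm": 500.0}]
        )
        with pytest.warns(UserWarning):
            out = cs.run_gradient_analysis(fits, sites, responses=("pareto_alpha",),
                                           n_replicates=100)
        assert out.empty
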