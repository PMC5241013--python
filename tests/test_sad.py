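"""SAD fitting: closed-form MLEs against numeric oracles, AIC comparison,
rank-abundance prediction, eligibility."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

import coversad as cs
from coversad.sad import DegenerateFitError


def numeric_pareto_mle(x, xmin):
    """Independent oracle: maximise the Pareto log-likelihood numerically."""

    def nll(alpha):
        return -(
            len(x) * np.log(alpha)
            + len(x) * alpha * np.log(xmin)
            - (alpha + 1) * np.sum(np.log(x))
        )

    res = optimize.minimize_scalar(nll, bounds=(1e-6, 1e3), method="bounded",
                                   options={"xatol": 1e-10})
    return res.x


def numeric_lognormal_sigma(x):
    """Independent oracle: profile the lognormal likelihood over sigma."""

    def nll(sigma):
        mu = np.mean(np.log(x))
        return -np.sum(stats.lognorm.logpdf(x, s=sigma, scale=np.exp(mu)))

    res = optimize.minimize_scalar(nll, bounds=(1e-8, 50), method="bounded",
                                   options={"xatol": 1e-10})
    return res.x


class TestEligibility:
    @pytest.mark.parametrize(
        "covers, expected",
        [([1.0] * 5, False), ([1.0] * 6, True), ([], False), ([1, 2, 3, 0, 0, 0, 0], False)],
    )
    def test_six_species_rule(self, covers, expected):
        assert cs.eligible_for_sad(covers) is expected


class TestFitPareto:
    def test_hand_worked_example(self):
        # alpha = n / sum ln(x/xmin) = 4 / (6 ln 2) for covers 1,2,4,8.
        fit = cs.fit_pareto([1, 2, 4, 8], xmin=1.0)
        assert fit.params["alpha"] == pytest.approx(4 / (6 * np.log(2)), rel=1e-12)
        assert fit.aic == pytest.approx(2 - 2 * fit.loglik)
        assert fit.n_species == 4

    def test_equals_numeric_maximiser(self, rng):
        for _ in range(20):
            x = (rng.pareto(1.2, size=12) + 1) * 0.099
            fit = cs.fit_pareto(x, xmin=0.099)
            assert fit.params["alpha"] == pytest.approx(
                numeric_pareto_mle(x, 0.099), abs=1e-6
            )

    def test_consistency_at_large_n(self, rng):
        alphas = [
            cs.fit_pareto((rng.pareto(2.0, 1000) + 1) * 0.099, xmin=0.099).params["alpha"]
            for _ in range(100)
        ]
        assert np.mean(alphas) == pytest.approx(2.0, rel=0.05)

    def test_cover_below_xmin_rejected(self):
        with pytest.raises(ValueError, match="xmin"):
            cs.fit_pareto([0.05, 1.0], xmin=0.099)

    def test_all_covers_at_xmin_divergent(self):
        with pytest.raises(DegenerateFitError):
            cs.fit_pareto([1.0, 1.0, 1.0], xmin=1.0)

    @given(
        st.lists(st.floats(0.1, 1000), min_size=3, max_size=30),
        st.floats(0.5, 20),
    )
    @settings(deadline=None, max_examples=60)
    def test_scale_equivariance(self, covers, c):
        covers = np.asarray(covers)
        xmin = covers.min()
        try:
            base = cs.fit_pareto(covers, xmin=xmin)
        except DegenerateFitError:
            return
        scaled = cs.fit_pareto(covers * c, xmin=xmin * c)
        assert scaled.params["alpha"] == pytest.approx(base.params["alpha"], rel=1e-9)

    def test_bias_correction_factor(self):
        x = [1, 2, 4, 8, 16]
        raw = cs.fit_pareto(x, xmin=1.0).params["alpha"]
        corr = cs.fit_pareto(x, xmin=1.0, bias_correction=True).params["alpha"]
        assert corr == pytest.approx(raw * 3 / 5)


class TestFitParetoTail:
    def test_recovers_shape_on_clean_pareto_data(self, rng):
        alphas = [
            cs.fit_pareto_tail((rng.pareto(1.0, 40) + 1) * 0.1).params["alpha"]
            for _ in range(300)
        ]
        assert np.mean(alphas) == pytest.approx(1.0, rel=0.07)

    def test_ignores_noise_below_threshold(self, rng):
        # Corrupting every cover below the median must not move the estimate.
        x = np.sort((rng.pareto(1.0, 30) + 1))[::-1]
        fit = cs.fit_pareto_tail(x)
        k = len(x) // 2
        noisy = x.copy()
        noisy[k + 1 :] *= rng.uniform(0.2, 1.0, size=len(x) - k - 1)
        fit_noisy = cs.fit_pareto_tail(np.sort(noisy)[::-1])
        assert fit_noisy.params["alpha"] == pytest.approx(fit.params["alpha"], rel=1e-9)

    def test_too_few_covers_rejected(self):
        with pytest.raises(ValueError):
            cs.fit_pareto_tail([1.0, 2.0, 3.0])


class TestFitLognormal:
    def test_closed_form_example(self):
        fit = cs.fit_lognormal([1.0, np.e**2, 1.0, np.e**2])
        assert fit.params["mu"] == pytest.approx(1.0)
        assert fit.params["sigma"] == pytest.approx(1.0)
        assert fit.aic == pytest.approx(4 - 2 * fit.loglik)

    def test_equal_covers_degenerate_flag(self):
        fit = cs.fit_lognormal([3.0, 3.0, 3.0])
        assert fit.degenerate
        assert fit.params["sigma"] == 0.0
        assert fit.aic == np.inf

    def test_sigma_matches_numeric_maximiser(self, rng):
        for _ in range(10):
            x = rng.lognormal(0.5, 1.3, size=20)
            fit = cs.fit_lognormal(x)
            assert fit.params["sigma"] == pytest.approx(
                numeric_lognormal_sigma(x), abs=1e-6
            )

    def test_nonpositive_covers_rejected(self):
        with pytest.raises(ValueError):
            cs.fit_lognormal([1.0, 0.0, 2.0])


class TestCompareModels:
    def _fits(self, covers):
        return [cs.fit_pareto(covers, xmin=min(covers)), cs.fit_lognormal(covers)]

    def test_lowest_aic_wins(self):
        a = cs.SadFit("pareto", {"alpha": 1.0}, loglik=-49, aic=100, n_species=10)
        b = cs.SadFit("lognormal", {"mu": 0, "sigma": 1}, loglik=-53, aic=110, n_species=10)
        assert cs.compare_models([a, b]) == "pareto"
        assert cs.compare_models([b, a]) == "pareto"

    def test_tie_breaks_toward_fewer_parameters(self):
        a = cs.SadFit("pareto", {"alpha": 1.0}, loglik=-49, aic=100, n_species=10)
        b = cs.SadFit("lognormal", {"mu": 0, "sigma": 1}, loglik=-48, aic=100, n_species=10)
        assert cs.compare_models([b, a]) == "pareto"

    def test_mismatched_data_lengths_rejected(self):
        a = cs.SadFit("pareto", {"alpha": 1.0}, loglik=-49, aic=100, n_species=10)
        b = cs.SadFit("lognormal", {"mu": 0, "sigma": 1}, loglik=-48, aic=99, n_species=12)
        with pytest.raises(ValueError, match="different"):
            cs.compare_models([a, b])

    def test_pareto_data_selects_pareto_mostly(self, rng):
        wins = 0
        n_rep = 200
        for _ in range(n_rep):
            x = (rng.pareto(1.0, 30) + 1) * 0.099
            if cs.compare_models(self._fits(list(x))) == "pareto":
                wins += 1
        assert wins > n_rep / 2


class TestPredictRad:
    def test_single_species_gets_median(self):
        fit = cs.fit_pareto([1, 2, 4, 8], xmin=1.0)
        pred = cs.predict_rad(fit, 1)
        alpha = fit.params["alpha"]
        # Closed-form Pareto quantile Q(p) = xmin (1-p)^(-1/alpha) at p=0.5.
        assert pred[0] == pytest.approx(1.0 * 0.5 ** (-1 / alpha))

    def test_matches_numeric_cdf_inversion(self):
        from scipy.optimize import brentq

        fit = cs.fit_pareto([1, 2, 4, 8, 16, 32], xmin=1.0)
        alpha = fit.params["alpha"]
        S = 6
        pred = cs.predict_rad(fit, S)
        for i in range(1, S + 1):
            p = (S - i + 0.5) / S
            q = brentq(lambda x: 1 - (1.0 / x) ** alpha - p, 1.0, 1e9)
            assert pred[i - 1] == pytest.approx(q, rel=1e-8)

    @given(st.floats(0.3, 5.0), st.integers(1, 40))
    @settings(deadline=None, max_examples=60)
    def test_predictions_non_increasing(self, alpha, s):
        fit = cs.SadFit("pareto", {"alpha": alpha}, loglik=0.0, aic=0.0, n_species=s, xmin=0.099)
        pred = cs.predict_rad(fit, s)
        assert np.all(np.diff(pred) <= 1e-12)

    def test_lognormal_predictions_non_increasing(self):
        fit = cs.fit_lognormal([0.1, 0.5, 1.0, 4.0, 9.0, 20.0])
        pred = cs.predict_rad(fit, 6)
        assert np.all(np.diff(pred) <= 0)

    @pytest.mark.parametrize("alpha_pair", [(0.5, 1.0), (1.0, 2.0), (2.0, 4.0)])
    def test_lower_alpha_means_less_even_rad(self, alpha_pair):
        # A smaller shape gives a heavier tail: the top-ranked species takes
        # a larger share of total cover, so the Gini-Simpson evenness of the
        # predicted ranks falls.  (As alpha -> infinity all covers collapse
        # onto the scale and the shares become equal.)
        evenness = []
        for alpha in alpha_pair:
            fit = cs.SadFit(
                "pareto", {"alpha": alpha}, loglik=0.0, aic=0.0, n_species=20, xmin=0.099
            )
            evenness.append(cs.simpson_index(cs.predict_rad(fit, 20)))
        assert evenness[0] < evenness[1]
        # and the dominant species' share of the predicted total shrinks
        shares = [
            (p := cs.predict_rad(
                cs.SadFit("pareto", {"alpha": a}, loglik=0.0, aic=0.0,
                          n_species=20, xmin=0.099), 20)
             )[0] / p.sum()
            for a in alpha_pair
        ]
        assert shares[0] > shares[1]


class TestFitSadsTable:
    def test_exclusions_and_fits(self):
        cfg = cs.LandscapeConfig(n_plots_per_group=4, groups=("G",), n_species=10, seed=2)
        visits = cs.simulate_landscape(cfg)
        matrix = cs.build_cover_matrix(visits)
        fits = cs.fit_sads_table(matrix)
        assert len(fits) == 4
        fitted = fits[fits["excluded_reason"] == ""]
        assert (fitted["pareto_alpha"] > 0).all()
        assert (fitted["lognormal_sigma"] > 0).all()
        assert set(fitted["best_model"]) <= {"pareto", "lognormal"}

    def test_small_plot_excluded_with_reason(self):
        import pandas as pd

        matrix = pd.DataFrame(
            [[10.0, 5.0, 2.0, 1.0, 0.5, 0.0]],
            index=pd.MultiIndex.from_tuples([("P1", "V1")], names=["plot_id", "visit_id"]),
            columns=[f"S{i}" for i in range(6)],
        )
        fits = cs.fit_sads_table(matrix)
        assert fits.loc[0, "excluded_reason"] != ""
        assert np.isnan(fits.loc[0, "pareto_alpha"])
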