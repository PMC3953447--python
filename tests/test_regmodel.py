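"""Sample-level regression engine: R², type-II partials, VIF, bootstrap optimism."""

import numpy as np
import pytest

from bodycomp import tables
from bodycomp.corrstats import (
    multiple_r2_from_corr, round_half_up, sample_with_exact_corr,
)
from bodycomp.regmodel import fit_model, optimism_bootstrap, sample_corr_partial
from conftest import make_adjusted

MEN = tables.adjusted_corr_target("male")
WOMEN = tables.adjusted_corr_target("female")


def table_sample(corr, outcome, n, seed=0):
    """Adjusted-matrix sample whose sample correlations equal the printed table."""
    lab = [outcome] + tables.PREDICTORS
    x = sample_with_exact_corr(corr.loc[lab, lab], n, seed=seed)
    return make_adjusted(x, lab)


class TestFitModel:
    @pytest.mark.parametrize("corr,outcome,n,expected_pct", [
        (MEN, "SMT", 598, 45), (WOMEN, "SMT", 594, 53), (MEN, "VAT", 598, 65),
    ])
    def test_published_r2_on_table_matched_samples(self, corr, outcome, n, expected_pct):
        fit = fit_model(table_sample(corr, outcome, n), outcome, tables.PREDICTORS)
        assert round_half_up(100 * fit.r2) == expected_pct

    def test_r2_equals_matrix_route_on_sample_correlations(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((120, 4)) @ rng.standard_normal((4, 4))
        am = make_adjusted(x, ["y", "a", "b", "c"])
        fit = fit_model(am, "y", ["a", "b", "c"])
        c = np.corrcoef(x, rowvar=False)
        r2_matrix = multiple_r2_from_corr(c[0, 1:], c[1:, 1:])
        assert fit.r2 == pytest.approx(r2_matrix, abs=1e-10)

    def test_type2_partial_equals_matrix_partial(self):
        """Dual-implementation oracle: SSE-increment vs precision-matrix route."""
        rng = np.random.default_rng(11)
        x = rng.standard_normal((200, 4)) @ rng.standard_normal((4, 4))
        am = make_adjusted(x, ["y", "a", "b", "c"])
        fit = fit_model(am, "y", ["a", "b", "c"])
        for pred in ("a", "b", "c"):
            others = [p for p in ("a", "b", "c") if p != pred]
            alt = sample_corr_partial(am, "y", pred, others)
            assert fit.partial(pred).r == pytest.approx(alt, abs=1e-10)

    def test_agrees_with_statsmodels_and_pingouin_oracles(self):
        """Independent-library cross-check of R², partial r and VIF."""
        import pandas as pd
        import pingouin as pg
        import statsmodels.api as sm

        rng = np.random.default_rng(21)
        x = rng.standard_normal((150, 4)) @ rng.standard_normal((4, 4))
        am = make_adjusted(x, ["y", "a", "b", "c"])
        fit = fit_model(am, "y", ["a", "b", "c"])

        sm_fit = sm.OLS(x[:, 0], sm.add_constant(x[:, 1:])).fit()
        assert fit.r2 == pytest.approx(sm_fit.rsquared, abs=1e-10)

        df = pd.DataFrame(x, columns=["y", "a", "b", "c"])
        for pred in ("a", "b", "c"):
            covar = [p for p in ("a", "b", "c") if p != pred]
            pg_r = pg.partial_corr(df, x=pred, y="y", covar=covar)["r"].iloc[0]
            assert fit.partial(pred).r == pytest.approx(pg_r, abs=1e-8)

    def test_men_vat_wc_partial_before_rounding(self):
        fit = fit_model(table_sample(MEN, "VAT", 598), "VAT", tables.PREDICTORS)
        assert fit.partial("WC").r == pytest.approx(0.4380, abs=5e-4)

    def test_orthogonal_predictors_vif_one_partial_equals_marginal(self):
        # outcome correlates 0.6 with predictor a only; predictors mutually orthogonal
        target = np.eye(4)
        target[0, 1] = target[1, 0] = 0.6
        x = sample_with_exact_corr(target, 150, seed=2)
        am = make_adjusted(x, ["y", "a", "b", "c"])
        fit = fit_model(am, "y", ["a", "b", "c"])
        assert all(v == pytest.approx(1.0, abs=1e-8) for v in fit.vifs.values())
        assert fit.partial("a").r == pytest.approx(0.6, abs=1e-6)

    def test_vif_closed_form_for_correlated_pair(self):
        c = np.array([[1.0, 0.3, 0.3], [0.3, 1.0, 0.9], [0.3, 0.9, 1.0]])
        am = make_adjusted(sample_with_exact_corr(c, 100, seed=4), ["y", "a", "b"])
        fit = fit_model(am, "y", ["a", "b"])
        assert fit.vifs["a"] == pytest.approx(1 / (1 - 0.81), abs=1e-6)
        assert fit.vifs["b"] == pytest.approx(1 / (1 - 0.81), abs=1e-6)

    def test_partial_within_its_ci(self):
        fit = fit_model(table_sample(WOMEN, "VAT", 594), "VAT", tables.PREDICTORS)
        for p in fit.partials:
            assert p.ci_low <= p.r <= p.ci_high

    def test_monotonicity_adding_predictor(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((80, 4))
        am = make_adjusted(x, ["y", "a", "b", "c"])
        r2_two = fit_model(am, "y", ["a", "b"]).r2
        r2_three = fit_model(am, "y", ["a", "b", "c"]).r2
        assert r2_three >= r2_two - 1e-12

    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(50)
        x = np.column_stack([rng.standard_normal(50), a, 2 * a])
        am = make_adjusted(x, ["y", "a", "b"])
        with pytest.raises(ValueError, match="collinear"):
            fit_model(am, "y", ["a", "b"])


class TestOptimismBootstrap:
    def informative_sample(self, n, seed, r2=0.65):
        rng = np.random.default_rng(seed)
        p = 3
        x = rng.standard_normal((n, p))
        beta = np.full(p, np.sqrt(r2 / p))
        y = x @ beta + np.sqrt(1 - r2) * rng.standard_normal(n)
        return make_adjusted(np.column_stack([y, x]), ["y", "a", "b", "c"])

    def test_identity_resampler_gives_zero_optimism(self):
        am = self.informative_sample(100, 0)
        res = optimism_bootstrap(am, "y", ["a", "b", "c"], b=5,
                                 resampler=lambda rng, n: np.arange(n))
        assert res.optimism == 0.0
        assert res.corrected_r2 == res.apparent_r2

    def test_noise_regression_optimism_matches_brute_force_oracle(self):
        """Pure-noise fit at n=20, p=3: bootstrap optimism tracks the true
        optimism E[R²_apparent − R²_on_fresh_data], estimated by brute force.

        (Note: the true optimism exceeds the expected apparent R² of
        p/(n−1) ≈ 0.16 because a noise model has *negative* out-of-sample
        R²; both terms contribute.)
        """
        rng = np.random.default_rng(3)
        n, p = 20, 3
        # brute-force oracle: apparent minus fresh-sample R² over many datasets
        oracle = []
        for _ in range(300):
            x = rng.standard_normal((n, p))
            y = rng.standard_normal(n)
            design = np.column_stack([np.ones(n), x])
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            r2_app = 1 - ((y - design @ beta) ** 2).sum() / ((y - y.mean()) ** 2).sum()
            xf = rng.standard_normal((2000, p))
            yf = rng.standard_normal(2000)
            pred = np.column_stack([np.ones(2000), xf]) @ beta
            r2_new = 1 - ((yf - pred) ** 2).sum() / ((yf - yf.mean()) ** 2).sum()
            oracle.append(r2_app - r2_new)
        opt = []
        for seed in range(8):
            x = np.random.default_rng(50 + seed).standard_normal((n, p + 1))
            am = make_adjusted(x, ["y", "a", "b", "c"])
            res = optimism_bootstrap(am, "y", ["a", "b", "c"], b=200, seed=seed)
            opt.append(res.optimism)
        assert np.mean(opt) == pytest.approx(np.mean(oracle), abs=0.08)

    def test_corrected_below_apparent_in_expectation(self):
        opts = [
            optimism_bootstrap(self.informative_sample(150, s), "y",
                               ["a", "b", "c"], b=40, seed=s).optimism
            for s in range(20)
        ]
        assert np.mean(opts) > 0

    def test_seeded_reproducibility(self):
        am = self.informative_sample(80, 1)
        r1 = optimism_bootstrap(am, "y", ["a", "b", "c"], b=30, seed=42)
        r2 = optimism_bootstrap(am, "y", ["a", "b", "c"], b=30, seed=42)
        assert r1.optimism == r2.optimism

    def test_invalid_b_rejected(self):
        am = self.informative_sample(50, 0)
        with pytest.raises(ValueError):
            optimism_bootstrap(am, "y", ["a", "b", "c"], b=0)
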