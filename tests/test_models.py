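"""OLS/AICc machinery, polynomial fits, correlation and Mantel tests."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel

from commphylo import (
    candidate_rankings,
    fit_ols_ml,
    fit_poly2,
    mantel,
    mt_wilhelm_indices,
    pearson,
    rank_models,
    zscore,
)
from commphylo.errors import DomainError, ValidationError


class TestZscore:
    def test_example(self):
        assert np.allclose(zscore([1, 2, 3]), [-1, 0, 1])

    def test_moments(self):
        rng = np.random.default_rng(0)
        z = zscore(rng.normal(3, 7, size=40))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(DomainError):
            zscore([2.0, 2.0, 2.0])


class TestOLS:
    def test_matches_statsmodels(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(12, 2)), columns=["u", "v"])
        y = 1.0 + 0.5 * X["u"] - 2.0 * X["v"] + rng.normal(0, 0.3, 12)
        fit = fit_ols_ml(y, X)
        ref = sm.OLS(np.asarray(y), sm.add_constant(X.to_numpy())).fit()
        assert np.allclose(fit.coefficients, ref.params, atol=1e-9)
        assert fit.rss == pytest.approx(ref.ssr, abs=1e-9)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-9)

    def test_published_null_model_row(self):
        table = mt_wilhelm_indices()
        fit = fit_ols_ml(table["nri"], None, response="nri")
        assert fit.loglik == pytest.approx(-13.688, abs=0.01)
        assert fit.aicc == pytest.approx(33.8, abs=0.1)

    def test_perfect_fit_rejected(self):
        x = np.arange(8.0)
        with pytest.raises(DomainError, match="unbounded|zero"):
            fit_ols_ml(2 * x + 1, x[:, None])

    def test_rank_deficiency_rejected(self):
        x = np.arange(8.0)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValidationError):
            fit_ols_ml(np.random.default_rng(1).normal(size=8), X)

    def test_too_few_observations(self):
        with pytest.raises(DomainError):
            fit_ols_ml([1.0, 2.0], np.arange(2.0)[:, None])


class TestRanking:
    def test_single_model_weight_one(self):
        fit = fit_ols_ml(np.array([1.0, 2.0, 4.0, 3.0, 5.0]), None)
        ranked = rank_models([fit])
        assert ranked["weight"].iloc[0] == pytest.approx(1.0)
        assert ranked["delta_aicc"].iloc[0] == 0.0

    def test_two_model_closed_form_weights(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=10)
        f1 = fit_ols_ml(y, None)
        f2 = fit_ols_ml(y, None)
        f2.aicc = f1.aicc + 2.0  # forced Delta = 2
        ranked = rank_models([f1, f2])
        e = np.exp(-1.0)
        assert ranked["weight"].iloc[0] == pytest.approx(1 / (1 + e))
        assert ranked["weight"].iloc[1] == pytest.approx(e / (1 + e))

    def test_weights_sum_to_one(self):
        table = mt_wilhelm_indices()
        ranking = candidate_rankings(
            table, ["nri", "nti", "ses_pd"],
            ["plant_richness", "predator_abundance", "temperature"],
        )
        for resp, grp in ranking.groupby("response"):
            assert len(grp) == 8
            assert grp["weight"].sum() == pytest.approx(1.0, abs=1e-12)
            assert grp["delta_aicc"].min() == 0.0

    # Published ranking table: (response, predictors) -> (loglik, aicc, delta, weight).
    # Computed here from the printed 2-dp per-site table, so small deviations
    # from the published (unrounded-input) values are expected.
    PUBLISHED = {
        ("nri", ()): (-13.688, 33.8, 0.00, 0.540),
        ("nri", ("plant_richness",)): (-11.944, 35.9, 2.11, 0.188),
        ("nri", ("predator_abundance",)): (-11.951, 35.9, 2.12, 0.187),
        ("nri", ("temperature",)): (-12.898, 37.8, 4.02, 0.072),
        ("nri", ("predator_abundance", "temperature")): (-10.332, 42.0, 8.22, 0.009),
        ("nri", ("plant_richness", "predator_abundance")): (-11.533, 44.4, 10.62, 0.003),
        ("nri", ("plant_richness", "temperature")): (-11.915, 45.2, 11.39, 0.002),
        ("nri", ("plant_richness", "predator_abundance", "temperature")):
            (-10.047, 60.1, 26.32, 0.000),
        ("nti", ()): (-14.991, 36.4, 0.00, 0.694),
        ("nti", ("temperature",)): (-13.705, 39.4, 3.03, 0.153),
        ("nti", ("plant_richness",)): (-14.486, 41.0, 4.59, 0.07),
        ("nti", ("predator_abundance",)): (-14.544, 41.1, 4.71, 0.066),
        ("nti", ("predator_abundance", "temperature")): (-11.319, 44.0, 7.59, 0.016),
        ("nti", ("plant_richness", "temperature")): (-13.702, 48.7, 12.36, 0.001),
        ("nti", ("plant_richness", "predator_abundance")): (-14.421, 50.2, 13.79, 0.001),
        ("nti", ("plant_richness", "predator_abundance", "temperature")):
            (-10.324, 60.6, 24.27, 0.000),
        ("ses_pd", ()): (-16.191, 38.8, 0.00, 0.535),
        ("ses_pd", ("temperature",)): (-14.095, 40.2, 1.41, 0.265),
        ("ses_pd", ("plant_richness",)): (-15.133, 42.3, 3.48, 0.094),
        ("ses_pd", ("predator_abundance",)): (-15.212, 42.4, 3.64, 0.087),
        ("ses_pd", ("predator_abundance", "temperature")): (-12.272, 45.9, 7.10, 0.015),
        ("ses_pd", ("plant_richness", "temperature")): (-14.014, 49.4, 10.58, 0.003),
        ("ses_pd", ("plant_richness", "predator_abundance")): (-14.956, 51.2, 12.46, 0.001),
        ("ses_pd", ("plant_richness", "predator_abundance", "temperature")):
            (-10.792, 61.6, 22.80, 0.000),
    }

    def test_full_published_table_within_rounding(self):
        table = mt_wilhelm_indices()
        ranking = candidate_rankings(
            table, ["nri", "nti", "ses_pd"],
            ["plant_richness", "predator_abundance", "temperature"],
        )
        by_key = {
            (row["response"], tuple(sorted(p for p in row["model"].split(" + ")
                                           if p != "Null"))): row
            for _, row in ranking.iterrows()
        }
        for (resp, preds), (loglik, aicc_v, delta, weight) in self.PUBLISHED.items():
            row = by_key[(resp, tuple(sorted(preds)))]
            assert row["loglik"] == pytest.approx(loglik, abs=0.05)
            assert row["aicc"] == pytest.approx(aicc_v, abs=0.3)
            assert row["delta_aicc"] == pytest.approx(delta, abs=0.3)
            assert row["weight"] == pytest.approx(weight, abs=0.01)

    def test_ranking_invariant_to_predictor_scaling(self):
        table = mt_wilhelm_indices().copy()
        base = candidate_rankings(table, ["nri"], ["plant_richness", "temperature"])
        table["plant_richness"] *= 37.0
        scaled = candidate_rankings(table, ["nri"], ["plant_richness", "temperature"])
        assert np.allclose(base["aicc"], scaled["aicc"], atol=1e-9)


class TestPoly2:
    def test_exact_quadratic_flagged(self):
        x = np.linspace(-2, 2, 10)
        res = fit_poly2(x**2, x)
        assert res.exact and res.quadratic_p == 0.0
        assert res.quadratic_coefficient == pytest.approx(1.0, abs=1e-9)

    def test_p_matches_raw_basis_t_test(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=15)
        y = 1 + x + rng.normal(size=15)
        res = fit_poly2(y, x)
        ref = sm.OLS(y, sm.add_constant(np.column_stack([x, x**2]))).fit()
        assert res.quadratic_p == pytest.approx(ref.pvalues[2], abs=1e-9)
        assert res.quadratic_coefficient == pytest.approx(ref.params[2], abs=1e-9)

    def test_null_p_uniform(self):
        # y independent of x: the quadratic-term p-value is U(0,1)
        rng = np.random.default_rng(12)
        x = rng.normal(size=12)
        ps = [fit_poly2(rng.normal(size=12), x).quadratic_p for _ in range(400)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPearson:
    def test_identity_and_reversal(self):
        x = np.arange(10.0)
        assert pearson(x, x).r == pytest.approx(1.0)
        assert pearson(x, x[::-1]).r == pytest.approx(-1.0)

    def test_published_index_correlation(self):
        table = mt_wilhelm_indices()
        res = pearson(table["nti"], table["ses_pd"])
        assert res.r == pytest.approx(-0.97, abs=0.01)
        assert res.p < 0.0001

    def test_constant_rejected(self):
        with pytest.raises(DomainError):
            pearson([1, 1, 1], [1, 2, 3])


def _random_dm(n, seed, ids=None):
    rng = np.random.default_rng(seed)
    M = rng.random((n, n))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0)
    return DistanceMatrix(M, ids=ids or [str(i) for i in range(n)])


class TestMantel:
    def test_identical_matrices(self):
        d = _random_dm(8, 1)
        res = mantel(d, d, permutations=199, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 200)

    def test_seed_reproducible(self):
        d1, d2 = _random_dm(8, 2), _random_dm(8, 3)
        a = mantel(d1, d2, permutations=99, seed=42)
        b = mantel(d1, d2, permutations=99, seed=42)
        assert a.r == b.r and a.p == b.p

    def test_statistic_matches_skbio(self):
        d1, d2 = _random_dm(9, 4), _random_dm(9, 5)
        ours = mantel(d1, d2, permutations=99, seed=0)
        r_ref, p_ref, _ = skbio_mantel(
            d1, d2, method="pearson", permutations=0, alternative="greater"
        )
        assert ours.r == pytest.approx(r_ref, abs=1e-12)

    def test_label_mismatch_rejected(self):
        d1 = _random_dm(5, 6)
        d2 = _random_dm(5, 7, ids=list("vwxyz"))
        with pytest.raises(ValidationError):
            mantel(d1, d2, permutations=9, seed=0)

    def test_label_reordering_aligned(self):
        d1 = _random_dm(6, 8)
        order = ["3", "1", "0", "5", "4", "2"]
        d2 = d1.filter(order)
        res = mantel(d1, d2, permutations=9, seed=0)
        assert res.r == pytest.approx(1.0)
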