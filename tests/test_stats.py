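import numpy as np
import pandas as pd
import pytest

from mpod.errors import CollinearityError, DegenerateVariableError
from mpod.stats import factor_analysis, multiple_regression, stepwise_forward


def _frame(**cols):
    return pd.DataFrame(cols)


class TestFactorAnalysis:
    def test_perfect_collinearity_groups_onto_one_factor(self):
        rng = np.random.default_rng(0)
        v1 = rng.normal(size=200)
        table = _frame(v1=v1, v2=v1.copy(), v3=rng.normal(size=200))
        fr = factor_analysis(table, ["v1", "v2", "v3"], n_factors=2)
        f1 = fr.loadings["F1"].abs()
        assert f1["v1"] > 0.99 and f1["v2"] > 0.99
        assert fr.loadings["F2"].abs()["v3"] > 0.9
        assert not fr.significant["F1"]["v3"]

    def test_correlated_trio_yields_single_dominant_factor(self):
        rng = np.random.default_rng(1)
        n, rho = 500, 0.98
        S = np.full((3, 3), rho)
        np.fill_diagonal(S, 1.0)
        draws = rng.multivariate_normal(np.zeros(3), S, size=n)
        cols = {f"faz{i}": draws[:, i] for i in range(3)}
        fr = factor_analysis(_frame(**cols), list(cols))
        assert fr.loadings.shape[1] == 1
        assert fr.variance_explained[0] > 0.97
        assert fr.significant["F1"].all()

    def test_orthogonal_variables_show_no_groupings(self):
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            table = pd.DataFrame(rng.normal(size=(1000, 6)),
                                 columns=list("abcdef"))
            fr = factor_analysis(table, list("abcdef"))
            assert (fr.significant.sum(axis=0) <= 1).all()

    def test_loadings_reproduce_correlation_matrix(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(300, 4))
        x[:, 1] += 0.7 * x[:, 0]
        x[:, 3] -= 0.4 * x[:, 2]
        table = pd.DataFrame(x, columns=list("wxyz"))
        fr = factor_analysis(table, list("wxyz"))
        L = fr.loadings_full.to_numpy()
        corr = np.corrcoef(
            ((table - table.mean()) / table.std(ddof=1)).to_numpy(), rowvar=False)
        np.testing.assert_allclose(L @ L.T, corr, atol=1e-10)

    def test_variance_explained_non_increasing(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(200, 5))
        x[:, 1] += x[:, 0]
        table = pd.DataFrame(x, columns=list("abcde"))
        fr = factor_analysis(table, list("abcde"), n_factors=3)
        assert (np.diff(fr.variance_explained) <= 1e-12).all()

    def test_constant_column_named_in_error(self):
        table = _frame(a=np.arange(10.0), b=np.ones(10))
        with pytest.raises(DegenerateVariableError, match="b"):
            factor_analysis(table, ["a", "b"], n_factors=1)


class TestMultipleRegression:
    @staticmethod
    def _linked_predictors(n, seed):
        # predictors equicorrelated so that Var(0.605 x1+0.426 x2+0.19 x3) = 1,
        # making the exact linear combination itself a standardised variable
        beta = np.array([0.605, 0.426, 0.190])
        rho = (1.0 - beta @ beta) / (2 * (beta[0] * beta[1] + beta[0] * beta[2]
                                          + beta[1] * beta[2]))
        S = np.full((3, 3), rho)
        np.fill_diagonal(S, 1.0)
        rng = np.random.default_rng(seed)
        X = rng.multivariate_normal(np.zeros(3), S, size=n)
        return X, beta

    def test_exact_linear_target_recovered(self):
        X, beta = self._linked_predictors(4000, 4)
        y = X @ beta
        table = pd.DataFrame(np.column_stack([y, X]),
                             columns=["y", "x1", "x2", "x3"])
        res = multiple_regression(table, "y", ["x1", "x2", "x3"])
        assert res.r2 == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(res.betas.to_numpy(), beta, atol=0.02)
        assert res.useful

    def test_independent_response_gives_near_zero_r2(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(rng.normal(size=(3000, 3)), columns=["y", "x1", "x2"])
        res = multiple_regression(table, "y", ["x1", "x2"])
        assert res.r2 < 0.01
        assert not res.useful

    def test_duplicated_predictor_rejected(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=50)
        table = _frame(y=rng.normal(size=50), x1=x, x2=x.copy())
        with pytest.raises(CollinearityError):
            multiple_regression(table, "y", ["x1", "x2"])

    def test_missing_rows_dropped_listwise(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=60)
        y = 0.9 * x + 0.1 * rng.normal(size=60)
        table = _frame(y=y, x=x)
        table.loc[:9, "y"] = np.nan
        res = multiple_regression(table, "y", ["x"])
        assert res.n_used == 50


class TestStepwiseForward:
    def test_ordered_marginal_contributions(self):
        rng = np.random.default_rng(8)
        n = 500
        X = rng.normal(size=(n, 3))
        y = 0.9 * X[:, 0] + 0.4 * X[:, 1] + 0.2 * X[:, 2] + 0.3 * rng.normal(size=n)
        table = pd.DataFrame(np.column_stack([y, X]),
                             columns=["y", "x1", "x2", "x3"])
        res = stepwise_forward(table, "y", ["x3", "x1", "x2"])
        assert res.selected_order == ["x1", "x2", "x3"]
        assert res.stepwise_r2_increments is not None
        assert np.all(np.diff(res.stepwise_r2_increments) < 0)

    def test_increments_sum_to_total(self):
        rng = np.random.default_rng(9)
        n = 200
        X = rng.normal(size=(n, 4))
        y = X @ np.array([0.7, 0.4, 0.2, 0.0]) + 0.5 * rng.normal(size=n)
        table = pd.DataFrame(np.column_stack([y, X]),
                             columns=["y", "a", "b", "c", "d"])
        res = stepwise_forward(table, "y", ["a", "b", "c", "d"])
        assert sum(res.stepwise_r2_increments) == pytest.approx(res.r2, abs=1e-12)

    def test_single_informative_predictor(self):
        rng = np.random.default_rng(10)
        n = 1000
        X = rng.normal(size=(n, 4))
        y = 0.8 * X[:, 2] + 0.3 * rng.normal(size=n)
        table = pd.DataFrame(np.column_stack([y, X]),
                             columns=["y", "n1", "n2", "sig", "n3"])
        res = stepwise_forward(table, "y", ["n1", "n2", "sig", "n3"])
        assert res.selected_order[0] == "sig"
        assert set(res.selected_order) - {"sig"} == set()

    def test_zero_alpha_selects_nothing(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=100)
        table = _frame(y=0.9 * x, x=x)
        res = stepwise_forward(table, "y", ["x"], alpha_enter=0.0)
        assert res.selected_order == []
        assert res.r2 == 0.0
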