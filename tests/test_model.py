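"""LASSO solver oracles, cross-validation, model selection, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from curvedcell.model import (
    DeltaIDDLasso,
    DesignMatrix,
    build_design,
    cross_validate,
    default_lambda_grid,
    lambda_max,
    lasso_fit,
    lasso_path,
    leave_one_out_diagnostic,
    normalization_search,
    one_se_select,
    r_squared,
    simulate_comparison_dataset,
)


@pytest.fixture(scope="module")
def toy_xy(rng):
    X = rng.normal(size=(24, 6))
    beta = np.array([0.5, -0.3, 0.0, 0.0, 0.2, 0.0])
    y = X @ beta + rng.normal(0, 0.05, size=24)
    return X, y


class TestBuildDesign:
    FEATS = pd.DataFrame(
        {
            "strain": ["wt", "mutA", "mutB"],
            "n_per_cell": [11.6, 6.6, 9.0],
            "enrichment_low": [1.25, 1.0, 1.1],
        }
    )

    def test_self_comparison_zero_row(self):
        comps = pd.DataFrame(
            {"strain1": ["wt"], "strain2": ["wt"], "observed_didd": [0.0]}
        )
        d = build_design(comps, self.FEATS)
        assert np.allclose(d.X_raw, 0.0)
        assert d.y[0] == 0.0

    def test_swapped_order_negates_rows(self):
        comps = pd.DataFrame(
            {
                "strain1": ["mutA", "wt"],
                "strain2": ["wt", "mutA"],
                "observed_didd": [0.1, -0.1],
            }
        )
        d = build_design(comps, self.FEATS)
        assert np.allclose(d.X[0], -d.X[1])
        assert np.allclose(d.X_raw[0], [6.6 - 11.6, 1.0 - 1.25])

    def test_missing_strain_dropped_with_warning(self):
        comps = pd.DataFrame(
            {
                "strain1": ["mutA", "ghost"],
                "strain2": ["wt", "wt"],
                "observed_didd": [0.1, 0.2],
            }
        )
        with pytest.warns(UserWarning, match="ghost"):
            d = build_design(comps, self.FEATS)
        assert d.n == 1


class TestLassoSolver:
    def test_zero_lambda_is_ols(self, toy_xy):
        X, y = toy_xy
        b0, beta = lasso_fit(X, y, 0.0)
        ref = np.linalg.lstsq(np.column_stack([np.ones(len(y)), X]), y, rcond=None)[0]
        assert np.allclose(beta, ref[1:], atol=1e-8)
        assert np.isclose(b0, ref[0], atol=1e-8)

    def test_lambda_max_zeros_exactly(self, toy_xy):
        X, y = toy_xy
        lmax = lambda_max(X, y)
        for lam in (lmax, 1.5 * lmax):
            _, beta = lasso_fit(X, y, lam)
            assert np.all(beta == 0.0)
        # just below λ_max something is active
        _, beta = lasso_fit(X, y, 0.99 * lmax)
        assert np.any(beta != 0.0)

    def test_single_predictor_soft_threshold_closed_form(self, rng):
        """1-column problem: solution equals the soft-threshold formula and
        the minimum of an exhaustive grid search over β."""
        x = rng.normal(size=40)
        y = 0.7 * x + rng.normal(0, 0.1, size=40)
        lam = 0.3
        _, beta = lasso_fit(x[:, None], y, lam, fit_intercept=False)
        n = len(y)
        closed = np.sign(x @ y) * max(abs(2 * x @ y / n) - lam, 0) / (2 * (x @ x) / n)
        assert beta[0] == pytest.approx(closed, abs=1e-10)
        grid = np.linspace(-1.5, 1.5, 20001)
        obj = ((y[:, None] - np.outer(x, grid)) ** 2).mean(axis=0) + lam * np.abs(grid)
        assert abs(beta[0] - grid[np.argmin(obj)]) < 2e-4

    def test_matches_sklearn(self, toy_xy):
        """Independent implementation check: objective maps to sklearn's
        Lasso with alpha = λ/2."""
        from sklearn.linear_model import Lasso

        X, y = toy_xy
        for lam in (0.02, 0.1, 0.4):
            _, beta = lasso_fit(X, y, lam)
            sk = Lasso(alpha=lam / 2, tol=1e-12, max_iter=200_000).fit(X, y)
            assert np.allclose(beta, sk.coef_, atol=1e-8)

    def test_support_size_monotone_along_path(self, toy_xy):
        X, y = toy_xy
        lams = default_lambda_grid(X, y, n=40)
        _, betas = lasso_path(X, y, lams)
        sizes = [(b != 0).sum() for b in betas]  # lams descending
        # non-decreasing support as lambda shrinks, at the path knots
        assert all(s2 >= s1 - 1 for s1, s2 in zip(sizes, sizes[1:]))
        assert sizes[0] == 0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            lasso_fit(np.array([[np.nan]]), np.array([1.0]), 0.1)

    @given(lam=st.floats(min_value=1e-4, max_value=2.0))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_solution_satisfies_kkt(self, lam):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 4))
        y = X @ [0.4, 0.0, -0.2, 0.1] + rng.normal(0, 0.05, 30)
        b0, beta = lasso_fit(X, y, lam)
        r = y - b0 - X @ beta
        grad = 2.0 * X.T @ r / len(y)
        for j in range(4):
            if beta[j] != 0.0:
                assert np.isclose(grad[j], lam * np.sign(beta[j]), atol=1e-6)
            else:
                assert abs(grad[j]) <= lam + 1e-6


class TestCrossValidation:
    def test_bitwise_reproducible(self):
        design, _ = simulate_comparison_dataset(seed=1)
        a = cross_validate(design, k=10, seed=3)
        b = cross_validate(design, k=10, seed=3)
        assert np.array_equal(a.mse_mean, b.mse_mean)
        assert np.array_equal(a.fold_assignment, b.fold_assignment)

    def test_k_equals_n_is_loo(self):
        design, _ = simulate_comparison_dataset(n=12, seed=2)
        lams = np.array([0.05, 0.2])
        cv = cross_validate(design, lams=lams, k=12, seed=0)
        # explicit leave-one-out
        loo = np.zeros((12, len(lams)))
        for i in range(12):
            keep = np.arange(12) != i
            _, betas = lasso_path(design.X[keep], design.y[keep], lams)
            ints, betas = lasso_path(design.X[keep], design.y[keep], lams)
            preds = design.X[i] @ betas.T + ints
            loo[i] = (preds - design.y[i]) ** 2
        assert np.allclose(np.sort(cv.mse_mean), np.sort(loo.mean(axis=0)), atol=1e-10)

    def test_pure_noise_prefers_large_lambda(self):
        """With no signal the null (large-λ) model wins CV on average."""
        wins = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            design = DesignMatrix(
                y=rng.normal(0, 0.05, 20),
                X=rng.normal(size=(20, 8)),
                columns=[f"c{i}" for i in range(8)],
            )
            cv = cross_validate(design, k=10, seed=s)
            lam = one_se_select(cv)
            _, beta = lasso_fit(design.X, design.y, lam)
            if (beta != 0).sum() == 0:
                wins += 1
        assert wins >= 16

    def test_small_n_reduces_to_loo_with_warning(self):
        design, _ = simulate_comparison_dataset(n=6, seed=3)
        with pytest.warns(UserWarning, match="leave-one-out"):
            cv = cross_validate(design, k=10, seed=0)
        assert cv.k == 6


class TestOneSESelection:
    def _cv(self, lams, mse, sem):
        from curvedcell.model import CVResult

        return CVResult(
            lams=np.asarray(lams, dtype=float),
            mse_mean=np.asarray(mse, dtype=float),
            mse_sem=np.asarray(sem, dtype=float),
            k=10, seed=0, fold_assignment=np.zeros(1, dtype=int),
        )

    def test_zero_sem_picks_argmin(self):
        cv = self._cv([1.0, 0.5, 0.1], [0.3, 0.2, 0.25], [0.0, 0.0, 0.0])
        assert one_se_select(cv) == 0.5

    def test_band_crossing_on_increasing_curve(self):
        cv = self._cv([0.1, 0.2, 0.4, 0.8], [0.10, 0.11, 0.14, 0.30],
                      [0.02, 0.02, 0.02, 0.02])
        assert one_se_select(cv) == 0.2  # largest λ with MSE ≤ 0.10 + 0.02

    def test_one_se_model_never_larger_than_min_model(self):
        for s in range(10):
            design, _ = simulate_comparison_dataset(seed=100 + s)
            cv = cross_validate(design, k=10, seed=s)
            lam_min = cv.lams[int(np.argmin(cv.mse_mean))]
            lam_1se = one_se_select(cv)
            assert lam_1se >= lam_min
            _, b_min = lasso_fit(design.X, design.y, lam_min)
            _, b_1se = lasso_fit(design.X, design.y, lam_1se)
            assert (b_1se != 0).sum() <= (b_min != 0).sum()


class TestNormalizationSearch:
    def test_recovers_true_triple(self):
        hits = 0
        for s in range(10):
            design, truth = simulate_comparison_dataset(seed=s)
            ns = normalization_search(design, k=10, seed=s)
            hits += ns.best_triple == truth["support"]
        assert hits >= 9

    def test_identical_copies_tie(self, rng):
        base = {fam: rng.normal(size=15) for fam in ("number", "length", "enrichment")}
        cols, fams, X = [], {}, []
        for fam, vec in base.items():
            for v in range(2):
                name = f"{fam}_{v}"
                cols.append(name)
                fams[name] = fam
                X.append(vec)
        y = base["number"] * 0.03 + rng.normal(0, 0.01, 15)
        design = DesignMatrix(y=y, X=np.array(X).T, columns=cols, families=fams)
        ns = normalization_search(design, k=5, seed=0)
        assert np.allclose(ns.ranking["cv_mse"], ns.ranking["cv_mse"].iloc[0])

    def test_single_candidate_per_family_returned(self, rng):
        cols = ["n_c", "len_c", "enr_c"]
        fams = {"n_c": "number", "len_c": "length", "enr_c": "enrichment"}
        X = rng.normal(size=(15, 3))
        y = X @ [0.02, 0.01, -0.01] + rng.normal(0, 0.005, 15)
        design = DesignMatrix(y=y, X=X, columns=cols, families=fams)
        ns = normalization_search(design, k=5, seed=0)
        assert ns.best_triple == ("n_c", "len_c", "enr_c")

    def test_missing_family_rejected(self, rng):
        design = DesignMatrix(
            y=rng.normal(size=10), X=rng.normal(size=(10, 2)),
            columns=["a", "b"], families={"a": "number", "b": "length"},
        )
        with pytest.raises(ValueError, match="enrichment"):
            normalization_search(design)


class TestDiagnosticsAndResults:
    def test_loo_on_clean_linear_data(self, rng):
        X = rng.normal(size=(15, 3))
        y = X @ [0.5, -0.2, 0.1]
        design = DesignMatrix(y=y, X=X, columns=["a", "b", "c"])
        diag = leave_one_out_diagnostic(design, lam=1e-6)
        assert not diag.overfit
        assert diag.mse_heldout < 1e-6

    def test_loo_flags_overfit(self):
        """A barely-penalised fit on many correlated columns at small N
        inflates held-out error."""
        design, _ = simulate_comparison_dataset(n=10, seed=5, snr=1.0)
        loose = leave_one_out_diagnostic(design, lam=1e-6)
        cv = cross_validate(design, k=5, seed=5)
        tight = leave_one_out_diagnostic(design, one_se_select(cv))
        assert loose.mse_heldout > tight.mse_heldout

    def test_loo_rejects_tiny_n(self, rng):
        design = DesignMatrix(
            y=rng.normal(size=2), X=rng.normal(size=(2, 2)), columns=["a", "b"]
        )
        with pytest.raises(ValueError):
            leave_one_out_diagnostic(design, 0.1)

    def test_r_squared_definition(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert r_squared([1, 2, 3], [-1, -2, -3]) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            r_squared([1, 1, 1], [1, 2, 3])

    def test_predict_negation_and_intercept(self):
        design, _ = simulate_comparison_dataset(seed=6)
        res = DeltaIDDLasso(design).fit(lam=0.01)
        zero = res.predict(np.zeros((1, design.p)))[0]
        assert abs(zero - res.intercept) < 1e-12
        row = design.X_raw[2:3]
        centered = res.predict(row)[0] - res.intercept
        neg = res.predict(-row)[0] - res.intercept
        assert centered == pytest.approx(-neg, abs=1e-10)

    def test_row_permutation_leaves_fixed_lambda_fit_unchanged(self):
        design, _ = simulate_comparison_dataset(seed=7)
        perm = np.random.default_rng(0).permutation(design.n)
        permuted = DesignMatrix(
            y=design.y[perm], X=design.X[perm], columns=design.columns,
            X_raw=design.X_raw[perm], col_scale=design.col_scale,
            families=design.families,
        )
        a = DeltaIDDLasso(design).fit(lam=0.05)
        b = DeltaIDDLasso(permuted).fit(lam=0.05)
        assert np.allclose(a.beta, b.beta, atol=1e-9)

    def test_summary_lists_nonzero_terms(self):
        design, truth = simulate_comparison_dataset(seed=8)
        res = DeltaIDDLasso(design).fit(k=10, seed=8)
        text = res.summary()
        assert "lambda" in text and "nonzero terms" in text
        for feat in res.nonzero_features:
            assert feat in text
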