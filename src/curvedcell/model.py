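"""Sparse linear modelling of shape change: ΔIDD regressed on Δ-features.

The response y is the observed change in intracellular diameter deviation
between strain pairs that differ by a single genetic change; the design X
holds the corresponding changes in polymer/enrichment features, with each
feature present in several normalisation variants (per cell, per surface
area, per volume).  The model is the LASSO,

    minimise (1/N)·‖y − β₀ − Xβ‖₂² + λ·‖β‖₁,

fit by coordinate descent with an unpenalised intercept.  λ is chosen by
k-fold cross-validation with the one-standard-error rule (the most
regularised model whose CV MSE is within one SEM of the minimum).  Because
normalisation variants of the same feature are strongly correlated, a
combination search scores every {number-variant × length-variant ×
enrichment-variant} triple by CV, and a leave-one-out diagnostic flags
overfit models.

The public surface follows the Model → fit() → Results convention:
:class:`DeltaIDDLasso` is built from data, ``fit`` returns a
:class:`DeltaIDDLassoResults` carrying estimates, the CV curve, selected
features and a ``summary()`` table.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    """Aligned (y, X) for the shape-change regression.

    ``X`` is the standardised design actually fed to the solver (columns
    scaled to unit variance, not centered, so swapping the two strains of
    a comparison negates the row exactly); ``X_raw`` keeps the raw
    Δ-features; ``col_scale`` maps between the two.  ``families`` tags each
    column with its feature family (e.g. "number", "length", "enrichment").
    """

    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    X_raw: np.ndarray = None
    col_scale: np.ndarray = None
    families: dict[str, str] = field(default_factory=dict)
    comparisons: pd.DataFrame | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape[0] != len(self.y):
            raise ValueError("X rows must align with y")
        if self.X.shape[1] != len(self.columns):
            raise ValueError("column names must match X")
        if not (np.all(np.isfinite(self.y)) and np.all(np.isfinite(self.X))):
            raise ValueError("non-finite values in design")
        if self.X_raw is None:
            self.X_raw = self.X.copy()
        if self.col_scale is None:
            self.col_scale = np.ones(self.X.shape[1])

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]


def build_design(
    comparisons: pd.DataFrame,
    features: pd.DataFrame,
    feature_columns: list[str] | None = None,
    families: dict[str, str] | None = None,
    observed_col: str = "observed_didd",
    standardize: bool = True,
) -> DesignMatrix:
    """Assemble the Δ-feature design from per-strain feature means.

    ``comparisons`` needs columns ``strain1``, ``strain2`` and the observed
    ΔIDD; ``features`` is indexed by strain (or has a ``strain`` column)
    with one column per feature-normalisation variant.  Each design row is
    feature(strain1) − feature(strain2).  Comparisons whose strains lack
    features are dropped with a warning.  Columns are scaled to unit
    variance (scaling stored for back-transforming coefficients).
    """
    if "strain" in features.columns:
        features = features.set_index("strain")
    if feature_columns is None:
        feature_columns = [c for c in features.columns if features[c].dtype.kind in "fc"]
    rows, y, kept = [], [], []
    for idx, row in comparisons.iterrows():
        s1, s2 = row["strain1"], row["strain2"]
        if s1 not in features.index or s2 not in features.index:
            warnings.warn(f"dropping comparison ({s1}, {s2}): missing features", stacklevel=2)
            continue
        delta = (
            features.loc[s1, feature_columns].to_numpy(dtype=float)
            - features.loc[s2, feature_columns].to_numpy(dtype=float)
        )
        rows.append(delta)
        y.append(float(row[observed_col]))
        kept.append(idx)
    if not rows:
        raise ValueError("no usable comparisons")
    X_raw = np.vstack(rows)
    if standardize:
        scale = X_raw.std(axis=0, ddof=0)
        scale = np.where(scale > 0, scale, 1.0)
    else:
        scale = np.ones(X_raw.shape[1])
    return DesignMatrix(
        y=np.asarray(y),
        X=X_raw / scale,
        columns=list(feature_columns),
        X_raw=X_raw,
        col_scale=scale,
        families=families or {},
        comparisons=comparisons.loc[kept].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# LASSO solver (coordinate descent on (1/N)‖y − β₀ − Xβ‖² + λ‖β‖₁)
# ---------------------------------------------------------------------------


def lambda_max(X: np.ndarray, y: np.ndarray, fit_intercept: bool = True) -> float:
    """Smallest λ at which every coefficient is exactly zero: 2·max|Xᵀỹ|/N."""
    yc = y - y.mean() if fit_intercept else y
    xc = X - X.mean(axis=0) if fit_intercept else X
    return float(2.0 * np.abs(xc.T @ yc).max() / len(y))


def _cd_gram(G, c, half_nl, beta, tol, max_iter):
    """Cyclic coordinate descent on the Gram system (the hot loop)."""
    p = G.shape[0]
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            gjj = G[j, j]
            if gjj == 0.0:
                beta[j] = 0.0
                continue
            rho = c[j] - np.dot(G[j], beta) + gjj * beta[j]
            z = abs(rho) - half_nl
            new = (z if z > 0.0 else 0.0) * (1.0 if rho >= 0.0 else -1.0) / gjj
            delta = abs(new - beta[j])
            if delta > 0.0:
                beta[j] = new
                if delta > max_delta:
                    max_delta = delta
        if max_delta < tol:
            break
    return beta


try:   # numba gives a ~100x faster inner loop; plain Python is the fallback
    from numba import njit

    _cd_gram = njit(cache=True)(_cd_gram)
except Exception:   # pragma: no cover
    pass


def lasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    fit_intercept: bool = True,
    beta0: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 10_000,
):
    """Coordinate-descent solution of the penalised least-squares objective.

    Returns ``(intercept, beta)``.  At λ = 0 this is ordinary least
    squares; at λ ≥ :func:`lambda_max` the coefficient vector is exactly
    zero.  Deterministic given (X, y, λ).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    n, p = X.shape
    if fit_intercept:
        xm = X.mean(axis=0)
        ym = y.mean()
        Xc = X - xm
        yc = y - ym
    else:
        xm = np.zeros(p)
        ym = 0.0
        Xc, yc = X, y
    if lam == 0.0:
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        intercept = ym - xm @ beta if fit_intercept else 0.0
        return float(intercept), beta
    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=float)
    G = np.ascontiguousarray(Xc.T @ Xc)
    c = Xc.T @ yc
    beta = _cd_gram(G, c, 0.5 * n * lam, beta, tol, max_iter)
    intercept = ym - xm @ beta if fit_intercept else 0.0
    return float(intercept), beta


def lasso_path(X: np.ndarray, y: np.ndarray, lams: np.ndarray, fit_intercept=True):
    """Warm-started coefficient path over a descending λ grid.

    Returns ``(intercepts, betas)`` with ``betas[i]`` the solution at
    ``lams[i]`` (grid is sorted descending internally; results follow the
    input order).
    """
    lams = np.asarray(lams, dtype=float)
    order = np.argsort(lams)[::-1]
    betas = np.zeros((len(lams), X.shape[1]))
    intercepts = np.zeros(len(lams))
    beta = None
    for i in order:
        b0, beta = lasso_fit(X, y, lams[i], fit_intercept=fit_intercept, beta0=beta)
        betas[i] = beta
        intercepts[i] = b0
    return intercepts, betas


def default_lambda_grid(
    X: np.ndarray, y: np.ndarray, n: int = 100, floor_ratio: float = 1e-4
) -> np.ndarray:
    """Log-spaced λ grid from λ_max down to floor_ratio·λ_max, descending,
    with the working values 0.02 and 0.022 inserted when they fall inside."""
    lmax = lambda_max(X, y)
    if lmax <= 0:
        raise ValueError("response is orthogonal to every column (λ_max = 0)")
    grid = np.geomspace(lmax, lmax * floor_ratio, n)
    for v in (0.02, 0.022):
        if grid.min() < v < grid.max():
            grid = np.append(grid, v)
    return np.sort(grid)[::-1]


# ---------------------------------------------------------------------------
# cross-validation and model selection
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    lams: np.ndarray
    mse_mean: np.ndarray
    mse_sem: np.ndarray
    k: int
    seed: int
    fold_assignment: np.ndarray


def _fold_assignment(n: int, k: int, seed: int) -> np.ndarray:
    """Seeded uniform shuffle, then contiguous blocks of near-equal size."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    folds = np.empty(n, dtype=int)
    start = 0
    for f, s in enumerate(sizes):
        folds[perm[start : start + s]] = f
        start += s
    return folds


def cross_validate(
    design: DesignMatrix,
    lams: np.ndarray | None = None,
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """k-fold CV of the LASSO path: held-out MSE per λ with its SEM.

    Fold assignment is reproducible from ``seed``.  If there are fewer
    samples than folds, k is reduced to N (leave-one-out) with a warning.
    """
    X, y = design.X, design.y
    n = design.n
    if lams is None:
        lams = default_lambda_grid(X, y)
    lams = np.asarray(lams, dtype=float)
    if n < k:
        warnings.warn(f"N = {n} < k = {k}; using leave-one-out", stacklevel=2)
        k = n
    folds = _fold_assignment(n, k, seed)
    fold_mse = np.empty((k, len(lams)))
    for f in range(k):
        test = folds == f
        train = ~test
        ints, betas = lasso_path(X[train], y[train], lams)
        pred = X[test] @ betas.T + ints[None, :]
        fold_mse[f] = ((pred - y[test, None]) ** 2).mean(axis=0)
    return CVResult(
        lams=lams,
        mse_mean=fold_mse.mean(axis=0),
        mse_sem=fold_mse.std(axis=0, ddof=1) / np.sqrt(k),
        k=k,
        seed=seed,
        fold_assignment=folds,
    )


def one_se_select(cv: CVResult) -> float:
    """One-standard-error λ: the largest λ whose CV MSE is within one SEM
    of the minimum (the most compact model statistically tied with the
    best)."""
    i_min = int(np.argmin(cv.mse_mean))
    bound = cv.mse_mean[i_min] + cv.mse_sem[i_min]
    ok = cv.mse_mean <= bound
    if not ok.any():   # flat/degenerate curve
        warnings.warn("flat CV curve; selecting the largest λ", stacklevel=2)
        return float(cv.lams.max())
    return float(cv.lams[ok].max())


def _cv_mse_ols(X: np.ndarray, y: np.ndarray, k: int, seed: int) -> float:
    """k-fold CV MSE of ordinary least squares on a fixed column subset."""
    n = len(y)
    k = min(k, n)
    folds = _fold_assignment(n, k, seed)
    total, count = 0.0, 0
    for f in range(k):
        test = folds == f
        train = ~test
        Xt = X[train]
        xm, ym = Xt.mean(axis=0), y[train].mean()
        beta, *_ = np.linalg.lstsq(Xt - xm, y[train] - ym, rcond=None)
        pred = (X[test] - xm) @ beta + ym
        total += float(((pred - y[test]) ** 2).sum())
        count += int(test.sum())
    return total / count


@dataclass
class NormalizationSearchResult:
    ranking: pd.DataFrame          # all triples with CV MSE, best first
    best_triple: tuple[str, str, str]
    elevated_lambda: float
    elevated_support: list[str]    # nonzero features of the path fit at that λ
    beats_two_plus_one: bool


def normalization_search(
    design: DesignMatrix,
    k: int = 10,
    seed: int = 0,
    elevated_lambda: float = 0.022,
    core_families: tuple[str, str, str] = ("number", "length", "enrichment"),
) -> NormalizationSearchResult:
    """Resolve which normalisation variants carry the signal.

    Two complementary analyses: (i) the LASSO path refit at an elevated λ,
    whose surviving support is reported; (ii) every {number × length ×
    enrichment} variant triple scored by k-fold CV of an OLS fit on just
    those three columns, ranked by CV MSE.  Also checks whether the best
    triple outperforms every "two of the three plus any other column"
    alternative.
    """
    fams = design.families
    groups = {
        fam: [c for c in design.columns if fams.get(c) == fam] for fam in core_families
    }
    for fam, cols in groups.items():
        if not cols:
            raise ValueError(f"no design columns tagged with family {fam!r}")
    col_idx = {c: i for i, c in enumerate(design.columns)}

    records = []
    for triple in itertools.product(*[groups[f] for f in core_families]):
        idx = [col_idx[c] for c in triple]
        mse = _cv_mse_ols(design.X[:, idx], design.y, k, seed)
        records.append({"triple": triple, "cv_mse": mse})
    ranking = pd.DataFrame(records).sort_values("cv_mse").reset_index(drop=True)
    best = tuple(ranking.loc[0, "triple"])

    # elevated-λ path solution
    b0, beta = lasso_fit(design.X, design.y, elevated_lambda)
    support = [c for c, b in zip(design.columns, beta) if b != 0.0]

    # two-from-the-triple plus any single other column
    best_mse = float(ranking.loc[0, "cv_mse"])
    beats = True
    others = [c for c in design.columns if c not in best]
    for drop in range(3):
        pair = [c for i, c in enumerate(best) if i != drop]
        for extra in others:
            idx = [col_idx[c] for c in pair + [extra]]
            if _cv_mse_ols(design.X[:, idx], design.y, k, seed) < best_mse:
                beats = False
                break
        if not beats:
            break
    return NormalizationSearchResult(
        ranking=ranking,
        best_triple=best,
        elevated_lambda=elevated_lambda,
        elevated_support=support,
        beats_two_plus_one=beats,
    )


@dataclass
class LooDiagnostic:
    table: pd.DataFrame
    mse_insample: float
    mse_heldout: float
    inflation: float
    overfit: bool


def leave_one_out_diagnostic(
    design: DesignMatrix, lam: float, inflation_threshold: float = 2.0
) -> LooDiagnostic:
    """Refit with each comparison held out and predict it.

    The verdict compares held-out MSE to in-sample MSE; an inflation above
    ``inflation_threshold`` flags an overfit model.
    """
    n = design.n
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 comparisons")
    X, y = design.X, design.y
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        b0, beta = lasso_fit(X[keep], y[keep], lam)
        preds[i] = X[i] @ beta + b0
    b0, beta = lasso_fit(X, y, lam)
    fitted = X @ beta + b0
    mse_in = float(((fitted - y) ** 2).mean())
    mse_out = float(((preds - y) ** 2).mean())
    floor = 1e-10 * float(np.var(y)) if np.var(y) > 0 else 1e-30
    inflation = mse_out / max(mse_in, floor)
    table = pd.DataFrame(
        {"observed": y, "fitted": fitted, "loo_predicted": preds}
    )
    if design.comparisons is not None and len(design.comparisons) == n:
        table.insert(0, "strain1", design.comparisons["strain1"].to_numpy())
        table.insert(1, "strain2", design.comparisons["strain2"].to_numpy())
    return LooDiagnostic(
        table=table,
        mse_insample=mse_in,
        mse_heldout=mse_out,
        inflation=inflation,
        overfit=bool(inflation > inflation_threshold),
    )


def r_squared(predicted, observed) -> float:
    """Square of the Pearson correlation coefficient between the two vectors."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if len(predicted) != len(observed) or len(predicted) < 3:
        raise ValueError("need at least 3 aligned pairs")
    if predicted.std() == 0 or observed.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(predicted, observed)[0, 1] ** 2)


# ---------------------------------------------------------------------------
# Model / Results API
# ---------------------------------------------------------------------------


class DeltaIDDLasso:
    """L1-penalised linear model of shape change built from a design matrix.

    Construct directly from a :class:`DesignMatrix` or via
    :meth:`from_frames` (per-strain features + comparison table).  ``fit``
    selects λ by cross-validation with the one-SE rule unless a λ is given,
    and returns a :class:`DeltaIDDLassoResults`.
    """

    def __init__(self, design: DesignMatrix):
        self.design = design

    @classmethod
    def from_frames(
        cls,
        comparisons: pd.DataFrame,
        features: pd.DataFrame,
        feature_columns: list[str] | None = None,
        families: dict[str, str] | None = None,
    ) -> "DeltaIDDLasso":
        return cls(build_design(comparisons, features, feature_columns, families))

    def fit(
        self,
        lam: float | None = None,
        k: int = 10,
        seed: int = 0,
        lams: np.ndarray | None = None,
    ) -> "DeltaIDDLassoResults":
        design = self.design
        cv = None
        if lam is None:
            cv = cross_validate(design, lams=lams, k=k, seed=seed)
            lam = one_se_select(cv)
        b0, beta = lasso_fit(design.X, design.y, lam)
        return DeltaIDDLassoResults(
            model=self, lam=float(lam), intercept=b0, beta=beta, cv=cv, seed=seed
        )


class DeltaIDDLassoResults:
    """Fitted ΔIDD model: coefficients, CV curve, predictions, diagnostics."""

    def __init__(self, model, lam, intercept, beta, cv=None, seed=0):
        self.model = model
        self.design = model.design
        self.lam = lam
        self.intercept = intercept
        self.beta = np.asarray(beta, dtype=float)          # standardized scale
        self.cv = cv
        self.seed = seed

    @property
    def params(self) -> pd.Series:
        """Coefficients on the raw Δ-feature scale."""
        return pd.Series(
            self.beta / self.design.col_scale, index=self.design.columns, name="coef"
        )

    @property
    def params_standardized(self) -> pd.Series:
        return pd.Series(self.beta, index=self.design.columns, name="coef_std")

    @property
    def nonzero_features(self) -> list[str]:
        return [c for c, b in zip(self.design.columns, self.beta) if b != 0.0]

    def predict(self, delta_features) -> np.ndarray:
        """Predict ΔIDD for raw Δ-feature rows (DataFrame or array)."""
        if isinstance(delta_features, pd.DataFrame):
            missing = [c for c in self.design.columns if c not in delta_features]
            if missing:
                raise ValueError(f"missing features: {missing}")
            Xr = delta_features[self.design.columns].to_numpy(dtype=float)
        else:
            Xr = np.atleast_2d(np.asarray(delta_features, dtype=float))
            if Xr.shape[1] != self.design.p:
                raise ValueError("feature count mismatch")
        if not np.all(np.isfinite(Xr)):
            raise ValueError("non-finite features")
        return (Xr / self.design.col_scale) @ self.beta + self.intercept

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.design.X @ self.beta + self.intercept

    @property
    def rsquared(self) -> float:
        return r_squared(self.fittedvalues, self.design.y)

    def loo(self, inflation_threshold: float = 2.0) -> LooDiagnostic:
        return leave_one_out_diagnostic(self.design, self.lam, inflation_threshold)

    def normalization_search(self, k: int = 10, seed: int | None = None, **kw):
        return normalization_search(
            self.design, k=k, seed=self.seed if seed is None else seed, **kw
        )

    def summary(self) -> str:
        lines = [
            "ΔIDD LASSO regression results",
            "=" * 46,
            f"N comparisons      {self.design.n}",
            f"candidate columns  {self.design.p}",
            f"lambda             {self.lam:.4g}"
            + ("  (one-SE rule)" if self.cv is not None else "  (fixed)"),
            f"nonzero terms      {len(self.nonzero_features)}",
            f"in-sample r²       {self.rsquared:.3f}",
            "-" * 46,
            f"{'feature':<30}{'coef':>9}{'coef_std':>12}",
        ]
        raw = self.params
        for c, b in zip(self.design.columns, self.beta):
            if b != 0.0:
                lines.append(f"{c:<30}{raw[c]:>11.4g}{b:>11.4g}")
        lines.append(f"{'intercept':<30}{self.intercept:>11.4g}")
        if self.cv is not None:
            i = int(np.argmin(self.cv.mse_mean))
            lines.append("-" * 46)
            lines.append(
                f"CV ({self.cv.k}-fold, seed {self.cv.seed}): min MSE "
                f"{self.cv.mse_mean[i]:.4g} at λ = {self.cv.lams[i]:.4g}"
            )
        return "\n".join(lines)

    def plot_cv(self, ax=None):
        """CV MSE versus λ with its one-SEM band and the selected λ."""
        import matplotlib.pyplot as plt

        if self.cv is None:
            raise ValueError("model was fitted at a fixed λ; no CV curve")
        if ax is None:
            _, ax = plt.subplots()
        cv = self.cv
        order = np.argsort(cv.lams)
        ax.fill_between(
            cv.lams[order],
            (cv.mse_mean - cv.mse_sem)[order],
            (cv.mse_mean + cv.mse_sem)[order],
            alpha=0.3,
        )
        ax.plot(cv.lams[order], cv.mse_mean[order])
        ax.axvline(self.lam, color="r", ls="--", lw=1)
        ax.set_xscale("log")
        ax.set_xlabel("λ")
        ax.set_ylabel(f"{cv.k}-fold CV MSE")
        return ax

    def to_dict(self) -> dict:
        out = {
            "lambda": self.lam,
            "intercept": self.intercept,
            "columns": list(self.design.columns),
            "beta_standardized": self.beta.tolist(),
            "col_scale": self.design.col_scale.tolist(),
            "seed": self.seed,
        }
        if self.cv is not None:
            out["cv"] = {
                "lams": self.cv.lams.tolist(),
                "mse_mean": self.cv.mse_mean.tolist(),
                "mse_sem": self.cv.mse_sem.tolist(),
                "k": self.cv.k,
                "seed": self.cv.seed,
            }
        return out


# ---------------------------------------------------------------------------
# synthetic comparison sets for procedure validation
# ---------------------------------------------------------------------------

_SIM_FAMILIES = {
    "n_per_cell": "number",
    "n_per_area": "number",
    "n_per_volume": "number",
    "total_length_per_cell": "length",
    "total_length_per_area": "length",
    "total_length_per_volume": "length",
    "enrichment_low": "enrichment",
    "enrichment_high": "enrichment",
    "angle_per_cell": "angle",
    "angle_per_volume": "angle",
    "membrane_fraction": "membrane",
    "mean_length_gt200": "length_mean",
}

_SIM_TRUE_SUPPORT = ("n_per_cell", "total_length_per_volume", "enrichment_low")


def simulate_comparison_dataset(
    n: int = 20,
    seed: int = 0,
    snr: float = 3.0,
    within_family_corr: float = 0.7,
    coefs: tuple[float, float, float] = (0.035, 0.03, -0.025),
):
    """Generate a comparison set with a known sparse truth.

    Twelve candidate columns in correlated families mimic the
    feature × normalisation structure of the real design; the response is
    a linear combination of one variant from each of the number, length
    and enrichment families plus Gaussian noise at the requested
    signal-to-noise ratio (SD of signal over SD of noise).  Returns
    ``(design, truth_dict)``.
    """
    rng = np.random.default_rng(seed)
    cols = list(_SIM_FAMILIES)
    fam_of = dict(_SIM_FAMILIES)
    latents = {}
    X = np.empty((n, len(cols)))
    rho = np.sqrt(within_family_corr)
    for j, c in enumerate(cols):
        fam = fam_of[c]
        if fam not in latents:
            latents[fam] = rng.normal(size=n)
        X[:, j] = rho * latents[fam] + np.sqrt(1 - rho**2) * rng.normal(size=n)
    idx = [cols.index(c) for c in _SIM_TRUE_SUPPORT]
    signal = X[:, idx] @ np.asarray(coefs)
    noise_sd = signal.std() / snr
    y = signal + rng.normal(0.0, noise_sd, size=n)
    design = DesignMatrix(
        y=y,
        X=X,
        columns=cols,
        families=fam_of,
        comparisons=pd.DataFrame(
            {"strain1": [f"mut{i}" for i in range(n)], "strain2": ["wt"] * n}
        ),
    )
    truth = {
        "support": _SIM_TRUE_SUPPORT,
        "coefs": dict(zip(_SIM_TRUE_SUPPORT, coefs)),
        "noise_sd": noise_sd,
    }
    return design, truth
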