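"""Latent cardiovascular-health (CVH) factors from raw measures.

Seven measures — mean heart rate, low- and high-frequency HRV power,
systolic and diastolic blood pressure, white-matter hyperintensity volume
and BMI — are screened for normality (one-sample Kolmogorov-Smirnov against
a normal with the sample mean and SD; no Lilliefors correction), failing
variables are log-transformed, and an exploratory maximum-likelihood factor
analysis with varimax rotation summarises them as a small number of
standardized factor scores (regression method).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.multivariate.factor import Factor

UNIQUENESS_FLOOR = 1e-3


@dataclass
class CvhMatrix:
    """Transformed measure matrix plus the per-variable transform record."""

    values: pd.DataFrame
    transforms: dict[str, str]  # variable -> {"none", "log"}

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


@dataclass
class FactorSolution:
    """Rotated factor solution: loadings, uniquenesses and subject scores."""

    loadings: np.ndarray      # (n_vars, k)
    uniquenesses: np.ndarray  # (n_vars,)
    scores: np.ndarray        # (n_subjects, k), standardized
    k: int
    rotation: str = "varimax"
    variables: list[str] = None

    @property
    def communalities(self) -> np.ndarray:
        return (self.loadings**2).sum(axis=1)


def ks_normality_pvalue(x: np.ndarray) -> float:
    """One-sample KS test against a normal with the sample mean and SD."""
    x = np.asarray(x, dtype=float)
    return float(stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).pvalue)


def normality_transform(
    raw: pd.DataFrame | np.ndarray,
    alpha: float = 0.05,
    columns: list[str] | None = None,
) -> CvhMatrix:
    """Log-transform variables that fail the KS normality screen.

    A failing variable must be strictly positive (the log is undefined
    otherwise — this raises, naming the variable).  Each transformed
    variable is re-tested; a persistent failure is recorded with a warning
    but the log transform is kept, matching the screen-then-transform rule.
    """
    if isinstance(raw, np.ndarray):
        columns = columns or [f"var{i}" for i in range(raw.shape[1])]
        raw = pd.DataFrame(raw, columns=columns)
    if len(raw) < 20:
        raise ValueError(f"need at least 20 subjects for the normality screen, got {len(raw)}")
    if raw.isna().any().any():
        raise ValueError("missing values in cardiovascular measures")

    out = raw.copy()
    transforms: dict[str, str] = {}
    for name in raw.columns:
        x = raw[name].to_numpy(dtype=float)
        if ks_normality_pvalue(x) >= alpha:
            transforms[name] = "none"
            continue
        if np.any(x <= 0):
            raise ValueError(
                f"variable {name!r} fails the normality screen but has "
                "nonpositive values; cannot log-transform"
            )
        lx = np.log(x)
        transforms[name] = "log"
        out[name] = lx
        if ks_normality_pvalue(lx) < alpha:
            warnings.warn(
                f"variable {name!r} still non-normal after log transform",
                stacklevel=2,
            )
    return CvhMatrix(values=out, transforms=transforms)


def choose_n_factors(X: CvhMatrix | np.ndarray, override: int | None = 3) -> int:
    """Kaiser rule (correlation-matrix eigenvalues > 1), with an optional
    fixed override (default 3, the configuration used throughout the
    pipeline)."""
    if override is not None:
        return int(override)
    arr = X.to_array() if isinstance(X, CvhMatrix) else np.asarray(X, dtype=float)
    R = np.corrcoef(arr, rowvar=False)
    # strict "> 1" with a float guard so an exactly-flat spectrum counts zero
    return int((np.linalg.eigvalsh(R) > 1.0 + 1e-8).sum())


def _varimax(L: np.ndarray, max_iter: int = 500, tol: float = 1e-8) -> np.ndarray:
    """Varimax rotation matrix for loadings L (n_vars, k)."""
    p, k = L.shape
    R = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        )
        R = u @ vt
        new_var = s.sum()
        if new_var < var * (1 + tol):
            break
        var = new_var
    return R


class CardioHealthFactors(BaseEstimator, TransformerMixin):
    """Exploratory factor analysis of cardiovascular measures.

    Parameters
    ----------
    n_factors : int or "kaiser"
        Number of factors; "kaiser" counts correlation-matrix eigenvalues
        above 1.
    method : {"ml", "pca"}
        Extraction: maximum-likelihood common-factor model (default) or
        principal-component extraction.
    rotation : {"varimax", None}
        Orthogonal rotation of the loadings.

    Fitting standardizes the input variables, so scores are invariant to
    affine rescaling of the measures.  Factors are ordered by explained
    variance and sign-fixed so each factor's largest-|loading| variable
    loads positively; scores (regression method) are standardized to mean 0,
    SD 1.  Heywood cases are clamped at a uniqueness floor with a warning.
    """

    def __init__(self, n_factors: int | str = 3, method: str = "ml",
                 rotation: str | None = "varimax"):
        self.n_factors = n_factors
        self.method = method
        self.rotation = rotation

    def fit(self, X, y=None):
        arr, names = self._validate(X)
        n, p = arr.shape
        k = (
            choose_n_factors(arr, override=None)
            if self.n_factors == "kaiser"
            else int(self.n_factors)
        )
        if not 0 < k < p:
            raise ValueError(f"n_factors must be in (0, {p}), got {k}")

        self.mean_ = arr.mean(axis=0)
        self.scale_ = arr.std(axis=0, ddof=1)
        if np.any(self.scale_ <= 0):
            raise ValueError("constant input variable; correlation matrix singular")
        Z = (arr - self.mean_) / self.scale_
        R = np.corrcoef(Z, rowvar=False)
        if np.linalg.eigvalsh(R).min() <= 1e-10:
            raise ValueError("correlation matrix is not positive definite")

        if self.method == "ml":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    fa = Factor(Z, n_factor=k, method="ml").fit()
                except Exception as err:  # non-convergence in the ML optimiser
                    raise RuntimeError(f"ML factor analysis did not converge: {err}")
            L = np.asarray(fa.loadings)[:, :k]
            uniq = np.asarray(fa.uniqueness, dtype=float)
        elif self.method == "pca":
            vals, vecs = np.linalg.eigh(R)
            order = np.argsort(vals)[::-1][:k]
            L = vecs[:, order] * np.sqrt(vals[order])
            uniq = 1.0 - (L**2).sum(axis=1)
        else:
            raise ValueError(f"unknown extraction method {self.method!r}")

        if np.any(uniq < UNIQUENESS_FLOOR):
            warnings.warn(
                "Heywood case: uniqueness clamped at "
                f"{UNIQUENESS_FLOOR} for variable(s) "
                f"{[names[i] for i in np.nonzero(uniq < UNIQUENESS_FLOOR)[0]]}",
                stacklevel=2,
            )
            uniq = np.maximum(uniq, UNIQUENESS_FLOOR)

        if self.rotation == "varimax" and k > 1:
            L = L @ _varimax(L)
        elif self.rotation not in (None, "varimax"):
            raise ValueError(f"unknown rotation {self.rotation!r}")

        # order by explained variance, sign-fix on the dominant variable
        order = np.argsort(-(L**2).sum(axis=0), kind="stable")
        L = L[:, order]
        for j in range(k):
            i = int(np.argmax(np.abs(L[:, j])))
            if L[i, j] < 0:
                L[:, j] = -L[:, j]

        # regression-method scoring coefficients: R^{-1} Lambda
        self.scoring_ = np.linalg.solve(R, L)
        self.loadings_ = L
        self.uniquenesses_ = uniq
        self.n_factors_ = k
        self.variables_ = names
        # standardization of the scores is frozen on the training sample
        raw_scores = Z @ self.scoring_
        self.score_mean_ = raw_scores.mean(axis=0)
        self.score_scale_ = raw_scores.std(axis=0, ddof=0)
        self.score_scale_[self.score_scale_ == 0] = 1.0
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        arr, _ = self._validate(X, n_min=1)
        Z = (arr - self.mean_) / self.scale_
        return (Z @ self.scoring_ - self.score_mean_) / self.score_scale_

    @staticmethod
    def _validate(X, n_min: int = 20):
        if isinstance(X, CvhMatrix):
            arr, names = X.to_array(), list(X.values.columns)
        elif isinstance(X, pd.DataFrame):
            arr, names = X.to_numpy(dtype=float), list(X.columns)
        else:
            arr = np.asarray(X, dtype=float)
            names = [f"var{i}" for i in range(arr.shape[1])]
        if arr.ndim != 2 or arr.shape[0] < n_min:
            raise ValueError(f"need a 2D matrix with at least {n_min} rows")
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite values in factor-analysis input")
        return arr, names


def fit_efa(X: CvhMatrix | pd.DataFrame | np.ndarray, k: int,
            method: str = "ml") -> FactorSolution:
    """Fit the factor model and return the rotated solution with scores."""
    est = CardioHealthFactors(n_factors=k, method=method).fit(X)
    return FactorSolution(
        loadings=est.loadings_,
        uniquenesses=est.uniquenesses_,
        scores=est.transform(X),
        k=est.n_factors_,
        rotation=est.rotation or "none",
        variables=est.variables_,
    )


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient between two loading vectors."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def match_factors(est: np.ndarray, true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Match estimated to true factor columns by |congruence| (greedy optimal
    assignment); returns (permutation, signed congruences)."""
    from scipy.optimize import linear_sum_assignment

    k_e, k_t = est.shape[1], true.shape[1]
    C = np.zeros((k_t, k_e))
    for i in range(k_t):
        for j in range(k_e):
            C[i, j] = tucker_congruence(true[:, i], est[:, j])
    rows, cols = linear_sum_assignment(-np.abs(C))
    return cols, C[rows, cols]
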