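"""Group spatial ICA of subject-level summary maps (source-based morphometry).

A subjects-by-voxels matrix for one modality (RSFA, CBF or GMV) is reduced
by PCA to an order chosen with the eigenvalue-based minimum description
length (MDL) criterion and decomposed by FastICA into a source matrix
(independent spatial maps, components x voxels) and a mixing matrix
(subjects x components).  Mixing loadings standardized per component are
the subject-level summary measures used by the between-subject analyses.

Subjects are the observations and voxels the variables; independence is
sought across voxels, so FastICA runs on the transposed (voxels as samples)
matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import skew
from sklearn.base import BaseEstimator
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils.validation import check_is_fitted


@dataclass
class Decomposition:
    """Spatial sources plus subject mixing loadings for one modality."""

    sources: np.ndarray    # (k, V) unit-norm spatial independent components
    mixing: np.ndarray     # (n, k)
    loadings_z: np.ndarray  # mixing standardized per component
    order: int
    modality: str = ""
    mean: np.ndarray = None  # (n,) per-subject offset removed before ICA
    objective: float = np.nan

    def reconstruct(self) -> np.ndarray:
        """Rank-k approximation of the original matrix."""
        out = self.mixing @ self.sources
        if self.mean is not None:
            out = out + self.mean[:, None]
        return out


def mdl_spectrum(eigenvalues: np.ndarray, n_samples: int) -> np.ndarray:
    """MDL(k) for k = 0..p-1 from covariance eigenvalues.

    MDL(k) = -N (p-k) log( geometric/arithmetic mean of the p-k smallest
    eigenvalues ) + 1/2 k (2p - k + 1) log N — the eigenvalue-based order
    selection functional (no i.i.d. subsampling correction).
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    lam = np.maximum(lam, 1e-300)
    p = lam.size
    N = float(n_samples)
    out = np.empty(p)
    for k in range(p):
        tail = lam[k:]
        log_gm = np.mean(np.log(tail))
        am = np.mean(tail)
        out[k] = -N * (p - k) * (log_gm - np.log(am)) + 0.5 * k * (2 * p - k + 1) * np.log(N)
    return out


def estimate_order_mdl(X: np.ndarray) -> int:
    """MDL-optimal PCA order of a subjects-by-voxels matrix.

    The subject-by-subject covariance is estimated with voxels as samples;
    the order minimising MDL over candidates 1..subjects-1 is returned.
    """
    X = np.asarray(X, dtype=float)
    n, V = X.shape
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    Xc = X - X.mean(axis=1, keepdims=True)
    C = Xc @ Xc.T / V
    lam = np.linalg.eigvalsh(C)[::-1]
    if lam.max() <= 0:
        raise ValueError("degenerate covariance: data has no variance")
    # exact linear dependencies (e.g. duplicated subjects) contribute zero
    # eigenvalues that would blow up the likelihood term: restrict to the
    # numerical rank, which leaves the criterion scale-invariant
    lam = lam[lam > 1e-12 * lam.max()]
    if lam.size < 3:
        raise ValueError("degenerate covariance: rank below 3")
    crit = mdl_spectrum(lam, V)[1:]  # candidates k = 1..rank-1
    return int(np.argmin(crit)) + 1


def _negentropy(S: np.ndarray) -> float:
    """Log-cosh negentropy proxy, summed over components (larger = more
    non-Gaussian)."""
    gauss = 0.3745672966837089  # E[log cosh g], g ~ N(0,1)
    Sz = (S - S.mean(axis=0)) / S.std(axis=0, ddof=0)
    return float((((np.log(np.cosh(Sz))).mean(axis=0) - gauss) ** 2).sum())


class GroupICA(BaseEstimator):
    """PCA + FastICA decomposition of a subjects-by-voxels matrix.

    Parameters
    ----------
    n_components : int or "mdl"
        Decomposition order; "mdl" selects it with the MDL criterion.
    n_restarts : int
        Seeded FastICA restarts; the run with the best log-cosh negentropy
        objective is kept.
    random_state : int
        Base seed; restart r uses random_state + r.

    Fitted attributes: ``sources_`` (k, V) unit-norm rows sign-fixed to
    positive skewness and ordered by explained variance, ``mixing_`` (n, k),
    ``loadings_z_`` (n, k) with exactly mean 0 / SD 1 columns, ``order_``,
    ``mean_`` and ``objective_``.
    """

    def __init__(self, n_components: int | str = "mdl", n_restarts: int = 5,
                 max_iter: int = 1000, tol: float = 1e-6, random_state: int = 0):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a subjects-by-voxels matrix")
        n, V = X.shape
        k = estimate_order_mdl(X) if self.n_components == "mdl" else int(self.n_components)
        if not 1 <= k <= min(n, V):
            raise ValueError(f"order {k} outside [1, min(subjects, voxels)]")

        best = None
        failures = []
        for r in range(self.n_restarts):
            ica = FastICA(
                n_components=k, fun="logcosh", whiten="unit-variance",
                max_iter=self.max_iter, tol=self.tol,
                random_state=int(self.random_state) + r,
            )
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", ConvergenceWarning)
                S = ica.fit_transform(X.T)  # (V, k): voxels are the samples
                converged = not any(
                    issubclass(w.category, ConvergenceWarning) for w in caught
                )
            obj = _negentropy(S)
            if not converged:
                failures.append(f"restart {r}: no convergence in {ica.n_iter_} iterations")
                continue
            if best is None or obj > best[0]:
                best = (obj, S, ica)
        if best is None:
            raise RuntimeError(
                "FastICA failed to converge in all restarts: " + "; ".join(failures)
            )
        obj, S, ica = best

        mixing = ica.mixing_          # (n, k): X.T ~ S @ mixing.T + mean_
        mean = ica.mean_              # (n,) per-subject offset
        # unit-norm sources, scale absorbed into the mixing matrix
        norms = np.linalg.norm(S, axis=0)
        norms[norms == 0] = 1.0
        sources = (S / norms).T       # (k, V)
        mixing = mixing * norms

        sign = np.where(skew(sources, axis=1) < 0, -1.0, 1.0)
        sources *= sign[:, None]
        mixing *= sign
        order = np.argsort(-mixing.var(axis=0), kind="stable")
        sources, mixing = sources[order], mixing[:, order]

        self.sources_ = sources
        self.mixing_ = mixing
        self.mean_ = mean
        self.order_ = k
        self.objective_ = obj
        sd = mixing.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        self.loadings_z_ = (mixing - mixing.mean(axis=0)) / sd
        return self

    def to_decomposition(self, modality: str = "") -> Decomposition:
        check_is_fitted(self, "sources_")
        return Decomposition(
            sources=self.sources_, mixing=self.mixing_,
            loadings_z=self.loadings_z_, order=self.order_,
            modality=modality, mean=self.mean_, objective=self.objective_,
        )


def fit_group_ica(X: np.ndarray, k: int | str = "mdl", seed: int = 0,
                  modality: str = "", n_restarts: int = 5) -> Decomposition:
    """Fit GroupICA and return the Decomposition."""
    est = GroupICA(n_components=k, random_state=seed, n_restarts=n_restarts).fit(X)
    return est.to_decomposition(modality)


def match_components(
    est_sources: np.ndarray, true_sources: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal one-to-one matching of estimated to reference spatial maps.

    Maximises total |spatial correlation| (Hungarian assignment); handles
    unequal component counts by partial matching.  Returns
    (assignment: true index -> estimated index, signs, correlations).
    """
    E = np.asarray(est_sources, dtype=float)
    T = np.asarray(true_sources, dtype=float)
    if E.shape[1] != T.shape[1]:
        raise ValueError("component maps live on different voxel grids")
    Ec = E - E.mean(axis=1, keepdims=True)
    Tc = T - T.mean(axis=1, keepdims=True)
    C = (Tc @ Ec.T) / np.outer(
        np.linalg.norm(Tc, axis=1), np.linalg.norm(Ec, axis=1)
    )
    rows, cols = linear_sum_assignment(-np.abs(C))
    corr = C[rows, cols]
    return cols, np.sign(corr), corr
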