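"""Distribution-shape permutation test on voxel-wise age-residual correlations.

The question addressed here is not "which voxels survive correction" but
"does the *distribution* of age-residual correlations across voxels differ
from what pure randomness would produce".  The procedure:

1. Build P+1 distributions of age-residual correlations across voxels
   (``D_Voxels``): index 0 from the observed RSFA matrix, indices 1..P from
   subject-permuted RSFA matrices (one joint row permutation per iteration,
   shared across voxels so the spatial correlation structure of each null
   draw is preserved).  Only RSFA is permuted; the stage-one design is reused.
2. Compare the observed distribution to the pooled permuted correlations:
   Wilcoxon rank-sum for medians, two-sample Kolmogorov-Smirnov for shape.
3. Pairwise KS statistics between all P+1 distributions give each
   distribution a similarity profile (``D_Similarity``).  Np counts how many
   permuted profiles the observed profile differs from (Wilcoxon rank-sum at
   ``alpha``).  ``p_ratio = Np/(P+1)``; an observed distribution unlike its
   permutation null differs from essentially every permuted profile, so the
   reported significance level is the complement ``p_value = 1 - p_ratio``
   (small when the observed shape is anomalous).

The whole procedure is repeated per tissue class (grey matter, white
matter, CSF voxels at probability > 0.4) and for the whole brain.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import ModelSpec, build_designs, batched_lstsq

logger = logging.getLogger(__name__)

TISSUE_NAMES = ("GM", "WM", "CSF")
ANALYSIS_TISSUE_THRESHOLD = 0.4


@dataclass
class PermDistResult:
    """Full output of the distribution-shape permutation procedure."""

    d_voxels: np.ndarray          # (P+1, V) correlations; row 0 observed
    similarity: np.ndarray        # (P+1, P+1) symmetric KS matrix, zero diagonal
    d_similarity: np.ndarray      # (P+1, P) per-index profiles (diagonal removed)
    np_count: int                 # Np: significant Wilcoxon comparisons
    p_ratio: float                # Np / (P+1)
    p_value: float                # 1 - p_ratio; small = observed shape anomalous
    median_p: float               # Wilcoxon observed-vs-pooled-permuted
    shape_p: float                # KS observed-vs-pooled-permuted
    alpha: float
    tissue_class: str = "whole_brain"
    n_voxels: int = 0

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def ks_statistic(a: np.ndarray, b: np.ndarray, return_p: bool = False):
    """Two-sample Kolmogorov-Smirnov sup-distance between empirical CDFs."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("KS statistic requires two nonempty samples")
    res = stats.ks_2samp(a, b)
    if return_p:
        return float(res.statistic), float(res.pvalue)
    return float(res.statistic)


def ranksum_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when both samples have n <= 10 and no ties; normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("rank-sum test requires two nonempty samples")
    pooled = np.concatenate([a, b])
    uniq = np.unique(pooled)
    if uniq.size == 1:  # every value tied: no evidence of any difference
        return 1.0
    no_ties = uniq.size == pooled.size
    method = "exact" if (a.size <= 10 and b.size <= 10 and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def _pairwise_ks(d: np.ndarray) -> np.ndarray:
    """Symmetric matrix of two-sample KS statistics between rows of d.

    Equivalent to scipy.stats.ks_2samp on every pair, vectorised via sorted
    rows and searchsorted (each row's ECDF evaluated at the other's points).
    """
    m, V = d.shape
    ds = np.sort(d, axis=1)
    # self-ECDF at each row's own points via searchsorted, so tied values get
    # the final (correct) cumulative count
    self_cdf = [np.searchsorted(ds[i], ds[i], side="right") / V for i in range(m)]
    M = np.zeros((m, m))
    for i in range(m):
        a = ds[i]
        for j in range(i + 1, m):
            b = ds[j]
            da = np.abs(np.searchsorted(a, b, side="right") / V - self_cdf[j]).max()
            db = np.abs(np.searchsorted(b, a, side="right") / V - self_cdf[i]).max()
            M[i, j] = M[j, i] = max(da, db)
    return M


def build_dvoxels(
    Y: np.ndarray,
    spec: ModelSpec,
    covariates: dict,
    P: int,
    seed: int,
    cvh: np.ndarray | None = None,
    cbf: np.ndarray | None = None,
    gmv: np.ndarray | None = None,
    robust_in_permutations: bool = False,
) -> np.ndarray:
    """(P+1, V) distributions of age-residual correlations.

    Row 0 is the observed analysis (robust per `spec.robust`); rows 1..P
    permute the subject labels of the RSFA matrix jointly across voxels and
    refit against the unchanged design.  Inside permutations the fit is OLS
    unless `robust_in_permutations` is set (logged); the voxel-wise designs
    are fixed, so OLS residual makers are precomputed once.
    """
    Y = np.asarray(Y, dtype=float)
    n, V = Y.shape
    age = covariates["age"]
    if P < 19:
        raise ValueError(f"need at least 19 permutations, got {P}")
    if n <= 12 and P > math.factorial(n) - 1:
        raise ValueError(
            f"P={P} exceeds the {math.factorial(n) - 1} distinct non-identity "
            f"permutations available at n={n}"
        )
    if not robust_in_permutations:
        logger.info("permutation refits use OLS (robust_in_permutations=False)")

    X = build_designs(spec, covariates, cvh=cvh, cbf=cbf, gmv=gmv, n_targets=V)
    _, resid_obs = batched_lstsq(X, Y, robust=spec.robust)

    ac = age - age.mean()
    ac_norm = np.linalg.norm(ac)

    def corr_of(resid: np.ndarray) -> np.ndarray:
        rc = resid - resid.mean(axis=0)
        denom = np.linalg.norm(rc, axis=0) * ac_norm
        denom[denom == 0] = np.inf
        return rc.T @ ac / denom

    d = np.empty((P + 1, V))
    d[0] = corr_of(resid_obs)

    shared_design = X.ndim == 2
    if not robust_in_permutations:
        if shared_design:
            Q, _ = np.linalg.qr(X)
            annihilate = lambda Yp: Yp - Q @ (Q.T @ Yp)  # noqa: E731
        else:
            pinv = np.linalg.pinv(X)  # (V, p, n)

    rng = np.random.default_rng(seed)
    for it in range(1, P + 1):
        perm = rng.permutation(n)
        Yp = Y[perm]
        if robust_in_permutations:
            _, resid = batched_lstsq(X, Yp, robust=True)
        elif shared_design:
            resid = annihilate(Yp)
        else:
            beta = np.einsum("vpn,nv->vp", pinv, Yp, optimize=True)
            resid = Yp - np.einsum("vnp,vp->nv", X, beta, optimize=True)
        d[it] = corr_of(resid)
    return d


def compare_median_and_shape(
    d: np.ndarray, pooled: bool = True
) -> tuple[float, float]:
    """Observed-vs-permuted comparison of distribution median and shape.

    With `pooled` (default) the observed correlations are compared against
    all permuted correlations pooled together; otherwise the median across
    per-permutation p-values is returned for each test.
    """
    obs = d[0]
    if pooled:
        null = d[1:].ravel()
        return ranksum_test(obs, null), ks_statistic(obs, null, return_p=True)[1]
    med = [ranksum_test(obs, row) for row in d[1:]]
    shp = [ks_statistic(obs, row, return_p=True)[1] for row in d[1:]]
    return float(np.median(med)), float(np.median(shp))


def similarity_np_ratio(
    d: np.ndarray,
    alpha: float = 0.05,
    tissue_class: str = "whole_brain",
) -> PermDistResult:
    """Pairwise-KS similarity profiles, Np count and significance ratio."""
    d = np.asarray(d, dtype=float)
    m = d.shape[0]
    if m < 20:
        raise ValueError(f"need at least 20 distributions (P+1), got {m}")
    M = _pairwise_ks(d)
    profiles = np.array([np.delete(M[i], i) for i in range(m)])
    obs_profile = profiles[0]
    np_count = 0
    for j in range(1, m):
        if ranksum_test(obs_profile, profiles[j]) < alpha:
            np_count += 1
    p_ratio = np_count / m
    median_p, shape_p = compare_median_and_shape(d)
    return PermDistResult(
        d_voxels=d,
        similarity=M,
        d_similarity=profiles,
        np_count=np_count,
        p_ratio=p_ratio,
        p_value=1.0 - p_ratio,
        median_p=median_p,
        shape_p=shape_p,
        alpha=alpha,
        tissue_class=tissue_class,
        n_voxels=d.shape[1],
    )


def run_distribution_test(
    Y: np.ndarray,
    spec: ModelSpec,
    covariates: dict,
    P: int,
    seed: int,
    alpha: float = 0.05,
    tissue_class: str = "whole_brain",
    **predictors,
) -> PermDistResult:
    """build_dvoxels + similarity_np_ratio in one call."""
    d = build_dvoxels(Y, spec, covariates, P=P, seed=seed, **predictors)
    return similarity_np_ratio(d, alpha=alpha, tissue_class=tissue_class)


def _tissue_masks(
    n_voxels: int,
    tissue_labels: np.ndarray | None = None,
    tissue_probs: np.ndarray | None = None,
    threshold: float = ANALYSIS_TISSUE_THRESHOLD,
) -> dict[str, np.ndarray]:
    masks = {"whole_brain": np.ones(n_voxels, dtype=bool)}
    if tissue_probs is not None:
        probs = np.asarray(tissue_probs, dtype=float)
        if probs.shape != (3, n_voxels):
            raise ValueError(f"tissue_probs must be (3, {n_voxels})")
        for c, name in enumerate(TISSUE_NAMES):
            masks[name] = probs[c] > threshold
    elif tissue_labels is not None:
        labels = np.asarray(tissue_labels)
        if labels.shape != (n_voxels,):
            raise ValueError(f"tissue_labels must have length {n_voxels}")
        for c, name in enumerate(TISSUE_NAMES):
            masks[name] = labels == c
    else:
        raise ValueError("provide tissue_labels or tissue_probs")
    return masks


def run_tissue_variants(
    Y: np.ndarray,
    spec: ModelSpec,
    covariates: dict,
    P: int,
    seed: int,
    alpha: float = 0.05,
    tissue_labels: np.ndarray | None = None,
    tissue_probs: np.ndarray | None = None,
    threshold: float = ANALYSIS_TISSUE_THRESHOLD,
    cvh: np.ndarray | None = None,
    cbf: np.ndarray | None = None,
    gmv: np.ndarray | None = None,
    robust_in_permutations: bool = False,
) -> dict[str, PermDistResult]:
    """Whole-brain plus per-tissue distribution tests for one model.

    Tissue membership is probability > `threshold` when probability maps
    are given, or exact label match for synthetic class labels.  Empty
    classes are skipped with a warning.  Voxel-matched predictors are
    subset alongside the RSFA voxels.
    """
    Y = np.asarray(Y, dtype=float)
    masks = _tissue_masks(Y.shape[1], tissue_labels, tissue_probs, threshold)
    out: dict[str, PermDistResult] = {}
    for name, mask in masks.items():
        if not mask.any():
            logger.warning("tissue class %s has no voxels; skipped", name)
            continue
        sub = {
            "cvh": cvh,
            "cbf": None if cbf is None else np.asarray(cbf, float)[:, mask],
            "gmv": None if gmv is None else np.asarray(gmv, float)[:, mask],
        }
        d = build_dvoxels(
            Y[:, mask], spec, covariates, P=P, seed=seed,
            robust_in_permutations=robust_in_permutations, **sub,
        )
        out[name] = similarity_np_ratio(d, alpha=alpha, tissue_class=name)
    return out


def table_report(results: dict[str, dict[str, PermDistResult]]) -> pd.DataFrame:
    """Model-by-tissue table of significance levels (1 - Np/(P+1)).

    Rows are models, columns whole brain / GM / WM / CSF — the standard
    report layout for the distribution-based analysis.
    """
    cols = ["whole_brain", *TISSUE_NAMES]
    rows = {}
    for model_id, per_tissue in results.items():
        rows[model_id] = {c: per_tissue[c].p_value if c in per_tissue else np.nan
                          for c in cols}
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)
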