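"""Two-stage residual analysis of RSFA against age.

Stage one regresses RSFA (per voxel or per ICA component) on vascular and
volumetric predictors plus covariates of no interest — never on age.  Stage
two correlates the stage-one residuals with age; a surviving correlation
means the predictors could not account for the age-related variability.
Six nested model specifications are provided:

    I    covariates only
    II   + CBF (voxel-matched at the voxel level)
    III  + CVH factor scores
    IV   + CBF + CVH
    V    + GMV (voxel-matched; CSF signal added as covariate)
    VI   + GMV orthogonalised with respect to CVH

Stage-one fits use iteratively reweighted least squares with the Tukey
bisquare weight function (tuning constant 4.685, scale = MAD/0.6745) when
`robust` is set, implemented as a batched numpy kernel so that thousands of
voxel-wise designs fit in one call; plain OLS otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

BISQUARE_C = 4.685
MAD_NORM = 0.6745

STANDARD_MODELS = {
    "I": (),
    "II": ("CBF",),
    "III": ("CVH",),
    "IV": ("CBF", "CVH"),
    "V": ("GMV",),
    "VI": ("GMV_orth_CVH",),
}

VOXEL_MATCHED = {"CBF", "GMV", "GMV_orth_CVH"}


@dataclass(frozen=True)
class ModelSpec:
    """Definition of one stage-one regression model."""

    id: str
    predictors: tuple[str, ...]
    robust: bool = True
    voxel_matched: bool = True  # CBF/GMV taken voxel-by-voxel when targets are voxels

    def __post_init__(self) -> None:
        known = {"CBF", "CVH", "GMV", "GMV_orth_CVH"}
        bad = set(self.predictors) - known
        if bad:
            raise ValueError(f"unknown predictors {sorted(bad)}")

    @property
    def needs_csf_covariate(self) -> bool:
        return bool({"GMV", "GMV_orth_CVH"} & set(self.predictors))

    @classmethod
    def standard(cls, model_id: str, robust: bool = True) -> "ModelSpec":
        if model_id not in STANDARD_MODELS:
            raise ValueError(f"unknown model id {model_id!r}; expected one of I..VI")
        return cls(id=model_id, predictors=STANDARD_MODELS[model_id], robust=robust)

    @classmethod
    def suite(cls, ids: str | list[str] = "I,II,III,IV,V,VI", robust: bool = True):
        if isinstance(ids, str):
            ids = [s.strip() for s in ids.split(",") if s.strip()]
        return [cls.standard(i, robust=robust) for i in ids]


@dataclass
class ResidualAgeResult:
    """Stage-two output: residual-age correlation per target with BH-FDR mask."""

    model_id: str
    r: np.ndarray
    p: np.ndarray
    fdr_mask: np.ndarray
    crit_p: float
    n_targets: int
    excluded: np.ndarray = field(default=None)  # zero-variance targets

    @property
    def n_significant(self) -> int:
        return int(self.fdr_mask.sum())

    def summary(self) -> dict:
        valid = ~self.excluded if self.excluded is not None else np.ones_like(self.r, bool)
        return {
            "model": self.model_id,
            "n_targets": self.n_targets,
            "n_significant": self.n_significant,
            "median_abs_r": float(np.median(np.abs(self.r[valid]))) if valid.any() else np.nan,
        }


# ---------------------------------------------------------------------------
# batched (ro)bust least squares
# ---------------------------------------------------------------------------

def _as_batched(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Normalise to X (V, n, p), Y (V, n)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    single = Y.ndim == 1
    if single:
        Y = Y[:, None]
    Yb = Y.T  # (V, n)
    if X.ndim == 2:
        Xb = np.broadcast_to(X, (Yb.shape[0],) + X.shape)
    elif X.ndim == 3:
        if X.shape[0] != Yb.shape[0]:
            raise ValueError(
                f"batched design has {X.shape[0]} targets but Y has {Yb.shape[0]}"
            )
        Xb = X
    else:
        raise ValueError("design must be (n, p) or (V, n, p)")
    if Xb.shape[1] != Yb.shape[1]:
        raise ValueError(f"design rows {Xb.shape[1]} != observations {Yb.shape[1]}")
    return Xb, Yb, single


def _check_rank(X: np.ndarray) -> None:
    # check the shared or the first per-voxel design; collinearity is almost
    # always structural (duplicated column), not voxel-specific
    X0 = X[0]
    rank = np.linalg.matrix_rank(X0)
    if rank < X0.shape[1]:
        s = np.linalg.svd(X0, compute_uv=False)
        raise np.linalg.LinAlgError(
            f"rank-deficient stage-one design: rank {rank} < {X0.shape[1]} columns "
            f"(singular values {np.round(s, 6)})"
        )


def _wls_solve(Xb: np.ndarray, Yb: np.ndarray, w: np.ndarray | None) -> np.ndarray:
    """Solve per-target (weighted) normal equations. Returns beta (V, p)."""
    if w is None:
        Xw = Xb
    else:
        Xw = Xb * w[:, :, None]
    XtX = np.einsum("vnp,vnq->vpq", Xw, Xb, optimize=True)
    Xty = np.einsum("vnp,vn->vp", Xw, Yb, optimize=True)
    p = Xb.shape[2]
    XtX = XtX + 1e-12 * np.eye(p)
    return np.linalg.solve(XtX, Xty[..., None])[..., 0]


def batched_lstsq(
    X: np.ndarray,
    Y: np.ndarray,
    robust: bool = False,
    c: float = BISQUARE_C,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """(Robust) linear fit of many targets at once.

    Parameters
    ----------
    X : (n, p) shared design or (V, n, p) per-target designs.
    Y : (n,) or (n, V) target values.
    robust : bool
        If True, IRLS with Tukey bisquare weights; scale is the median
        absolute residual divided by 0.6745, re-estimated each iteration.

    Returns
    -------
    beta : (p,) or (V, p) coefficients
    resid : (n,) or (n, V) residuals
    """
    Xb, Yb, single = _as_batched(X, Y)
    n, p = Xb.shape[1], Xb.shape[2]
    if n <= p + 5:
        raise ValueError(f"need n > p + 5 observations (n={n}, p={p})")
    if not (np.all(np.isfinite(Xb)) and np.all(np.isfinite(Yb))):
        raise ValueError("missing or non-finite values in stage-one inputs")
    _check_rank(Xb)

    beta = _wls_solve(Xb, Yb, None)
    if robust:
        for _ in range(max_iter):
            resid = Yb - np.einsum("vnp,vp->vn", Xb, beta, optimize=True)
            scale = np.median(np.abs(resid), axis=1) / MAD_NORM
            # perfect fits: leave their coefficients at the OLS solution
            active = scale > 1e-12
            if not active.any():
                break
            u = resid[active] / (c * scale[active, None])
            w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
            new_beta = beta.copy()
            new_beta[active] = _wls_solve(Xb[active], Yb[active], w)
            delta = np.max(np.abs(new_beta - beta) / np.maximum(1.0, np.abs(beta)))
            beta = new_beta
            if delta < tol:
                break
    resid = Yb - np.einsum("vnp,vp->vn", Xb, beta, optimize=True)
    if single:
        return beta[0], resid[0]
    return beta, resid.T


def fit_first_stage(
    y: np.ndarray,
    X: np.ndarray,
    robust: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Stage-one fit of one target vector on an explicit design.

    Returns (residuals, coefficients)."""
    beta, resid = batched_lstsq(X, np.asarray(y, dtype=float), robust=robust)
    return resid, beta


def orthogonalize_gmv(gmv: np.ndarray, cvh: np.ndarray) -> np.ndarray:
    """Residualise each GMV column on the CVH factor scores (OLS + intercept)."""
    gmv = np.asarray(gmv, dtype=float)
    cvh = np.asarray(cvh, dtype=float)
    if gmv.shape[0] != cvh.shape[0]:
        raise ValueError("GMV and CVH must have the same number of subjects")
    X = np.column_stack([np.ones(cvh.shape[0]), cvh])
    beta, *_ = np.linalg.lstsq(X, gmv, rcond=None)
    return gmv - X @ beta


def correlate_residuals_age(
    residuals: np.ndarray,
    age: np.ndarray,
    q: float = 0.05,
    model_id: str = "",
) -> ResidualAgeResult:
    """Stage two: Pearson correlation of each residual column with age.

    Two-sided p-values from the t transform with n-2 degrees of freedom;
    zero-variance targets are flagged and excluded from the BH-FDR step.
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.ndim == 1:
        residuals = residuals[:, None]
    age = np.asarray(age, dtype=float)
    n = age.shape[0]
    if residuals.shape[0] != n:
        raise ValueError("residuals and age are not aligned")
    if n < 10:
        raise ValueError(f"need at least 10 subjects, got {n}")

    ac = age - age.mean()
    rc = residuals - residuals.mean(axis=0)
    denom = np.linalg.norm(rc, axis=0) * np.linalg.norm(ac)
    excluded = denom <= 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(excluded, np.nan, rc.T @ ac / np.where(excluded, 1.0, denom))
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
    p = np.where(np.isnan(r), np.nan, 2.0 * stats.t.sf(np.abs(t), df=n - 2))

    mask, crit = fdr_bh(p[~excluded], q)
    full_mask = np.zeros(r.shape[0], dtype=bool)
    full_mask[~excluded] = mask
    return ResidualAgeResult(
        model_id=model_id, r=r, p=p, fdr_mask=full_mask, crit_p=crit,
        n_targets=r.shape[0], excluded=excluded,
    )


def fdr_bh(p: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up at level q. Returns (reject mask, critical p)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject = multipletests(p, alpha=q, method="fdr_bh")[0]
    crit = float(p[reject].max()) if reject.any() else 0.0
    return reject, crit


# ---------------------------------------------------------------------------
# model suite
# ---------------------------------------------------------------------------

def prepare_covariates(subjects: pd.DataFrame, csf_signal: np.ndarray | None = None) -> dict:
    """Standardised covariates of no interest from a subject table.

    Sex is coded +/-0.5; handedness, head motion (and the CSF signal when
    given) are z-scored.  Age is returned separately and never enters
    stage one.
    """
    def z(x):
        x = np.asarray(x, dtype=float)
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    sex = np.asarray(subjects["sex"], dtype=float)
    out = {
        "age": np.asarray(subjects["age"], dtype=float),
        "sex": sex - sex.mean(),  # centred; +/-0.5 coding when balanced 0/1
        "handedness": z(subjects["handedness"]),
        "head_motion": z(subjects["head_motion"]),
    }
    # exact +/-0.5 coding for binary input
    uniq = np.unique(sex)
    if uniq.size == 2:
        out["sex"] = np.where(sex == uniq.max(), 0.5, -0.5)
    if csf_signal is not None:
        out["csf_signal"] = z(csf_signal)
    return out


def _standardize_cols(M: np.ndarray) -> np.ndarray:
    Mc = M - M.mean(axis=0)
    sd = Mc.std(axis=0)
    sd[sd == 0] = 1.0
    return Mc / sd


def build_designs(
    spec: ModelSpec,
    covariates: dict,
    cvh: np.ndarray | None = None,
    cbf: np.ndarray | None = None,
    gmv: np.ndarray | None = None,
    n_targets: int | None = None,
    level: str = "voxel",
) -> np.ndarray:
    """Stage-one design(s) for a model.

    At `level="voxel"` the voxel-matched predictors (CBF, GMV) contribute
    one column per target, yielding a batched (V, n, p) design; `cbf`/`gmv`
    are (n, V) matrices aligned to the targets.  At `level="component"` the
    full CBF/GMV loading matrices enter as shared design columns and a
    single (n, p) design is returned.
    """
    if level not in ("voxel", "component"):
        raise ValueError(f"unknown level {level!r}")
    n = covariates["age"].shape[0]
    shared = [np.ones(n), covariates["sex"], covariates["head_motion"],
              covariates["handedness"]]
    if spec.needs_csf_covariate:
        if "csf_signal" not in covariates:
            raise ValueError("GMV models require a csf_signal covariate")
        shared.append(covariates["csf_signal"])
    if "CVH" in spec.predictors:
        if cvh is None:
            raise ValueError("model requires CVH scores")
        shared.extend(np.asarray(cvh, dtype=float).T)
    S = np.column_stack(shared)

    matched = []
    if "CBF" in spec.predictors:
        if cbf is None:
            raise ValueError("model requires CBF values")
        matched.append(np.asarray(cbf, dtype=float))
    if "GMV" in spec.predictors:
        if gmv is None:
            raise ValueError("model requires GMV values")
        matched.append(np.asarray(gmv, dtype=float))
    if "GMV_orth_CVH" in spec.predictors:
        if gmv is None or cvh is None:
            raise ValueError("model VI requires GMV and CVH")
        matched.append(orthogonalize_gmv(np.asarray(gmv, float), np.asarray(cvh, float)))

    if not matched:
        return S
    if level == "component":
        return np.column_stack([S] + [_standardize_cols(M) for M in matched])
    V = matched[0].shape[1]
    if n_targets is not None and V != n_targets:
        raise ValueError(f"voxel-matched predictor has {V} targets, expected {n_targets}")
    Xb = np.empty((V, n, S.shape[1] + len(matched)))
    Xb[:, :, : S.shape[1]] = S
    for i, M in enumerate(matched):
        # standardise each matched column for comparable coefficients
        Xb[:, :, S.shape[1] + i] = _standardize_cols(M).T
    return Xb


def run_model(
    Y: np.ndarray,
    spec: ModelSpec,
    covariates: dict,
    cvh: np.ndarray | None = None,
    cbf: np.ndarray | None = None,
    gmv: np.ndarray | None = None,
    q: float = 0.05,
    level: str = "voxel",
    return_residuals: bool = False,
):
    """Both stages for one model over all targets (columns of Y)."""
    Y = np.asarray(Y, dtype=float)
    X = build_designs(spec, covariates, cvh=cvh, cbf=cbf, gmv=gmv,
                      n_targets=Y.shape[1], level=level)
    _, resid = batched_lstsq(X, Y, robust=spec.robust)
    result = correlate_residuals_age(resid, covariates["age"], q=q, model_id=spec.id)
    if return_residuals:
        return result, resid
    return result


def run_model_suite(
    Y: np.ndarray,
    specs: list[ModelSpec],
    covariates: dict,
    cvh: np.ndarray | None = None,
    cbf: np.ndarray | None = None,
    gmv: np.ndarray | None = None,
    q: float = 0.05,
    level: str = "voxel",
) -> dict[str, ResidualAgeResult]:
    """Run the two-stage procedure for each model spec; log per-model summaries."""
    out: dict[str, ResidualAgeResult] = {}
    for spec in specs:
        res = run_model(Y, spec, covariates, cvh=cvh, cbf=cbf, gmv=gmv, q=q,
                        level=level)
        out[spec.id] = res
        logger.info("model %s: %s", spec.id, res.summary())
    return out
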