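"""Resting-state fluctuation amplitude (RSFA) estimation.

RSFA is the standard deviation over time of a resting BOLD time series at
each voxel, computed on the residual of a nuisance general linear model
(GLM).  The GLM removes a linear trend, expansions of the six realignment
parameters (raw + backward first difference + square), mean white-matter and
cerebrospinal-fluid signals with the same expansions, and a discrete cosine
transform (DCT) set whose frequencies lie *outside* the pass band — so that
regressing the design out band-passes the residual and nuisance regression
and temporal filtering happen simultaneously in a single fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

logger = logging.getLogger(__name__)

#: low/high band edges in Hz used throughout the pipeline
DEFAULT_BAND = (0.0078, 0.1)


@dataclass
class TimeSeriesImage:
    """4D BOLD image: spatial grid (x, y, z) by time, with repetition time."""

    data: np.ndarray  # (x, y, z, t)
    tr: float  # seconds

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D (x,y,z,t) data, got shape {self.data.shape}")
        if self.tr <= 0:
            raise ValueError(f"TR must be positive, got {self.tr}")
        if self.n_volumes < 8:
            raise ValueError(f"need at least 8 volumes, got {self.n_volumes}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def to_matrix(self) -> np.ndarray:
        """Flatten to (n_volumes, n_voxels)."""
        return self.data.reshape(-1, self.n_volumes).T


@dataclass
class NuisanceDesign:
    """Time-by-regressor nuisance design with per-column labels."""

    matrix: np.ndarray  # (n_volumes, n_regressors)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2D")
        if len(self.labels) != self.matrix.shape[1]:
            raise ValueError("one label per design column required")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))


def tissue_mean_signal(
    ts: TimeSeriesImage,
    tissue_prob: np.ndarray,
    threshold: float = 0.7,
    tissue_name: str = "tissue",
) -> np.ndarray:
    """Average time course over voxels whose tissue probability exceeds `threshold`.

    The mask is strict (> threshold), so a probability exactly at the
    threshold does not contribute.
    """
    tissue_prob = np.asarray(tissue_prob, dtype=float)
    if tissue_prob.shape != ts.grid_dims:
        raise ValueError(
            f"tissue probability grid {tissue_prob.shape} does not match "
            f"time series grid {ts.grid_dims}"
        )
    mask = tissue_prob > threshold
    if not mask.any():
        raise ValueError(
            f"no {tissue_name} voxels with probability > {threshold}; cannot form mean signal"
        )
    return ts.data[mask].mean(axis=0)


def dct_basis(n_volumes: int, order: np.ndarray) -> np.ndarray:
    """DCT-II basis columns cos(pi*(2t+1)*k/(2N)) for the given orders k."""
    t = np.arange(n_volumes)
    k = np.asarray(order, dtype=float)
    cols = np.cos(np.pi * np.outer(2 * t + 1, k) / (2.0 * n_volumes))
    # orthonormalize scale (k>0 columns have norm sqrt(N/2))
    return cols * np.sqrt(2.0 / n_volumes)


def dct_frequencies(n_volumes: int, tr: float) -> np.ndarray:
    """Frequency (Hz) of DCT order k = 0..N-1: f_k = k / (2 N TR)."""
    return np.arange(n_volumes) / (2.0 * n_volumes * tr)


def build_dct_bandstop(
    n_volumes: int,
    tr: float,
    band: tuple[float, float] = DEFAULT_BAND,
) -> np.ndarray:
    """DCT columns at frequencies *outside* [band.low, band.high].

    Including these columns in the nuisance GLM removes fluctuations below
    the low edge and above the high edge (up to Nyquist), so the residual is
    band-passed.  Order k = 0 (constant) is excluded; the intercept covers it.
    """
    low, high = band
    nyquist = 1.0 / (2.0 * tr)
    if not (0 < low < high < nyquist):
        raise ValueError(
            f"require 0 < low < high < Nyquist ({nyquist:.4f} Hz); got ({low}, {high})"
        )
    f = dct_frequencies(n_volumes, tr)
    if not np.any((f >= low) & (f <= high)):
        raise ValueError(
            f"degenerate band ({low}, {high}) Hz: no DCT frequency inside it at "
            f"n={n_volumes}, TR={tr} (step {f[1]:.3g} Hz); nothing would survive"
        )
    keep = (f > 0) & ((f < low) | (f > high))
    orders = np.nonzero(keep)[0]
    # a band covering every frequency legitimately yields zero stop columns
    return dct_basis(n_volumes, orders)


def _expand(series: np.ndarray, name: str) -> tuple[np.ndarray, list[str]]:
    """Raw + backward first difference (zero first element) + square."""
    series = np.atleast_2d(series.T).T  # (n, m)
    n, m = series.shape
    deriv = np.zeros_like(series)
    deriv[1:] = np.diff(series, axis=0)
    quad = series**2
    cols = np.hstack([series, deriv, quad])
    labels = (
        [f"{name}[{i}]" for i in range(m)]
        + [f"{name}_deriv[{i}]" for i in range(m)]
        + [f"{name}_sq[{i}]" for i in range(m)]
    )
    return cols, labels


def build_nuisance_design(
    motion: np.ndarray,
    wm: np.ndarray | None,
    csf: np.ndarray | None,
    n_volumes: int,
    dct: np.ndarray | None = None,
) -> NuisanceDesign:
    """Assemble the nuisance GLM design.

    Columns: intercept, linear trend, 6 motion parameters with derivative and
    quadratic expansions (18 columns), WM and CSF mean signals with the same
    expansions, and the stop-band DCT set.  Columns that do not increase the
    design rank (e.g. the all-zero derivative of a constant regressor) are
    dropped with a warning.
    """
    blocks: list[np.ndarray] = []
    labels: list[str] = []

    blocks.append(np.ones((n_volumes, 1)))
    labels.append("intercept")
    trend = np.linspace(-1.0, 1.0, n_volumes)[:, None]
    blocks.append(trend)
    labels.append("linear_trend")

    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[0] != n_volumes:
        raise ValueError(f"motion table must be ({n_volumes}, 6), got {motion.shape}")
    cols, labs = _expand(motion, "motion")
    blocks.append(cols)
    labels.extend(labs)

    for series, name in ((wm, "wm"), (csf, "csf")):
        if series is None:
            continue
        series = np.asarray(series, dtype=float)
        if series.shape != (n_volumes,):
            raise ValueError(f"{name} signal must have length {n_volumes}")
        cols, labs = _expand(series[:, None], name)
        blocks.append(cols)
        labels.extend(labs)

    if dct is not None:
        dct = np.asarray(dct, dtype=float)
        if dct.shape[0] != n_volumes:
            raise ValueError("DCT columns must have n_volumes rows")
        blocks.append(dct)
        labels.extend([f"dct[{i}]" for i in range(dct.shape[1])])

    X = np.hstack(blocks)
    if not np.all(np.isfinite(X)):
        raise ValueError("nuisance design contains NaN or infinite values")

    keep = _independent_columns(X)
    if not keep.all():
        dropped = [labels[i] for i in np.nonzero(~keep)[0]]
        warnings.warn(
            f"dropping {len(dropped)} rank-deficient nuisance column(s): {dropped}",
            stacklevel=2,
        )
        X = X[:, keep]
        labels = [lab for lab, k in zip(labels, keep) if k]
    return NuisanceDesign(X, labels)


def _independent_columns(X: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Boolean mask of a maximal left-to-right linearly independent column set."""
    n, m = X.shape
    keep = np.zeros(m, dtype=bool)
    basis = np.empty((n, 0))
    for j in range(m):
        col = X[:, j]
        norm = np.linalg.norm(col)
        if norm <= tol:
            continue
        if basis.shape[1]:
            resid = col - basis @ (basis.T @ col)
        else:
            resid = col
        if np.linalg.norm(resid) > tol * max(1.0, norm):
            keep[j] = True
            q = resid / np.linalg.norm(resid)
            basis = np.hstack([basis, q[:, None]])
    return keep


def glm_residuals(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Least-squares residuals of each column of Y on design X."""
    beta, *_ = scipy.linalg.lstsq(X, Y, lapack_driver="gelsd")
    return Y - X @ beta


def compute_rsfa(
    ts: TimeSeriesImage,
    design: NuisanceDesign,
    normalization: str = "mean",
    ddof: int = 0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Voxel-wise RSFA map: SD over time of the GLM residual.

    Parameters
    ----------
    normalization : {"mean", "raw"}
        "mean" divides the residual SD by the voxel's temporal mean of the
        *raw* series (a coefficient of variation, robust to arbitrary
        scanner intensity scaling); "raw" returns the plain SD.
    ddof : int
        Delta degrees of freedom of the SD (0 = population convention).
    mask : bool array, optional
        Brain mask; voxels outside are returned as NaN, never zero.
    """
    if normalization not in ("mean", "raw"):
        raise ValueError(f"unknown normalization mode {normalization!r}")
    X = design.matrix
    n = ts.n_volumes
    if X.shape[0] != n:
        raise ValueError(f"design has {X.shape[0]} rows but series has {n} volumes")
    if design.rank >= n:
        raise ValueError("design leaves no residual degrees of freedom")

    Y = ts.to_matrix()  # (t, V)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != ts.grid_dims:
            raise ValueError("mask grid does not match time series grid")
        flat_mask = mask.ravel()
        Y_in = Y[:, flat_mask]
    else:
        flat_mask = np.ones(Y.shape[1], dtype=bool)
        Y_in = Y

    resid = glm_residuals(Y_in, X)
    sd = resid.std(axis=0, ddof=ddof)

    if normalization == "mean":
        base = Y_in.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            sd = np.where(np.abs(base) > 1e-12, sd / np.abs(base), np.nan)

    out = np.full(Y.shape[1], np.nan)
    out[flat_mask] = sd
    return out.reshape(ts.grid_dims)


def rms_displacement(motion: np.ndarray) -> float:
    """Head-motion summary: root-mean-square volume-to-volume translation.

    Uses the first three motion-parameter columns (translations, mm).
    """
    motion = np.asarray(motion, dtype=float)
    d = np.diff(motion[:, :3], axis=0)
    return float(np.sqrt((d**2).sum(axis=1).mean()))
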