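"""Synthetic multimodal cohort with planted vascular mediation structure.

The generator emulates the statistical structure the two-stage residual
analysis assumes: three latent cardiovascular-health factors whose scores
correlate with age at configurable levels, seven raw cardiovascular
measures that are noisy linear mixtures of those factors, spatially
structured subject-by-voxel CBF / GMV / RSFA maps built from shared smooth
blob sources, and BOLD time series whose post-filtering voxel SD matches a
target RSFA map.  Age acts on RSFA only through the vascular variables
unless a direct age effect is planted, which makes the generator a ground
truth for mediation-recovery tests: stage-one models that condition on the
vascular variables should abolish the residual age correlation.

All randomness flows from ``CohortSpec.seed`` through fixed per-operation
substreams, so identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rsfa import TimeSeriesImage, dct_basis, dct_frequencies, DEFAULT_BAND

GM, WM, CSF = 0, 1, 2
TISSUE_NAMES = ("GM", "WM", "CSF")

MEASURE_NAMES = ["HR", "LF_HRV", "HF_HRV", "BP_sys", "BP_dia", "WMH", "BMI"]

# loadings of the 7 raw measures on the 3 latent factors:
# factor 1 = blood pressure, factor 2 = heart rate / HRV,
# factor 3 = WMH burden with high systolic BP and low HRV
MEASURE_LOADINGS = np.array(
    [
        # F1     F2     F3
        [0.00, -0.80, 0.00],  # HR (high factor-2 score = low resting pulse)
        [0.00, 0.75, -0.30],  # LF-HRV
        [0.00, 0.80, -0.25],  # HF-HRV
        [0.75, 0.00, 0.30],   # systolic BP
        [0.85, 0.00, 0.00],   # diastolic BP
        [0.00, 0.00, 0.85],   # WMH (on the log scale; exponentiated below)
        [0.25, 0.00, 0.65],   # BMI (adiposity tracks the vascular-risk factor)
    ]
)

# measurement units: (offset, scale) applied to the standardized measure
MEASURE_UNITS = {
    "HR": (65.0, 10.0),        # beats/min
    "LF_HRV": (600.0, 150.0),  # power, a.u.
    "HF_HRV": (550.0, 140.0),  # power, a.u.
    "BP_sys": (125.0, 15.0),   # mmHg
    "BP_dia": (75.0, 10.0),    # mmHg
    "WMH": (1.0, 0.8),         # log-scale location/spread; marginal is log-normal
    "BMI": (26.0, 4.0),        # kg/m^2
}

# fixed substream tags so each generator draws from an independent stream
_STREAM = {"subjects": 11, "sources": 23, "maps": 37, "bold": 53}


def _rng(spec: "CohortSpec", stage: str) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed), _STREAM[stage]])


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    mediation_effects (standardized path coefficients):
      cvh_rsfa : latent factor -> RSFA component loading
      cbf_rsfa : CBF component loading -> RSFA component loading
      age_cbf  : age -> CBF component loading
      age_gmv  : age -> GMV component loading
      cvh_gmv  : latent factor -> GMV component loading
    """

    n_subjects: int = 250
    age_range: tuple[float, float] = (18.0, 88.0)
    grid_dims: tuple[int, int, int] = (16, 16, 16)
    n_sources: int = 4
    factor_age_correlations: tuple[float, float, float] = (0.061, -0.417, 0.713)
    factor_intercorrelation: float = 0.0
    mediation_effects: dict = field(
        default_factory=lambda: {
            "cvh_rsfa": 0.5,
            "cbf_rsfa": 0.5,
            "age_cbf": -0.5,
            "age_gmv": -0.4,
            "cvh_gmv": 0.3,
        }
    )
    direct_age_effect: float = 0.0
    noise_sd: dict = field(
        default_factory=lambda: {"rsfa": 0.4, "cbf": 0.866, "gmv": 0.6}
    )
    voxel_noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 10:
            raise ValueError(f"need at least 10 subjects, got {self.n_subjects}")
        if any(abs(r) > 1 for r in self.factor_age_correlations):
            raise ValueError("factor-age correlations must lie in [-1, 1]")
        if abs(self.factor_intercorrelation) > 1:
            raise ValueError("factor intercorrelation must lie in [-1, 1]")
        if any(v <= 0 for v in self.noise_sd.values()) or self.voxel_noise_sd <= 0:
            raise ValueError("noise SDs must be positive")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be (min, max) with min < max")
        # feasibility of the joint (age, factors) correlation matrix
        self.joint_correlation()

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_dims))

    def joint_correlation(self) -> np.ndarray:
        """4x4 target correlation matrix of (age, f1, f2, f3); must be PSD."""
        r = np.asarray(self.factor_age_correlations, dtype=float)
        R = np.full((4, 4), self.factor_intercorrelation)
        np.fill_diagonal(R, 1.0)
        R[0, 1:] = R[1:, 0] = r
        eigmin = float(np.linalg.eigvalsh(R).min())
        if eigmin < -1e-10:
            raise ValueError(
                "infeasible correlation targets: joint (age, factors) matrix has "
                f"minimum eigenvalue {eigmin:.4g} < 0 for age correlations "
                f"{tuple(r)} and intercorrelation {self.factor_intercorrelation}"
            )
        return R


@dataclass
class GroundTruth:
    """Planted structure behind a synthetic cohort (for recovery tests only)."""

    source_maps: dict          # modality -> (k, V); shared across modalities
    tissue_of_source: np.ndarray  # (k,) tissue class per source
    centers: np.ndarray        # (k, 3) blob centers in voxel coordinates
    sigma: float               # blob width (voxels)
    tissue_labels: np.ndarray  # (V,) in {GM, WM, CSF}
    tissue_probs: np.ndarray   # (3, V) pseudo tissue-probability maps
    grid_dims: tuple[int, int, int]
    component_factor: np.ndarray = None  # (k,) latent factor index per component
    true_loadings: dict = field(default_factory=dict)  # modality -> (n, k)
    mediation_paths: dict = field(default_factory=dict)
    age_effect_per_component: np.ndarray = None  # planted total age->RSFA path
    age_corr_realized: np.ndarray = None         # sample corr(age, RSFA loading)

    def support(self, component: int, frac: float = 0.05) -> np.ndarray:
        """Voxels where a source exceeds `frac` of its peak value."""
        s = next(iter(self.source_maps.values()))[component]
        return s > frac * s.max()


@dataclass
class MapMatrix:
    """Subjects-by-voxels matrix for one modality with grid metadata."""

    values: np.ndarray  # (n_subjects, n_voxels)
    modality: str
    grid_dims: tuple[int, int, int]
    subject_ids: list = None
    tissue_labels: np.ndarray = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("MapMatrix values must be (subjects, voxels)")
        if self.values.shape[1] != int(np.prod(self.grid_dims)):
            raise ValueError(
                f"{self.values.shape[1]} voxels inconsistent with grid {self.grid_dims}"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def volume(self, subject: int) -> np.ndarray:
        return self.values[subject].reshape(self.grid_dims)


def _orthonormal_noise(rng: np.random.Generator, n: int, m: int,
                       against: np.ndarray) -> np.ndarray:
    """n-by-m noise columns made exactly orthogonal to `against` columns and
    to each other, each with unit sample SD (population convention)."""
    G = rng.standard_normal((n, m))
    A = np.column_stack([np.ones(n), against])
    Q, _ = np.linalg.qr(A)
    G = G - Q @ (Q.T @ G)
    # Gram-Schmidt among the noise columns
    for j in range(m):
        for i in range(j):
            G[:, j] -= G[:, i] * (G[:, i] @ G[:, j]) / (G[:, i] @ G[:, i])
    return G / G.std(axis=0, ddof=0)


def generate_subjects(spec: CohortSpec) -> pd.DataFrame:
    """Subject table: demographics, covariates and 7 raw cardiovascular measures.

    The three latent factor scores are planted with *exact* sample
    correlations to age (the noise component is residualised against age
    before mixing), so the generator hits its calibration targets at any n.
    The latent scores are kept as ``latent_f1..3`` columns — ground truth
    for recovery tests, never an input to the analysis.
    """
    rng = _rng(spec, "subjects")
    n = spec.n_subjects
    lo, hi = spec.age_range

    age = rng.uniform(lo, hi, size=n)
    z_age = (age - age.mean()) / age.std(ddof=0)

    R = spec.joint_correlation()
    L = np.linalg.cholesky(R + 1e-12 * np.eye(4))
    G = _orthonormal_noise(rng, n, 3, z_age[:, None])
    # factors = r_k * z_age + mixed orthogonal noise -> exact sample correlations
    factors = z_age[:, None] * L[1:, 0] + G @ L[1:, 1:].T
    factors /= factors.std(axis=0, ddof=0)

    # 7 standardized measures: factor mixture + unique noise
    lam = MEASURE_LOADINGS
    unique_sd = np.sqrt(1.0 - (lam**2).sum(axis=1))
    meas = factors @ lam.T + rng.standard_normal((n, 7)) * unique_sd

    data = {"subject_id": [f"sub-{i:04d}" for i in range(n)], "age": age}
    data["sex"] = rng.integers(0, 2, size=n)
    data["handedness"] = np.clip(rng.normal(60.0, 40.0, size=n), -100.0, 100.0)
    # head motion (mm RMS displacement), mildly age-correlated, strictly positive
    data["head_motion"] = 0.15 * np.exp(
        0.3 * z_age + 0.5 * rng.standard_normal(n)
    )
    for j, name in enumerate(MEASURE_NAMES):
        off, scale = MEASURE_UNITS[name]
        col = off + scale * meas[:, j]
        if name == "WMH":
            col = np.exp(off + scale * meas[:, j])  # log-normal, strictly positive
        data[name] = col
    for k in range(3):
        data[f"latent_f{k + 1}"] = factors[:, k]
    return pd.DataFrame(data)


def generate_spatial_sources(spec: CohortSpec) -> GroundTruth:
    """Smooth unit-norm Gaussian blob sources with near-disjoint supports.

    Blob centers are placed greedily with a minimum pairwise separation of
    4.5 sigma, which bounds pairwise |cosine| below 0.2 and support overlap
    below 20%.  Each source gets a dominant tissue class (cycling GM, WM,
    CSF); per-voxel labels assign every voxel to the class of its strongest
    source, and pseudo probability maps mix source activations with a weak
    background so thresholded masks behave like segmentations.
    """
    rng = _rng(spec, "sources")
    dims = np.asarray(spec.grid_dims, dtype=float)
    sigma = float(min(dims)) / 9.0
    margin = 2.0 * sigma
    min_sep = 3.5 * sigma  # |cosine| = exp(-min_sep^2/(4 sigma^2)) ~ 0.05

    # candidate pool: jittered corners/face-centres of the margin box (the
    # best-separated placements) plus random interior points; greedy maximin
    lo, hi = np.full(3, margin), dims - margin
    if np.any(hi <= lo):
        raise ValueError(f"grid {spec.grid_dims} too small for blob width {sigma:.1f}")
    anchors = np.array(
        [[a, b, c] for a in (lo[0], hi[0]) for b in (lo[1], hi[1])
         for c in (lo[2], hi[2])]
        + [[(lo[0] + hi[0]) / 2, (lo[1] + hi[1]) / 2, z] for z in (lo[2], hi[2])]
    )
    anchors = anchors + rng.uniform(-0.5 * sigma, 0.5 * sigma, anchors.shape)
    pool = np.vstack([anchors, rng.uniform(lo, hi, size=(512, 3))])
    pool = np.clip(pool, lo, hi)

    first = int(rng.integers(len(pool)))
    chosen = [first]
    dist = np.linalg.norm(pool - pool[first], axis=1)
    while len(chosen) < spec.n_sources:
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(pool - pool[nxt], axis=1))
    centers = pool[chosen]
    seps = [np.linalg.norm(centers[i] - centers[j])
            for i in range(len(centers)) for j in range(i + 1, len(centers))]
    if seps and min(seps) < min_sep:
        raise ValueError(
            f"cannot place {spec.n_sources} sources with separation "
            f"{min_sep:.1f} voxels on grid {spec.grid_dims} "
            f"(best achieved {min(seps):.1f})"
        )

    grid = np.stack(
        np.meshgrid(*[np.arange(d) for d in spec.grid_dims], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    sources = np.empty((spec.n_sources, spec.n_voxels))
    for k, c in enumerate(centers):
        d2 = ((grid - c) ** 2).sum(axis=1)
        blob = np.exp(-d2 / (2.0 * sigma**2))
        sources[k] = blob / np.linalg.norm(blob)

    tissue_of_source = np.array(
        [(GM, WM, CSF)[k % 3] for k in range(spec.n_sources)]
    )
    class_act = np.zeros((3, spec.n_voxels))
    for k in range(spec.n_sources):
        class_act[tissue_of_source[k]] += sources[k]
    background = np.array([0.02, 0.01, 0.01])[:, None]
    probs = (class_act + background) / (class_act + background).sum(axis=0)
    labels = np.argmax(class_act + background, axis=0)

    return GroundTruth(
        source_maps={m: sources for m in ("rsfa", "cbf", "gmv")},
        tissue_of_source=tissue_of_source,
        centers=centers,
        sigma=sigma,
        tissue_labels=labels,
        tissue_probs=probs,
        grid_dims=spec.grid_dims,
        component_factor=np.arange(spec.n_sources) % 3,
        mediation_paths=dict(spec.mediation_effects),
    )


def generate_modality_maps(
    subjects: pd.DataFrame, truth: GroundTruth, spec: CohortSpec
) -> dict[str, MapMatrix]:
    """Subject-by-voxel CBF, GMV and RSFA maps realising the mediation process.

    Component loadings (one column per spatial source):
      CBF_j  = age_cbf * z_age                                + noise
      GMV_j  = age_gmv * z_age + cvh_gmv * f_{m(j)}           + noise
      RSFA_j = cvh_rsfa * f_{m(j)} + cbf_rsfa * CBF_j
               + direct_age_effect * z_age                    + noise
    where m(j) cycles through the three latent factors.  Maps are
    loadings @ sources + isotropic voxel noise.
    """
    rng = _rng(spec, "maps")
    n = len(subjects)
    k = spec.n_sources
    if truth.source_maps["rsfa"].shape[0] != k:
        raise ValueError("ground truth sources inconsistent with spec.n_sources")

    age = subjects["age"].to_numpy(dtype=float)
    z_age = (age - age.mean()) / age.std(ddof=0)
    factors = subjects[[f"latent_f{i + 1}" for i in range(3)]].to_numpy(dtype=float)
    fmap = truth.component_factor
    eff = spec.mediation_effects

    cbf_load = eff["age_cbf"] * z_age[:, None] + spec.noise_sd["cbf"] * (
        rng.standard_normal((n, k))
    )
    gmv_load = (
        eff["age_gmv"] * z_age[:, None]
        + eff["cvh_gmv"] * factors[:, fmap]
        + spec.noise_sd["gmv"] * rng.standard_normal((n, k))
    )
    rsfa_load = (
        eff["cvh_rsfa"] * factors[:, fmap]
        + eff["cbf_rsfa"] * cbf_load
        + spec.direct_age_effect * z_age[:, None]
        + spec.noise_sd["rsfa"] * rng.standard_normal((n, k))
    )

    loadings = {"cbf": cbf_load, "gmv": gmv_load, "rsfa": rsfa_load}
    maps = {}
    for modality, load in loadings.items():
        S = truth.source_maps[modality]
        vals = load @ S + spec.voxel_noise_sd * rng.standard_normal((n, S.shape[1]))
        maps[modality] = MapMatrix(
            values=vals,
            modality=modality,
            grid_dims=spec.grid_dims,
            subject_ids=list(subjects["subject_id"]),
            tissue_labels=truth.tissue_labels,
        )

    truth.true_loadings = loadings
    r_age = np.asarray(spec.factor_age_correlations)
    truth.age_effect_per_component = (
        eff["cvh_rsfa"] * r_age[fmap]
        + eff["cbf_rsfa"] * eff["age_cbf"]
        + spec.direct_age_effect
    )
    zc = z_age - z_age.mean()
    lc = rsfa_load - rsfa_load.mean(axis=0)
    truth.age_corr_realized = (lc.T @ zc) / (
        np.linalg.norm(lc, axis=0) * np.linalg.norm(zc)
    )
    return maps


@dataclass
class SimulatedBold:
    """BOLD simulation output: the image plus its nuisance ground truth."""

    ts: TimeSeriesImage
    motion: np.ndarray       # (n_volumes, 6) realignment-parameter table
    wm_signal: np.ndarray    # planted WM nuisance time course
    csf_signal: np.ndarray   # planted CSF nuisance time course
    target_rsfa: np.ndarray  # (V,) the RSFA values the series encodes


def generate_bold_timeseries(
    target_rsfa: np.ndarray,
    spec: CohortSpec,
    n_volumes: int = 255,
    tr: float = 1.97,
    band: tuple[float, float] = DEFAULT_BAND,
    baseline: float = 100.0,
    tissue_probs: np.ndarray | None = None,
    seed: int | None = None,
) -> SimulatedBold:
    """BOLD series whose band-passed voxel SD equals a target RSFA map.

    The stochastic signal is white noise projected onto the in-band DCT
    space — the same projector the estimator uses — and rescaled per voxel
    so the target amplitude is attainable exactly.  Planted nuisance:
    motion-locked drift (exactly spanned by the realignment parameters) and
    global WM/CSF signals weighted by tissue probability.
    """
    target = np.asarray(target_rsfa, dtype=float).ravel()
    if n_volumes <= 0:
        raise ValueError(f"volume count must be positive, got {n_volumes}")
    if np.any(target < 0):
        raise ValueError("target RSFA values must be nonnegative")
    V = target.size
    rng = (
        np.random.default_rng([int(spec.seed), _STREAM["bold"]])
        if seed is None
        else np.random.default_rng(seed)
    )

    f = dct_frequencies(n_volumes, tr)
    in_band = np.nonzero((f >= band[0]) & (f <= band[1]))[0]
    B = dct_basis(n_volumes, in_band)  # (t, K)
    sig = B @ rng.standard_normal((in_band.size, V))
    sd = sig.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    sig *= target / sd

    # slow realignment-parameter drifts (mm / radians)
    motion = np.cumsum(rng.normal(0.0, 2e-3, size=(n_volumes, 6)), axis=0)
    motion -= motion.mean(axis=0)
    amp = float(np.median(target[target > 0])) if (target > 0).any() else 1.0
    W = rng.normal(0.0, 0.3 * amp, size=(3, V))
    mz = motion[:, :3] / np.maximum(motion[:, :3].std(axis=0), 1e-12)
    data = baseline + sig + mz @ W

    low = dct_basis(n_volumes, np.nonzero((f > 0) & (f < band[0]))[0])
    wm_signal = low @ rng.standard_normal(low.shape[1]) * 0.5 * amp
    csf_signal = low @ rng.standard_normal(low.shape[1]) * 0.5 * amp
    if tissue_probs is not None:
        probs = np.asarray(tissue_probs, dtype=float)
        data = data + np.outer(wm_signal, probs[WM]) + np.outer(csf_signal, probs[CSF])

    side = round(V ** (1 / 3))
    dims = (side, side, side) if side**3 == V else (V, 1, 1)
    ts = TimeSeriesImage(data.T.reshape(dims + (n_volumes,)), tr=tr)
    return SimulatedBold(
        ts=ts, motion=motion, wm_signal=wm_signal, csf_signal=csf_signal,
        target_rsfa=target,
    )


def csf_mean_value(rsfa_map: MapMatrix, tissue_labels: np.ndarray) -> np.ndarray:
    """Per-subject mean map value over CSF-labelled voxels (covariate for
    the GMV models)."""
    mask = np.asarray(tissue_labels) == CSF
    if not mask.any():
        raise ValueError("no CSF voxels in tissue labels")
    return rsfa_map.values[:, mask].mean(axis=1)
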