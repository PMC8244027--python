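"""Benchmark experiments on synthetic cohorts.

Self-contained, seeded procedures that exercise the pipeline end to end and
return the quantities a user would quote: oracle agreement of the numerical
primitives, band-pass filter energy contracts, ICA/EFA recovery of planted
structure, the Model I vs Model IV mediation pattern, and type-I/power rates
of the distribution-shape permutation decision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import (
    MEASURE_LOADINGS, MEASURE_NAMES, CohortSpec, csf_mean_value,
    generate_modality_maps, generate_spatial_sources, generate_subjects,
)
from .factors import CardioHealthFactors, match_factors, normality_transform
from .ica import fit_group_ica, match_components
from .models import ModelSpec, fdr_bh, prepare_covariates, run_model
from .permtest import build_dvoxels, similarity_np_ratio
from .rsfa import build_dct_bandstop, glm_residuals


# ---------------------------------------------------------------------------
# numerical primitives vs independent oracles
# ---------------------------------------------------------------------------

def rsfa_oracle_max_diff(n_images: int = 50, seed: int = 0) -> float:
    """Max |RSFA - oracle| over random small images, where the oracle solves
    the normal equations explicitly and takes the residual SD."""
    from .rsfa import NuisanceDesign, TimeSeriesImage, compute_rsfa

    rng = np.random.default_rng([seed, 1])
    worst = 0.0
    for _ in range(n_images):
        t = int(rng.integers(25, 60))
        X = np.column_stack([np.ones(t), rng.standard_normal((t, int(rng.integers(2, 8))))])
        design = NuisanceDesign(X, [f"c{i}" for i in range(X.shape[1])])
        data = rng.standard_normal((3, 3, 2, t))
        out = compute_rsfa(TimeSeriesImage(data, tr=2.0), design, normalization="raw")
        Y = data.reshape(-1, t).T
        beta = np.linalg.solve(X.T @ X, X.T @ Y)
        oracle = (Y - X @ beta).std(axis=0, ddof=0).reshape(3, 3, 2)
        worst = max(worst, float(np.abs(out - oracle).max()))
    return worst


def bh_fdr_mismatches(n_vectors: int = 1000, seed: int = 0) -> int:
    """Count of disagreements between fdr_bh and a brute-force step-up."""
    rng = np.random.default_rng([seed, 2])
    mism = 0
    for _ in range(n_vectors):
        m = int(rng.integers(1, 60))
        p = rng.uniform(0, 1, m) ** float(rng.uniform(0.5, 3.0))
        mask, _ = fdr_bh(p, 0.05)
        order = np.argsort(p)
        ps = p[order]
        kmax = 0
        for i in range(1, m + 1):
            if ps[i - 1] <= i * 0.05 / m:
                kmax = i
        ref = np.zeros(m, dtype=bool)
        ref[order[:kmax]] = True
        mism += not np.array_equal(mask, ref)
    return mism


def ks_wilcoxon_enumeration_max_diff(seed: int = 0, max_n: int = 8) -> tuple[float, float]:
    """Max |statistic - exhaustive oracle| for the two-sample KS distance and
    the two-sided Wilcoxon rank-sum p over all sample sizes up to max_n."""
    import itertools

    from .permtest import ks_statistic, ranksum_test

    rng = np.random.default_rng([seed, 3])
    worst_ks = worst_w = 0.0
    for n1 in range(1, max_n + 1):
        for n2 in range(1, max_n + 1):
            a = rng.standard_normal(n1)
            b = rng.standard_normal(n2)
            pooled = np.concatenate([a, b])
            d_oracle = max(abs((a <= t).mean() - (b <= t).mean()) for t in pooled)
            worst_ks = max(worst_ks, abs(ks_statistic(a, b) - d_oracle))
            obs_u = sum((x > y) for x in a for y in b)
            mu = n1 * n2 / 2
            us = [
                sum((x > y) for x in pooled[list(idx)]
                    for y in np.delete(pooled, list(idx)))
                for idx in itertools.combinations(range(n1 + n2), n1)
            ]
            p_oracle = np.mean(np.abs(np.array(us) - mu) >= abs(obs_u - mu) - 1e-12)
            worst_w = max(worst_w, abs(ranksum_test(a, b) - p_oracle))
    return float(worst_ks), float(worst_w)


def filter_energy_retention(
    n: int = 255, tr: float = 1.97, band=(0.0078, 0.1)
) -> dict[str, float]:
    """Fraction of sinusoid energy surviving the DCT-GLM, per frequency."""
    t = np.arange(n) * tr
    cols = build_dct_bandstop(n, tr, band)
    X = np.column_stack([np.ones(n), cols])
    out = {}
    for name, freq in (("in_band_0.05Hz", 0.05), ("below_band_0.003Hz", 0.003),
                       ("above_band_0.15Hz", 0.15)):
        x = np.sin(2 * np.pi * freq * t)
        resid = glm_residuals(x[:, None], X)[:, 0]
        out[name] = float((resid**2).sum() / (x**2).sum())
    return out


# ---------------------------------------------------------------------------
# recovery of planted structure
# ---------------------------------------------------------------------------

def ica_recovery(n_seeds: int = 5, base_seed: int = 0) -> np.ndarray:
    """Min matched |spatial correlation| per seeded cohort (default study
    conditions: n=250 subjects, 4096 voxels, 4 disjoint sources)."""
    out = []
    for s in range(n_seeds):
        spec = CohortSpec(seed=base_seed + s)
        subj = generate_subjects(spec)
        truth = generate_spatial_sources(spec)
        maps = generate_modality_maps(subj, truth, spec)
        dec = fit_group_ica(maps["rsfa"].values, k=spec.n_sources, seed=base_seed + s)
        _, _, corr = match_components(dec.sources, truth.source_maps["rsfa"])
        out.append(np.abs(corr).min())
    return np.array(out)


def efa_recovery(n_seeds: int = 20, n_subjects: int = 500,
                 base_seed: int = 0) -> np.ndarray:
    """Min |Tucker congruence| of matched factors per seeded cohort."""
    out = []
    for s in range(n_seeds):
        spec = CohortSpec(n_subjects=n_subjects, seed=base_seed + s)
        subj = generate_subjects(spec)
        cvh = normality_transform(subj[MEASURE_NAMES])
        est = CardioHealthFactors(n_factors=3).fit(cvh)
        _, cong = match_factors(est.loadings_, MEASURE_LOADINGS)
        out.append(np.abs(cong).min())
    return np.array(out)


def factor_age_correlations(seed: int = 0, n_subjects: int = 500) -> dict[str, float]:
    """Age correlations of the *estimated* CVH factor scores, matched to the
    planted factors (blood pressure, heart rate/HRV, WMH-risk)."""
    spec = CohortSpec(n_subjects=n_subjects, seed=seed)
    subj = generate_subjects(spec)
    cvh = normality_transform(subj[MEASURE_NAMES])
    est = CardioHealthFactors(n_factors=3).fit(cvh)
    scores = est.transform(cvh)
    perm, cong = match_factors(est.loadings_, MEASURE_LOADINGS)
    age = subj["age"].to_numpy()
    out = {}
    for i, name in enumerate(("bp", "hrv", "wmh_risk")):
        s = scores[:, perm[i]] * np.sign(cong[i])
        out[name] = float(np.corrcoef(age, s)[0, 1])
    return out


# ---------------------------------------------------------------------------
# mediation pattern (Model I vs Model IV)
# ---------------------------------------------------------------------------

def analyze_cohort(spec: CohortSpec, model_ids=("I", "IV"), q: float = 0.05) -> dict:
    """Full per-cohort analysis: EFA scores, voxel-wise models, support overlap."""
    subj = generate_subjects(spec)
    truth = generate_spatial_sources(spec)
    maps = generate_modality_maps(subj, truth, spec)
    cvh = normality_transform(subj[MEASURE_NAMES])
    scores = CardioHealthFactors(n_factors=3).fit(cvh).transform(cvh)
    covs = prepare_covariates(
        subj, csf_signal=csf_mean_value(maps["rsfa"], truth.tissue_labels)
    )
    affected = np.zeros(spec.n_voxels, dtype=bool)
    for j in range(spec.n_sources):
        if abs(truth.age_effect_per_component[j]) > 0.1:
            affected |= truth.support(j, frac=0.02)
    out = {"affected_voxels": int(affected.sum())}
    for mid in model_ids:
        res = run_model(
            maps["rsfa"].values, ModelSpec.standard(mid), covs,
            cvh=scores, cbf=maps["cbf"].values, gmv=maps["gmv"].values, q=q,
        )
        sig = res.fdr_mask
        out[f"model_{mid}_significant"] = int(sig.sum())
        out[f"model_{mid}_in_support"] = int((sig & affected).sum())
    return out


def mediation_pattern(n_cohorts: int = 20, base_seed: int = 0) -> pd.DataFrame:
    """Model I vs Model IV FDR counts over seeded cohorts with no direct age
    effect (age reaches RSFA only through CVH and CBF)."""
    rows = []
    for s in range(n_cohorts):
        spec = CohortSpec(seed=base_seed + 1000 + s, direct_age_effect=0.0)
        rows.append(analyze_cohort(spec))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# permutation-test calibration and power
# ---------------------------------------------------------------------------

def _random_covariates(rng, n):
    subj = pd.DataFrame({
        "age": rng.uniform(18, 88, n),
        "sex": rng.integers(0, 2, n),
        "handedness": rng.normal(60, 30, n),
        "head_motion": rng.uniform(0.05, 0.3, n),
    })
    return prepare_covariates(subj)


def permtest_decision_rates(
    n_runs: int = 100, P: int = 99, V: int = 500, n: int = 60,
    base_seed: int = 0, effect: str = "null", alpha: float = 0.05,
) -> float:
    """Fraction of seeded runs in which the distribution-shape decision fires.

    effect="null": RSFA is pure noise (type-I rate expected <= alpha).
    effect="variance": voxel-specific age effects widen the observed
    correlation distribution to ~5x the null variance (power run).
    """
    fires = 0
    spec = ModelSpec.standard("I")
    for s in range(n_runs):
        rng = np.random.default_rng([base_seed, 7, s])
        covs = _random_covariates(rng, n)
        Y = rng.standard_normal((n, V))
        if effect == "variance":
            z = covs["age"] - covs["age"].mean()
            z = z / z.std()
            slopes = rng.standard_normal(V) * (2.0 / np.sqrt(n))
            Y = Y + np.outer(z, slopes)
        elif effect != "null":
            raise ValueError(f"unknown effect {effect!r}")
        d = build_dvoxels(Y, spec, covs, P=P, seed=int(rng.integers(2**31)))
        res = similarity_np_ratio(d, alpha=alpha)
        fires += res.significant
    return fires / n_runs
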