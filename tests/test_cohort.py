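"""Synthetic cohort generator: planted correlations, sources, maps, BOLD."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rsfavasc.cohort import (
    CohortSpec,
    generate_bold_timeseries,
    generate_modality_maps,
    generate_spatial_sources,
    generate_subjects,
)
from rsfavasc.rsfa import build_dct_bandstop, build_nuisance_design, compute_rsfa


class TestGenerateSubjects:
    def test_planted_age_factor_correlations(self):
        spec = CohortSpec(n_subjects=500, seed=1)
        subj = generate_subjects(spec)
        age = subj["age"].to_numpy()
        for k, target in enumerate(spec.factor_age_correlations):
            r = np.corrcoef(age, subj[f"latent_f{k + 1}"])[0, 1]
            assert abs(r - target) < 0.08
        # the second factor lands in the documented window
        r2 = np.corrcoef(age, subj["latent_f2"])[0, 1]
        assert -0.50 <= r2 <= -0.34

    def test_null_correlations_stay_null(self):
        spec = CohortSpec(n_subjects=500, factor_age_correlations=(0, 0, 0), seed=3)
        subj = generate_subjects(spec)
        age = subj["age"].to_numpy()
        for k in range(3):
            assert abs(np.corrcoef(age, subj[f"latent_f{k + 1}"])[0, 1]) < 0.12

    def test_deterministic_given_seed(self):
        spec = CohortSpec(n_subjects=60, seed=9)
        a, b = generate_subjects(spec), generate_subjects(spec)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = generate_subjects(CohortSpec(n_subjects=60, seed=1))
        b = generate_subjects(CohortSpec(n_subjects=60, seed=2))
        assert not np.allclose(a["age"], b["age"])

    def test_infeasible_correlation_triple_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            CohortSpec(factor_age_correlations=(0.9, 0.9, -0.9))

    def test_ranges_and_positivity(self):
        spec = CohortSpec(n_subjects=400, seed=5)
        subj = generate_subjects(spec)
        assert subj["age"].between(*spec.age_range).all()
        assert (subj["WMH"] > 0).all()
        assert (subj["head_motion"] > 0).all()
        assert subj["handedness"].between(-100, 100).all()
        assert not subj.isna().any().any()
        # motion is mildly age-correlated
        r = np.corrcoef(subj["age"], np.log(subj["head_motion"]))[0, 1]
        assert 0.1 < r < 0.6

    def test_wmh_lognormal_marginal(self):
        subj = generate_subjects(CohortSpec(n_subjects=400, seed=11))
        x = subj["WMH"].to_numpy()

        def ks_p(v):
            return stats.kstest(v, "norm", args=(v.mean(), v.std(ddof=1))).pvalue

        assert ks_p(x) < 0.05          # raw WMH fails the normality screen
        assert ks_p(np.log(x)) > 0.05  # and passes after the log transform


class TestSpatialSources:
    def test_unit_norm_and_near_orthogonal(self, small_cohort):
        _, _, truth, _ = small_cohort
        S = truth.source_maps["rsfa"]
        assert np.allclose(np.linalg.norm(S, axis=1), 1.0)
        G = S @ S.T
        off = np.abs(G - np.diag(np.diag(G)))
        assert off.max() < 0.2

    def test_single_source_norm(self):
        spec = CohortSpec(n_sources=1, grid_dims=(12, 12, 12))
        truth = generate_spatial_sources(spec)
        assert np.linalg.norm(truth.source_maps["rsfa"][0]) == pytest.approx(1.0)

    def test_seed_moves_centers(self):
        t1 = generate_spatial_sources(CohortSpec(seed=1))
        t2 = generate_spatial_sources(CohortSpec(seed=2))
        assert not np.allclose(t1.centers, t2.centers)

    def test_too_many_sources_rejected(self):
        with pytest.raises(ValueError, match="cannot place"):
            generate_spatial_sources(CohortSpec(n_sources=60, grid_dims=(10, 10, 10)))

    def test_tissue_labels_partition(self, small_cohort):
        _, _, truth, _ = small_cohort
        assert set(np.unique(truth.tissue_labels)) <= {0, 1, 2}
        assert truth.tissue_labels.shape == (1000,)
        assert np.allclose(truth.tissue_probs.sum(axis=0), 1.0)


class TestModalityMaps:
    def test_no_direct_age_effect_after_conditioning(self):
        spec = CohortSpec(n_subjects=500, seed=21)
        subj = generate_subjects(spec)
        truth = generate_spatial_sources(spec)
        generate_modality_maps(subj, truth, spec)
        age = subj["age"].to_numpy()
        z = (age - age.mean()) / age.std()
        partials = []
        for j in range(spec.n_sources):
            y = truth.true_loadings["rsfa"][:, j]
            X = np.column_stack([
                np.ones_like(z),
                subj[[f"latent_f{i + 1}" for i in range(3)]].to_numpy(),
                truth.true_loadings["cbf"][:, j],
            ])
            ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
            rz = z - X @ np.linalg.lstsq(X, z, rcond=None)[0]
            partials.append(abs(np.corrcoef(ry, rz)[0, 1]))
        assert np.mean(partials) < 0.1

    def test_global_null_voxelwise(self):
        spec = CohortSpec(
            n_subjects=250, seed=13,
            mediation_effects={"cvh_rsfa": 0, "cbf_rsfa": 0, "age_cbf": 0,
                               "age_gmv": 0, "cvh_gmv": 0},
            direct_age_effect=0.0,
        )
        subj = generate_subjects(spec)
        truth = generate_spatial_sources(spec)
        maps = generate_modality_maps(subj, truth, spec)
        age = subj["age"].to_numpy()
        R = np.corrcoef(np.column_stack([age, maps["rsfa"].values]), rowvar=False)[0, 1:]
        # null sampling bound at n=250: nearly all voxels below 0.15, and
        # even the extreme voxel stays within ~4 SE of zero
        assert np.quantile(np.abs(R), 0.95) < 0.15
        assert np.abs(R).max() < 4.5 / np.sqrt(250)

    def test_cvh_path_lights_up_support_voxels(self, desk_cohort):
        spec, subj, truth, maps = desk_cohort
        age = subj["age"].to_numpy()
        vals = maps["rsfa"].values
        r = np.array([np.corrcoef(age, vals[:, v])[0, 1] for v in range(vals.shape[1])])
        # strongest planted component (largest |total age path|)
        j = int(np.argmax(np.abs(truth.age_effect_per_component)))
        support = truth.support(j, frac=0.3)
        null_vox = ~np.any([truth.support(k, 0.02) for k in range(spec.n_sources)], axis=0)
        thresh = np.quantile(np.abs(r[null_vox]), 0.95)
        assert np.median(np.abs(r[support])) > thresh

    def test_deterministic(self, small_spec):
        subj = generate_subjects(small_spec)
        t1 = generate_spatial_sources(small_spec)
        t2 = generate_spatial_sources(small_spec)
        m1 = generate_modality_maps(subj, t1, small_spec)
        m2 = generate_modality_maps(subj, t2, small_spec)
        for mod in ("rsfa", "cbf", "gmv"):
            assert np.array_equal(m1[mod].values, m2[mod].values)


class TestBoldTimeseries:
    @pytest.fixture(scope="class")
    def tiny_spec(self):
        return CohortSpec(n_subjects=12, grid_dims=(6, 6, 6), n_sources=3, seed=2)

    def _recover(self, sim, band=(0.0078, 0.1)):
        dct = build_dct_bandstop(sim.ts.n_volumes, sim.ts.tr, band)
        design = build_nuisance_design(sim.motion, None, None, sim.ts.n_volumes, dct)
        return compute_rsfa(sim.ts, design, normalization="raw").ravel()

    def test_recovery_correlation(self, tiny_spec, rng):
        target = rng.uniform(0.5, 2.0, size=216)
        sim = generate_bold_timeseries(target, tiny_spec, seed=4)
        est = self._recover(sim)
        assert np.corrcoef(est, target)[0, 1] >= 0.95

    def test_zero_target_below_noise_floor(self, tiny_spec):
        sim = generate_bold_timeseries(np.zeros(216), tiny_spec, seed=4)
        est = self._recover(sim)
        assert np.abs(est).max() < 1e-8

    def test_amplitude_ratio_recovered(self, tiny_spec):
        target = np.where(np.arange(216) < 108, 3.0, 1.0)
        sim = generate_bold_timeseries(target, tiny_spec, seed=5)
        est = self._recover(sim)
        ratio = est[:108].mean() / est[108:].mean()
        assert 2.5 <= ratio <= 3.5

    def test_duration_and_shape(self, tiny_spec):
        sim = generate_bold_timeseries(np.ones(216), tiny_spec)
        assert sim.ts.n_volumes == 255
        assert sim.ts.n_volumes * sim.ts.tr == pytest.approx(502.35)
        assert sim.motion.shape == (255, 6)

    def test_invalid_inputs(self, tiny_spec):
        with pytest.raises(ValueError, match="positive"):
            generate_bold_timeseries(np.ones(8), tiny_spec, n_volumes=0)
        with pytest.raises(ValueError, match="nonnegative"):
            generate_bold_timeseries(np.array([-1.0, 1.0]), tiny_spec)

    def test_deterministic(self, tiny_spec):
        a = generate_bold_timeseries(np.ones(216), tiny_spec, seed=8)
        b = generate_bold_timeseries(np.ones(216), tiny_spec, seed=8)
        assert np.array_equal(a.ts.data, b.ts.data)
        assert np.array_equal(a.motion, b.motion)
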