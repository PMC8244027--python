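"""End-to-end pipeline: simulate -> rsfa -> factors -> ica -> models -> permtest.

Each stage writes its artifacts to fixed names under the output directory
and is skipped on re-run when those artifacts already exist, so a partial
run resumes from disk.  A JSON manifest records the config echo, software
version, per-stage wall-clock, output hashes and summary statistics.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    CohortSpec, MapMatrix, csf_mean_value, generate_bold_timeseries,
    generate_modality_maps, generate_spatial_sources, generate_subjects,
)
from .config import RunConfig
from .factors import CardioHealthFactors, normality_transform
from .ica import GroupICA
from .models import ModelSpec, prepare_covariates, run_model_suite
from .niftiio import read_map_stack, read_table, write_map_stack, write_table
from .permtest import run_tissue_variants, table_report
from .rsfa import build_dct_bandstop, build_nuisance_design, compute_rsfa, tissue_mean_signal
from .cohort import MEASURE_NAMES

logger = logging.getLogger(__name__)

MODALITIES = ("rsfa", "cbf", "gmv")


def _hash(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


class Pipeline:
    """Stage runner bound to one RunConfig and its output directory."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "config": config.to_dict(),
            "version": __version__,
            "stages": {},
        }

    # -- artifact paths -----------------------------------------------------
    def path(self, name: str) -> Path:
        return self.out / name

    def _record(self, stage: str, t0: float, files: list[Path], **summary) -> None:
        self.manifest["stages"][stage] = {
            "wall_clock_s": round(time.time() - t0, 3),
            "outputs": {f.name: _hash(f) for f in files},
            **summary,
        }
        with open(self.path("manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)

    def _done(self, *names: str) -> bool:
        return all(self.path(n).exists() for n in names)

    # -- stages -------------------------------------------------------------
    def simulate(self) -> None:
        names = ["subjects.tsv"] + [f"{m}_maps.nii" for m in MODALITIES] + [
            "tissue_labels.nii", "truth_sources.nii", "truth.json"]
        if self._done(*names):
            logger.info("simulate: artifacts present, skipping")
            return
        t0 = time.time()
        cfg = self.config
        spec = CohortSpec(
            n_subjects=cfg.n_subjects, grid_dims=cfg.grid_dims,
            n_sources=cfg.n_sources, direct_age_effect=cfg.direct_age_effect,
            seed=cfg.seed,
        )
        subjects = generate_subjects(spec)
        truth = generate_spatial_sources(spec)
        maps = generate_modality_maps(subjects, truth, spec)

        files = [write_table(self.path("subjects.tsv"), subjects)]
        for m in MODALITIES:
            files.append(write_map_stack(self.path(f"{m}_maps.nii"),
                                         maps[m].values, cfg.grid_dims))
        files.append(write_map_stack(self.path("tissue_labels.nii"),
                                     truth.tissue_labels[None, :].astype(float),
                                     cfg.grid_dims))
        files.append(write_map_stack(self.path("truth_sources.nii"),
                                     truth.source_maps["rsfa"], cfg.grid_dims))
        truth_rec = {
            "tissue_of_source": truth.tissue_of_source.tolist(),
            "component_factor": truth.component_factor.tolist(),
            "age_effect_per_component": truth.age_effect_per_component.tolist(),
            "mediation_paths": truth.mediation_paths,
            "sigma": truth.sigma,
            "centers": truth.centers.tolist(),
        }
        with open(self.path("truth.json"), "w") as fh:
            json.dump(truth_rec, fh, indent=2)
        files.append(self.path("truth.json"))
        self._record("simulate", t0, files, n_subjects=len(subjects))

    def rsfa_stage(self) -> None:
        """BOLD round trip for a few subjects: synthesize series from the
        simulated RSFA targets, re-estimate RSFA through the nuisance GLM,
        and record the recovery correlation."""
        if self.config.bold_subjects <= 0 or self._done("rsfa_from_bold.nii"):
            if self._done("rsfa_from_bold.nii"):
                logger.info("rsfa: artifacts present, skipping")
            return
        t0 = time.time()
        cfg = self.config
        rsfa_vals = read_map_stack(self.path("rsfa_maps.nii"))
        labels = read_map_stack(self.path("tissue_labels.nii"))[0].astype(int)
        spec = CohortSpec(n_subjects=cfg.n_subjects, grid_dims=cfg.grid_dims,
                          n_sources=cfg.n_sources, seed=cfg.seed)
        probs = np.zeros((3, labels.size))
        probs[labels, np.arange(labels.size)] = 1.0

        recovered, corrs = [], []
        for s in range(min(cfg.bold_subjects, rsfa_vals.shape[0])):
            target = np.abs(rsfa_vals[s])  # RSFA amplitudes are nonnegative
            sim = generate_bold_timeseries(
                target, spec, band=cfg.band, tissue_probs=probs,
                seed=int(np.random.default_rng([cfg.seed, 97, s]).integers(2**31)),
            )
            dct = build_dct_bandstop(sim.ts.n_volumes, sim.ts.tr, cfg.band)
            wm = tissue_mean_signal(sim.ts, probs[1].reshape(cfg.grid_dims),
                                    cfg.nuisance_tissue_threshold, "WM")
            csf = tissue_mean_signal(sim.ts, probs[2].reshape(cfg.grid_dims),
                                     cfg.nuisance_tissue_threshold, "CSF")
            design = build_nuisance_design(sim.motion, wm, csf,
                                           sim.ts.n_volumes, dct)
            est = compute_rsfa(sim.ts, design, normalization="raw").ravel()
            recovered.append(est)
            corrs.append(float(np.corrcoef(est, target)[0, 1]))
        files = [write_map_stack(self.path("rsfa_from_bold.nii"),
                                 np.array(recovered), cfg.grid_dims)]
        self._record("rsfa", t0, files, recovery_correlations=corrs)

    def factors_stage(self) -> None:
        if self._done("cvh_scores.tsv", "cvh_solution.json"):
            logger.info("factors: artifacts present, skipping")
            return
        t0 = time.time()
        subjects = read_table(self.path("subjects.tsv"))
        cvh_raw = subjects[MEASURE_NAMES]
        cvh = normality_transform(cvh_raw)
        est = CardioHealthFactors(n_factors=self.config.n_factors).fit(cvh)
        scores = est.transform(cvh)
        df = pd.DataFrame(scores, columns=[f"CVH{i + 1}" for i in range(scores.shape[1])])
        df.insert(0, "subject_id", subjects["subject_id"])
        files = [write_table(self.path("cvh_scores.tsv"), df)]
        sidecar = {
            "transforms": cvh.transforms,
            "k": est.n_factors_,
            "rotation": est.rotation,
            "loadings": est.loadings_.tolist(),
            "uniquenesses": est.uniquenesses_.tolist(),
            "variables": est.variables_,
        }
        with open(self.path("cvh_solution.json"), "w") as fh:
            json.dump(sidecar, fh, indent=2)
        files.append(self.path("cvh_solution.json"))
        self._record("factors", t0, files, k=est.n_factors_)

    def ica_stage(self) -> None:
        names = [f"{m}_{s}" for m in MODALITIES
                 for s in ("ica_sources.nii", "ica_loadings.tsv", "ica.json")]
        if self._done(*names):
            logger.info("ica: artifacts present, skipping")
            return
        t0 = time.time()
        cfg = self.config
        files, orders = [], {}
        subjects = read_table(self.path("subjects.tsv"))
        for m in MODALITIES:
            X = read_map_stack(self.path(f"{m}_maps.nii"))
            est = GroupICA(n_components=cfg.ica_order,
                           random_state=cfg.seed).fit(X)
            orders[m] = est.order_
            files.append(write_map_stack(self.path(f"{m}_ica_sources.nii"),
                                         est.sources_, cfg.grid_dims))
            df = pd.DataFrame(
                est.loadings_z_,
                columns=[f"IC{i + 1}" for i in range(est.order_)],
            )
            df.insert(0, "subject_id", subjects["subject_id"])
            files.append(write_table(self.path(f"{m}_ica_loadings.tsv"), df))
            with open(self.path(f"{m}_ica.json"), "w") as fh:
                json.dump({"order": est.order_, "seed": cfg.seed,
                           "objective": est.objective_}, fh, indent=2)
            files.append(self.path(f"{m}_ica.json"))
        self._record("ica", t0, files, orders=orders)

    def _load_analysis_inputs(self):
        cfg = self.config
        subjects = read_table(self.path("subjects.tsv"))
        rsfa = read_map_stack(self.path("rsfa_maps.nii"))
        cbf = read_map_stack(self.path("cbf_maps.nii"))
        gmv = read_map_stack(self.path("gmv_maps.nii"))
        labels = read_map_stack(self.path("tissue_labels.nii"))[0].astype(int)
        scores = read_table(self.path("cvh_scores.tsv"))
        cvh = scores[[c for c in scores.columns if c.startswith("CVH")]].to_numpy()
        rsfa_map = MapMatrix(rsfa, "rsfa", cfg.grid_dims)
        covs = prepare_covariates(subjects, csf_signal=csf_mean_value(rsfa_map, labels))
        return subjects, rsfa, cbf, gmv, labels, cvh, covs

    def models_stage(self) -> None:
        if self._done("model_results.tsv"):
            logger.info("models: artifacts present, skipping")
            return
        t0 = time.time()
        cfg = self.config
        _, rsfa, cbf, gmv, labels, cvh, covs = self._load_analysis_inputs()
        specs = [ModelSpec.standard(i, robust=cfg.robust) for i in cfg.models]

        if cfg.level == "component":
            Y = read_table(self.path("rsfa_ica_loadings.tsv"))
            Y = Y[[c for c in Y.columns if c.startswith("IC")]].to_numpy()
            cbf_in = read_table(self.path("cbf_ica_loadings.tsv"))
            cbf_in = cbf_in[[c for c in cbf_in.columns if c.startswith("IC")]].to_numpy()
            gmv_in = read_table(self.path("gmv_ica_loadings.tsv"))
            gmv_in = gmv_in[[c for c in gmv_in.columns if c.startswith("IC")]].to_numpy()
        else:
            Y, cbf_in, gmv_in = rsfa, cbf, gmv

        results = run_model_suite(Y, specs, covs, cvh=cvh, cbf=cbf_in,
                                  gmv=gmv_in, q=cfg.q, level=cfg.level)
        rows = []
        files = []
        for mid, res in results.items():
            rows.append(res.summary())
            if cfg.level == "voxel":
                with np.errstate(divide="ignore"):
                    stack = np.vstack([res.r, -np.log10(np.maximum(res.p, 1e-300))])
                files.append(write_map_stack(
                    self.path(f"model_{mid}_maps.nii"), stack, cfg.grid_dims))
        files.insert(0, write_table(self.path("model_results.tsv"),
                                    pd.DataFrame(rows)))
        self._record("models", t0, files,
                     significant={mid: r.n_significant for mid, r in results.items()})

    def permtest_stage(self) -> None:
        if self._done("permtest_table.tsv", "permtest.json"):
            logger.info("permtest: artifacts present, skipping")
            return
        t0 = time.time()
        cfg = self.config
        _, rsfa, cbf, gmv, labels, cvh, covs = self._load_analysis_inputs()
        all_results, diagnostics = {}, {}
        for mid in cfg.permtest_models:
            spec = ModelSpec.standard(mid, robust=cfg.robust)
            per_tissue = run_tissue_variants(
                rsfa, spec, covs, P=cfg.permutations, seed=cfg.seed,
                alpha=cfg.alpha, tissue_labels=labels, cvh=cvh, cbf=cbf, gmv=gmv,
            )
            all_results[mid] = per_tissue
            diagnostics[mid] = {
                name: {"Np": r.np_count, "p_ratio": r.p_ratio,
                       "p_value": r.p_value, "median_p": r.median_p,
                       "shape_p": r.shape_p, "n_voxels": r.n_voxels,
                       "significant": bool(r.significant)}
                for name, r in per_tissue.items()
            }
        table = table_report(all_results).reset_index(names="model")
        files = [write_table(self.path("permtest_table.tsv"), table)]
        with open(self.path("permtest.json"), "w") as fh:
            json.dump(diagnostics, fh, indent=2)
        files.append(self.path("permtest.json"))
        self._record("permtest", t0, files)

    def run(self) -> dict:
        for stage in (self.simulate, self.rsfa_stage, self.factors_stage,
                      self.ica_stage, self.models_stage, self.permtest_stage):
            name = stage.__name__
            try:
                stage()
            except Exception:
                logger.error("pipeline aborted in stage %s; completed stages: %s",
                             name, list(self.manifest["stages"]))
                raise
        return self.manifest


def pipeline_run(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest."""
    return Pipeline(config).run()
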