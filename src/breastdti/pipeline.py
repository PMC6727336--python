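"""End-to-end pipeline: simulate -> features -> models -> validation -> report.

A single YAML/JSON config (validated with pydantic) drives all stages with
seeded reproducibility: rerunning an identical config produces byte-identical
numeric report content.  Stages write plain CSV/JSON intermediates so partial
runs can resume.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .exceptions import ConfigError
from .features import (
    CLINICAL_DCE_FEATURES,
    DTI_FEATURES,
    prepare_features,
    spearman_matrix,
)
from .gee import univariate_table
from .gradients import make_gradient_scheme
from .lasso import LassoSpec
from .roi import lesion_summary, refine_roi
from .simulate import (
    CohortConfig,
    PhantomConfig,
    PhantomRegion,
    simulate_cohort,
    simulate_dwi_phantom,
)
from .tensor import DiffusionTensorModel
from .validation import bootstrap_auc_diff, bootstrap_optimism_auc, roc_coordinates

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"

#: The three primary model specifications.
MODEL_FEATURES = {
    "clinical_dce": CLINICAL_DCE_FEATURES,
    "dti_only": DTI_FEATURES,
    "combined": CLINICAL_DCE_FEATURES + DTI_FEATURES,
}
_LOG_FEATURES = ("size_cm", "mean_fa")


class StageToggles(BaseModel):
    simulate: bool = True
    model: bool = True
    validate_: bool = Field(True, alias="validate")
    report: bool = True

    model_config = {"populate_by_name": True}


class LassoOptions(BaseModel):
    n_grid: int = 20
    cv: int | str = 10  # grouped K-fold; "lopo" for leave-one-patient-out
    reselect_penalty: bool = False  # fast mode for demo runs


class BootstrapOptions(BaseModel):
    B: int = 100


class RunConfig(BaseModel):
    """Validated pipeline configuration."""

    seed: int = 0
    out_dir: str = "breastdti_run"
    n_patients: int = 200
    stages: StageToggles = Field(default_factory=StageToggles)
    imaging_demo: bool = True
    lasso: LassoOptions = Field(default_factory=LassoOptions)
    bootstrap: BootstrapOptions = Field(default_factory=BootstrapOptions)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        try:
            return cls.model_validate(payload)
        except Exception as exc:  # pydantic ValidationError
            raise ConfigError(f"invalid pipeline config {path}: {exc}") from exc

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(by_alias=True), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Paths of the artifacts a pipeline run produced."""

    cohort: Path | None = None
    univariate: Path | None = None
    multivariate: Path | None = None
    validation: Path | None = None
    roc_curves: dict[str, Path] | None = None
    manifest: Path | None = None
    imaging_demo: Path | None = None


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, float_format=_FLOAT_FMT)
    return path


def stage_simulate(config: RunConfig, out: Path) -> Path:
    cohort, truth = simulate_cohort(
        CohortConfig(n_patients=config.n_patients, seed=config.seed)
    )
    path = out / "cohort.csv"
    cohort.to_csv(path, index=False, float_format=_FLOAT_FMT)
    if config.imaging_demo:
        _imaging_demo(config, out)
    return path


def _imaging_demo(config: RunConfig, out: Path) -> Path:
    """Run one phantom lesion through the full imaging path (fit -> ROI -> features)."""
    scheme = make_gradient_scheme()
    pconf = PhantomConfig(
        grid_shape=(10, 10, 3),
        regions=(
            PhantomRegion(
                slices=((3, 7), (3, 7), (1, 2)),
                evals=(2.2e-3, 2.0e-3, 1.8e-3),
            ),
        ),
        noise_sigma=0.0,
        seed=config.seed,
    )
    dwi, truth = simulate_dwi_phantom(pconf, scheme)
    res = DiffusionTensorModel(dwi).fit()
    combined = res.combined_dwi(800.0)
    seed_vox = np.argwhere(truth.labels == "lesion")
    roi = refine_roi(combined, seed_vox, threshold_fraction=0.5)
    feats = lesion_summary(res.scalar_maps, roi)
    path = out / "imaging_demo.json"
    path.write_text(json.dumps(feats.as_dict(), indent=2, sort_keys=True))
    return path


def stage_model(config: RunConfig, out: Path) -> tuple[Path, Path]:
    cohort = pd.read_csv(out / "cohort.csv")
    fm = prepare_features(cohort)
    uni = univariate_table(fm)
    uni_path = _write_csv(uni, out / "univariate.csv")
    _write_csv(spearman_matrix(
        cohort[["mean_adc", "mean_fa", "mean_axial", "mean_radial",
                "mean_lambda_diff"]]
    ), out / "spearman_dti.csv")

    rows = {}
    for name, feats in MODEL_FEATURES.items():
        spec = _lasso_spec(config, feats)
        fit = spec.fit(cohort)
        ors = fit.results.odds_ratios
        rows[name] = {
            f: (float(ors[f]) if f in fit.results.selected else np.nan)
            for f in feats
        }
    multi = pd.DataFrame(rows)
    multi_path = _write_csv(multi, out / "multivariate.csv")
    return uni_path, multi_path


def _lasso_spec(config: RunConfig, features) -> LassoSpec:
    log_feats = tuple(f for f in _LOG_FEATURES if f in features)
    return LassoSpec(
        features,
        log_features=log_feats,
        n_grid=config.lasso.n_grid,
        cv=config.lasso.cv,
        reselect_penalty=config.lasso.reselect_penalty,
    )


def stage_validate(config: RunConfig, out: Path) -> tuple[Path, dict[str, Path]]:
    cohort = pd.read_csv(out / "cohort.csv")
    B = config.bootstrap.B
    rows = []
    roc_paths = {}
    specs = {}
    for name, feats in MODEL_FEATURES.items():
        spec = _lasso_spec(config, feats)
        specs[name] = spec
        est = bootstrap_optimism_auc(spec, cohort, B=B, seed=config.seed)
        rows.append(
            {
                "model": name,
                "apparent_auc": est.apparent,
                "adjusted_auc": est.adjusted,
                "ci_low": est.ci[0],
                "ci_high": est.ci[1],
                "B": est.B,
            }
        )
        scores = spec.fit(cohort).predict_scores(cohort)
        roc = roc_coordinates(scores, cohort["malignant"].to_numpy())
        roc_paths[name] = _write_csv(roc, out / f"roc_{name}.csv")
    for a, b in (("combined", "clinical_dce"), ("combined", "dti_only")):
        diff = bootstrap_auc_diff(specs[a], specs[b], cohort, B=B, seed=config.seed)
        rows.append(
            {
                "model": f"{a}_minus_{b}",
                "apparent_auc": diff.delta,
                "adjusted_auc": np.nan,
                "ci_low": diff.ci[0],
                "ci_high": diff.ci[1],
                "B": diff.B,
                "p": diff.p,
            }
        )
    val = pd.DataFrame(rows).set_index("model")
    return _write_csv(val, out / "validation.csv"), roc_paths


def stage_report(config: RunConfig, out: Path) -> Path:
    manifest = {
        "package": "breastdti",
        "version": __version__,
        "seed": config.seed,
        "config": config.model_dump(by_alias=True),
        "config_hash": config.config_hash(),
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the enabled stages in order and return the artifact paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle()
    t0 = time.time()
    if config.stages.simulate:
        logger.info("stage=simulate seed=%d", config.seed)
        bundle.cohort = stage_simulate(config, out)
        if config.imaging_demo:
            bundle.imaging_demo = out / "imaging_demo.json"
    if config.stages.model:
        if not (out / "cohort.csv").exists():
            raise ConfigError("model stage requires cohort.csv (run simulate first)")
        logger.info("stage=model")
        bundle.univariate, bundle.multivariate = stage_model(config, out)
    if config.stages.validate_:
        if not (out / "cohort.csv").exists():
            raise ConfigError("validate stage requires cohort.csv")
        logger.info("stage=validate B=%d", config.bootstrap.B)
        bundle.validation, bundle.roc_curves = stage_validate(config, out)
    if config.stages.report:
        bundle.manifest = stage_report(config, out)
    logger.info("pipeline done in %.1fs", time.time() - t0)
    return bundle
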