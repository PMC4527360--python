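"""End-to-end orchestration of the two-level terroir analysis.

Level 1 fits an oCPLS2-DA model of macrozone membership with vintage as the
constraint, selects the component count at the first maximum of 7-fold Q2
under the permutation-test constraint, post-transforms the model and
extracts markers. Level 2 repeats the same protocol within each macrozone
with vineyard as the class. The identical path runs on a (log-scale) gene
expression matrix, restricted to the configured stages — the pipeline is
matrix-agnostic.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    FeatureAnnotation,
    FeatureTable,
    StudyDesign,
    build_constraint_block,
    dummy_code,
    write_model_tables,
)
from .markers import correlation_loadings, extract_markers
from .posttransform import post_transform
from .preprocess import Preprocessor
from .validation import ModelRecipe, validate_model

logger = logging.getLogger("terroirpls")

__all__ = ["PipelineConfig", "LevelResult", "run_two_level_analysis",
           "run_transcript_analysis"]


@dataclass
class PipelineConfig:
    """Everything one run needs; every default is echoed into the run log."""

    class_factor: str = "macrozone"
    constraint_factor: str = "vintage"
    level2_factor: str = "vineyard"
    preprocess: tuple = ("mfc", "log")  # centering is appended per fold
    max_components: int = 4
    folds: tuple = (6, 7, 8)
    n_perm: int = 400
    marker_threshold: float = 0.5
    seed: int = 0
    out_dir: str | None = None
    stages: tuple | None = None  # restrict to these developmental stages

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("preprocess", "folds", "stages"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class LevelResult:
    name: str
    report: object  # ValidationReport
    model: object | None = None
    posttransformed: object | None = None
    markers: pd.DataFrame | None = None


def _check_factors(config: PipelineConfig, design: StudyDesign) -> None:
    for fac in (config.class_factor, config.constraint_factor,
                config.level2_factor):
        if fac not in design.table.columns:
            raise ValueError(f"config names missing design factor {fac!r}")


def _run_one_level(
    name: str,
    X_raw: np.ndarray,
    labels: np.ndarray,
    constraint_labels: np.ndarray,
    feature_ids: list,
    config: PipelineConfig,
    out_dir: Path | None,
) -> LevelResult:
    recipe = ModelRecipe(
        method="ocpls2da",
        preprocess=tuple(config.preprocess),
        constraint=constraint_labels,
    )
    report = validate_model(
        recipe,
        X_raw,
        labels,
        max_A=config.max_components,
        schemes=tuple(config.folds),
        n_perm=config.n_perm,
        seed=config.seed,
    )
    logger.info("[%s] status=%s selected_A=%s q2=%s", name, report.status,
                report.selected_A,
                {k: round(v, 3) for k, v in report.q2_by_scheme.items()})
    result = LevelResult(name, report)
    if report.selected_A is None:
        return result
    classes = list(pd.unique(labels))
    prep, model = recipe.fit(
        X_raw, labels, report.selected_A, classes,
        constraint_train=constraint_labels,
    )
    Xp = prep.X_fitted_
    Y = dummy_code(labels, config.class_factor)
    pt = post_transform(model, Y)
    loads = correlation_loadings(pt, Xp, Y, feature_ids=feature_ids)
    marks = extract_markers(loads, threshold=config.marker_threshold)
    result.model = model
    result.posttransformed = pt
    result.markers = marks
    if out_dir is not None:
        level_dir = out_dir / name
        level_dir.mkdir(parents=True, exist_ok=True)
        model.feature_ids = list(feature_ids)
        write_model_tables(model, level_dir)
        pd.DataFrame(
            pt.T_pred,
            columns=[f"tpred{a + 1}" for a in range(pt.T_pred.shape[1])],
        ).to_csv(level_dir / "scores_predictive.csv", index=False)
        loads.p_corr.to_csv(level_dir / "correlation_loadings_p.csv")
        loads.q_corr.to_csv(level_dir / "correlation_loadings_q.csv")
        marks.to_csv(level_dir / "markers.csv")
        with open(level_dir / "validation.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
    return result


def run_two_level_analysis(
    config: PipelineConfig,
    table: FeatureTable,
    design: StudyDesign,
    annotation: FeatureAnnotation | None = None,
) -> dict:
    """Run the macrozone model, then per-macrozone vineyard models.

    Returns a bundle mapping level name -> :class:`LevelResult`; writes all
    model tables and a run log when ``config.out_dir`` is set.
    """
    _check_factors(config, design)
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "run_config.json", "w") as fh:
            json.dump(
                {
                    **{k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(config).items()},
                    "timestamp": datetime.datetime.now().isoformat(),
                    "n_samples": table.shape[0],
                    "n_features": table.shape[1],
                },
                fh,
                indent=2,
            )
    if config.stages is not None:
        keep = np.isin(design.factor("stage"), config.stages)
        table = FeatureTable(table.data.loc[keep], table.state)
        design = design.subset(keep)
    X_raw = table.values
    labels = design.factor(config.class_factor)
    constraint = design.factor(config.constraint_factor)
    bundle: dict[str, LevelResult] = {}
    bundle["level1_" + config.class_factor] = _run_one_level(
        "level1_" + config.class_factor,
        X_raw,
        labels,
        constraint,
        table.features,
        config,
        out_dir,
    )
    for zone in pd.unique(labels):
        sel = labels == zone
        sub_labels = design.factor(config.level2_factor)[sel]
        if len(pd.unique(sub_labels)) < 2:
            logger.info("[level2_%s] single %s; skipped", zone,
                        config.level2_factor)
            continue
        bundle[f"level2_{zone}"] = _run_one_level(
            f"level2_{zone}",
            X_raw[sel],
            sub_labels,
            constraint[sel],
            table.features,
            config,
            out_dir,
        )
    return bundle


def run_transcript_analysis(
    config: PipelineConfig,
    gene_table: FeatureTable,
    design: StudyDesign,
) -> dict:
    """Run the level-1 protocol on a log-scale gene expression matrix.

    Expression matrices arrive already log-transformed, so the default
    preprocessing reduces to per-fold centering unless the config says
    otherwise; stage restriction (e.g. mid-ripening + fully mature) comes
    from ``config.stages``.
    """
    _check_factors(config, design)
    if config.stages is not None:
        keep = np.isin(design.factor("stage"), config.stages)
        gene_table = FeatureTable(gene_table.data.loc[keep], gene_table.state)
        design = design.subset(keep)
    out_dir = Path(config.out_dir) if config.out_dir else None
    result = _run_one_level(
        "transcripts_" + config.class_factor,
        gene_table.values,
        design.factor(config.class_factor),
        design.factor(config.constraint_factor),
        gene_table.features,
        PipelineConfig(**{**asdict(config), "preprocess": tuple(config.preprocess)}),
        out_dir,
    )
    return {"transcripts": result}
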