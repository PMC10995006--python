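"""End-to-end orchestration: simulate -> features -> classify -> lesion -> compare.

A single master seed fans out into named substreams (cohort synthesis,
shuffle permutations) so each stage is reproducible in isolation, and two
runs with the same config and seed produce byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from ._seeds import child_seed
from .classifiers import ModelSpec
from .comparestats import ComparisonResult, rank_and_group, shapiro_normality, wilcoxon_signed
from .evaluation import (
    BaselineResult,
    CVResult,
    lopo_partition,
    pooled_accuracy_ci,
    run_cv,
    shuffle_baseline,
)
from .lesion import band_scheme, region_scheme, run_lesion_experiment
from .spectra import build_feature_table, feature_columns
from .synthgen import CohortConfig, EffectProfile, generate_cohort

logger = logging.getLogger(__name__)

BINARY_CONDITIONS = (0, 40)
MULTICLASS_CONDITIONS = (0, 20, 30, 40)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full experiment run."""

    task: str = "binary"  # "binary" | "multiclass"
    seed: int = 0
    shuffle_iters: int = 100
    lesion_axes: Tuple[str, ...] = ("band", "region")
    n_participants: int = 12
    n_epochs: int = 30
    fs: float = 256.0
    epoch_s: float = 2.0
    profile_overrides: Dict = field(default_factory=dict)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.task not in ("binary", "multiclass"):
            raise ValueError("task must be 'binary' or 'multiclass'")
        bad = [a for a in self.lesion_axes if a not in ("band", "region")]
        if bad:
            raise ValueError(f"unknown lesion axes {bad}")

    @property
    def conditions(self) -> Tuple[int, ...]:
        return BINARY_CONDITIONS if self.task == "binary" else MULTICLASS_CONDITIONS

    @property
    def model_spec(self) -> ModelSpec:
        return ModelSpec("binary-svm" if self.task == "binary" else "ovo-svm")

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n_participants=self.n_participants,
            conditions=self.conditions,
            fs=self.fs,
            epoch_s=self.epoch_s,
            n_epochs=self.n_epochs,
            seed=child_seed(self.seed, "cohort"),
        )

    def effect_profile(self) -> EffectProfile:
        return EffectProfile(**self.profile_overrides)

    def to_dict(self) -> Dict:
        d = asdict(self)
        d["lesion_axes"] = list(self.lesion_axes)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "lesion_axes" in raw:
            raw["lesion_axes"] = tuple(raw["lesion_axes"])
        return cls(**raw)


@dataclass
class ReportBundle:
    """Everything a run produced, ready for write_report."""

    config: RunConfig
    features: Optional[pd.DataFrame] = None
    cv: Optional[CVResult] = None
    accuracy_ci: Optional[Tuple[float, float, float]] = None
    baseline: Optional[BaselineResult] = None
    wilcoxon: Optional[Tuple[float, float]] = None
    shapiro: Optional[Tuple[float, float]] = None
    matrices: Dict[str, pd.DataFrame] = field(default_factory=dict)
    comparisons: Dict[str, ComparisonResult] = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute every stage of the experiment under one master seed.

    Simulates a cohort, extracts the band x channel feature table, runs
    leave-one-participant-out CV of the task's SVM with its shuffle
    baseline and Wilcoxon contrast, then each requested lesioning axis
    with its Friedman/Nemenyi comparison.
    """
    bundle = ReportBundle(config=config)
    stage = "simulate"
    try:
        recordings = generate_cohort(config.cohort_config(), config.effect_profile())
        logger.info("simulate: %d recordings", len(recordings))

        stage = "features"
        bundle.features = build_feature_table(recordings)
        logger.info(
            "features: %d rows x %d features",
            len(bundle.features),
            len(feature_columns(bundle.features)),
        )

        stage = "classify"
        partition = lopo_partition(bundle.features)
        shuffle_seed = child_seed(config.seed, "shuffle")
        bundle.cv = run_cv(bundle.features, config.model_spec, partition)
        bundle.accuracy_ci = pooled_accuracy_ci(bundle.cv, alpha=config.alpha)
        bundle.baseline = shuffle_baseline(
            bundle.features,
            config.model_spec,
            partition,
            n_iterations=config.shuffle_iters,
            seed=shuffle_seed,
        )
        diffs = bundle.cv.accuracies - bundle.baseline.per_fold_mean
        if len(diffs) >= 5:  # signed-rank test needs at least 5 pairs
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bundle.shapiro = shapiro_normality(diffs)
                bundle.wilcoxon = wilcoxon_signed(
                    bundle.cv.accuracies, bundle.baseline.per_fold_mean
                )
        else:
            logger.info("fewer than 5 folds; Wilcoxon/Shapiro contrast skipped")
        logger.info(
            "classify: accuracy %.3f, baseline %.3f",
            bundle.cv.mean_accuracy,
            bundle.baseline.grand_mean,
        )

        stage = "lesion/compare"
        cols = feature_columns(bundle.features)
        for axis in config.lesion_axes:
            scheme = (
                band_scheme(cols)
                if axis == "band"
                else region_scheme(cols, config.effect_profile().region_map)
            )
            matrix = run_lesion_experiment(
                bundle.features,
                scheme,
                config.model_spec,
                partition,
                shuffle_iters=config.shuffle_iters,
                seed=shuffle_seed,
            )
            bundle.matrices[axis] = matrix
            bundle.comparisons[axis] = rank_and_group(matrix, alpha=config.alpha)
            logger.info("lesion[%s]: matrix %s", axis, matrix.shape)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return bundle


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str, index: bool) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=index)


def write_report(bundle: ReportBundle, directory) -> List[str]:
    """Write the report bundle with stable file names; returns files written.

    File set for a full run: features.csv, confusion_<task>.csv,
    acc_matrix_<axis>.csv and comparison_<axis>.json per axis,
    baseline.json, run.log. Existing files are overwritten with a warning
    in the log. Every output carries the config hash in its header.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config
    h = cfg.config_hash
    written: List[str] = []
    overwritten: List[str] = []

    def target(name: str) -> Path:
        p = directory / name
        if p.exists():
            overwritten.append(name)
        written.append(name)
        return p

    if bundle.features is not None:
        _write_csv(bundle.features, target("features.csv"), h, index=False)
    if bundle.cv is not None:
        _write_csv(
            bundle.cv.aggregate_confusion.rename_axis("true_condition"),
            target(f"confusion_{cfg.task}.csv"),
            h,
            index=True,
        )
    for axis, matrix in bundle.matrices.items():
        _write_csv(matrix, target(f"acc_matrix_{axis}.csv"), h, index=True)
    for axis, comparison in bundle.comparisons.items():
        payload = {"config_hash": h, "axis": axis, **comparison.to_dict()}
        target(f"comparison_{axis}.json").write_text(json.dumps(payload, indent=2))
    if bundle.baseline is not None:
        payload = {"config_hash": h, **bundle.baseline.to_dict()}
        if bundle.cv is not None:
            mean, lo, hi = bundle.accuracy_ci
            payload["model_accuracy"] = {
                "mean": mean,
                "ci_low": lo,
                "ci_high": hi,
                "alpha": cfg.alpha,
            }
        if bundle.wilcoxon is not None:
            payload["wilcoxon_vs_baseline"] = {
                "statistic": bundle.wilcoxon[0],
                "p_value": bundle.wilcoxon[1],
            }
        if bundle.shapiro is not None:
            payload["shapiro_normality"] = {
                "W": bundle.shapiro[0],
                "p_value": bundle.shapiro[1],
            }
        target("baseline.json").write_text(json.dumps(payload, indent=2))

    lines = [
        f"config_hash={h}",
        f"seed={cfg.seed}",
        f"task={cfg.task}",
        f"numpy={np.__version__}",
        f"pandas={pd.__version__}",
        f"config={json.dumps(cfg.to_dict(), sort_keys=True)}",
        f"files={','.join(n for n in written)}",
    ]
    if overwritten:
        lines.append(f"overwritten={','.join(overwritten)}")
        logger.warning("overwrote existing report files: %s", overwritten)
    run_log = directory / "run.log"
    if run_log.exists():
        overwritten.append("run.log")
    run_log.write_text("\n".join(lines) + "\n")
    written.append("run.log")
    return written
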