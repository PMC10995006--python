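"""Feature lesioning over frequency bands and scalp regions.

For each group g on an axis (band or region) two lesioned feature sets are
built: "only-g" (just g's columns) and "without-g" (everything else). All
lesioned models, the complete model and the shuffle baseline are evaluated
with identical folds and seed discipline, yielding the folds x 10 accuracy
matrix that feeds the rank-based model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

import pandas as pd

from .classifiers import ModelSpec
from .evaluation import FoldPartition, lopo_partition, run_cv, shuffle_baseline
from .spectra import DEFAULT_BANDS, ID_COLUMNS, feature_columns


@dataclass(frozen=True)
class LesionScheme:
    """Named feature-column groups along one axis (band or region)."""

    axis: str  # "band" | "region"
    groups: tuple  # ((name, (columns,...)), ...) in fixed order

    def __post_init__(self) -> None:
        if self.axis not in ("band", "region"):
            raise ValueError("axis must be 'band' or 'region'")

    @property
    def group_names(self) -> List[str]:
        return [name for name, _ in self.groups]

    def columns_of(self, name: str) -> List[str]:
        for g, cols in self.groups:
            if g == name:
                return list(cols)
        raise KeyError(name)

    def validate_against(self, table: pd.DataFrame) -> None:
        cols = feature_columns(table)
        grouped = [c for _, gc in self.groups for c in gc]
        if sorted(grouped) != sorted(cols) or len(grouped) != len(set(grouped)):
            raise ValueError(
                f"{self.axis} groups do not partition the table's feature columns"
            )


def band_scheme(feature_cols: Sequence[str], band_names: Sequence[str] | None = None) -> LesionScheme:
    """Group band:channel columns by their band prefix."""
    if band_names is None:
        band_names = [b.name for b in DEFAULT_BANDS]
    groups = []
    for band in band_names:
        cols = tuple(c for c in feature_cols if c.split(":", 1)[0] == band)
        if not cols:
            raise ValueError(f"no feature columns for band {band!r}")
        groups.append((band, cols))
    return LesionScheme(axis="band", groups=tuple(groups))


def region_scheme(
    feature_cols: Sequence[str], region_map: Mapping[str, str]
) -> LesionScheme:
    """Group band:channel columns by the region of their channel suffix.

    Region lesioning removes (or keeps) all four bands of a region's
    channels at once.
    """
    regions: Dict[str, List[str]] = {}
    for c in feature_cols:
        channel = c.split(":", 1)[1]
        if channel not in region_map:
            raise KeyError(f"channel {channel!r} has no region assignment")
        regions.setdefault(region_map[channel], []).append(c)
    order = ("frontal", "lateral", "central", "occipital")
    groups = tuple(
        (r, tuple(regions[r])) for r in order if r in regions
    ) + tuple((r, tuple(cols)) for r, cols in regions.items() if r not in order)
    return LesionScheme(axis="region", groups=groups)


def make_lesioned_sets(
    feature_table: pd.DataFrame, scheme: LesionScheme
) -> Dict[str, pd.DataFrame]:
    """Named lesioned tables: only-g and without-g for every group g.

    Rows and labels are untouched; only feature columns change. only-g and
    without-g are complementary column sets for each g.
    """
    scheme.validate_against(feature_table)
    cols = feature_columns(feature_table)
    out: Dict[str, pd.DataFrame] = {}
    for name, gcols in scheme.groups:
        keep_only = [c for c in cols if c in set(gcols)]
        keep_without = [c for c in cols if c not in set(gcols)]
        if not keep_only or not keep_without:
            raise ValueError(f"lesioned table for group {name!r} would be empty")
        out[f"only-{name}"] = feature_table[list(ID_COLUMNS) + keep_only].copy()
        out[f"without-{name}"] = feature_table[list(ID_COLUMNS) + keep_without].copy()
    return out


def model_order(scheme: LesionScheme) -> List[str]:
    """Fixed column order of the accuracy matrix: complete, shuffle, then
    only-g/without-g pairs in group order."""
    names = ["complete", "shuffle"]
    for g in scheme.group_names:
        names.extend([f"only-{g}", f"without-{g}"])
    return names


def run_lesion_experiment(
    feature_table: pd.DataFrame,
    scheme: LesionScheme,
    model_spec: ModelSpec,
    partition: FoldPartition | None = None,
    shuffle_iters: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Folds x models accuracy matrix for the 10-model comparison.

    Evaluates the complete model, the shuffle baseline (per-fold
    iteration-mean accuracies, so it enters paired rank comparisons as one
    model), and the 8 lesioned variants, all with identical folds and the
    same seed discipline. Rows are fold test participants; columns follow
    ``model_order``.
    """
    if partition is None:
        partition = lopo_partition(feature_table)
    fold_ids = [fold[1] for fold in partition]
    matrix = pd.DataFrame(index=fold_ids, columns=model_order(scheme), dtype=float)
    matrix.index.name = "fold_participant"

    matrix["complete"] = run_cv(feature_table, model_spec, partition).accuracies
    baseline = shuffle_baseline(
        feature_table, model_spec, partition, n_iterations=shuffle_iters, seed=seed
    )
    matrix["shuffle"] = baseline.per_fold_mean
    for name, lesioned in make_lesioned_sets(feature_table, scheme).items():
        matrix[name] = run_cv(lesioned, model_spec, partition).accuracies
    return matrix
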