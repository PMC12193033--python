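"""Flat feature tables: reading, writing, splitting, normalisation.

The exchange object everywhere in this package is the
:class:`FeatureTable` — an ``n x 9`` numeric matrix of sensor channels
plus one integer exercise label per row.  Files are plain delimited text
with a header; a leading time-index column (which carries no information
about the performed exercise) is dropped on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler

#: Channel order of the wearable unit: tri-axial accelerometer,
#: gyroscope, magnetometer.
DEFAULT_FEATURE_NAMES = (
    "acc_x", "acc_y", "acc_z",
    "gyr_x", "gyr_y", "gyr_z",
    "mag_x", "mag_y", "mag_z",
)

#: Fixed label vocabulary: exercise name for class indices 0..7.
EXERCISE_NAMES = (
    "extended leg raises",
    "forward bending",
    "straight lying-leg raises",
    "side-lying hip abduction",
    "alternating leg lifts prone",
    "elbow flexion",
    "shoulder abduction",
    "prone lying elbow extension",
)

LABEL_COLUMN = "label"
N_FEATURES = 9


class LabelVocabulary:
    """Bidirectional map between exercise names and class indices 0..7."""

    names: tuple[str, ...] = EXERCISE_NAMES

    @classmethod
    def to_index(cls, name: str) -> int:
        try:
            return cls.names.index(name.strip().lower())
        except ValueError:
            raise KeyError(f"unknown exercise name: {name!r}") from None

    @classmethod
    def to_name(cls, index: int) -> str:
        if not 0 <= index < len(cls.names):
            raise IndexError(f"class index {index} out of range 0..{len(cls.names) - 1}")
        return cls.names[index]


@dataclass
class FeatureTable:
    """n x 9 sensor matrix plus per-row class labels."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(
        default_factory=lambda: list(DEFAULT_FEATURE_NAMES)
    )

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"features has {self.features.shape[0]} rows but labels has "
                f"{self.labels.shape[0]} entries"
            )
        if self.features.shape[1] != len(self.feature_names):
            raise ValueError(
                f"features has {self.features.shape[1]} columns but "
                f"{len(self.feature_names)} feature names were given"
            )
        if self.features.size and not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be nonnegative class indices")

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if len(self) else 0

    def class_counts(self, n_classes: int | None = None) -> np.ndarray:
        k = n_classes if n_classes is not None else self.n_classes
        return np.bincount(self.labels, minlength=k)

    def take(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            features=self.features[idx],
            labels=self.labels[idx],
            feature_names=list(self.feature_names),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df[LABEL_COLUMN] = self.labels
        return df


@dataclass
class SplitResult:
    """An 80/20-style train/test partition of a table."""

    train: FeatureTable
    test: FeatureTable
    test_fraction: float
    seed: int
    stratified: bool


def _is_time_column(name: str) -> bool:
    return name.strip().lower() in {"time", "time index", "time_index", "timeindex"}


def read_feature_table(
    path,
    delimiter: str = ",",
    has_time_index: bool | None = None,
) -> FeatureTable:
    """Read a delimited feature table, dropping any time-index column.

    The file must have a header; the label column is named ``label`` (or
    is the last column).  ``has_time_index=None`` auto-detects a leading
    column named "time"/"time index" (case-insensitive); pass True/False
    to force.  Labels may be integer class indices or exercise names
    resolved through :class:`LabelVocabulary`; unknown names are errors.
    """
    df = pd.read_csv(path, sep=delimiter)
    cols = list(df.columns)
    if has_time_index is True:
        df = df.drop(columns=cols[0])
    elif has_time_index is None and cols and _is_time_column(cols[0]):
        df = df.drop(columns=cols[0])

    if LABEL_COLUMN in df.columns:
        label_series = df[LABEL_COLUMN]
        feat_df = df.drop(columns=[LABEL_COLUMN])
    else:
        label_series = df.iloc[:, -1]
        feat_df = df.iloc[:, :-1]

    if feat_df.shape[1] != N_FEATURES:
        raise ValueError(
            f"expected {N_FEATURES} feature columns, found {feat_df.shape[1]} "
            f"({list(feat_df.columns)})"
        )

    features = np.empty(feat_df.shape, dtype=float)
    for j, col in enumerate(feat_df.columns):
        values = pd.to_numeric(feat_df[col], errors="coerce")
        bad = values.isna() & feat_df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric value in column {col!r}, row {row}: "
                f"{feat_df[col].iloc[row]!r}"
            )
        if values.isna().any():
            row = int(np.flatnonzero(values.isna())[0])
            raise ValueError(f"missing value in column {col!r}, row {row}")
        features[:, j] = values.to_numpy(dtype=float)

    if len(label_series) and label_series.dtype == object:
        labels = np.array([LabelVocabulary.to_index(v) for v in label_series])
    else:
        labels = label_series.to_numpy(dtype=int) if len(label_series) else np.array([], dtype=int)

    return FeatureTable(
        features=features,
        labels=labels,
        feature_names=[str(c) for c in feat_df.columns],
    )


def write_feature_table(table: FeatureTable, path, delimiter: str = ",") -> None:
    """Write header + rows as delimited text, keeping >= 12 significant digits."""
    df = table.to_frame()
    df.to_csv(path, sep=delimiter, index=False, float_format="%.12g")


def stratified_split(
    table: FeatureTable,
    test_fraction: float = 0.2,
    seed: int = 0,
    stratified: bool = True,
) -> SplitResult:
    """Partition rows into train/test with largest-remainder class counts.

    The total test size is ``round(n * test_fraction)``.  Under
    stratification it is apportioned over classes by the largest-remainder
    method on the per-class quotas ``count_k * test_fraction``, so each
    class's test count differs from its exact quota by less than 1.
    Deterministic given ``seed``.
    """
    if not 0 <= test_fraction < 1:
        raise ValueError("test_fraction must be in [0, 1)")
    n = len(table)
    rng = np.random.default_rng(seed)
    n_test = int(np.floor(n * test_fraction + 0.5))

    if not stratified or n_test == 0:
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
    else:
        k = table.n_classes
        counts = table.class_counts(k)
        if np.any(counts == 0):
            empty = int(np.flatnonzero(counts == 0)[0])
            raise ValueError(
                f"stratified split requires at least one row per class; "
                f"class {empty} has none"
            )
        quota = counts * test_fraction
        per_class = np.floor(quota).astype(int)
        short = n_test - per_class.sum()
        order = np.argsort(-(quota - np.floor(quota)), kind="stable")
        per_class[order[:short]] += 1
        test_parts, train_parts = [], []
        for c in range(k):
            idx = np.flatnonzero(table.labels == c)
            idx = rng.permutation(idx)
            test_parts.append(idx[: per_class[c]])
            train_parts.append(idx[per_class[c]:])
        test_idx = np.concatenate(test_parts)
        train_idx = np.concatenate(train_parts)
        # shuffle so downstream consumers never see class-blocked order
        test_idx = rng.permutation(test_idx)
        train_idx = rng.permutation(train_idx)

    return SplitResult(
        train=table.take(train_idx),
        test=table.take(test_idx),
        test_fraction=test_fraction,
        seed=seed,
        stratified=stratified,
    )


class TrainOnlyStandardizer:
    """Per-feature z-scoring with moments estimated on the training
    partition only, then applied to any partition — the leakage-safe
    normalisation convention."""

    def __init__(self) -> None:
        self._scaler = StandardScaler()

    def fit(self, train: FeatureTable) -> "TrainOnlyStandardizer":
        self._scaler.fit(train.features)
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        return FeatureTable(
            features=self._scaler.transform(table.features),
            labels=table.labels,
            feature_names=list(table.feature_names),
        )

    def fit_transform(self, train: FeatureTable) -> FeatureTable:
        return self.fit(train).transform(train)
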