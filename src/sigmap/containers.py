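"""Core in-memory containers shared across the pipeline.

Expression data travels as a features x samples :class:`pandas.DataFrame`
wrapped in :class:`ExpressionMatrix`, which also records the scale the
values live on (log2 intensities for microarray-like data, raw counts for
RNA-seq-like data).  A :class:`ReferenceCompendium` additionally carries a
per-sample metadata table with a cell-state/treatment ``group`` label and a
``dataset`` of origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_SCALES = ("log2", "count")


class ValidationError(ValueError):
    """Raised when an input violates a declared contract."""


@dataclass
class ExpressionMatrix:
    """A features x samples numeric matrix with a declared value scale.

    Parameters
    ----------
    values:
        DataFrame indexed by feature ID with one column per sample.
    scale:
        ``"log2"`` for log2 intensities, ``"count"`` for raw counts.
    """

    values: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValidationError(
                f"scale must be one of {VALID_SCALES}, got {self.scale!r}"
            )
        if not isinstance(self.values, pd.DataFrame):
            raise ValidationError("values must be a pandas DataFrame")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature IDs: {dups[:10]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups[:10]}")

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def linear(self) -> pd.DataFrame:
        """Values on linear scale (exponentiates log2 input)."""
        if self.scale == "log2":
            return np.exp2(self.values)
        return self.values

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], scale=self.scale)


@dataclass
class ReferenceCompendium:
    """An :class:`ExpressionMatrix` whose samples carry group/dataset labels."""

    expr: ExpressionMatrix
    sample_meta: pd.DataFrame  # index: sample_id; columns: group, dataset

    def __post_init__(self) -> None:
        meta = self.sample_meta
        missing_cols = {"group", "dataset"} - set(meta.columns)
        if missing_cols:
            raise ValidationError(f"sample_meta missing columns: {sorted(missing_cols)}")
        if not meta.index.equals(self.expr.samples):
            if set(meta.index) != set(self.expr.samples):
                raise ValidationError("sample_meta index does not match matrix samples")
            # reorder to match the matrix column order
            self.sample_meta = meta.loc[self.expr.samples]

    @property
    def groups(self) -> pd.Series:
        """Sample -> group label, aligned to the matrix column order."""
        return self.sample_meta["group"]

    @property
    def group_labels(self) -> list[str]:
        """Group labels in first-appearance order."""
        return list(dict.fromkeys(self.sample_meta["group"]))


SIGNATURE_COLUMNS = ["feature_id", "direction", "score", "p", "p_adj", "fold_change"]


@dataclass
class Signature:
    """Up/down feature lists for one two-group contrast.

    ``table`` has one row per signature feature with its direction
    (``"up"``/``"down"``), the test statistic, raw and adjusted p, and the
    linear-scale fold change of group means (group A over group B).
    """

    contrast: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(SIGNATURE_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValidationError(f"signature table missing columns: {sorted(missing)}")
        if self.table["feature_id"].duplicated().any():
            raise ValidationError("signature features must be unique")
        bad = ~self.table["direction"].isin(["up", "down"])
        if bad.any():
            raise ValidationError("direction must be 'up' or 'down'")
        lfc = np.log2(self.table["fold_change"].to_numpy(float))
        want_up = lfc > 0
        is_up = (self.table["direction"] == "up").to_numpy()
        if np.any(want_up != is_up):
            raise ValidationError("direction inconsistent with sign of log2 fold change")

    @property
    def up(self) -> list[str]:
        return self.table.loc[self.table["direction"] == "up", "feature_id"].tolist()

    @property
    def down(self) -> list[str]:
        return self.table.loc[self.table["direction"] == "down", "feature_id"].tolist()

    @property
    def features(self) -> list[str]:
        return self.table["feature_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class CoexpressionResult:
    """Everything produced by mapping a signature onto a compendium.

    Attributes
    ----------
    features:
        Signature features present in the compendium, in signature order,
        excluding zero-variance features.
    correlation:
        Pearson gene-gene correlation matrix across reference samples.
    linkage:
        SciPy-format merge history of the hierarchical clustering.
    leaf_order:
        Feature IDs in dendrogram leaf order.
    clusters:
        Series feature -> integer cluster label (1-based, stable).
    attribution:
        Cluster x reference-group table of mean scaled intensities.
    top_groups:
        Series cluster -> best-scoring reference group.
    display:
        Row-z-scaled, clipped-to-[-2, 2] matrix (features x reference samples).
    missing_features:
        Signature features absent from the compendium.
    zero_variance_features:
        Features excluded from correlation/clustering for lack of variance.
    """

    features: list[str]
    correlation: pd.DataFrame
    linkage: np.ndarray
    leaf_order: list[str]
    clusters: pd.Series
    attribution: pd.DataFrame
    top_groups: pd.Series
    display: pd.DataFrame
    missing_features: list[str] = field(default_factory=list)
    zero_variance_features: list[str] = field(default_factory=list)
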