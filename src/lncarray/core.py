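"""Core containers shared by every pipeline stage.

The pipeline operates on log2-scale expression matrices (features in rows,
samples in columns) together with per-sample clinical metadata: the ordered
disease entities of plasma-cell dyscrasia (normal plasma cells through
plasma-cell leukemia), a dataset/batch label, and the molecular-subgroup
flags used for the supervised contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Ordered clinical entities, from normal donors to plasma-cell leukemia.
ENTITY_ORDER: tuple[str, ...] = ("N", "MGUS", "SMM", "MM", "PCL")

#: Mutually exclusive molecular subgroups of MM (exactly one per MM sample).
MM_SUBGROUPS: tuple[str, ...] = (
    "HD",
    "t_11_14_or_6_14",
    "t_4_14",
    "t_14_16_or_14_20",
    "other",
)

#: Independent cytogenetic lesion flags.
LESION_FLAGS: tuple[str, ...] = ("del13", "del17", "gain1q")

EXPRESSION_LEVELS = ("probe", "lncRNA", "gene")


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


@dataclass
class ExpressionMatrix:
    """A features x samples matrix of finite log2 expression values.

    Parameters
    ----------
    values
        DataFrame with unique feature ids as index and unique sample ids
        as columns; all entries finite floats on the log2 scale.
    level
        Aggregation level of the rows: ``probe``, ``lncRNA`` or ``gene``.
    """

    values: pd.DataFrame
    level: str = "probe"

    def __post_init__(self) -> None:
        if self.level not in EXPRESSION_LEVELS:
            raise ValidationError(f"unknown expression level {self.level!r}")
        v = self.values
        if v.index.has_duplicates:
            raise ValidationError("duplicate feature ids")
        if v.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if v.size and not np.isfinite(v.to_numpy(dtype=float)).all():
            raise ValidationError("expression values must be finite")
        self.values = v.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], self.level)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, path, level: str = "probe") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df, level)


@dataclass
class SampleMetadata:
    """Per-sample clinical annotation.

    ``table`` is indexed by sample_id and carries ``entity``, ``batch`` and
    one boolean column per subgroup/lesion flag. MM samples carry exactly
    one of the mutually exclusive molecular-subgroup flags; lesion flags
    are independent booleans.
    """

    table: pd.DataFrame
    flag_columns: tuple[str, ...] = field(default=MM_SUBGROUPS + LESION_FLAGS)

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise ValidationError("duplicate sample ids in metadata")
        for col in ("entity", "batch"):
            if col not in t.columns:
                raise ValidationError(f"metadata missing column {col!r}")
        bad = set(t["entity"]) - set(ENTITY_ORDER)
        if bad:
            raise ValidationError(f"unknown entities: {sorted(bad)}")
        present_flags = [c for c in self.flag_columns if c in t.columns]
        self.table = t.copy()
        for c in present_flags:
            self.table[c] = self.table[c].astype(bool)
        mm = self.table[self.table["entity"] == "MM"]
        groups = [c for c in MM_SUBGROUPS if c in self.table.columns]
        if len(groups) == len(MM_SUBGROUPS) and len(mm):
            n_true = mm[list(groups)].sum(axis=1)
            if not (n_true == 1).all():
                raise ValidationError(
                    "each MM sample must carry exactly one molecular subgroup flag"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def entities(self) -> pd.Series:
        return self.table["entity"]

    def batches(self) -> pd.Series:
        return self.table["batch"]

    def entity_counts(self) -> dict[str, int]:
        counts = self.table["entity"].value_counts()
        return {e: int(counts.get(e, 0)) for e in ENTITY_ORDER}

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "SampleMetadata":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df)


def check_aligned(matrix: ExpressionMatrix, metadata: SampleMetadata) -> None:
    """Require that every matrix sample has metadata."""
    missing = set(matrix.sample_ids) - set(metadata.sample_ids)
    if missing:
        raise ValidationError(f"samples without metadata: {sorted(missing)[:5]}")
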