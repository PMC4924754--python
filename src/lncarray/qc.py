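"""Sample-level quality control and the batch-adjustment step.

Array quality is summarized per sample by relative log expression (RLE:
each value minus its feature's median across samples) and, when per-feature
standard errors are available, by the normalized unscaled standard error
(NUSE: each SE divided by its feature's median SE). Samples whose RLE or
NUSE quartiles drift from their reference values (0 and 1 respectively)
beyond fixed bounds are removed before any downstream analysis.

Batch structure from merging datasets is removed by per-feature, per-batch
mean centering (the grand mean is added back), which exactly removes
additive per-batch offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, SampleMetadata, ValidationError, check_aligned

logger = logging.getLogger(__name__)

RLE_BOUND_DEFAULT = 0.5
NUSE_BOUND_DEFAULT = 1.05


@dataclass
class QcReport:
    """Per-sample quartiles of the QC statistics plus pass/fail calls.

    ``table`` is indexed by sample_id with columns rle_q25, rle_median,
    rle_q75 and (when SEs were supplied) nuse_q25, nuse_median, nuse_q75,
    plus a boolean ``pass``. The NUSE band is symmetric in ratio around 1:
    [2 - nuse_bound, nuse_bound].
    """

    table: pd.DataFrame
    rle_bound: float = RLE_BOUND_DEFAULT
    nuse_bound: float = NUSE_BOUND_DEFAULT

    @property
    def has_nuse(self) -> bool:
        return "nuse_q25" in self.table.columns

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample_id")


def _quartiles(arr: np.ndarray) -> np.ndarray:
    # type-7 (linear interpolation) estimator, numpy's default
    return np.percentile(arr, [25, 50, 75], axis=0)


def compute_rle(matrix: ExpressionMatrix, rle_bound: float = RLE_BOUND_DEFAULT) -> QcReport:
    """Per-sample quartiles of value minus per-feature cross-sample median."""
    if matrix.shape[1] < 2:
        raise ValidationError("RLE needs at least 2 samples")
    x = matrix.values.to_numpy()
    rle = x - np.median(x, axis=1, keepdims=True)
    q = _quartiles(rle)
    table = pd.DataFrame(
        {"rle_q25": q[0], "rle_median": q[1], "rle_q75": q[2]},
        index=matrix.values.columns,
    )
    report = QcReport(table, rle_bound=rle_bound)
    _apply_pass(report)
    return report


def compute_nuse(
    se_matrix: ExpressionMatrix,
    report: QcReport | None = None,
    nuse_bound: float = NUSE_BOUND_DEFAULT,
) -> QcReport:
    """Per-sample quartiles of SE divided by per-feature median SE.

    When ``report`` is given (an RLE report), the NUSE columns are merged
    into it; otherwise a NUSE-only report is returned.
    """
    se = se_matrix.values.to_numpy()
    if (se <= 0).any():
        raise ValidationError("standard errors must be positive")
    nuse = se / np.median(se, axis=1, keepdims=True)
    q = _quartiles(nuse)
    nuse_table = pd.DataFrame(
        {"nuse_q25": q[0], "nuse_median": q[1], "nuse_q75": q[2]},
        index=se_matrix.values.columns,
    )
    if report is None:
        report = QcReport(nuse_table, nuse_bound=nuse_bound)
    else:
        report = QcReport(
            report.table.drop(columns=["pass"], errors="ignore").join(nuse_table, how="left"),
            rle_bound=report.rle_bound,
            nuse_bound=nuse_bound,
        )
    _apply_pass(report)
    return report


def _apply_pass(report: QcReport) -> None:
    t = report.table
    ok = pd.Series(True, index=t.index)
    if "rle_q25" in t.columns:
        ok &= (t["rle_q25"].abs() <= report.rle_bound) & (
            t["rle_q75"].abs() <= report.rle_bound
        )
    if report.has_nuse:
        lo = 2.0 - report.nuse_bound
        ok &= t["nuse_q25"].between(lo, report.nuse_bound) & t["nuse_q75"].between(
            lo, report.nuse_bound
        )
    report.table = t.assign(**{"pass": ok})


def compute_rle_per_batch(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    rle_bound: float = RLE_BOUND_DEFAULT,
) -> QcReport:
    """RLE computed within each batch separately, then concatenated.

    Centering against the within-batch feature medians keeps additive
    batch offsets (a location difference between datasets, not an array
    quality problem) out of the quality statistics.
    """
    check_aligned(matrix, metadata)
    batches = metadata.table.loc[matrix.sample_ids, "batch"]
    parts = []
    for _, cols in matrix.values.columns.groupby(batches).items():
        part = compute_rle(matrix.subset_samples(list(cols)), rle_bound=rle_bound)
        parts.append(part.table)
    table = pd.concat(parts).loc[matrix.sample_ids]
    report = QcReport(table, rle_bound=rle_bound)
    _apply_pass(report)
    return report


def qc_filter(report: QcReport) -> tuple[list[str], list[str]]:
    """Split sample ids into (kept, removed) from the report's pass calls."""
    t = report.table
    kept = list(t.index[t["pass"]])
    removed = list(t.index[~t["pass"]])
    if removed:
        logger.info("QC removed %d samples: %s", len(removed), removed[:10])
    return kept, removed


def batch_center(matrix: ExpressionMatrix, metadata: SampleMetadata) -> ExpressionMatrix:
    """Remove additive batch structure by per-feature batch-mean centering.

    For every feature, each batch's mean is subtracted and the grand mean
    (over all samples) added back, so single-batch input is returned
    unchanged and planted additive offsets are removed exactly.
    """
    check_aligned(matrix, metadata)
    batches = metadata.table.loc[matrix.sample_ids, "batch"]
    counts = batches.value_counts()
    singletons = counts[counts < 2]
    if len(singletons):
        raise ValidationError(f"batches with <2 samples: {sorted(singletons.index)}")
    x = matrix.values
    grand = x.to_numpy().mean(axis=1, keepdims=True)
    centered = x.copy()
    for batch, cols in x.columns.groupby(batches).items():
        block = x.loc[:, list(cols)]
        centered.loc[:, list(cols)] = (
            block.to_numpy() - block.to_numpy().mean(axis=1, keepdims=True) + grand
        )
    return ExpressionMatrix(centered, matrix.level)
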