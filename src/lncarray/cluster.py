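"""Unsupervised sample clustering with correlation distance.

Samples are clustered by average-linkage (UPGMA) agglomeration on the
Pearson-correlation distance d(s, t) = 1 - r(s, t) computed over the
selected features (optionally z-scored per feature first). Every internal
branch of the dendrogram is then scored for enrichment of each clinical
entity with a one-sided hypergeometric tail test (branch membership versus
entity membership), which formalizes "all controls cluster together"
statements. The test ignores the multiplicity of branches scored; p-values
are per-branch, not tree-wide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats

from .core import ENTITY_ORDER, ExpressionMatrix, SampleMetadata, ValidationError, check_aligned


def pearson_distance(matrix: ExpressionMatrix, zscore: bool = True) -> pd.DataFrame:
    """Sample x sample table of 1 - Pearson r over the matrix's features."""
    x = matrix.values.to_numpy().T  # samples x features
    if zscore:
        mu = x.mean(axis=0, keepdims=True)
        sd = x.std(axis=0, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd
    sds = x.std(axis=1, ddof=0)
    zero = np.flatnonzero(sds == 0)
    if len(zero):
        bad = [matrix.sample_ids[i] for i in zero]
        raise ValidationError(f"zero-variance samples: {bad[:5]}")
    r = np.corrcoef(x)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(d, index=matrix.sample_ids, columns=matrix.sample_ids)


@dataclass
class DendrogramResult:
    """UPGMA tree over samples plus per-branch entity enrichment."""

    linkage: np.ndarray  # scipy linkage matrix
    sample_ids: list[str]
    branches: pd.DataFrame | None = None  # node_id, leaf_count, per-entity counts & p

    @property
    def leaf_order(self) -> list[str]:
        return [self.sample_ids[i] for i in hierarchy.leaves_list(self.linkage)]

    def branch_leaves(self) -> dict[int, list[int]]:
        """node_id -> leaf indices, for every internal node."""
        n = len(self.sample_ids)
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        for k, (a, b, _, _) in enumerate(self.linkage):
            members[n + k] = members[int(a)] + members[int(b)]
        return {node: leaves for node, leaves in members.items() if node >= n}

    def cophenetic(self) -> pd.DataFrame:
        coph = squareform(hierarchy.cophenet(self.linkage))
        return pd.DataFrame(coph, index=self.sample_ids, columns=self.sample_ids)

    def to_newick(self) -> str:
        n = len(self.sample_ids)
        names: dict[int, str] = {i: self.sample_ids[i] for i in range(n)}
        heights: dict[int, float] = {i: 0.0 for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = (h - heights[a]) / 2.0
            lb = (h - heights[b]) / 2.0
            names[n + k] = f"({names[a]}:{la:.6g},{names[b]}:{lb:.6g})"
            heights[n + k] = h
        return names[n + len(self.linkage) - 1] + ";"


def cluster_average(distance: pd.DataFrame) -> DendrogramResult:
    """Average-linkage agglomeration of a symmetric zero-diagonal distance table."""
    d = distance.to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValidationError("NaN distances")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValidationError("distance table must be symmetric with zero diagonal")
    condensed = squareform(d, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    return DendrogramResult(Z, list(distance.index))


def branch_enrichment(
    dendrogram: DendrogramResult,
    metadata: SampleMetadata,
    entities: tuple[str, ...] = ENTITY_ORDER,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of each entity in each branch.

    For branch size n containing k samples of an entity with K cohort
    members out of N total, p = P(X >= k), X ~ Hypergeom(N, K, n).
    """
    labels = metadata.table.loc[dendrogram.sample_ids, "entity"].to_numpy()
    N = len(labels)
    totals = {e: int((labels == e).sum()) for e in entities}
    rows = []
    for node, leaves in sorted(dendrogram.branch_leaves().items()):
        branch_labels = labels[leaves]
        row: dict = {"node_id": node, "leaf_count": len(leaves)}
        for e in entities:
            k = int((branch_labels == e).sum())
            row[f"n_{e}"] = k
            row[f"p_{e}"] = float(stats.hypergeom.sf(k - 1, N, totals[e], len(leaves)))
        rows.append(row)
    table = pd.DataFrame(rows).set_index("node_id")
    dendrogram.branches = table
    return table


def best_branch(branches: pd.DataFrame, entity: str) -> pd.Series:
    """The branch with the smallest enrichment p for ``entity``."""
    return branches.loc[branches[f"p_{entity}"].idxmin()]


class HierarchicalClustering:
    """Pearson-distance / average-linkage clustering model over samples."""

    def __init__(
        self,
        matrix: ExpressionMatrix,
        metadata: SampleMetadata | None = None,
        zscore: bool = True,
    ):
        if metadata is not None:
            check_aligned(matrix, metadata)
        self.matrix = matrix
        self.metadata = metadata
        self.zscore = zscore

    def fit(self) -> DendrogramResult:
        dist = pearson_distance(self.matrix, zscore=self.zscore)
        result = cluster_average(dist)
        if self.metadata is not None:
            branch_enrichment(result, self.metadata)
        return result
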