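"""Progressive-trend screen across ordered disease stages.

Features whose expression rises or falls steadily from normal plasma cells
through MGUS, SMM, MM to PCL are detected by combining three criteria:

* a Jonckheere-Terpstra (JT) rank test for an ordered alternative across
  the staged groups, Benjamini-Hochberg adjusted over all tested features;
* strictly monotone group medians along the stage order (plateaus fail) —
  a guard against the heavy group-size imbalance of the cohort;
* a Kruskal-Wallis test requiring differential expression in at least one
  stage.

The JT statistic is U = sum over ordered group pairs (i < j) of the number
of pairs (x in G_i, y in G_j) with x < y, counting ties one half. Small
instances are evaluated exactly by enumerating all arrangements of the
pooled values over the group sizes; larger ones use the normal
approximation with the tie-corrected variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ENTITY_ORDER, ExpressionMatrix, SampleMetadata, ValidationError, check_aligned

EXACT_LIMIT_DEFAULT = 100_000


def _group_arrays(values, group_labels, order) -> list[np.ndarray]:
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    groups = [values[group_labels == g] for g in order]
    if any(len(g) == 0 for g in groups):
        empty = [o for o, g in zip(order, groups) if len(g) == 0]
        raise ValidationError(f"empty ordered groups: {empty}")
    return groups


def jt_statistic(groups: list[np.ndarray]) -> float:
    """U with half-counted ties, summed over ordered group pairs."""
    u = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            xi = groups[i][:, None]
            yj = groups[j][None, :]
            u += (xi < yj).sum() + 0.5 * (xi == yj).sum()
    return float(u)


def n_arrangements(sizes: list[int]) -> int:
    n = sum(sizes)
    total = math.factorial(n)
    for s in sizes:
        total //= math.factorial(s)
    return total


def _all_label_vectors(sizes: list[int]) -> np.ndarray:
    """Every assignment of positions 0..n-1 to groups of the given sizes."""
    n = sum(sizes)
    out: list[list[int]] = []

    def rec(remaining: tuple[int, ...], labels: dict[int, int], g: int) -> None:
        if g == len(sizes):
            out.append([labels[p] for p in range(n)])
            return
        import itertools

        for combo in itertools.combinations(remaining, sizes[g]):
            new_labels = dict(labels)
            for p in combo:
                new_labels[p] = g
            rec(tuple(p for p in remaining if p not in combo), new_labels, g + 1)

    rec(tuple(range(n)), {}, 0)
    return np.array(out, dtype=np.int8)


def _exact_jt_distribution(values: np.ndarray, sizes: list[int]) -> np.ndarray:
    """U over all arrangements of the pooled values into the group sizes."""
    v = np.asarray(values, dtype=float)
    C = (v[:, None] < v[None, :]).astype(float) + 0.5 * (v[:, None] == v[None, :])
    np.fill_diagonal(C, 0.0)
    L = _all_label_vectors(sizes)
    mask = L[:, :, None] < L[:, None, :]
    return np.einsum("apq,pq->a", mask, C)


def _jt_null_moments(values: np.ndarray, sizes: np.ndarray) -> tuple[float, float]:
    """Mean and tie-corrected variance of U under the null."""
    N = int(sizes.sum())
    mean = (N**2 - (sizes**2).sum()) / 4.0
    _, t = np.unique(values, return_counts=True)
    n_i = sizes.astype(float)
    a1 = (
        N * (N - 1) * (2 * N + 5)
        - (n_i * (n_i - 1) * (2 * n_i + 5)).sum()
        - (t * (t - 1) * (2 * t + 5)).sum()
    ) / 72.0
    a2 = 0.0
    if N > 2:
        a2 = ((n_i * (n_i - 1) * (n_i - 2)).sum() * (t * (t - 1) * (t - 2)).sum()) / (
            36.0 * N * (N - 1) * (N - 2)
        )
    a3 = ((n_i * (n_i - 1)).sum() * (t * (t - 1)).sum()) / (8.0 * N * (N - 1))
    return float(mean), float(a1 + a2 + a3)


def jt_test(
    values,
    group_labels,
    order,
    mode: str = "auto",
    exact_limit: int = EXACT_LIMIT_DEFAULT,
    continuity: bool = True,
) -> tuple[float, float, float]:
    """Jonckheere-Terpstra test along the given group order.

    Returns (statistic, one_sided_p_ascending, two_sided_p). ``mode`` is
    ``exact`` (full enumeration), ``approx`` (tie-corrected normal), or
    ``auto`` (exact while the arrangement count stays within
    ``exact_limit``).
    """
    if len(order) < 2:
        raise ValidationError("need >= 2 ordered groups")
    groups = _group_arrays(values, group_labels, order)
    sizes = [len(g) for g in groups]
    u = jt_statistic(groups)
    pooled = np.concatenate(groups)

    if mode == "auto":
        mode = "exact" if n_arrangements(sizes) <= exact_limit else "approx"
    if mode == "exact":
        total = n_arrangements(sizes)
        if total > exact_limit:
            raise ValidationError(
                f"{total} arrangements exceed exact_limit={exact_limit}"
            )
        dist = _exact_jt_distribution(pooled, sizes)
        eps = 1e-9
        p_asc = float((dist >= u - eps).sum()) / len(dist)
        p_desc = float((dist <= u + eps).sum()) / len(dist)
    elif mode == "approx":
        mean, var = _jt_null_moments(pooled, np.array(sizes))
        if var <= 0:
            p_asc = p_desc = 1.0
        else:
            sd = math.sqrt(var)
            cc = 0.5 if continuity else 0.0
            p_asc = float(stats.norm.sf((u - cc - mean) / sd))
            p_desc = float(stats.norm.cdf((u + cc - mean) / sd))
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    two_sided = min(1.0, 2.0 * min(p_asc, p_desc))
    return u, p_asc, two_sided


def monotone_median(values, group_labels, order) -> tuple[bool, str | None]:
    """Strictly monotone group medians along the order; plateaus fail."""
    groups = _group_arrays(values, group_labels, order)
    med = np.array([np.median(g) for g in groups])
    diffs = np.diff(med)
    if (diffs > 0).all():
        return True, "asc"
    if (diffs < 0).all():
        return True, "desc"
    return False, None


def kw_test(values, group_labels) -> float:
    """Tie-corrected Kruskal-Wallis p; 1.0 when all values are identical."""
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    groups = [values[group_labels == g] for g in pd.unique(group_labels)]
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    if np.all(values == values[0]):
        return 1.0
    return float(stats.kruskal(*groups).pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# the screen


@dataclass
class TrendScreenResults:
    """Per-feature trend statistics with the three-criterion selection."""

    table: pd.DataFrame  # jt_statistic, jt_p, medians..., monotone, direction, kw_p, p_adj, selected
    order: tuple[str, ...]
    alpha: float

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    def summary(self) -> str:
        sel = self.table[self.table["selected"]]
        lines = [
            "Progressive-trend screen",
            f"  stage order: {' -> '.join(self.order)}   alpha = {self.alpha}",
            f"  features tested: {len(self.table)}   selected: {len(sel)}"
            f" (asc {int((sel['direction'] == 'asc').sum())},"
            f" desc {int((sel['direction'] == 'desc').sum())})",
        ]
        if len(sel):
            cols = ["jt_p", "p_adj", "kw_p", "direction"]
            lines += ["", sel.sort_values("p_adj")[cols].head(15).to_string()]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="feature_id")


class TrendScreen:
    """Screen every feature for a monotone stage trend.

    Parameters
    ----------
    matrix, metadata
        expression (any level) and sample metadata; every stage in
        ``order`` must be present with >= 2 samples.
    order
        ordered entity labels, default N -> MGUS -> SMM -> MM -> PCL.
    alpha
        level for both the BH-adjusted JT gate and the Kruskal-Wallis gate.
    adjust
        ``jt_only`` (default) BH-adjusts JT p-values only; ``joint``
        BH-adjusts JT and KW p-values together.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        metadata: SampleMetadata,
        order: tuple[str, ...] = ENTITY_ORDER,
        alpha: float = 0.05,
        jt_mode: str = "auto",
        adjust: str = "jt_only",
    ):
        check_aligned(matrix, metadata)
        entities = metadata.table.loc[matrix.sample_ids, "entity"]
        for stage in order:
            n = int((entities == stage).sum())
            if n < 2:
                raise ValidationError(f"stage {stage!r} has {n} samples (needs >= 2)")
        self.matrix = matrix
        self.entities = entities
        self.order = tuple(order)
        self.alpha = alpha
        self.jt_mode = jt_mode
        self.adjust = adjust

    def fit(self) -> TrendScreenResults:
        X = self.matrix.values
        labels = self.entities.to_numpy()
        rows = []
        for fid in self.matrix.feature_ids:
            v = X.loc[fid].to_numpy()
            u, _, p2 = jt_test(v, labels, self.order, mode=self.jt_mode)
            mono, direction = monotone_median(v, labels, self.order)
            meds = {
                f"median_{g}": float(np.median(v[labels == g])) for g in self.order
            }
            if direction is None:
                direction = "asc" if meds[f"median_{self.order[-1]}"] >= meds[
                    f"median_{self.order[0]}"
                ] else "desc"
            kw_p = kw_test(v, labels)
            rows.append(
                {"jt_statistic": u, "jt_p": p2, **meds, "monotone": mono,
                 "direction": direction, "kw_p": kw_p}
            )
        table = pd.DataFrame(rows, index=pd.Index(self.matrix.feature_ids, name="feature_id"))
        if self.adjust == "joint":
            both = np.concatenate([table["jt_p"], table["kw_p"]])
            adj = bh_adjust(both)
            table["p_adj"] = adj[: len(table)]
            table["kw_p_adj"] = adj[len(table):]
            kw_gate = table["kw_p_adj"] < self.alpha
        else:
            table["p_adj"] = bh_adjust(table["jt_p"].to_numpy())
            kw_gate = table["kw_p"] < self.alpha
        table["selected"] = (table["p_adj"] < self.alpha) & table["monotone"] & kw_gate
        return TrendScreenResults(table, self.order, self.alpha)


def trend_screen(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    order: tuple[str, ...] = ENTITY_ORDER,
    alpha: float = 0.05,
    jt_mode: str = "auto",
) -> TrendScreenResults:
    """Functional entry point; see :class:`TrendScreen`."""
    return TrendScreen(matrix, metadata, order, alpha, jt_mode).fit()
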