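"""Two-class significance analysis of microarrays (SAM) and related screens.

SAM tests each feature with a moderated difference statistic

    d_f = (mean_1 - mean_2) / (s_f + s0)

where s_f is the pooled-variance standard error of the mean difference and
s0 is a small "fudge" constant chosen so that the spread of d is as uniform
as possible across the range of s_f (it damps the otherwise explosive d of
low-variance features). Significance is judged against label permutations:
the sorted observed d are compared with the permutation-averaged order
statistics, a threshold Delta on the deviation defines the called set, the
median number of permuted exceedances estimates false calls, and each
feature's q-value is the smallest estimated FDR at which it is called.

The module also provides the supporting screens used around SAM: the
row-variability filter, subgroup-versus-rest contrasts, expression-quartile
stratification of samples by a chosen feature, and the check for gradual
modulation across quartiles.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, SampleMetadata, ValidationError, check_aligned

logger = logging.getLogger(__name__)

QUARTILE_NAMES = ("I", "II", "III", "IV")

#: tolerance for boundary comparisons against the Delta cut points, so that
#: ties between a cut and a d value are resolved identically regardless of
#: floating-point summation order
CUT_EPS = 1e-9


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=den > 0)
    return out


def variability_filter(
    matrix: ExpressionMatrix, fold: float = 1.5, mode: str = "mean_abs"
) -> list[str]:
    """Keep features whose variation around their row mean reaches ``fold``.

    ``mean_abs`` (default): mean over samples of |x - rowmean| >= log2(fold),
    boundary inclusive. ``max_abs``: any single sample's |x - rowmean|
    reaches the threshold.
    """
    if fold <= 1:
        raise ValidationError("fold must be > 1")
    x = matrix.values.to_numpy()
    dev = np.abs(x - x.mean(axis=1, keepdims=True))
    stat = dev.mean(axis=1) if mode == "mean_abs" else dev.max(axis=1)
    keep = stat >= np.log2(fold)
    return [f for f, k in zip(matrix.feature_ids, keep) if k]


# ---------------------------------------------------------------------------
# the SAM model


def _pooled_se(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Per-feature pooled standard error of the mean difference (rows = features)."""
    n1, n2 = x1.shape[1], x2.shape[1]
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    return np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def choose_s0(numerator: np.ndarray, s: np.ndarray, n_bins: int | None = None) -> float:
    """Tusher-style fudge factor: the s-quantile whose d has the most
    uniform spread across the range of s.

    Candidates are the alpha-quantiles of s for alpha in 0, 0.05, ..., 1.
    For each, features are windowed by s-quantile and the coefficient of
    variation of the windows' MADs of d is minimized.
    """
    m = len(s)
    if n_bins is None:
        n_bins = min(100, max(2, m // 5))
    order = np.argsort(s, kind="stable")
    windows = np.array_split(order, n_bins)
    alphas = np.arange(0.0, 1.0001, 0.05)
    best_cv, best_s0 = np.inf, 0.0
    for alpha in alphas:
        s0 = float(np.quantile(s, alpha))
        d = numerator / (s + s0)
        v = np.array([_mad(d[w]) for w in windows if len(w)])
        mean_v = v.mean()
        cv = np.inf if mean_v == 0 else v.std() / mean_v
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, s0
    return best_s0


def _enumerate_group1(n: int, n1: int):
    """All index subsets of size n1, lexicographic (exhaustive permutations)."""
    return itertools.combinations(range(n), n1)


@dataclass
class SAMResults:
    """Fitted SAM: per-feature statistics, permutation diagnostics, Delta table."""

    feature_ids: list[str]
    numerator: np.ndarray
    s: np.ndarray
    d: np.ndarray
    fold_change: np.ndarray
    q_values: np.ndarray
    dbar: np.ndarray  # expected order statistics (ascending)
    delta_grid: pd.DataFrame  # delta, cut_low, cut_up, n_called, median_false, fdr
    s0: float
    pi0: float
    n_permutations: int
    exhaustive: bool
    seed: int | None
    groups: tuple[str, str]

    def __post_init__(self) -> None:
        self._order = np.argsort(self.d, kind="stable")

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "numerator": self.numerator,
                "s": self.s,
                "d": self.d,
                "fold_change": self.fold_change,
                "q_value": self.q_values,
            },
            index=pd.Index(self.feature_ids, name="feature_id"),
        )

    def called_at(self, delta: float) -> tuple[list[str], list[str]]:
        """(up, down) feature ids called at threshold ``delta``."""
        cut_low, cut_up = _cutpoints(np.sort(self.d), self.dbar, delta)
        up = [f for f, d in zip(self.feature_ids, self.d)
              if np.isfinite(cut_up) and d >= cut_up - CUT_EPS]
        down = [f for f, d in zip(self.feature_ids, self.d)
                if np.isfinite(cut_low) and d <= cut_low + CUT_EPS]
        return up, down

    def tune_delta(self, q_target: float) -> tuple[float | None, list[str], list[str]]:
        """Smallest grid Delta whose non-empty called set has max q <= q_target.

        Returns (delta, up_ids, down_ids); (None, [], []) with a warning when
        no threshold achieves the target.
        """
        q = pd.Series(self.q_values, index=self.feature_ids)
        for row in self.delta_grid.sort_values("delta").itertuples(index=False):
            if row.n_called == 0:
                continue
            up, down = self.called_at(row.delta)
            called = up + down
            if called and q.loc[called].max() <= q_target:
                return float(row.delta), up, down
        logger.warning("no Delta achieves q <= %g; returning empty call set", q_target)
        return None, [], []

    def top_features(self, k: int = 10) -> list[str]:
        idx = np.argsort(-np.abs(self.d), kind="stable")[:k]
        return [self.feature_ids[i] for i in idx]

    def summary(self) -> str:
        g1, g2 = self.groups
        lines = [
            "SAM two-class results",
            f"  contrast: {g1} vs {g2} (numerator = mean[{g1}] - mean[{g2}])",
            f"  features: {len(self.feature_ids)}   s0 = {self.s0:.4g}   pi0 = {self.pi0:.3f}",
            f"  permutations: {self.n_permutations}"
            + (" (exhaustive)" if self.exhaustive else f" (random, seed={self.seed})"),
            f"  features with q < 0.05: {int((self.q_values < 0.05).sum())}",
            "",
            self.table.reindex(self.table["d"].abs().sort_values(ascending=False).index)
            .head(10)
            .to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


class SAMTwoClass:
    """Two-class unpaired SAM model.

    Parameters
    ----------
    matrix
        log2 expression, features x samples.
    labels
        mapping or Series sample_id -> group label (exactly two labels).
    groups
        optional (group1, group2) order; numerator is mean(group1) -
        mean(group2) and fold change 2**numerator. Defaults to order of
        first appearance in the matrix's samples.
    n_permutations
        permutation budget; all distinct label assignments are enumerated
        when their count does not exceed it, otherwise this many random
        permutations are drawn.
    s0_mode
        "auto" for the Tusher window-CV choice, or a fixed float (0 gives
        the ordinary pooled-variance t statistic).
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        labels,
        groups: tuple[str, str] | None = None,
        n_permutations: int = 1000,
        seed: int | None = 0,
        s0_mode="auto",
    ):
        if n_permutations < 10:
            raise ValidationError("n_permutations must be >= 10")
        if not isinstance(labels, pd.Series):
            labels = pd.Series(labels)
        labels = labels.reindex(matrix.sample_ids)
        if labels.isna().any():
            raise ValidationError("labels missing for some samples")
        uniq = list(dict.fromkeys(labels))
        if len(uniq) != 2:
            raise ValidationError(f"need exactly 2 groups, got {uniq}")
        if groups is None:
            groups = (uniq[0], uniq[1])
        if set(groups) != set(uniq):
            raise ValidationError("groups does not match the labels present")
        counts = labels.value_counts()
        if counts.min() < 2:
            raise ValidationError("each group needs >= 2 samples")
        self.matrix = matrix
        self.labels = labels
        self.groups = groups
        self.n_permutations = n_permutations
        self.seed = seed
        self.s0_mode = s0_mode

    def fit(self) -> SAMResults:
        X = self.matrix.values.to_numpy()
        g1, g2 = self.groups
        mask1 = (self.labels == g1).to_numpy()
        idx1 = np.flatnonzero(mask1)
        idx2 = np.flatnonzero(~mask1)
        n, n1 = X.shape[1], len(idx1)
        m = X.shape[0]

        numerator = X[:, idx1].mean(axis=1) - X[:, idx2].mean(axis=1)
        s = _pooled_se(X[:, idx1], X[:, idx2])
        if self.s0_mode == "auto":
            s0 = choose_s0(numerator, s)
        else:
            s0 = float(self.s0_mode)
        d = _safe_div(numerator, s + s0)

        # permutation pool: exhaustive label assignments when feasible
        total = math.comb(n, n1)
        exhaustive = total <= self.n_permutations
        if exhaustive:
            group1_sets = [np.array(c) for c in _enumerate_group1(n, n1)]
        else:
            rng = np.random.default_rng(self.seed)
            group1_sets = [rng.permutation(n)[:n1] for _ in range(self.n_permutations)]
        B = len(group1_sets)

        # vectorized permuted d via membership indicators
        Z = np.zeros((n, B))
        for b, g1_idx in enumerate(group1_sets):
            Z[g1_idx, b] = 1.0
        n2 = n - n1
        X2 = X**2
        sum1 = X @ Z
        sumsq1 = X2 @ Z
        mean1 = sum1 / n1
        mean2 = (X.sum(axis=1, keepdims=True) - sum1) / n2
        ss = (
            sumsq1
            - n1 * mean1**2
            + (X2.sum(axis=1, keepdims=True) - sumsq1)
            - n2 * mean2**2
        )
        ss = np.maximum(ss, 0.0)
        s_perm = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
        d_perm = _safe_div(mean1 - mean2, s_perm + s0)

        d_perm_sorted = np.sort(d_perm, axis=0)
        dbar = d_perm_sorted.mean(axis=1)

        q25, q75 = np.percentile(d, [25, 75])
        pi0 = min(
            1.0,
            float(((d_perm >= q25 - CUT_EPS) & (d_perm <= q75 + CUT_EPS)).sum())
            / (0.5 * m * B),
        )

        delta_grid = _delta_table(d, dbar, d_perm_sorted, pi0)
        q_values = _q_values(d, delta_grid)
        fold_change = 2.0**numerator

        return SAMResults(
            feature_ids=self.matrix.feature_ids,
            numerator=numerator,
            s=s,
            d=d,
            fold_change=fold_change,
            q_values=q_values,
            dbar=dbar,
            delta_grid=delta_grid,
            s0=s0,
            pi0=pi0,
            n_permutations=B,
            exhaustive=exhaustive,
            seed=self.seed,
            groups=self.groups,
        )


def _cutpoints(d_sorted: np.ndarray, dbar: np.ndarray, delta: float) -> tuple[float, float]:
    """Tusher cut points: scanning out from the origin of the quantile plot,
    the first sorted d deviating from its expectation by >= delta fixes the
    cut in that direction; (cut_low, cut_up), NaN when no crossing."""
    m = len(d_sorted)
    gaps = d_sorted - dbar
    # origin indices with a tolerance band so the rule is exactly mirror
    # symmetric under label exchange (dbar values of +-0 land in both scans)
    i_up = int(np.searchsorted(dbar, -CUT_EPS, side="left"))
    i_low = int(np.searchsorted(dbar, CUT_EPS, side="right")) - 1
    cut_up = np.nan
    for i in range(i_up, m):
        if gaps[i] >= delta - CUT_EPS:
            cut_up = d_sorted[i]
            break
    cut_low = np.nan
    for i in range(min(i_low, m - 1), -1, -1):
        if -gaps[i] >= delta - CUT_EPS:
            cut_low = d_sorted[i]
            break
    return cut_low, cut_up


def _delta_table(
    d: np.ndarray, dbar: np.ndarray, d_perm_sorted: np.ndarray, pi0: float
) -> pd.DataFrame:
    d_sorted = np.sort(d)
    gaps = np.abs(d_sorted - dbar)
    grid = np.unique(gaps[gaps > 0])
    rows = []
    for delta in grid:
        cut_low, cut_up = _cutpoints(d_sorted, dbar, delta)
        n_up = int((d >= cut_up - CUT_EPS).sum()) if np.isfinite(cut_up) else 0
        n_low = int((d <= cut_low + CUT_EPS).sum()) if np.isfinite(cut_low) else 0
        n_called = n_up + n_low
        false_counts = np.zeros(d_perm_sorted.shape[1])
        if np.isfinite(cut_up):
            false_counts += (d_perm_sorted >= cut_up - CUT_EPS).sum(axis=0)
        if np.isfinite(cut_low):
            false_counts += (d_perm_sorted <= cut_low + CUT_EPS).sum(axis=0)
        median_false = float(np.median(false_counts))
        # the FDR estimate uses the permutation *average* of the false-call
        # count (the original formulation); the median is liberal for small
        # call sets (it is 0 whenever most permutations have no exceedance)
        mean_false = float(np.mean(false_counts))
        fdr = 0.0 if n_called == 0 else min(1.0, pi0 * mean_false / n_called)
        rows.append((delta, cut_low, cut_up, n_called, median_false, mean_false, fdr))
    return pd.DataFrame(
        rows,
        columns=["delta", "cut_low", "cut_up", "n_called",
                 "median_false", "mean_false", "fdr"],
    )


def _q_values(d: np.ndarray, delta_grid: pd.DataFrame) -> np.ndarray:
    q = np.ones(len(d))
    for row in delta_grid.itertuples(index=False):
        called = np.zeros(len(d), dtype=bool)
        if np.isfinite(row.cut_up):
            called |= d >= row.cut_up - CUT_EPS
        if np.isfinite(row.cut_low):
            called |= d <= row.cut_low + CUT_EPS
        q[called] = np.minimum(q[called], row.fdr)
    return q


def sam_two_class(
    matrix: ExpressionMatrix,
    labels,
    groups: tuple[str, str] | None = None,
    n_permutations: int = 1000,
    seed: int | None = 0,
    s0_mode="auto",
) -> SAMResults:
    """Functional entry point; see :class:`SAMTwoClass`."""
    return SAMTwoClass(matrix, labels, groups, n_permutations, seed, s0_mode).fit()


# ---------------------------------------------------------------------------
# subgroup contrasts and quartile stratification

SUBGROUP_CONTRAST_FLAGS = (
    "HD",
    "t_11_14_or_6_14",
    "t_4_14",
    "t_14_16_or_14_20",
    "del13",
    "del17",
    "gain1q",
)


def subgroup_contrasts(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    flags: tuple[str, ...] = SUBGROUP_CONTRAST_FLAGS,
    restrict_entity: str | None = "MM",
    n_permutations: int = 1000,
    seed: int | None = 0,
    top_k: int = 10,
) -> dict[str, SAMResults]:
    """One flag-versus-rest SAM per molecular subgroup / lesion flag.

    Restricted to MM samples by default (the molecularly characterized
    panel). Degenerate flags (<2 members on either side) are skipped with a
    log entry. Each result additionally carries ``top`` — the top_k feature
    ids by |d|.
    """
    check_aligned(matrix, metadata)
    meta = metadata.table.loc[matrix.sample_ids]
    if restrict_entity is not None:
        meta = meta[meta["entity"] == restrict_entity]
    sub = matrix.subset_samples(meta.index)
    out: dict[str, SAMResults] = {}
    for flag in flags:
        if flag not in meta.columns:
            logger.warning("flag %s absent from metadata; skipped", flag)
            continue
        members = meta[flag].astype(bool)
        if members.sum() < 2 or (~members).sum() < 2:
            logger.warning("flag %s degenerate (%d/%d); skipped",
                           flag, int(members.sum()), len(members))
            continue
        labels = members.map({True: flag, False: "rest"})
        res = sam_two_class(
            sub, labels, groups=(flag, "rest"),
            n_permutations=n_permutations, seed=seed,
        )
        res.top = res.top_features(top_k)
        out[flag] = res
    return out


@dataclass
class QuartileLabels:
    """Sample -> expression quartile (I = lowest) for one ranking feature."""

    feature_id: str
    labels: pd.Series  # sample_id -> "I".."IV"

    def samples_in(self, quartile: str) -> list[str]:
        return list(self.labels.index[self.labels == quartile])


def quartile_stratify(matrix: ExpressionMatrix, feature_id: str) -> QuartileLabels:
    """Rank samples by one feature's expression and split into four
    contiguous blocks, lowest expression first; remainders go to the lower
    quartiles and ties break by sample order."""
    if feature_id not in matrix.values.index:
        raise ValidationError(f"feature {feature_id!r} not in matrix")
    n = matrix.shape[1]
    if n < 4:
        raise ValidationError("need >= 4 samples to stratify")
    values = matrix.values.loc[feature_id]
    order = np.argsort(values.to_numpy(), kind="stable")  # stable = sample-order ties
    base, rem = divmod(n, 4)
    sizes = [base + (1 if i < rem else 0) for i in range(4)]
    labels = pd.Series(index=matrix.values.columns, dtype=object)
    pos = 0
    for name, size in zip(QUARTILE_NAMES, sizes):
        labels.iloc[order[pos : pos + size]] = name
        pos += size
    return QuartileLabels(feature_id, labels)


def gradual_modulation_check(
    matrix: ExpressionMatrix, labels: QuartileLabels, features=None
) -> pd.Series:
    """True per feature iff the four quartile medians are strictly monotone."""
    if set(matrix.sample_ids) - set(labels.labels.index):
        raise ValidationError("quartile labels do not cover all samples")
    features = list(features) if features is not None else matrix.feature_ids
    med = {
        q: matrix.values.loc[features, labels.samples_in(q)].median(axis=1)
        for q in QUARTILE_NAMES
    }
    M = pd.DataFrame(med)[list(QUARTILE_NAMES)]
    diffs = M.diff(axis=1).iloc[:, 1:]
    return (diffs.gt(0).all(axis=1)) | (diffs.lt(0).all(axis=1))
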