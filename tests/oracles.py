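"""Independent brute-force reference implementations used by the tests.

Everything here is written with plain loops and enumeration, deliberately
avoiding the vectorized code paths of the package, so the two routes can
be compared on small instances.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# SAM: naive exhaustive-permutation reimplementation


def sam_oracle(X: np.ndarray, n1: int) -> dict:
    """Two-class SAM by direct loops; group 1 = first n1 columns.

    Follows the documented algorithm: pooled-variance s per feature, fudge
    factor from the window-CV rule, exhaustive enumeration of all
    C(n, n1) group-1 index sets, average sorted permuted d, Tusher cut
    points scanned from the origin over the grid of observed |d - dbar|
    gaps, FDR = pi0 * mean false calls / called, q = minimal FDR at which
    the feature is called.
    """
    m, n = X.shape
    n2 = n - n1

    def stats_for(idx1):
        idx1 = list(idx1)
        idx2 = [j for j in range(n) if j not in idx1]
        num, s = np.empty(m), np.empty(m)
        for f in range(m):
            x1 = X[f, idx1]
            x2 = X[f, idx2]
            num[f] = x1.mean() - x2.mean()
            ss = ((x1 - x1.mean()) ** 2).sum() + ((x2 - x2.mean()) ** 2).sum()
            s[f] = np.sqrt((1 / n1 + 1 / n2) * ss / (n1 + n2 - 2))
        return num, s

    obs_idx1 = list(range(n1))
    num, s = stats_for(obs_idx1)

    # fudge factor: alpha-quantile of s minimizing the CV of windowed MADs
    n_bins = min(100, max(2, m // 5))
    order = np.argsort(s, kind="stable")
    windows = np.array_split(order, n_bins)
    best_cv, s0 = np.inf, 0.0
    for alpha in np.arange(0.0, 1.0001, 0.05):
        cand = float(np.quantile(s, alpha))
        d_try = num / (s + cand)
        mads = []
        for w in windows:
            if len(w):
                vals = d_try[w]
                mads.append(np.median(np.abs(vals - np.median(vals))))
        mads = np.array(mads)
        cv = np.inf if mads.mean() == 0 else mads.std() / mads.mean()
        if cv < best_cv - 1e-12:
            best_cv, s0 = cv, cand
    d = num / (s + s0)

    combos = list(itertools.combinations(range(n), n1))
    d_perm = np.empty((m, len(combos)))
    for b, idx1 in enumerate(combos):
        pnum, ps = stats_for(idx1)
        d_perm[:, b] = pnum / (ps + s0)
    d_perm_sorted = np.sort(d_perm, axis=0)
    dbar = d_perm_sorted.mean(axis=1)

    q25, q75 = np.percentile(d, [25, 75])
    B = len(combos)
    pi0 = min(
        1.0,
        ((d_perm >= q25 - 1e-9) & (d_perm <= q75 + 1e-9)).sum() / (0.5 * m * B),
    )

    d_sorted = np.sort(d)
    gaps = d_sorted - dbar
    grid = sorted({abs(g) for g in gaps if abs(g) > 0})
    tol = 1e-9
    i_up = next((i for i in range(m) if dbar[i] >= -tol), m)
    i_low = max((i for i in range(m) if dbar[i] <= tol), default=-1)
    rows = []
    q = np.ones(m)
    for delta in grid:
        cut_up = np.nan
        for i in range(i_up, m):
            if gaps[i] >= delta - tol:
                cut_up = d_sorted[i]
                break
        cut_low = np.nan
        for i in range(min(i_low, m - 1), -1, -1):
            if -gaps[i] >= delta - tol:
                cut_low = d_sorted[i]
                break
        eps = 1e-9  # same boundary tolerance as the implementation
        called = np.zeros(m, dtype=bool)
        if np.isfinite(cut_up):
            called |= d >= cut_up - eps
        if np.isfinite(cut_low):
            called |= d <= cut_low + eps
        n_called = int(called.sum())
        false_counts = []
        for b in range(B):
            c = 0
            for f in range(m):
                if np.isfinite(cut_up) and d_perm[f, b] >= cut_up - eps:
                    c += 1
                elif np.isfinite(cut_low) and d_perm[f, b] <= cut_low + eps:
                    c += 1
            false_counts.append(c)
        mean_false = float(np.mean(false_counts))
        fdr = 0.0 if n_called == 0 else min(1.0, pi0 * mean_false / n_called)
        q[called] = np.minimum(q[called], fdr)
        rows.append((delta, n_called, float(np.median(false_counts)), mean_false, fdr))
    return {"d": d, "dbar": dbar, "s0": s0, "pi0": pi0, "q": q, "grid": rows}


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra: recursive enumeration with scalar loops


def jt_u_naive(groups: list[np.ndarray]) -> float:
    u = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            for x in groups[i]:
                for y in groups[j]:
                    if x < y:
                        u += 1.0
                    elif x == y:
                        u += 0.5
    return u


def jt_exact_p_naive(values: np.ndarray, sizes: list[int], u_obs: float) -> tuple[float, float]:
    """(p_ascending, p_descending) by enumerating every arrangement."""
    values = list(values)
    n = len(values)
    us = []

    def rec(remaining: tuple[int, ...], chosen: list[list[int]]) -> None:
        if len(chosen) == len(sizes):
            groups = [np.array([values[i] for i in c]) for c in chosen]
            us.append(jt_u_naive(groups))
            return
        k = len(chosen)
        for combo in itertools.combinations(remaining, sizes[k]):
            rec(tuple(i for i in remaining if i not in combo), chosen + [list(combo)])

    rec(tuple(range(n)), [])
    us = np.array(us)
    eps = 1e-9
    return float((us >= u_obs - eps).mean()), float((us <= u_obs + eps).mean())


# ---------------------------------------------------------------------------
# probe assignment: quadratic all-pairs scan


def assign_oracle(probes, ensembl_like, lncipedia_like, strand_mode="ignore"):
    """All-pairs overlap scan reproducing the univocal-assignment contract."""

    def compatible(ps, ts):
        if strand_mode == "ignore" or "." in (ps, ts):
            return True
        return (ps == ts) if strand_mode == "same" else (ps != ts)

    def overlaps(placement, transcript):
        chrom, s, e, strand = placement
        if transcript.chrom != chrom or not compatible(strand, transcript.strand):
            return False
        return any(s < ee and es < e for es, ee in transcript.exons)

    assignments: dict[str, set[str]] = {}
    excluded: dict[str, str] = {}
    for probe in probes:
        hits_ens = any(
            overlaps(pl, t) for pl in probe.placements for t in ensembl_like
        )
        lnc_genes = {
            t.gene_id
            for pl in probe.placements
            for t in lncipedia_like
            if overlaps(pl, t)
        }
        if hits_ens:
            excluded[probe.probe_id] = "overlaps_ensembl"
        elif not lnc_genes:
            excluded[probe.probe_id] = "no_lnc_overlap"
        elif len(lnc_genes) > 1:
            excluded[probe.probe_id] = "ambiguous_lnc"
        else:
            assignments.setdefault(lnc_genes.pop(), set()).add(probe.probe_id)
    return assignments, excluded


# ---------------------------------------------------------------------------
# misc definitional oracles


def bed12_exons_naive(line: str) -> list[tuple[int, int]]:
    parts = line.rstrip("\n").split("\t")
    start = int(parts[1])
    sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
    offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
    return [(start + o, start + o + sz) for o, sz in zip(offsets, sizes)]


def bh_naive(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def kw_h_naive(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H from rank sums."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    i = 0
    sorted_vals = pooled[order]
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # average rank, 1-based
        i = j
    h = 0.0
    pos = 0
    for g in groups:
        r = ranks[pos : pos + len(g)]
        h += r.sum() ** 2 / len(g)
        pos += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie_corr
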