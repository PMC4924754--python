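"""Cis/antisense/parental partner finding and expression correlation screens.

For each lncRNA the candidate regulatory partners are: genes whose exons
overlap it on the same strand (sense_overlap), on the opposite strand
(antisense_overlap), and — for pseudogenes — the annotated parental gene
wherever it lies (parental). Pearson correlation with a two-sided t
approximation (n - 2 df) quantifies co-expression over the shared samples.
The genome-wide trans screen correlates every lncRNA against every gene and
keeps pairs with r strictly above a confidence threshold (0.9 by default).

A 2^-dCt helper converts qRT-PCR threshold cycles to relative quantities,
with Wilcoxon rank-sum and Kendall tau utilities for group comparisons of
such measurements.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .annotation import TranscriptAnnotation
from .core import ExpressionMatrix, ValidationError

RELATIONS = ("sense_overlap", "antisense_overlap", "parental", "trans")


def find_partners(
    lnc_annotation: list[TranscriptAnnotation],
    gene_annotation: list[TranscriptAnnotation],
) -> pd.DataFrame:
    """Candidate (lnc gene, partner gene, relation) pairs from annotation geometry.

    Overlap is exon-level with >= 1 shared base; strands '.' never resolve
    a sense/antisense call and are skipped. Pairs are emitted once at gene
    level even when several transcripts overlap.
    """
    trees: dict[str, IntervalTree] = {}
    for t in gene_annotation:
        tree = trees.setdefault(t.chrom, IntervalTree())
        for s, e in t.exons:
            tree.addi(s, e, (t.gene_id, t.strand))
    pairs: set[tuple[str, str, str]] = set()
    lnc_genes: dict[str, list[TranscriptAnnotation]] = {}
    for t in lnc_annotation:
        lnc_genes.setdefault(t.gene_id, []).append(t)
    for lnc_id, transcripts in lnc_genes.items():
        for t in transcripts:
            if t.parental_gene:
                pairs.add((lnc_id, t.parental_gene, "parental"))
            if t.strand == ".":
                continue
            tree = trees.get(t.chrom)
            if tree is None:
                continue
            for s, e in t.exons:
                for iv in tree.overlap(s, e):
                    gene_id, gstrand = iv.data
                    if gstrand == ".":
                        continue
                    relation = (
                        "sense_overlap" if gstrand == t.strand else "antisense_overlap"
                    )
                    pairs.add((lnc_id, gene_id, relation))
    return pd.DataFrame(
        sorted(pairs), columns=["lnc_id", "partner_id", "relation"]
    )


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    if not np.isfinite(r):
        return np.nan, np.nan
    r_ = min(max(r, -1.0), 1.0)
    if abs(r_) == 1.0:
        return r_, 0.0
    t = r_ * np.sqrt((n - 2) / (1 - r_**2))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return r_, p


def correlate_pairs(
    lnc_matrix: ExpressionMatrix,
    gene_matrix: ExpressionMatrix,
    pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson r and two-sided p per candidate pair over the shared samples.

    Pairs whose partner (or lncRNA) is absent from the matrices are kept
    with status ``NA - not detected`` and missing r, mirroring how
    undetected partners are reported.
    """
    shared = [s for s in lnc_matrix.sample_ids if s in set(gene_matrix.sample_ids)]
    if len(shared) < 3:
        raise ValidationError("need >= 3 shared samples")
    L = lnc_matrix.values[shared]
    G = gene_matrix.values[shared]
    rows = []
    for rec in pairs.itertuples(index=False):
        if rec.lnc_id not in L.index or rec.partner_id not in G.index:
            rows.append(
                {"lnc_id": rec.lnc_id, "partner_id": rec.partner_id,
                 "relation": rec.relation, "r": np.nan, "p": np.nan,
                 "n": len(shared), "status": "NA - not detected"}
            )
            continue
        r, p = _pearson_with_p(L.loc[rec.lnc_id].to_numpy(), G.loc[rec.partner_id].to_numpy())
        rows.append(
            {"lnc_id": rec.lnc_id, "partner_id": rec.partner_id,
             "relation": rec.relation, "r": r, "p": p, "n": len(shared),
             "status": "ok"}
        )
    return pd.DataFrame(
        rows, columns=["lnc_id", "partner_id", "relation", "r", "p", "n", "status"]
    )


def trans_screen(
    lnc_matrix: ExpressionMatrix,
    gene_matrix: ExpressionMatrix,
    r_threshold: float = 0.9,
) -> pd.DataFrame:
    """All lncRNA x gene Pearson correlations; keep r strictly > threshold.

    Returns records sorted by r descending with relation ``trans``.
    """
    shared = [s for s in lnc_matrix.sample_ids if s in set(gene_matrix.sample_ids)]
    if len(shared) < 3:
        raise ValidationError("need >= 3 shared samples")
    L = lnc_matrix.values[shared].to_numpy()
    G = gene_matrix.values[shared].to_numpy()
    n = len(shared)

    def standardize(x):
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = np.nan
        return (x - mu) / sd

    R = standardize(L) @ standardize(G).T / n
    rows = []
    lnc_ids, gene_ids = lnc_matrix.feature_ids, gene_matrix.feature_ids
    hit_l, hit_g = np.nonzero(R > r_threshold)
    for i, j in zip(hit_l, hit_g):
        r = float(np.clip(R[i, j], -1.0, 1.0))
        t = r * np.sqrt((n - 2) / max(1 - r**2, 1e-300))
        p = 2.0 * float(stats.t.sf(abs(t), n - 2))
        rows.append(
            {"lnc_id": lnc_ids[i], "partner_id": gene_ids[j], "relation": "trans",
             "r": r, "p": p, "n": n, "status": "ok"}
        )
    out = pd.DataFrame(
        rows, columns=["lnc_id", "partner_id", "relation", "r", "p", "n", "status"]
    )
    return out.sort_values("r", ascending=False, kind="stable").reset_index(drop=True)


def qpcr_relative(ct_target, ct_reference):
    """Relative quantity 2^-(Ct_target - Ct_reference)."""
    ct_target = np.asarray(ct_target, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    if not (np.isfinite(ct_target).all() and np.isfinite(ct_reference).all()):
        raise ValidationError("Ct values must be finite")
    out = 2.0 ** -(ct_target - ct_reference)
    return float(out) if out.ndim == 0 else out


def rank_sum_test(x, y) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) statistic and two-sided p."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall tau-b and two-sided p."""
    res = stats.kendalltau(x, y)
    return float(res.statistic), float(res.pvalue)
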