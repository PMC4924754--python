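"""Probe reannotation: from probe genomic placements to lncRNA-level signal.

Gene 1.0 ST probes were designed against protein-coding transcripts; to
measure lncRNAs the probes are re-assigned by genomic position. The pipeline
is: (1) drop cross-hybridizing probes (more than one genomic placement);
(2) assign each remaining probe to a lncRNA gene iff it overlaps an exon of
that gene and overlaps no exon of any transcript in the coding-like
("Ensembl") annotation — a *univocal* assignment; probes touching two
distinct lncRNA genes are discarded as ambiguous; (3) summarize each
lncRNA's probes by their per-sample median.

Coordinates are 0-based half-open internally. GTF input (1-based inclusive)
is converted on read; BED is native.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

SOURCES = ("ensembl_like", "lncipedia_like")
EXCLUSION_REASONS = ("cross_hyb", "overlaps_ensembl", "no_lnc_overlap", "ambiguous_lnc")

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


@dataclass
class TranscriptAnnotation:
    """One transcript: exon structure plus gene-level links."""

    transcript_id: str
    gene_id: str
    source: str
    biotype: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    aliases: list[str] = field(default_factory=list)
    parental_gene: str | None = None

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValidationError(f"unknown annotation source {self.source!r}")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: no exons")
        exons = sorted(tuple(map(int, e)) for e in self.exons)
        for (s, e) in exons:
            if s < 0 or e <= s:
                raise ValidationError(f"{self.transcript_id}: bad exon [{s}, {e})")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValidationError(f"{self.transcript_id}: overlapping exons")
        self.exons = exons

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class ProbeAlignment:
    """One probe's genomic placement(s); >1 placement marks cross-hybridization."""

    probe_id: str
    placements: list[tuple[str, int, int, str]]
    probeset_id: str | None = None
    flagged_cross_hyb: bool = False

    def __post_init__(self) -> None:
        if not self.placements:
            raise ValidationError(f"{self.probe_id}: no placements")
        for chrom, s, e, strand in self.placements:
            if e <= s:
                raise ValidationError(f"{self.probe_id}: bad placement [{s}, {e})")
        if self.probeset_id is None:
            self.probeset_id = self.probe_id

    @property
    def cross_hyb(self) -> bool:
        return self.flagged_cross_hyb or len(self.placements) > 1


@dataclass
class ProbeLncMap:
    """Partition of the input probes into per-lncRNA assignments and exclusions."""

    assignments: dict[str, set[str]]
    excluded: dict[str, str]

    def __post_init__(self) -> None:
        assigned = [p for probes in self.assignments.values() for p in probes]
        if len(assigned) != len(set(assigned)):
            raise ValidationError("a probe is assigned to more than one lncRNA")
        overlap = set(assigned) & set(self.excluded)
        if overlap:
            raise ValidationError(f"probes both assigned and excluded: {sorted(overlap)[:5]}")
        bad = set(self.excluded.values()) - set(EXCLUSION_REASONS)
        if bad:
            raise ValidationError(f"unknown exclusion reasons: {sorted(bad)}")

    @property
    def assigned_probes(self) -> set[str]:
        return {p for probes in self.assignments.values() for p in probes}

    def to_tsv(self, path) -> None:
        rows = []
        for lnc, probes in sorted(self.assignments.items()):
            rows.extend(
                {"probe_id": p, "status": "assigned", "lnc_id": lnc, "reason": ""}
                for p in sorted(probes)
            )
        rows.extend(
            {"probe_id": p, "status": "excluded", "lnc_id": "", "reason": r}
            for p, r in sorted(self.excluded.items())
        )
        pd.DataFrame(rows, columns=["probe_id", "status", "lnc_id", "reason"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "ProbeLncMap":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        assignments: dict[str, set[str]] = {}
        excluded: dict[str, str] = {}
        for row in df.itertuples(index=False):
            if row.status == "assigned":
                assignments.setdefault(row.lnc_id, set()).add(row.probe_id)
            else:
                excluded[row.probe_id] = row.reason
        return cls(assignments, excluded)


# ---------------------------------------------------------------------------
# readers


def _parse_gtf(path: Path, source: str) -> list[TranscriptAnnotation]:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "src", "feature", "start", "end", "score", "strand", "frame", "attrs"],
        dtype={"chrom": str},
    )
    df = df[df["feature"] == "exon"]
    n_bad = 0
    records: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError):
            n_bad += 1
            continue
        if start < 1 or end < start:
            n_bad += 1
            continue
        attrs = dict(_GTF_ATTR.findall(row.attrs))
        tid = attrs.get("transcript_id")
        if not tid:
            n_bad += 1
            continue
        rec = records.setdefault(
            tid,
            {
                "gene_id": attrs.get("gene_id", tid),
                "biotype": attrs.get("transcript_biotype")
                or attrs.get("gene_biotype", "protein_coding"),
                "chrom": row.chrom,
                "strand": row.strand,
                "exons": [],
                "parental_gene": attrs.get("parental_gene") or None,
            },
        )
        rec["exons"].append((start - 1, end))  # 1-based inclusive -> 0-based half-open
    if n_bad:
        logger.warning("%s: rejected %d malformed GTF records", path, n_bad)
    return [
        TranscriptAnnotation(transcript_id=tid, source=source, **rec)
        for tid, rec in records.items()
    ]


def _bed12_exons(chrom_start: int, block_sizes: str, block_starts: str) -> list[tuple[int, int]]:
    sizes = [int(x) for x in str(block_sizes).rstrip(",").split(",")]
    starts = [int(x) for x in str(block_starts).rstrip(",").split(",")]
    return [(chrom_start + s, chrom_start + s + sz) for s, sz in zip(starts, sizes)]


def _parse_bed12(path: Path, source: str) -> list[TranscriptAnnotation]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 12:
        raise ValidationError(f"{path}: BED12 requires 12 columns, found {df.shape[1]}")
    out = []
    n_bad = 0
    for row in df.itertuples(index=False):
        try:
            exons = _bed12_exons(int(row[1]), row[10], row[11])
        except (TypeError, ValueError):
            n_bad += 1
            continue
        name = str(row[3])
        # LNCipedia convention: transcript "lnc-FOO-1:2" belongs to gene "lnc-FOO-1"
        gene_id = name.rsplit(":", 1)[0]
        out.append(
            TranscriptAnnotation(
                transcript_id=name,
                gene_id=gene_id,
                source=source,
                biotype="lncRNA",
                chrom=str(row[0]),
                strand=str(row[5]),
                exons=exons,
            )
        )
    if n_bad:
        logger.warning("%s: rejected %d malformed BED12 records", path, n_bad)
    return out


def load_annotation(
    path,
    source: str,
    fmt: str,
    parental_map: dict[str, str] | None = None,
) -> list[TranscriptAnnotation]:
    """Read a transcript annotation file.

    Parameters
    ----------
    path : file path
    source : ``ensembl_like`` or ``lncipedia_like``
    fmt : ``GTF`` or ``BED12``
    parental_map : optional gene_id -> parental gene_id mapping (pseudogene
        links for BED input, which cannot carry attributes).
    """
    path = Path(path)
    if fmt.upper() == "GTF":
        transcripts = _parse_gtf(path, source)
    elif fmt.upper() == "BED12":
        transcripts = _parse_bed12(path, source)
    else:
        raise ValidationError(f"unknown annotation format {fmt!r}")
    if not transcripts:
        raise ValidationError(f"{path}: no parsable records")
    if parental_map:
        for t in transcripts:
            t.parental_gene = parental_map.get(t.gene_id, t.parental_gene)
    return transcripts


def load_probes(path) -> list[ProbeAlignment]:
    """Read probe alignments from BED6; rows sharing a name are one probe's placements."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str, 3: str})
    if df.shape[1] < 6:
        raise ValidationError(f"{path}: BED6 requires 6 columns")
    probes: dict[str, list] = {}
    for row in df.itertuples(index=False):
        probes.setdefault(str(row[3]), []).append(
            (str(row[0]), int(row[1]), int(row[2]), str(row[5]))
        )
    if not probes:
        raise ValidationError(f"{path}: no parsable records")
    return [ProbeAlignment(pid, placements) for pid, placements in probes.items()]


def write_probes_bed(probes: list[ProbeAlignment], path) -> None:
    rows = [
        (chrom, s, e, p.probe_id, 0, strand)
        for p in probes
        for chrom, s, e, strand in p.placements
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_annotation_bed12(transcripts: list[TranscriptAnnotation], path) -> None:
    rows = []
    for t in transcripts:
        start, end = t.span
        sizes = ",".join(str(e - s) for s, e in t.exons)
        starts = ",".join(str(s - start) for s, _ in t.exons)
        rows.append(
            (t.chrom, start, end, t.transcript_id, 0, t.strand,
             start, end, "0", len(t.exons), sizes, starts)
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_annotation_gtf(transcripts: list[TranscriptAnnotation], path) -> None:
    lines = []
    for t in transcripts:
        attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; transcript_biotype "{t.biotype}";'
        if t.parental_gene:
            attrs += f' parental_gene "{t.parental_gene}";'
        for s, e in t.exons:
            lines.append(
                f"{t.chrom}\tlncarray\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# the annotation pipeline


def filter_crosshyb(
    probes: list[ProbeAlignment],
) -> tuple[list[ProbeAlignment], list[ProbeAlignment]]:
    """Split probes into (kept, cross-hybridizing)."""
    kept = [p for p in probes if not p.cross_hyb]
    excluded = [p for p in probes if p.cross_hyb]
    return kept, excluded


def _strand_compatible(probe_strand: str, tx_strand: str, mode: str) -> bool:
    if mode == "ignore" or "." in (probe_strand, tx_strand):
        return True
    if mode == "same":
        return probe_strand == tx_strand
    if mode == "opposite":
        return probe_strand != tx_strand
    raise ValidationError(f"unknown strand_mode {mode!r}")


def _exon_tree(transcripts: list[TranscriptAnnotation], use_span: bool = False):
    """chrom -> IntervalTree of (gene_id, strand) payloads."""
    trees: dict[str, IntervalTree] = {}
    for t in transcripts:
        tree = trees.setdefault(t.chrom, IntervalTree())
        intervals = [t.span] if use_span else t.exons
        for s, e in intervals:
            tree.addi(s, e, (t.gene_id, t.strand))
    return trees


def assign_probes_univocal(
    probes: list[ProbeAlignment],
    ensembl_like: list[TranscriptAnnotation],
    lncipedia_like: list[TranscriptAnnotation],
    strand_mode: str = "ignore",
    overlap_level: str = "exon",
    exclusion_biotype_whitelist: set[str] | None = None,
) -> ProbeLncMap:
    """Assign cross-hyb-filtered probes univocally to lncRNA genes.

    A probe is assigned to lncRNA gene G iff some placement overlaps (>=1
    shared base) an exon of a transcript of G under ``strand_mode``, and no
    placement overlaps an exon of any ``ensembl_like`` transcript (biotypes
    in the whitelist, if given, are exempt from exclusion). Probes touching
    two distinct lncRNA genes are excluded as ``ambiguous_lnc``.
    """
    if not lncipedia_like:
        raise ValidationError("empty lncRNA annotation set")
    use_span = overlap_level == "span"
    whitelist = exclusion_biotype_whitelist or set()
    excl_tx = [t for t in ensembl_like if t.biotype not in whitelist]
    ens_trees = _exon_tree(excl_tx, use_span)
    lnc_trees = _exon_tree(lncipedia_like, use_span)

    assignments: dict[str, set[str]] = {}
    excluded: dict[str, str] = {}
    for probe in probes:
        hits_ensembl = False
        lnc_genes: set[str] = set()
        for chrom, s, e, strand in probe.placements:
            for iv in ens_trees.get(chrom, IntervalTree()).overlap(s, e):
                if _strand_compatible(strand, iv.data[1], strand_mode):
                    hits_ensembl = True
                    break
            if hits_ensembl:
                break
            for iv in lnc_trees.get(chrom, IntervalTree()).overlap(s, e):
                if _strand_compatible(strand, iv.data[1], strand_mode):
                    lnc_genes.add(iv.data[0])
        if hits_ensembl:
            excluded[probe.probe_id] = "overlaps_ensembl"
        elif not lnc_genes:
            excluded[probe.probe_id] = "no_lnc_overlap"
        elif len(lnc_genes) > 1:
            excluded[probe.probe_id] = "ambiguous_lnc"
        else:
            assignments.setdefault(lnc_genes.pop(), set()).add(probe.probe_id)
    return ProbeLncMap(assignments, excluded)


def summarize_by_median(
    probe_matrix: ExpressionMatrix,
    probe_map: ProbeLncMap,
    min_probes: int = 1,
) -> ExpressionMatrix:
    """Collapse probe-level values to one row per lncRNA by per-sample median.

    Only lncRNAs with at least ``min_probes`` assigned probes are kept; rows
    are ordered lexicographically by gene id.
    """
    if min_probes < 1:
        raise ValidationError("min_probes must be >= 1")
    available = set(probe_matrix.feature_ids)
    missing = probe_map.assigned_probes - available
    if missing:
        raise ValidationError(f"assigned probes absent from matrix: {sorted(missing)[:5]}")
    rows = {}
    for lnc in sorted(probe_map.assignments):
        probe_ids = sorted(probe_map.assignments[lnc])
        if len(probe_ids) < min_probes:
            continue
        rows[lnc] = np.median(probe_matrix.values.loc[probe_ids].to_numpy(), axis=0)
    summarized = pd.DataFrame.from_dict(
        rows, orient="index", columns=probe_matrix.sample_ids
    )
    logger.info("summarized %d lncRNAs from %d assigned probes",
                len(rows), len(probe_map.assigned_probes))
    return ExpressionMatrix(summarized, level="lncRNA")
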