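"""Synthetic-study generator: toy genome, probes, expression and ground truth.

Emulates the statistical structure the downstream screens assume, so every
stage can be exercised and validated without the original cohorts:

* a toy genome with lncRNA-only loci, coding loci, lnc/coding-overlapping
  loci (to exercise the univocality filter), probes per locus, intergenic
  decoy probes and a configurable fraction of multi-placement probes (to
  exercise the cross-hybridization filter);
* probe-level log2 intensities built additively:
  ``base(locus) + stage_shift(locus, entity) + batch_offset(batch)
  + affinity(probe) + N(0, noise_sd)``;
* planted ascending/descending stage trends (shifts 0, d, 2d, 3d, 4d from
  normal through PCL), subgroup differential effects, additive per-batch
  offsets, and bivariate-normal correlated lncRNA/gene pairs;
* a ``SyntheticTruth`` record of everything planted, for recovery tests.

All generators are pure functions of (config, seed). The default design
mirrors the study cohort's entity proportions at quarter scale
(N=3, MGUS=5, SMM=8, MM=42, PCL=9) to keep simulations fast.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    ProbeAlignment,
    TranscriptAnnotation,
    write_annotation_bed12,
    write_annotation_gtf,
    write_probes_bed,
)
from .core import ENTITY_ORDER, ExpressionMatrix, SampleMetadata, ValidationError

DEFAULT_DESIGN = {"N": 3, "MGUS": 5, "SMM": 8, "MM": 42, "PCL": 9}

# MM molecular-subgroup proportions of the characterized 129-patient panel
SUBGROUP_PROPORTIONS = {
    "HD": 48 / 129,
    "t_11_14_or_6_14": 34 / 129,
    "t_4_14": 19 / 129,
    "t_14_16_or_14_20": 6 / 129,
    "other": 22 / 129,
}
LESION_RATES = {"del13": 0.45, "del17": 0.10, "gain1q": 0.40}


@dataclass
class AnnotationConfig:
    """Toy-genome layout."""

    n_lnc: int = 100
    n_coding: int = 30
    n_overlap: int = 3  # lnc loci that also host a coding transcript
    probes_per_locus: int = 4
    n_decoy_probes: int = 10  # intergenic probes hitting nothing
    multi_hit_fraction: float = 0.0  # probes given a second placement
    n_pseudogenes: int = 4  # lnc loci linked to a coding parental gene
    exon_length: int = 300
    locus_spacing: int = 10_000

    def validate(self) -> None:
        for fld in ("n_lnc", "n_coding", "probes_per_locus"):
            if getattr(self, fld) <= 0:
                raise ValidationError(f"{fld} must be positive")
        for fld in ("n_overlap", "n_decoy_probes", "n_pseudogenes"):
            if getattr(self, fld) < 0:
                raise ValidationError(f"{fld} must be >= 0")
        if not 0 <= self.multi_hit_fraction <= 1:
            raise ValidationError("multi_hit_fraction must be in [0, 1]")
        if self.n_overlap > self.n_lnc:
            raise ValidationError("n_overlap cannot exceed n_lnc")
        if self.n_pseudogenes > self.n_lnc or self.n_pseudogenes > self.n_coding:
            raise ValidationError("n_pseudogenes cannot exceed n_lnc or n_coding")


@dataclass
class TruthSpec:
    """What to plant. Feature ids refer to lnc/coding gene ids."""

    trend_features: list[tuple[str, str, float]] = field(default_factory=list)
    de_features: list[tuple[str, str, float]] = field(default_factory=list)
    correlated_pairs: list[tuple[str, str, float]] = field(default_factory=list)


@dataclass
class StudyConfig:
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    design: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_DESIGN))
    batch_offsets: dict[str, float] = field(
        default_factory=lambda: {"dsA": 0.0, "dsB": 0.3}
    )
    noise_sd: float = 0.5
    affinity_sd: float = 1.0
    signal_sd: float = 0.3  # per-sample biological spread of each locus
    base_mean: float = 7.0
    base_sd: float = 1.0
    truth: TruthSpec | None = None  # None -> default plantings

    def validate(self) -> None:
        self.annotation.validate()
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        for e, n in self.design.items():
            if e not in ENTITY_ORDER:
                raise ValidationError(f"unknown entity {e!r}")
            if n < 2:
                raise ValidationError(f"need >= 2 samples per entity ({e}: {n})")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated study."""

    seed: int
    trend_features: list[tuple[str, str, float]]
    de_features: list[tuple[str, str, float]]
    correlated_pairs: list[tuple[str, str, float]]
    batch_offsets: dict[str, float]
    probe_affinities: dict[str, float]
    noise_sd: float
    locus_signal: pd.DataFrame | None = None  # noiseless per-locus signal (not serialized)

    def __post_init__(self) -> None:
        for _, _, rho in self.correlated_pairs:
            if not -1 < rho < 1:
                raise ValidationError(f"rho must be in (-1, 1), got {rho}")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "trend_features": [list(t) for t in self.trend_features],
            "de_features": [list(t) for t in self.de_features],
            "correlated_pairs": [list(t) for t in self.correlated_pairs],
            "batch_offsets": self.batch_offsets,
            "probe_affinities": self.probe_affinities,
            "noise_sd": self.noise_sd,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            seed=payload["seed"],
            trend_features=[tuple(t) for t in payload["trend_features"]],
            de_features=[tuple(t) for t in payload["de_features"]],
            correlated_pairs=[tuple(t) for t in payload["correlated_pairs"]],
            batch_offsets=payload["batch_offsets"],
            probe_affinities=payload["probe_affinities"],
            noise_sd=payload["noise_sd"],
        )


# ---------------------------------------------------------------------------
# annotation generation


def generate_annotation(
    config: AnnotationConfig, seed: int
) -> tuple[list[TranscriptAnnotation], list[ProbeAlignment]]:
    """Build the toy genome and its probes; deterministic given seed.

    Loci are laid out along one chromosome with generous spacing. The first
    ``n_overlap`` lncRNA loci also host an overlapping coding transcript,
    so their probes fail univocality; the first ``n_pseudogenes`` of the
    remaining lncRNAs carry a parental-gene link to a coding gene.
    ``multi_hit_fraction`` of all probes receive a second, intergenic
    placement and thereby become cross-hybridizing.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    L = config.exon_length
    spacing = config.locus_spacing
    transcripts: list[TranscriptAnnotation] = []
    probes: list[ProbeAlignment] = []
    lnc_spans: list[tuple[str, int, str]] = []  # (gene_id, start, strand)

    pos = spacing
    # lncRNA loci (BED-side annotation); two exons each
    for i in range(config.n_lnc):
        gid = f"LNC{i + 1:04d}"
        strand = "+" if i % 2 == 0 else "-"
        exons = [(pos, pos + L), (pos + 2 * L, pos + 3 * L)]
        transcripts.append(
            TranscriptAnnotation(
                transcript_id=f"{gid}:1", gene_id=gid, source="lncipedia_like",
                biotype="lncRNA", chrom=chrom, strand=strand, exons=exons,
            )
        )
        lnc_spans.append((gid, pos, strand))
        if i < config.n_overlap:
            # overlapping coding transcript on the same locus (opposite strand)
            cid = f"OVG{i + 1:04d}"
            transcripts.append(
                TranscriptAnnotation(
                    transcript_id=f"{cid}.t1", gene_id=cid, source="ensembl_like",
                    biotype="protein_coding", chrom=chrom,
                    strand="-" if strand == "+" else "+",
                    exons=[(pos + L // 2, pos + L + L // 2)],
                )
            )
        pos += spacing

    # coding-only loci (GTF-side annotation)
    coding_ids = []
    for j in range(config.n_coding):
        gid = f"GENE{j + 1:04d}"
        coding_ids.append(gid)
        strand = "+" if j % 2 == 0 else "-"
        exons = [(pos, pos + L), (pos + 2 * L, pos + 3 * L)]
        transcripts.append(
            TranscriptAnnotation(
                transcript_id=f"{gid}.t1", gene_id=gid, source="ensembl_like",
                biotype="protein_coding", chrom=chrom, strand=strand, exons=exons,
            )
        )
        pos += spacing

    # parental links: non-overlap lncRNAs become pseudogenes of coding genes
    plain_lnc = [gid for gid, _, _ in lnc_spans[config.n_overlap:]]
    for k, gid in enumerate(plain_lnc[: config.n_pseudogenes]):
        parent = coding_ids[k % len(coding_ids)]
        for t in transcripts:
            if t.gene_id == gid:
                t.biotype = "pseudogene"
                t.parental_gene = parent

    # probes: probes_per_locus per locus, inside the first exon
    locus_list = [(gid, start, strand) for gid, start, strand in lnc_spans]
    locus_list += [
        (t.gene_id, t.exons[0][0], t.strand)
        for t in transcripts
        if t.source == "ensembl_like" and t.gene_id.startswith("GENE")
    ]
    probe_no = 0
    for gid, start, strand in locus_list:
        step = max(1, (L - 25) // config.probes_per_locus)
        for p in range(config.probes_per_locus):
            probe_no += 1
            s = start + p * step
            probes.append(
                ProbeAlignment(f"P{probe_no:06d}", [(chrom, s, s + 25, strand)])
            )
    # intergenic decoys, past every locus
    decoy_base = pos + spacing
    for p in range(config.n_decoy_probes):
        probe_no += 1
        s = decoy_base + p * 100
        probes.append(ProbeAlignment(f"P{probe_no:06d}", [(chrom, s, s + 25, "+")]))

    # cross-hybridizers: add a second far-away placement
    n_multi = int(round(config.multi_hit_fraction * len(probes)))
    if n_multi:
        chosen = rng.choice(len(probes), size=n_multi, replace=False)
        far = decoy_base + 100 * (config.n_decoy_probes + 10)
        for extra, idx in enumerate(sorted(chosen)):
            s = far + extra * 200
            probes[idx].placements.append((chrom, s, s + 25, "+"))
    return transcripts, probes


def probe_to_locus(
    transcripts: list[TranscriptAnnotation], probes: list[ProbeAlignment]
) -> dict[str, str | None]:
    """Map each probe to the gene whose exon its first placement lies in."""
    mapping: dict[str, str | None] = {}
    for p in probes:
        chrom, s, e, _ = p.placements[0]
        hit = None
        for t in transcripts:
            if t.chrom == chrom and any(s < ee and es < e for es, ee in t.exons):
                if hit is None or not t.gene_id.startswith("OVG"):
                    hit = t.gene_id
        mapping[p.probe_id] = hit
    return mapping


# ---------------------------------------------------------------------------
# expression generation


def _default_truth(transcripts: list[TranscriptAnnotation], config: StudyConfig) -> TruthSpec:
    """Default plantings on clean (non-overlap, non-pseudogene) lncRNA loci."""
    lnc = [t.gene_id for t in transcripts
           if t.source == "lncipedia_like" and t.parental_gene is None]
    lnc = lnc[config.annotation.n_overlap:]  # skip univocality casualties
    coding = [t.gene_id for t in transcripts if t.gene_id.startswith("GENE")]
    pseudo = [(t.gene_id, t.parental_gene) for t in transcripts if t.parental_gene]
    spec = TruthSpec()
    pool = list(lnc)
    for _ in range(min(2, len(pool))):
        spec.trend_features.append((pool.pop(0), "asc", 1.0))
    for _ in range(min(1, len(pool))):
        spec.trend_features.append((pool.pop(0), "desc", 1.0))
    for _ in range(min(2, len(pool))):
        spec.de_features.append((pool.pop(0), "HD", 2.0))
    for gid, parent in pseudo[:2]:
        spec.correlated_pairs.append((gid, parent, 0.7))
    return spec


def _assign_metadata(design: dict[str, int], batches: list[str], rng) -> SampleMetadata:
    rows = []
    i = 0
    for entity in ENTITY_ORDER:
        for _ in range(design.get(entity, 0)):
            i += 1
            row = {
                "sample_id": f"S{i:04d}",
                "entity": entity,
                "batch": batches[(i - 1) % len(batches)],
            }
            for g in SUBGROUP_PROPORTIONS:
                row[g] = False
            if entity == "MM":
                groups = list(SUBGROUP_PROPORTIONS)
                probs = np.array([SUBGROUP_PROPORTIONS[g] for g in groups])
                row[rng.choice(groups, p=probs / probs.sum())] = True
            for lesion, rate in LESION_RATES.items():
                row[lesion] = bool(entity == "MM" and rng.random() < rate)
            rows.append(row)
    return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))


def generate_expression(
    transcripts: list[TranscriptAnnotation],
    probes: list[ProbeAlignment],
    config: StudyConfig,
    seed: int,
) -> tuple[ExpressionMatrix, SampleMetadata, SyntheticTruth]:
    """Probe-level log2 matrix + metadata + ground truth.

    Each locus carries a latent per-sample signal: a baseline drawn once
    per locus plus a per-sample N(0, signal_sd) fluctuation (bivariate for
    planted correlated pairs), plus the planted stage shift / subgroup
    effect. Probe values add the probe's affinity, its batch's offset and
    i.i.d. Gaussian noise.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    truth_spec = config.truth if config.truth is not None else _default_truth(transcripts, config)

    metadata = _assign_metadata(config.design, list(config.batch_offsets), rng)
    samples = metadata.sample_ids
    n = len(samples)
    entities = metadata.entities().to_numpy()
    stage_idx = np.array([ENTITY_ORDER.index(e) for e in entities])

    loci = sorted({t.gene_id for t in transcripts})
    known = set(loci)
    for fid, _, _ in truth_spec.trend_features:
        if fid not in known:
            raise ValidationError(f"planted trend feature {fid!r} not in annotation")
    for fid, _, _ in truth_spec.de_features:
        if fid not in known:
            raise ValidationError(f"planted DE feature {fid!r} not in annotation")
    for a, b, _ in truth_spec.correlated_pairs:
        for fid in (a, b):
            if fid not in known:
                raise ValidationError(f"planted pair member {fid!r} not in annotation")

    base = {g: rng.normal(config.base_mean, config.base_sd) for g in loci}
    fluct = pd.DataFrame(
        rng.normal(0.0, config.signal_sd, size=(len(loci), n)),
        index=loci, columns=samples,
    )
    # correlated pairs: replace both members' fluctuations with a bivariate draw
    for a, b, rho in truth_spec.correlated_pairs:
        cov = config.signal_sd**2 * np.array([[1.0, rho], [rho, 1.0]])
        draw = rng.multivariate_normal([0.0, 0.0], cov, size=n).T
        fluct.loc[a] = draw[0]
        fluct.loc[b] = draw[1]

    shift = pd.DataFrame(0.0, index=loci, columns=samples)
    for fid, direction, delta in truth_spec.trend_features:
        steps = stage_idx * delta
        shift.loc[fid] += steps if direction == "asc" else -steps
    flags = metadata.table
    for fid, contrast, effect in truth_spec.de_features:
        if contrast in flags.columns:
            mask = flags[contrast].astype(bool).to_numpy()
        elif contrast in ENTITY_ORDER:
            mask = entities == contrast
        else:
            raise ValidationError(f"unknown DE contrast {contrast!r}")
        shift.loc[fid, mask] += effect

    signal = fluct.add(pd.Series(base), axis=0) + shift

    batch_vec = np.array([config.batch_offsets[b] for b in metadata.batches()])
    affinities = {p.probe_id: float(rng.normal(0.0, config.affinity_sd)) for p in probes}
    locus_of = probe_to_locus(transcripts, probes)

    values = np.empty((len(probes), n))
    for i, p in enumerate(probes):
        locus = locus_of[p.probe_id]
        locus_signal = signal.loc[locus].to_numpy() if locus else config.base_mean
        values[i] = (
            locus_signal
            + batch_vec
            + affinities[p.probe_id]
            + rng.normal(0.0, config.noise_sd, size=n)
        )
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=[p.probe_id for p in probes], columns=samples),
        level="probe",
    )
    truth = SyntheticTruth(
        seed=seed,
        trend_features=truth_spec.trend_features,
        de_features=truth_spec.de_features,
        correlated_pairs=truth_spec.correlated_pairs,
        batch_offsets=dict(config.batch_offsets),
        probe_affinities=affinities,
        noise_sd=config.noise_sd,
        locus_signal=signal,
    )
    return matrix, metadata, truth


# ---------------------------------------------------------------------------
# on-disk bundles


def generate_study(config: StudyConfig, seed: int, outdir) -> dict:
    """Write a complete study bundle; returns the manifest dict.

    Files: coding.gtf, lncrna.bed12, probes.bed6, parental_links.tsv,
    probe_matrix.tsv, metadata.tsv, truth.json, manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts, probes = generate_annotation(config.annotation, seed)
    matrix, metadata, truth = generate_expression(transcripts, probes, config, seed)

    coding = [t for t in transcripts if t.source == "ensembl_like"]
    lnc = [t for t in transcripts if t.source == "lncipedia_like"]
    write_annotation_gtf(coding, outdir / "coding.gtf")
    write_annotation_bed12(lnc, outdir / "lncrna.bed12")
    write_probes_bed(probes, outdir / "probes.bed6")
    links = [(t.gene_id, t.parental_gene) for t in lnc if t.parental_gene]
    pd.DataFrame(sorted(set(links)), columns=["gene_id", "parental_gene"]).to_csv(
        outdir / "parental_links.tsv", sep="\t", index=False
    )
    matrix.to_tsv(outdir / "probe_matrix.tsv")
    metadata.to_tsv(outdir / "metadata.tsv")
    truth.to_json(outdir / "truth.json")

    manifest = {
        "seed": seed,
        "config": dataclasses.asdict(config),
        "files": {},
    }
    for f in sorted(outdir.glob("*")):
        if f.name == "manifest.json":
            continue
        manifest["files"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
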