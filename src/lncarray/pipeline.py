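"""End-to-end orchestration: annotate -> qc -> batch -> summarize -> screens.

A single :class:`PipelineConfig` names the inputs, toggles the stages and
fixes every tunable parameter plus the seed; ``run_pipeline`` validates the
enabled stages' inputs up front, executes the stages in order, writes each
stage's outputs into the run directory, and records a manifest (parameters,
seed, input checksums, stage summaries) sufficient to reproduce the run.
Identical config + seed give identical outputs. A stage failure aborts the
run with the failing stage named; outputs of completed stages remain.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann
from . import cluster as clus
from . import correlation as corr
from . import qc as qcmod
from . import sam as sammod
from . import trend as trendmod
from .core import ENTITY_ORDER, ExpressionMatrix, SampleMetadata

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    # inputs
    probes: str | None = None            # BED6 probe alignments
    ensembl: str | None = None           # GTF coding-like annotation
    lncipedia: str | None = None         # BED12 lncRNA annotation
    parental_links: str | None = None    # TSV gene_id -> parental_gene
    matrix: str | None = None            # probe-level TSV
    se_matrix: str | None = None         # optional SE TSV for NUSE
    metadata: str | None = None          # sample metadata TSV
    outdir: str = "lncarray_run"
    # stage toggles
    do_annotate: bool = True
    do_qc: bool = True
    do_batch: bool = True
    do_summarize: bool = True
    do_cluster: bool = True
    do_de: bool = True
    do_trend: bool = True
    do_correlate: bool = True
    # parameters
    strand_mode: str = "ignore"
    min_probes: int = 1
    rle_bound: float = 0.5
    nuse_bound: float = 1.05
    fold_filter: float = 1.5
    q_target: float = 0.0
    n_permutations: int = 1000
    alpha: float = 0.05
    r_threshold: float = 0.9
    entity_order: tuple[str, ...] = ENTITY_ORDER
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**payload)
        if isinstance(cfg.entity_order, list):
            cfg.entity_order = tuple(cfg.entity_order)
        return cfg

    def validate(self) -> None:
        required: list[tuple[str, str | None]] = []
        if self.do_annotate:
            required += [("probes", self.probes), ("ensembl", self.ensembl),
                         ("lncipedia", self.lncipedia)]
        required.append(("matrix", self.matrix))
        if self.do_qc or self.do_batch or self.do_de or self.do_trend or self.do_cluster:
            required.append(("metadata", self.metadata))
        for name, path in required:
            if path is None:
                raise PipelineError("validate", f"config missing required input {name!r}")
            if not Path(path).exists():
                raise PipelineError("validate", f"input {name!r} not found: {path}")


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages; returns the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("lncarray")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)

    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "inputs": {},
        "stages": {},
    }
    for name in ("probes", "ensembl", "lncipedia", "matrix", "se_matrix",
                 "metadata", "parental_links"):
        path = getattr(config, name)
        if path and Path(path).exists():
            manifest["inputs"][name] = _checksum(path)

    stage = "load"
    try:
        matrix = ExpressionMatrix.from_tsv(config.matrix, level="probe")
        metadata = SampleMetadata.from_tsv(config.metadata) if config.metadata else None

        probe_map = None
        lnc_tx = ens_tx = None
        if config.do_annotate:
            stage = "annotate"
            parental = None
            if config.parental_links and Path(config.parental_links).exists():
                links = pd.read_csv(config.parental_links, sep="\t")
                parental = dict(zip(links["gene_id"], links["parental_gene"]))
            ens_tx = ann.load_annotation(config.ensembl, "ensembl_like", "GTF")
            lnc_tx = ann.load_annotation(
                config.lncipedia, "lncipedia_like", "BED12", parental_map=parental
            )
            probes = ann.load_probes(config.probes)
            kept, crosshyb = ann.filter_crosshyb(probes)
            probe_map = ann.assign_probes_univocal(
                kept, ens_tx, lnc_tx, strand_mode=config.strand_mode
            )
            for p in crosshyb:
                probe_map.excluded[p.probe_id] = "cross_hyb"
            probe_map.to_tsv(outdir / "probe_map.tsv")
            manifest["stages"][stage] = {
                "probes_total": len(probes),
                "cross_hyb": len(crosshyb),
                "assigned": len(probe_map.assigned_probes),
                "lncRNAs_detected": len(probe_map.assignments),
            }
            logger.info("annotate: %s", manifest["stages"][stage])

        if config.do_qc:
            stage = "qc"
            report = (
                qcmod.compute_rle_per_batch(matrix, metadata, rle_bound=config.rle_bound)
                if metadata is not None
                else qcmod.compute_rle(matrix, rle_bound=config.rle_bound)
            )
            if config.se_matrix and Path(config.se_matrix).exists():
                se = ExpressionMatrix.from_tsv(config.se_matrix, level="probe")
                report = qcmod.compute_nuse(se, report, nuse_bound=config.nuse_bound)
            kept_samples, removed = qcmod.qc_filter(report)
            report.to_tsv(outdir / "qc_report.tsv")
            matrix = matrix.subset_samples(kept_samples)
            manifest["stages"][stage] = {"kept": len(kept_samples), "removed": removed}

        if config.do_batch:
            stage = "batch"
            matrix = qcmod.batch_center(matrix, metadata)
            manifest["stages"][stage] = {"batches": sorted(
                set(metadata.table.loc[matrix.sample_ids, "batch"]))}

        lnc_matrix = matrix
        if config.do_summarize:
            stage = "summarize"
            if probe_map is None:
                probe_map = ann.ProbeLncMap.from_tsv(outdir / "probe_map.tsv")
            lnc_matrix = ann.summarize_by_median(matrix, probe_map, config.min_probes)
            lnc_matrix.to_tsv(outdir / "lnc_matrix.tsv")
            manifest["stages"][stage] = {"lncRNAs": lnc_matrix.shape[0]}

        if config.do_cluster:
            stage = "cluster"
            keep = sammod.variability_filter(lnc_matrix, fold=config.fold_filter)
            if len(keep) >= 2:
                sub = ExpressionMatrix(lnc_matrix.values.loc[keep], lnc_matrix.level)
                dendro = clus.HierarchicalClustering(sub, metadata).fit()
                (outdir / "dendrogram.newick").write_text(dendro.to_newick() + "\n")
                dendro.branches.to_csv(outdir / "branch_enrichment.tsv", sep="\t")
                manifest["stages"][stage] = {"features_used": len(keep)}
            else:
                manifest["stages"][stage] = {"skipped": "fewer than 2 variable features"}

        if config.do_de:
            stage = "de"
            entities = metadata.table.loc[lnc_matrix.sample_ids, "entity"]
            de_counts = {}
            for entity in config.entity_order[1:]:
                pair = entities[entities.isin([config.entity_order[0], entity])]
                if pair.value_counts().min() < 2 or pair.nunique() < 2:
                    continue
                sub = lnc_matrix.subset_samples(pair.index)
                res = sammod.sam_two_class(
                    sub, pair, groups=(entity, config.entity_order[0]),
                    n_permutations=config.n_permutations, seed=config.seed,
                )
                res.table.to_csv(outdir / f"sam_{entity}_vs_{config.entity_order[0]}.tsv",
                                 sep="\t")
                _, up, down = res.tune_delta(config.q_target)
                de_counts[entity] = {"up": len(up), "down": len(down)}
            sub_results = sammod.subgroup_contrasts(
                lnc_matrix, metadata,
                n_permutations=config.n_permutations, seed=config.seed,
            )
            for flag, res in sub_results.items():
                res.table.to_csv(outdir / f"sam_subgroup_{flag}.tsv", sep="\t")
            manifest["stages"][stage] = {
                "entity_contrasts": de_counts,
                "subgroup_contrasts": sorted(sub_results),
            }

        if config.do_trend:
            stage = "trend"
            res = trendmod.TrendScreen(
                lnc_matrix, metadata, order=config.entity_order, alpha=config.alpha
            ).fit()
            res.to_tsv(outdir / "trend.tsv")
            manifest["stages"][stage] = {"selected": len(res.selected)}

        if config.do_correlate and config.do_annotate:
            stage = "correlate"
            # gene-level matrix: reuse the univocal assigner with the coding
            # annotation as the target set and no exclusion set
            gene_map = ann.assign_probes_univocal(
                [p for p in ann.load_probes(config.probes) if not p.cross_hyb],
                [], ens_tx,
            )
            gene_map.assignments = {
                g: probes & set(matrix.feature_ids)
                for g, probes in gene_map.assignments.items()
                if probes & set(matrix.feature_ids)
            }
            gene_matrix = ExpressionMatrix(
                ann.summarize_by_median(matrix, gene_map, min_probes=1).values,
                level="gene",
            )
            pairs = corr.find_partners(lnc_tx, ens_tx)
            records = corr.correlate_pairs(lnc_matrix, gene_matrix, pairs)
            records.to_csv(outdir / "partner_correlations.tsv", sep="\t", index=False)
            trans = corr.trans_screen(lnc_matrix, gene_matrix, config.r_threshold)
            trans.to_csv(outdir / "trans_screen.tsv", sep="\t", index=False)
            manifest["stages"][stage] = {
                "partner_pairs": len(records), "trans_hits": len(trans)
            }
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - name the failing stage
        raise PipelineError(stage, str(exc)) from exc
    finally:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        root.removeHandler(log_handler)
        log_handler.close()
    return outdir
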