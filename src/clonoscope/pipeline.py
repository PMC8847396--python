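"""End-to-end orchestration: ingest -> clonotype -> downstream stages.

One JSON config drives the run; every enabled stage writes its tables
under a stage-named subdirectory of the output directory, and a single
report JSON records parameters, row counts and filter reports.  Reruns
with identical config and inputs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from ._errors import ValidationError
from .clonotype import build_clones, clone_table
from .diversity import diversity_table
from .germline_usage import pairing_matrix, usage_correlation, usage_vector
from .model import EXPANDED, LOWLY_EXPANDED, Repertoire
from .overlap import overlap_matrix, public_clone_table
from .phenotype import (
    association_table,
    clone_cluster_composition,
    composition_table,
    expansion_cluster_association,
    stratum_composition,
)
from .similarity_network import build_network, edge_group_summary
from .vdj_io import assemble_cells, read_annotations, read_contigs

logger = logging.getLogger(__name__)

ALL_STAGES = ("clones", "diversity", "overlap", "network", "germline", "phenotype")


@dataclass
class SampleInput:
    contig_path: str
    dialect: str
    sample_id: str
    group_label: str


@dataclass
class PipelineConfig:
    samples: list[SampleInput]
    out_dir: str
    annotation_path: str | None = None
    stages: tuple = ALL_STAGES
    threshold: int = 7
    network_mode: str = "sum"
    top_n: int = 15
    label_threshold: int = 5
    correlation_method: str = "pearson"
    association_method: str = "fisher"
    overlap_restriction: str = "all"
    overlap_top_n: int = 10
    gene_space: str = "TRBV"
    usage_weighting: str = "per_cell"
    require_productive: bool = True
    require_cell: bool = True
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        samples = [SampleInput(**s) for s in raw.pop("samples")]
        raw["stages"] = tuple(raw.get("stages", ALL_STAGES))
        return cls(samples=samples, **raw)

    def effective_parameters(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "samples"}
        d["stages"] = list(self.stages)
        d["samples"] = [s.__dict__ for s in self.samples]
        return d


def _validate(config: PipelineConfig) -> None:
    """Pre-flight checks: fail before any computation starts."""
    ids = [s.sample_id for s in config.samples]
    if len(ids) != len(set(ids)):
        raise ValidationError(f"duplicate sample_ids in config: {sorted(ids)}")
    if not config.samples:
        raise ValidationError("config declares no samples")
    for s in config.samples:
        if not Path(s.contig_path).exists():
            raise ValidationError(f"contig file not found: {s.contig_path}")
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise ValidationError(f"unknown stages: {sorted(unknown)}")
    if "phenotype" in config.stages:
        if config.annotation_path is None:
            raise ValidationError("phenotype stage enabled but no annotation_path given")
        if not Path(config.annotation_path).exists():
            raise ValidationError(f"annotation file not found: {config.annotation_path}")


def _write(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all enabled stages in dependency order and return the report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    _validate(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "parameters": config.effective_parameters(),
        "stages": {},
    }

    # ingest + clonotype always run: everything downstream needs repertoires
    reps: list[Repertoire] = []
    ingest_info = {}
    for s in config.samples:
        records = read_contigs(s.contig_path, s.dialect, s.sample_id)
        cells, filt = assemble_cells(
            records,
            require_productive=config.require_productive,
            require_cell=config.require_cell,
        )
        rep = build_clones(cells, group_label=s.group_label, sample_id=s.sample_id)
        reps.append(rep)
        ingest_info[s.sample_id] = {
            "n_contigs": len(records),
            "filter_report": filt.as_dict(),
            "n_cells": rep.n_cells,
            "n_clones": rep.richness,
        }
    report["stages"]["ingest"] = ingest_info

    def _run_stage(name: str, fn) -> None:
        if name not in config.stages:
            report["stages"][name] = {"status": "skipped"}
            return
        try:
            info = fn()
            report["stages"][name] = {"status": "ok", **info}
        except Exception as exc:  # noqa: BLE001 - recorded, then re-raised
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            _write_report(report, out)
            raise

    def _clones_stage() -> dict:
        for rep in reps:
            _write(clone_table(rep), out / "clones" / f"{rep.sample_id}_clones.tsv")
        return {"n_repertoires": len(reps)}

    def _diversity_stage() -> dict:
        table = diversity_table(reps)
        _write(table, out / "diversity" / "diversity_summary.tsv")
        return {"n_rows": len(table)}

    def _overlap_stage() -> dict:
        kwargs = {}
        if config.overlap_restriction == "top_n":
            kwargs["n"] = config.overlap_top_n
        mat = overlap_matrix(reps, restriction=config.overlap_restriction, **kwargs)
        (out / "overlap").mkdir(parents=True, exist_ok=True)
        mat.write_tsv(out / "overlap" / "overlap_matrix.tsv")
        pub = public_clone_table(reps)
        _write(pub, out / "overlap" / "public_clones.tsv")
        return {"n_public_clones": len(pub)}

    def _network_stage() -> dict:
        net = build_network(reps, threshold=config.threshold, mode=config.network_mode)
        summary = edge_group_summary(net)
        _write(net.node_table(), out / "network" / "nodes.tsv")
        _write(net.edge_table(), out / "network" / "edges.tsv")
        _write(
            summary.group_pair_counts.reset_index(names="group"),
            out / "network" / "group_pair_edge_counts.tsv",
        )
        _write(summary.degree_table, out / "network" / "degrees.tsv")
        return {
            "n_nodes": net.n_nodes, "n_edges": net.n_edges,
            "within_group_edges": summary.within_group_edges,
            "between_group_edges": summary.between_group_edges,
        }

    def _germline_stage() -> dict:
        vectors = [
            usage_vector(r, gene_space=config.gene_space, weighting=config.usage_weighting)
            for r in reps
        ]
        usage = pd.DataFrame({v.sample_id: v.frequencies for v in vectors}).fillna(0.0)
        usage.index.name = "gene"
        _write(usage.reset_index(), out / "germline" / "usage_frequencies.tsv")
        for rep in reps:
            pm = pairing_matrix(rep, weighting=config.usage_weighting,
                                label_threshold=config.label_threshold)
            counts = pm.counts.reset_index(names="TRBV")
            _write(counts, out / "germline" / f"{rep.sample_id}_pairing.tsv")
            _write(pm.labeled_pairs(), out / "germline" / f"{rep.sample_id}_chord_pairs.tsv")
        info: dict = {"n_vectors": len(vectors)}
        if len(vectors) >= 2:
            corr, order = usage_correlation(vectors, method=config.correlation_method)
            corr.index.name = "sample_id"
            _write(corr.reset_index(), out / "germline" / "usage_correlation.tsv")
            info["dendrogram_order"] = order
        return info

    def _phenotype_stage() -> dict:
        annotations = read_annotations(config.annotation_path)
        info: dict = {}
        for rep in reps:
            comps = clone_cluster_composition(rep, annotations, top_n=config.top_n)
            _write(composition_table(comps),
                   out / "phenotype" / f"{rep.sample_id}_top_clone_composition.tsv")
            strata = []
            for stratum in (EXPANDED, LOWLY_EXPANDED):
                try:
                    strata.append(stratum_composition(rep, annotations, stratum))
                except ValidationError as exc:
                    logger.warning("%s: %s", rep.sample_id, exc)
            _write(composition_table(strata),
                   out / "phenotype" / f"{rep.sample_id}_stratum_composition.tsv")
            try:
                assoc = expansion_cluster_association(
                    rep, annotations, method=config.association_method
                )
                _write(association_table(assoc),
                       out / "phenotype" / f"{rep.sample_id}_association.tsv")
                info[rep.sample_id] = {"n_clusters_tested": len(assoc)}
            except ValidationError as exc:
                logger.warning("%s: association skipped (%s)", rep.sample_id, exc)
                info[rep.sample_id] = {"n_clusters_tested": 0}
        return info

    _run_stage("clones", _clones_stage)
    _run_stage("diversity", _diversity_stage)
    _run_stage("overlap", _overlap_stage)
    _run_stage("network", _network_stage)
    _run_stage("germline", _germline_stage)
    _run_stage("phenotype", _phenotype_stage)

    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
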