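"""End-to-end orchestration: DE test -> profiles -> enrichment -> network
-> optional qPCR, with a JSON run manifest.

Each stage writes a plain TSV so any stage can be re-run independently;
the manifest records every input, threshold and output checksum, and the
same configuration plus seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import network as net
from . import profiles as prof
from . import qpcr as qp
from . import rvm
from . import synthetic as synth
from .io_formats import (
    ExpressionMatrix,
    read_expression_matrix,
    read_gmt,
    read_qpcr_csv,
    read_sif,
    write_results_tables,
)

log = logging.getLogger("co2prof")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Everything a full run needs: inputs (files or a synthetic config)
    plus every stage threshold."""

    out_dir: str = "co2prof_out"
    seed: int = 0
    # inputs: either file paths or synthetic generation
    expression_path: str | None = None
    sample_sheet_path: str | None = None
    annotations_path: str | None = None
    annotations_namespace: str = "GO-BP"
    interactions_path: str | None = None
    qpcr_path: str | None = None
    qpcr_reference_gene: str = "actin"
    synth: synth.SyntheticConfig | None = None
    # stage thresholds
    p_max: float = 0.05
    fdr_max: float = 0.05
    alpha_profiles: float = 0.05
    min_corr: float | None = None
    enrich_p_max: float = 0.05
    enrich_re_min: float = 0.0
    network_alpha: float = 0.05
    top_k: int = 10

    def __post_init__(self) -> None:
        for name in ("p_max", "fdr_max", "alpha_profiles", "enrich_p_max", "network_alpha"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.synth is None and (
            self.expression_path is None or self.sample_sheet_path is None
        ):
            raise ValueError("either synth config or expression + sample sheet paths required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth_cfg = raw.pop("synth", None)
        cfg = cls(**raw, synth=synth.SyntheticConfig(**synth_cfg) if synth_cfg else None)
        return cfg


@dataclass
class PipelineResult:
    tables: dict[str, pd.DataFrame]
    manifest_path: str
    degs: list[str]
    significant_profiles: list[int]
    top_enriched: pd.DataFrame
    key_genes: pd.DataFrame
    truth: synth.TruthLabels | None = None


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute detest -> profiles -> enrichment -> signal-net -> (qpcr).

    Writes one TSV per stage plus a manifest under ``config.out_dir`` and
    returns the in-memory results.  Any stage failure raises
    :class:`StageError` naming the stage; tables produced so far are still
    written, alongside a FAILED marker file.
    """
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")
    tables: dict[str, pd.DataFrame] = {}
    truth: synth.TruthLabels | None = None
    try:
        # ingest ------------------------------------------------------------
        if config.synth is not None:
            matrix, truth = synth.generate_expression(config.synth)
            annotations, catalog = synth.generate_annotations(truth, config.synth)
            plate = None
        else:
            matrix = read_expression_matrix(config.expression_path, config.sample_sheet_path)
            annotations = (
                read_gmt(config.annotations_path, config.annotations_namespace)
                if config.annotations_path
                else None
            )
            catalog = read_sif(config.interactions_path) if config.interactions_path else None
            plate = (
                read_qpcr_csv(config.qpcr_path, config.qpcr_reference_gene)
                if config.qpcr_path
                else None
            )

        # differential expression ------------------------------------------
        de_results, degs = _run_detest(matrix, config)
        tables["de_results"] = de_results.reset_index()

        # profile clustering ------------------------------------------------
        stats, sig_profiles, study_genes = _run_profiles(matrix, degs, config)
        tables["profile_stats"] = stats.table

        # enrichment ---------------------------------------------------------
        if annotations is not None and study_genes:
            enriched = _run_enrichment(study_genes, matrix.probe_ids, annotations, config)
            tables["enrichment"] = enriched
        else:
            enriched = pd.DataFrame()

        # signal network -----------------------------------------------------
        if catalog is not None and study_genes:
            key_genes, node_table, edge_table = _run_network(
                matrix, study_genes, catalog, config
            )
            tables["network_nodes"] = node_table
            tables["network_edges"] = edge_table
            tables["key_genes"] = key_genes
        else:
            key_genes = pd.DataFrame()

        # qPCR validation ----------------------------------------------------
        if plate is not None:
            folds = qp.ddct_fold_change(plate, matrix.condition_order[0])
            tables["qpcr_folds"] = folds

        written = write_results_tables(
            tables, config.out_dir, parameters=_threshold_record(config), seed=config.seed
        )
        return PipelineResult(
            tables=tables,
            manifest_path=written["manifest"],
            degs=degs,
            significant_profiles=sig_profiles,
            top_enriched=enriched,
            key_genes=key_genes,
            truth=truth,
        )
    except StageError:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if tables:
            write_results_tables(tables, out, parameters=_threshold_record(config), seed=config.seed)
        (out / "FAILED").write_text("pipeline aborted; see logs\n")
        raise


@_stage("detest")
def _run_detest(matrix: ExpressionMatrix, config: PipelineConfig):
    prior = rvm.fit_rvm_prior(matrix)
    de_results = rvm.rvm_f_test(matrix, prior)
    degs = rvm.select_degs(de_results, p_max=config.p_max, q_max=config.fdr_max)
    log.info("detest: %d/%d genes selected (prior a=%.3f b=%.3f)",
             len(degs), len(de_results), prior.a, prior.b)
    return de_results, degs


@_stage("profiles")
def _run_profiles(matrix: ExpressionMatrix, degs: list[str], config: PipelineConfig):
    vectors = prof.log2_ratio_vectors(matrix, degs)
    profiles = prof.default_profiles(matrix.n_conditions)
    stats = prof.profile_stats(vectors, profiles, min_corr=config.min_corr)
    sig = prof.significant_profiles(stats, alpha=config.alpha_profiles)
    assignment, _ = prof.assign_profiles(vectors, profiles, min_corr=config.min_corr)
    study_genes = list(assignment.index[assignment.isin(sig)])
    log.info("profiles: %s significant; %d genes in significant profiles", sig, len(study_genes))
    return stats, sig, study_genes


@_stage("enrichment")
def _run_enrichment(study_genes, background, annotations, config: PipelineConfig):
    raw = enr.hypergeom_enrichment(study_genes, background, annotations)
    filtered = enr.filter_enriched(raw, p_max=config.enrich_p_max, re_min=config.enrich_re_min)
    log.info("enrichment: %d/%d categories pass", len(filtered), len(raw))
    return filtered


@_stage("signalnet")
def _run_network(matrix: ExpressionMatrix, study_genes, catalog, config: PipelineConfig):
    edges = net.correlation_edges(matrix, study_genes, alpha=config.network_alpha)
    network = net.build_signal_net(edges, catalog)
    key_genes = net.rank_key_genes(network, top_k=config.top_k)
    log.info("signalnet: %d nodes, %d edges", len(network.nodes), network.graph.number_of_edges())
    return key_genes, network.node_table(), network.edge_table()


def _threshold_record(config: PipelineConfig) -> dict[str, Any]:
    return {
        "p_max": config.p_max,
        "fdr_max": config.fdr_max,
        "de_thresholds_conjunctive": True,
        "alpha_profiles": config.alpha_profiles,
        "min_corr": config.min_corr,
        "enrich_p_max": config.enrich_p_max,
        "enrich_re_min": config.enrich_re_min,
        "network_alpha": config.network_alpha,
        "top_k": config.top_k,
        "synth": config.synth,
        "inputs": {
            "expression": config.expression_path,
            "sample_sheet": config.sample_sheet_path,
            "annotations": config.annotations_path,
            "interactions": config.interactions_path,
            "qpcr": config.qpcr_path,
        },
    }
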