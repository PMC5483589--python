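"""One-shot pipeline: targets -> enrichment -> module -> stratification -> benchmark.

``run_pipeline`` wires together the stages on files in the dialects the
package reads, validates every input before the first stage executes, and
writes all intermediate artifacts plus a machine-readable JSON report.
The report deliberately contains no timestamps: identical inputs and the
same master seed reproduce it byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .enrichment import common_targets, enrich_all, read_deg_table, read_gmt, split_targets
from .graph_core import read_sif
from .module_extraction import build_module, write_module_tables
from .random_benchmark import BenchmarkConfig, build_gene_pool, run_benchmark
from .survival_stratification import (
    SurvivalError,
    collapse_probes,
    read_expression,
    read_probe_map,
    read_survival,
    stratify,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    network: str
    deg_tables: list[str]
    gmt: str
    expression: str
    survival: str
    out_dir: str
    probe_map: str | None = None
    fdr_threshold: float = 0.05
    min_fraction: float = 0.125
    subtype_min_fraction: float = 0.25
    alpha: float = 0.05
    benchmark_n: int = 1000
    benchmark_size: int | None = None  # None = size of the mapped signature
    master_seed: int = 0
    time_unit: str = "years"
    min_subtype_patients: int = 16

    def validate(self) -> None:
        for p in [self.network, self.gmt, self.expression, self.survival, *self.deg_tables]:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.probe_map is not None and not Path(self.probe_map).exists():
            raise FileNotFoundError(self.probe_map)
        for name, v, lo, hi in [
            ("fdr_threshold", self.fdr_threshold, 0, 1),
            ("min_fraction", self.min_fraction, 0, 0.5),
            ("subtype_min_fraction", self.subtype_min_fraction, 0, 0.5),
            ("alpha", self.alpha, 0, 1),
        ]:
            if not (lo < v <= hi):
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")


@dataclass
class PipelineResult:
    report: dict
    report_path: Path
    artifacts: dict[str, Path] = field(default_factory=dict)


def _stratify_summary(res) -> dict:
    return {
        "n_clusters": int(res.n_clusters),
        "cluster_sizes": {str(k): int((res.assignment == k).sum()) for k in sorted(res.assignment.unique())},
        "logrank_chi_square": None if res.logrank is None else round(res.logrank.chi_square, 10),
        "logrank_df": None if res.logrank is None else res.logrank.df,
        "logrank_p": None if res.logrank is None else float(f"{res.logrank.pvalue:.10g}"),
        "survival_at_5y": {str(k): round(v, 10) for k, v in sorted(res.survival_at_5y.items())},
        "n_signature_mapped": int(res.n_signature_mapped),
        "n_signature_unmapped": len(res.unmapped_genes),
        "subtype_composition": {
            str(idx): {c: int(v) for c, v in row.items()}
            for idx, row in res.subtype_composition.iterrows()
        },
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage on the configured inputs and write a JSON report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # eager ingest: every input parsed before stage 1 runs
    log.info("stage 0: parsing inputs")
    net = read_sif(config.network)
    tables = [read_deg_table(p) for p in config.deg_tables]
    collection = read_gmt(config.gmt)
    expr = read_expression(config.expression)
    survival = read_survival(config.survival, time_unit=config.time_unit)
    probe_map = read_probe_map(config.probe_map) if config.probe_map else None
    if probe_map is not None:
        expr = collapse_probes(expr, probe_map)  # gene level from here on

    report: dict = {
        "version": __version__,
        "parameters": {
            "fdr_threshold": config.fdr_threshold,
            "min_fraction": config.min_fraction,
            "subtype_min_fraction": config.subtype_min_fraction,
            "alpha": config.alpha,
            "benchmark_n": config.benchmark_n,
            "master_seed": config.master_seed,
            "time_unit": config.time_unit,
        },
        "inputs": {
            "network_nodes": net.n_nodes,
            "network_edges": net.n_edges,
            "deg_tables": [t.comparison_label for t in tables],
            "gene_sets": len(collection),
            "expression_shape": list(expr.shape),
            "n_survival_records": int(len(survival)),
        },
    }
    artifacts: dict[str, Path] = {}

    log.info("stage 1: common targets")
    targets = common_targets(tables, config.fdr_threshold)
    lists = split_targets(targets)
    report["targets"] = {
        "n_common": len(targets),
        "n_up": len(lists.up),
        "n_down": len(lists.down),
    }
    tpath = out / "common_targets.tsv"
    pd.DataFrame(
        {"gene": sorted(targets), "log2fc": [targets[g] for g in sorted(targets)]}
    ).to_csv(tpath, sep="\t", index=False)
    artifacts["common_targets"] = tpath

    log.info("stage 2: enrichment")
    universe = set().union(*(t.genes for t in tables))
    enr = enrich_all(lists, collection, universe, mode="ora", alpha=config.alpha)
    epath = out / "enrichment.tsv"
    enr.to_csv(epath, sep="\t", index=False)
    artifacts["enrichment"] = epath
    report["enrichment"] = {
        "n_tests": int(enr["testable"].sum()),
        "n_significant": int(enr["significant"].sum()),
    }

    log.info("stage 3: module extraction")
    module = build_module(net, targets)
    write_module_tables(module, out / "module_nodes.tsv", out / "module_edges.tsv")
    artifacts["module_nodes"] = out / "module_nodes.tsv"
    artifacts["module_edges"] = out / "module_edges.tsv"
    report["module"] = {
        "n_terminals": len(module.terminals),
        "n_steiner": len(module.steiner_nodes),
        "n_total": module.n_nodes,
        "n_edges": module.subnetwork.n_edges,
    }
    signature = sorted(module.terminals | module.steiner_nodes)

    log.info("stage 4: whole-cohort stratification")
    strat = stratify(
        expr,
        survival,
        signature,
        min_fraction=config.min_fraction,
    )
    strat.assignment.to_frame().to_csv(out / "clusters.tsv", sep="\t")
    artifacts["clusters"] = out / "clusters.tsv"
    report["stratification"] = {"whole_cohort": _stratify_summary(strat)}

    log.info("stage 5: per-subtype stratification")
    report["stratification"]["per_subtype"] = {}
    counts = survival["subtype"].value_counts()
    for label in sorted(counts.index):
        if label == "unknown" or counts[label] < config.min_subtype_patients:
            continue
        try:
            sub = stratify(
                expr,
                survival,
                signature,
                min_fraction=config.subtype_min_fraction,
                subtype_filter=label,
            )
        except SurvivalError as exc:
            report["stratification"]["per_subtype"][label] = {"skipped": str(exc)}
            continue
        report["stratification"]["per_subtype"][label] = _stratify_summary(sub)

    log.info("stage 6: random-signature benchmark")
    pool = build_gene_pool(collection, {str(i).upper() for i in expr.index})
    size = config.benchmark_size or strat.n_signature_mapped
    bench_cfg = BenchmarkConfig(
        n_signatures=config.benchmark_n,
        signature_size=min(size, len(pool)),
        alpha=config.alpha,
        master_seed=config.master_seed,
        min_fraction=config.min_fraction,
    )
    original_p = strat.logrank.pvalue if strat.logrank is not None else None
    bench = run_benchmark(expr, survival, pool, bench_cfg, original_p=original_p)
    pd.DataFrame(
        {"signature_index": np.arange(len(bench.pvalues)), "logrank_p": bench.pvalues}
    ).to_csv(out / "benchmark_pvalues.tsv", sep="\t", index=False)
    artifacts["benchmark_pvalues"] = out / "benchmark_pvalues.tsv"
    report["benchmark"] = {
        "n_signatures": bench_cfg.n_signatures,
        "signature_size": bench_cfg.signature_size,
        "pool_size": len(pool),
        "frac_significant": round(bench.frac_significant, 10),
        "frac_outperforming": None
        if bench.frac_outperforming is None
        else round(bench.frac_outperforming, 10),
        "original_p": None if original_p is None else float(f"{original_p:.10g}"),
        "n_single_cluster": bench.n_single_cluster,
    }

    report_path = out / "report.json"
    with report_path.open("w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("pipeline complete: %s", report_path)
    return PipelineResult(report=report, report_path=report_path, artifacts=artifacts)
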