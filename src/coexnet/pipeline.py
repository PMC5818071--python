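"""End-to-end orchestration of the temporal coexpression analysis.

Per time point: preprocess, SAM differential expression, paired CTRL/HS
networks with CTRL-derived modules, connectivity rank change and module
preservation.  Jointly over all samples: one network, module eigengenes and
the module--trait relationship matrix against the case indicator and
one-vs-rest time-point indicators, plus GS-filtered hub/scatter tables.

All defaults equal the published procedural constants: soft threshold 10
(with an automatic check that the scale-free fit reaches 0.8), top 5000
most-variable genes, minimum module size 50, FDR target 10%, gold module of
1000 genes, 10 hubs per module, gene/module significance cutoffs 0.05/0.1.
Every stage logs its decisions and seeds so a report is self-describing.
"""

from __future__ import annotations

import dataclasses
import json
import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from coexnet.comparison import build_paired_networks, preservation_zsummary, rank_change, rank_connectivity
from coexnet.diffexpr import sam_permutation_fdr
from coexnet.module_stats import (
    gene_significance,
    gs_kwithin_scatter,
    module_eigengene,
    module_trait_matrix,
    top_hubs,
)
from coexnet.network import (
    GREY,
    adjacency,
    correlation_matrix,
    detect_modules,
    intramodular_connectivity,
    pick_soft_threshold,
    tom_similarity,
)
from coexnet.preprocess import filter_top_variable, quantile_normalize

__all__ = ["RunConfig", "run_timepoint_analysis", "run_joint_analysis", "run_full_analysis"]


@dataclass
class RunConfig:
    """Pipeline settings; defaults are the published procedural constants."""

    beta: float | str = 10.0  # fixed power, or "auto" to pick by scale-free fit
    target_r2: float = 0.8
    top_n_genes: int = 5000
    min_module_size: int = 50
    fdr_target: float = 0.10
    de_permutations: int = 200
    preservation_permutations: int = 100
    gold_size: int = 1000
    gs_p_cutoff: float = 0.05
    module_p_cutoff: float = 0.1
    hub_count: int = 10
    correlation: str = "bicor"
    quantile_normalize: bool = False  # synthetic data arrives normalised
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.fdr_target < 1):
            raise ValueError("fdr_target must be in (0, 1)")
        for name in ("gs_p_cutoff", "module_p_cutoff"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.top_n_genes < 1 or self.min_module_size < 2 or self.hub_count < 1:
            raise ValueError("counts must be positive (min_module_size >= 2)")
        if isinstance(self.beta, str) and self.beta != "auto":
            raise ValueError("beta must be a number or 'auto'")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        config = cls(**raw)
        config.validate()
        return config

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _validate_inputs(expr: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    for col in ("sample_id", "group", "timepoint"):
        if col not in samples.columns:
            raise ValueError(f"sample table lacks required column {col!r}")
    samples = samples.set_index("sample_id", drop=False)
    missing = [s for s in expr.columns if s not in samples.index]
    if missing:
        raise ValueError(f"samples missing from the metadata table: {missing[:5]}")
    return samples.loc[expr.columns]


def _resolve_beta(expr: pd.DataFrame, config: RunConfig, log: list[dict]) -> float:
    if config.beta == "auto":
        result = pick_soft_threshold(
            expr, target_r2=config.target_r2, method=config.correlation
        )
        log.append(
            {
                "stage": "soft_threshold",
                "beta": result.beta,
                "fit_index": result.fit_index,
                "reached_target": result.reached_target,
            }
        )
        return result.beta
    return float(config.beta)


def run_timepoint_analysis(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    config: RunConfig,
    timepoint: str,
    out_dir: str | os.PathLike | None = None,
) -> dict:
    """Paired CTRL/HS analysis for one time point.

    Returns a bundle with the DE result, paired networks, rank-change and
    preservation tables, hubs, and a structured log.  With ``out_dir`` the
    tables are also written as TSV plus a JSON summary.
    """
    config.validate()
    samples = _validate_inputs(expr, samples)
    sub = samples[samples["timepoint"] == timepoint]
    if sub.empty:
        raise ValueError(f"no samples at time point {timepoint!r}")
    expr = expr[sub["sample_id"]]
    log: list[dict] = [{"stage": "input", "timepoint": timepoint, "n_samples": len(sub)}]

    if config.quantile_normalize:
        expr = quantile_normalize(expr)
        log.append({"stage": "quantile_normalize"})
    expr = filter_top_variable(expr, config.top_n_genes)
    log.append({"stage": "variance_filter", "n_genes": expr.shape[0]})

    de = sam_permutation_fdr(
        expr,
        sub["group"],
        n_permutations=config.de_permutations,
        target_fdr=config.fdr_target,
        seed=config.seed,
    )
    log.append(
        {
            "stage": "differential_expression",
            "s0": de.s0,
            "selected_delta": de.selected_delta,
            "estimated_fdr": de.estimated_fdr,
            "n_called": len(de.called),
        }
    )

    ctrl_ids = sub.loc[sub["group"] == "CTRL", "sample_id"]
    hs_ids = sub.loc[sub["group"] == "HS", "sample_id"]
    beta = _resolve_beta(expr[ctrl_ids], config, log)
    paired = build_paired_networks(
        expr[ctrl_ids],
        expr[hs_ids],
        beta=beta,
        method=config.correlation,
        min_module_size=config.min_module_size,
    )
    log.append(
        {
            "stage": "paired_networks",
            "beta": beta,
            "modules": paired.assignment[paired.assignment != GREY].value_counts().to_dict(),
        }
    )

    stats_ref = intramodular_connectivity(paired.adjacency_ref, paired.assignment)
    stats_test = intramodular_connectivity(paired.adjacency_test, paired.assignment)
    ranks = rank_change(
        rank_connectivity(stats_ref), rank_connectivity(stats_test), paired.assignment
    )
    gold = min(config.gold_size, paired.adjacency_ref.shape[0])
    if gold < config.gold_size:
        warnings.warn(
            f"gold module reduced to {gold} genes (universe smaller than {config.gold_size})",
            stacklevel=2,
        )
    preservation = preservation_zsummary(
        paired,
        n_permutations=config.preservation_permutations,
        gold_size=gold,
        seed=config.seed,
    )
    hubs = top_hubs(stats_ref, n=config.hub_count)
    log.append({"stage": "comparison", "gold_size": gold})

    bundle = {
        "timepoint": timepoint,
        "de": de,
        "paired": paired,
        "stats_ref": stats_ref,
        "stats_test": stats_test,
        "rank_change": ranks,
        "preservation": preservation,
        "hubs": hubs,
        "log": log,
    }
    if out_dir is not None:
        _write_timepoint_bundle(bundle, out_dir)
    return bundle


def run_joint_analysis(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    config: RunConfig,
    out_dir: str | os.PathLike | None = None,
) -> dict:
    """Single network over all samples plus module--trait statistics."""
    config.validate()
    samples = _validate_inputs(expr, samples)
    log: list[dict] = [{"stage": "input", "n_samples": len(samples)}]
    if config.quantile_normalize:
        expr = quantile_normalize(expr)
    expr = filter_top_variable(expr, config.top_n_genes)
    log.append({"stage": "variance_filter", "n_genes": expr.shape[0]})

    beta = _resolve_beta(expr, config, log)
    adj = adjacency(correlation_matrix(expr, method=config.correlation), beta)
    assignment = detect_modules(tom_similarity(adj), min_module_size=config.min_module_size)
    log.append(
        {
            "stage": "network",
            "beta": beta,
            "modules": assignment[assignment != GREY].value_counts().to_dict(),
        }
    )

    eigengenes, varexp = module_eigengene(expr, assignment)
    traits = pd.DataFrame(index=expr.columns)
    traits["HS"] = (samples["group"] == "HS").astype(int).to_numpy()
    for tp in samples["timepoint"].unique():
        traits[f"timepoint_{tp}"] = (samples["timepoint"] == tp).astype(int).to_numpy()
    mt = module_trait_matrix(eigengenes, traits, p_threshold=config.module_p_cutoff)

    stats_table = intramodular_connectivity(adj, assignment)
    gs = gene_significance(expr, traits["HS"])
    stats_table = stats_table.join(gs)
    scatter, scatter_counts = gs_kwithin_scatter(stats_table, gs_p_cutoff=config.module_p_cutoff)
    significant_genes = stats_table[stats_table["GS_p"] <= config.gs_p_cutoff]
    hubs = top_hubs(stats_table, n=config.hub_count)
    log.append({"stage": "module_trait", "n_significant_genes": len(significant_genes)})

    bundle = {
        "assignment": assignment,
        "eigengenes": eigengenes,
        "variance_explained": varexp,
        "traits": traits,
        "module_trait": mt,
        "stats": stats_table,
        "scatter": scatter,
        "scatter_counts": scatter_counts,
        "significant_genes": significant_genes,
        "hubs": hubs,
        "log": log,
    }
    if out_dir is not None:
        _write_joint_bundle(bundle, out_dir)
    return bundle


def run_full_analysis(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    config: RunConfig,
    out_dir: str | os.PathLike,
) -> dict:
    """All per-time-point bundles plus the joint analysis, written to disk."""
    samples_idx = _validate_inputs(expr, samples)
    bundles = {}
    for tp in samples_idx["timepoint"].unique():
        bundles[tp] = run_timepoint_analysis(
            expr, samples, config, tp, out_dir=os.path.join(out_dir, "networks", tp)
        )
    bundles["joint"] = run_joint_analysis(
        expr, samples, config, out_dir=os.path.join(out_dir, "joint")
    )
    with open(os.path.join(out_dir, "config.yaml"), "w") as handle:
        yaml.safe_dump(config.to_dict(), handle)
    return bundles


def _dump_log(log: list[dict], path: str) -> None:
    with open(path, "w") as handle:
        for entry in log:
            handle.write(json.dumps(entry, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return str(obj)


def _write_timepoint_bundle(bundle: dict, out_dir: str | os.PathLike) -> None:
    os.makedirs(out_dir, exist_ok=True)
    de = bundle["de"]
    de_table = pd.DataFrame({"d": de.d, "s": de.s})
    de_table["called"] = de_table.index.isin(de.called.index)
    de_table["direction"] = de.called["direction"].reindex(de_table.index).fillna("")
    de_table.to_csv(os.path.join(out_dir, "de.tsv"), sep="\t")
    bundle["rank_change"].per_gene.to_csv(os.path.join(out_dir, "rank_change_genes.tsv"), sep="\t")
    bundle["rank_change"].per_module.to_csv(os.path.join(out_dir, "rank_change_modules.tsv"), sep="\t")
    bundle["preservation"].per_module.to_csv(os.path.join(out_dir, "preservation.tsv"), sep="\t")
    bundle["hubs"].to_csv(os.path.join(out_dir, "hubs.tsv"), sep="\t")
    bundle["stats_ref"].to_csv(os.path.join(out_dir, "gene_stats_ctrl.tsv"), sep="\t")
    bundle["stats_test"].to_csv(os.path.join(out_dir, "gene_stats_hs.tsv"), sep="\t")
    _dump_log(bundle["log"], os.path.join(out_dir, "log.jsonl"))


def _write_joint_bundle(bundle: dict, out_dir: str | os.PathLike) -> None:
    os.makedirs(out_dir, exist_ok=True)
    bundle["eigengenes"].to_csv(os.path.join(out_dir, "eigengenes.tsv"), sep="\t")
    bundle["module_trait"]["correlation"].to_csv(os.path.join(out_dir, "module_trait_cor.tsv"), sep="\t")
    bundle["module_trait"]["p_value"].to_csv(os.path.join(out_dir, "module_trait_p.tsv"), sep="\t")
    bundle["stats"].to_csv(os.path.join(out_dir, "gene_stats.tsv"), sep="\t")
    bundle["scatter"].to_csv(os.path.join(out_dir, "gs_kwithin_scatter.tsv"), sep="\t")
    bundle["hubs"].to_csv(os.path.join(out_dir, "hubs.tsv"), sep="\t")
    _dump_log(bundle["log"], os.path.join(out_dir, "log.jsonl"))
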