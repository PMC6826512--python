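"""End-to-end orchestration: load inputs, run every analysis, write reports.

``run_full_analysis`` reproduces the whole result battery from a config:
clock categorization counts, all Mann-Whitney trait contrasts, pairwise
independence tests, group rate summaries, the clade-age calibration
window, and — when a network is supplied — centralities, corrected
importances, community partitions by all four methods with their Q
values, the bipartition rate scan, and centrality-rate correlations.
Reports are written as JSON (machine) and TSV (tabular); rerunning with
the same config and seed reproduces them byte-identically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import calibration, network as net
from .core import (
    DEFAULT_CLOCK_THRESHOLD,
    TraitTable,
    categorize_clock,
    packaged_fixture,
    read_trait_table,
)
from .stats import run_trait_contrasts

__all__ = ["run_full_analysis", "load_config", "DEFAULT_CONFIG"]

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "traits": None,              # path to a trait table TSV, or "table4"/"table5"
    "bias_table": None,          # optional second table carrying bias labels
    "network": {"edges": None, "attrs": None},
    "clock_threshold": DEFAULT_CLOCK_THRESHOLD,
    "calibration_exclude": ["nsr"],
    "contrast_traits": ["sex_biased", "duplicated", "in_network", "clock_like"],
    "permutation_reps": 9999,
    "seed": 0,
    "community_methods": ["fast_greedy", "louvain", "edge_betweenness"],
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = {**DEFAULT_CONFIG, **user}
    if isinstance(user.get("network"), Mapping):
        cfg["network"] = {**DEFAULT_CONFIG["network"], **user["network"]}
    return cfg


def _resolve_traits(spec) -> TraitTable:
    if isinstance(spec, TraitTable):
        return spec
    if spec in ("table1", "table3", "table4", "table5"):
        return read_trait_table(packaged_fixture(spec))
    return read_trait_table(spec)


def _testresult_row(name: str, res) -> dict:
    row = {"contrast": name, **{k: v for k, v in res.statistics.items()}}
    row["n_groups"] = "/".join(str(n) for n in res.n_per_group)
    row["p_value"] = res.p_value
    row["p_method"] = res.p_method
    return row


def run_full_analysis(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Run the configured analyses and write ``report.json`` plus TSVs.

    Returns the report dict.  Raises before any computation when required
    inputs are missing.
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    cfg = {**DEFAULT_CONFIG, **config}
    if cfg["traits"] is None:
        raise ValueError("config must name a trait table ('traits')")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    table = _resolve_traits(cfg["traits"])
    threshold = float(cfg["clock_threshold"])
    table = categorize_clock(table, threshold=threshold)

    report: dict = {
        "config": {k: v for k, v in cfg.items() if k != "traits"},
        "provenance": table.provenance,
        "n_genes": len(table),
        "defaults_in_effect": {
            "clock_threshold": threshold,
            "tie_rule": "0.5 per cross-group tied pair",
            "permutation_estimator": "add-one",
        },
    }

    # clock categorization counts
    clock = table.column("clock_like")
    report["clock_categorization"] = {
        "clocklike": int((clock == True).sum()),  # noqa: E712 (pandas boolean)
        "heterogeneous": int((clock == False).sum()),  # noqa: E712
        "unclassified": int(clock.isna().sum()),
        "threshold": threshold,
    }

    # bias label counts if a bias table is provided
    if cfg.get("bias_table"):
        bias_tab = _resolve_traits(cfg["bias_table"])
        labels = bias_tab.column("bias_label")
        report["bias_labels"] = {
            "n_genes": len(bias_tab),
            "n_sex_biased": int((labels != "unbiased").sum()),
            "counts": labels.value_counts().to_dict(),
        }

    # trait contrasts + independence battery
    traits = [t for t in cfg["contrast_traits"] if table.has_column(t)]
    battery = run_trait_contrasts(
        table,
        traits,
        reps=int(cfg["permutation_reps"]),
        seed=int(cfg["seed"]),
    )
    report["contrasts"] = {k: r.to_dict() for k, r in battery["contrasts"].items()}
    report["independence"] = {k: r.to_dict() for k, r in battery["independence"].items()}
    report["contrast_groups"] = battery["groups"]

    # group rate summaries
    report["group_summaries"] = {
        trait: calibration.group_rate_summary(table, trait).to_dict(orient="index")
        for trait in traits
    }

    # calibration window, when age CIs are present
    if table.has_column("age_low"):
        try:
            selected = calibration.select_calibration_set(
                table, exclude=cfg["calibration_exclude"]
            )
            window = calibration.concordant_overlap([iv for _, iv in selected])
            report["calibration"] = {
                "n_intervals": len(selected),
                "genes": [g for g, _ in selected],
                "excluded": list(cfg["calibration_exclude"]),
                "window_low": window.low,
                "window_high": window.high,
                "prior": calibration.normal_calibration(
                    (window.low + window.high) / 2.0,
                    (window.high - window.low) / 4.0,
                ).to_dict(),
            }
        except ValueError as exc:
            log.warning("calibration skipped: %s", exc)

    # network analyses
    net_cfg = cfg.get("network") or {}
    if net_cfg.get("edges"):
        graph = net.read_edge_list(net_cfg["edges"], net_cfg.get("attrs"))
        rates = dict(graph.rates)
        if not rates:  # fall back to the trait table's rates
            df = table.df.dropna(subset=["rate"])
            rates = {
                g: r for g, r in zip(df["gene"], df["rate"]) if g in graph.graph
            }
        nrep: dict = {
            "n_nodes": graph.n_nodes,
            "n_edges": graph.n_edges,
            "closeness": net.closeness_centrality(graph),
            "eigen": net.eigen_centrality(graph),
        }
        if graph.total_interactions:
            nrep["corrected_closeness"] = net.importance_vector(
                graph, "closeness", corrected=True
            )
            nrep["corrected_eigen"] = net.importance_vector(
                graph, "eigen", corrected=True
            )
        partitions = {}
        for method in cfg["community_methods"]:
            p = net.communities(graph, method=method, seed=int(cfg["seed"]))
            partitions[method] = {
                "assignment": dict(sorted(p.assignment.items())),
                "n_communities": p.n_communities,
                "Q": net.modularity(graph, p),
            }
            scans = net.bipartition_scan(graph, p, rates=rates)
            partitions[method]["bipartition_scan"] = [
                {
                    "cut_edge": list(s.cut_edge),
                    "side_a": list(s.side_a),
                    "side_b": list(s.side_b),
                    **s.result.to_dict(),
                }
                for s in scans
            ]
            try:
                partitions[method]["module_rate_test"] = net.module_rate_test(
                    graph, p, rates=rates
                ).to_dict()
            except ValueError as exc:
                log.warning("module rate test (%s) skipped: %s", method, exc)
        nrep["partitions"] = partitions
        correlations = {}
        for measure in ("closeness", "eigen"):
            for corrected in (False, True):
                if corrected and not graph.total_interactions:
                    continue
                key = f"{measure}{'_corrected' if corrected else ''}"
                try:
                    correlations[key] = net.centrality_rate_tests(
                        graph, rates=rates, measure=measure, corrected=corrected
                    ).to_dict()
                except (ValueError, KeyError) as exc:
                    log.warning("centrality-rate test %s skipped: %s", key, exc)
        nrep["centrality_rate_correlations"] = correlations
        report["network"] = nrep

    _write_reports(report, out_dir)
    return report


def _write_reports(report: dict, out_dir: Path) -> None:
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    rows = [
        _restat(name, res) for name, res in report.get("contrasts", {}).items()
    ] + [
        _restat(name, res) for name, res in report.get("independence", {}).items()
    ]
    if rows:
        pd.DataFrame(rows).to_csv(out_dir / "contrasts.tsv", sep="\t", index=False)


def _restat(name: str, res: dict) -> dict:
    return {
        "contrast": name,
        **res["statistics"],
        "n_per_group": "/".join(str(n) for n in res["n_per_group"]),
        "p_value": res["p_value"],
        "p_method": res["p_method"],
    }
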