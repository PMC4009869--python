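"""End-to-end gap-character analysis: code gaps from an alignment, filter
by indel length, estimate trees under parsimony and corrected binary
likelihood, fit the nucleotide and combined partitioned models, and
quantify congruence — emitting a machine-readable report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional

import numpy as np

from . import gap_coding, likelihood, parsimony, treecompare
from .io_formats import Alignment, write_character_matrix, write_tree
from .trees import Tree

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    alignment: Alignment
    output_dir: Path
    seed: int = 0
    terminal_policy: str = "missing"
    length_filters: tuple[int, ...] = (1, 2, 3)  # min indel length per level
    ratchet_iterations: int = 10
    ratchet_swap: str = "spr"
    mp_bootstrap_replicates: int = 30
    ml_restarts: int = 1
    ml_gamma: bool = False
    ml_bootstrap_replicates: int = 0
    augmentation_grid: tuple[int, ...] = (0, 20, 200, 2000)
    run_combined: bool = True

    def __post_init__(self):
        if list(self.length_filters) != sorted(set(self.length_filters)):
            raise PipelineError("length_filters must be strictly increasing")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the report dict (also written to
    ``output_dir/report.json`` with trees and matrices beside it)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "settings": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
            if k not in ("alignment", "output_dir")
        },
        "stages": {},
    }

    def stage(name):
        def wrap(fn):
            try:
                report["stages"][name] = fn()
            except Exception as exc:
                _write_report(report, out)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    aln = config.alignment
    full_matrix = gap_coding.simple_indel_coding(aln, config.terminal_policy)
    levels: dict[str, gap_coding.GapCharacterMatrix] = {}
    trees_by_name: dict[str, Tree] = {}
    support_by_name: dict[str, treecompare.SupportTable] = {}

    @stage("gap_coding")
    def _code():
        result = {}
        for f in config.length_filters:
            m = gap_coding.filter_by_indel_length(full_matrix, f)
            name = "all" if f == 1 else f"gt{f - 1}bp"
            levels[name] = m
            write_character_matrix(m, out / f"gaps_{name}.nex")
            m.character_table().to_csv(out / f"gaps_{name}.tsv", sep="\t", index=False)
            result[name] = gap_coding.informative_counts(m)
        return result

    @stage("parsimony")
    def _mp():
        result = {}
        for name, m in levels.items():
            cfg = parsimony.RatchetConfig(
                iterations=config.ratchet_iterations,
                swap=config.ratchet_swap,
                seed=int(rng.integers(2**31 - 1)),
            )
            search = parsimony.ratchet_search(m, cfg)
            trees_by_name[f"mp_{name}"] = search.tree
            write_tree(search.tree, out / f"mp_{name}.nwk")
            boot = parsimony.mp_bootstrap(
                m,
                config.mp_bootstrap_replicates,
                replace(cfg, iterations=max(2, cfg.iterations // 3)),
                seed=int(rng.integers(2**31 - 1)),
            )
            support_by_name[f"mp_{name}"] = boot
            result[name] = {
                "best_length": search.length,
                "n_best_trees": len(search.trees),
                "bootstrap_replicates": config.mp_bootstrap_replicates,
            }
        return result

    @stage("likelihood_gaps")
    def _ml():
        result = {}
        gamma = 1.0 if config.ml_gamma else None
        for name, m in levels.items():
            model = likelihood.ModelSpec(
                "cfn", gamma_shape=gamma, correction="conditional"
            )
            search = likelihood.ml_search(
                m,
                model,
                likelihood.MLSearchConfig(
                    restarts=config.ml_restarts, seed=int(rng.integers(2**31 - 1))
                ),
            )
            trees_by_name[f"ml_{name}"] = search.tree
            write_tree(search.tree, out / f"ml_{name}.nwk")
            m_star, table, _ = likelihood.estimate_invariant_augmentation(
                m,
                search.tree,
                grid=config.augmentation_grid,
                model=likelihood.ModelSpec("cfn", gamma_shape=gamma),
                refine=False,
                optimize_model=config.ml_gamma,
            )
            table.to_csv(out / f"augmentation_{name}.tsv", sep="\t", index=False)
            entry = {
                "lnl": search.lnl,
                "m_star": int(m_star),
                "tree_length": search.tree.total_length(),
            }
            if config.ml_bootstrap_replicates:
                boot = likelihood.ml_bootstrap(
                    m,
                    config.ml_bootstrap_replicates,
                    model,
                    likelihood.MLSearchConfig(
                        restarts=1, seed=int(rng.integers(2**31 - 1))
                    ),
                )
                support_by_name[f"ml_{name}"] = boot
                entry["bootstrap_replicates"] = config.ml_bootstrap_replicates
            result[name] = entry
        return result

    @stage("likelihood_nucleotides")
    def _nuc():
        gamma = 1.0 if config.ml_gamma else None
        model = likelihood.ModelSpec("gtr", gamma_shape=gamma)
        search = likelihood.ml_search(
            aln,
            model,
            likelihood.MLSearchConfig(
                restarts=config.ml_restarts, seed=int(rng.integers(2**31 - 1))
            ),
        )
        trees_by_name["nuc"] = search.tree
        write_tree(search.tree, out / "nuc.nwk")
        return {"lnl": search.lnl, "tree_length": search.tree.total_length()}

    @stage("combined")
    def _combined():
        if not config.run_combined:
            return {"skipped": True}
        gamma = 1.0 if config.ml_gamma else None
        gap_model = likelihood.ModelSpec("cfn", gamma_shape=gamma, correction="conditional")
        nuc_model = likelihood.ModelSpec("gtr", gamma_shape=gamma)
        pm = likelihood.PartitionedModel(
            [
                likelihood.Partition(aln, nuc_model, 1.0),
                likelihood.Partition(levels["all"], gap_model, 0.2),
            ]
        )
        tree, fitted, lnl = likelihood.optimize_partitioned(
            trees_by_name["nuc"].copy(), pm, optimize_model=config.ml_gamma
        )
        trees_by_name["combined"] = tree
        write_tree(tree, out / "combined.nwk")
        return {
            "lnl": lnl,
            "gap_rate_multiplier": fitted.partitions[1].rate_multiplier,
        }

    @stage("comparisons")
    def _compare():
        result: dict = {"rf_distances": {}, "support_classes": {}}
        names = sorted(trees_by_name)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if set(trees_by_name[a].taxa) == set(trees_by_name[b].taxa):
                    result["rf_distances"][f"{a}__{b}"] = treecompare.rf_distance(
                        trees_by_name[a], trees_by_name[b]
                    )
        # retention indices of every matrix on the gap and nucleotide ML trees
        ri = {}
        for topo in ("ml_all", "nuc"):
            if topo not in trees_by_name:
                continue
            for name, m in levels.items():
                h = parsimony.homoplasy_indices(trees_by_name[topo], m)
                ri[f"{name}_on_{topo}"] = h.ensemble_ri
            h = parsimony.homoplasy_indices(trees_by_name[topo], aln)
            ri[f"nucleotides_on_{topo}"] = h.ensemble_ri
        result["retention_indices"] = ri
        # support comparison between the two coarsest gap levels
        mp_names = [n for n in support_by_name if n.startswith("mp_")]
        if len(mp_names) >= 2:
            tab = treecompare.compare_support(
                support_by_name[mp_names[0]], support_by_name[mp_names[1]]
            )
            tab.to_csv(out / "support_comparison.tsv", sep="\t", index=False)
            result["support_classes"] = tab["class"].value_counts().to_dict()
        # rate-converted gap tree and branch-length correlation
        if "ml_all" in trees_by_name and "nuc" in trees_by_name:
            m_star = report["stages"]["likelihood_gaps"]["all"]["m_star"]
            n_gap = levels["all"].n_characters + m_star
            converted = treecompare.gap_rate_convert(
                trees_by_name["ml_all"], n_gap, aln.n_columns
            )
            write_tree(converted, out / "ml_all_rate_converted.nwk")
            result["gap_rate_scale"] = n_gap / aln.n_columns
            comp = treecompare.branch_length_compare(
                trees_by_name["nuc"], trees_by_name["ml_all"]
            )
            comp.pairs.to_csv(out / "branch_length_pairs.tsv", sep="\t", index=False)
            result["branch_length_correlation"] = comp.correlation
            result["branch_length_pairs"] = len(comp.pairs)
        return result

    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    (out / "report.json").write_text(json.dumps(report, indent=2, default=_json_safe))


def _json_safe(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
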