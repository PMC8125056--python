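"""Config-driven orchestration of the full analysis.

Order of stages mirrors the intended reading of the methods: diversity
statistics run on the rarefied counts; the network branch runs on relative
abundances of the same rarefied table after the low-abundance filter. One
master seed is expanded deterministically into per-stage seeds, all of which
are logged in the run report.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, io, network, preprocess, simulate
from .containers import OtuTable, SampleMetadata

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]

logger = logging.getLogger(__name__)

_STAGE_SEEDS = ("simulate", "otu_tree", "rarefy", "permanova", "mantel_diet", "mantel_phylo", "alpha_tests")


@dataclass
class PipelineConfig:
    """Everything one run needs; serialisable to/from YAML."""

    # either file inputs ...
    otu_table: str | None = None
    metadata: str | None = None
    host_tree: str | None = None
    otu_tree: str | None = None
    orientation: str = "samples-as-rows"
    # ... or simulation
    simulate: dict | None = None  # SimConfig overrides; {} = study-scale defaults

    rarefaction_depth: int = 5000
    min_mean_relabund: float = 1e-4
    abundance_criterion: str = "mean"
    rho_min: float = 0.6
    q_max: float = 0.01
    min_component_size: int = 4
    sc_method: str = "components"
    permanova_permutations: int = 999
    mantel_permutations: int = 9999
    alpha_test_permutations: int = 999
    adjust_method: str = "bh"
    seed: int = 0
    out_dir: str = "otunet_out"

    def validate(self) -> None:
        has_files = self.otu_table is not None
        if has_files == (self.simulate is not None):
            raise ValueError("config must give either file inputs or a 'simulate' section, not both")
        if has_files and self.metadata is None:
            raise ValueError("file inputs require a metadata sheet")
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")
        if not 0 <= self.min_mean_relabund < 1:
            raise ValueError("min_mean_relabund must be in [0, 1)")
        if not 0 < self.rho_min <= 1 or not 0 < self.q_max <= 1:
            raise ValueError("network thresholds out of range")
        if self.min_component_size < 1:
            raise ValueError("min_component_size must be >= 1")
        if self.adjust_method != "bh":
            raise ValueError("only Benjamini-Hochberg adjustment is supported")
        for attr in ("permanova_permutations", "mantel_permutations", "alpha_test_permutations"):
            if getattr(self, attr) < 1:
                raise ValueError(f"{attr} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def stage_seeds(self) -> dict[str, int]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGE_SEEDS))
        return {
            name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
            for name, child in zip(_STAGE_SEEDS, children)
        }


@dataclass
class RunReport:
    """Per-stage provenance plus the run's headline results."""

    config: dict
    stage_seeds: dict
    stages: list[dict] = field(default_factory=list)
    headline: dict = field(default_factory=dict)

    def add_stage(self, name: str, *, params: dict, items_in: dict, items_out: dict, seconds: float) -> None:
        self.stages.append(
            {
                "stage": name,
                "params": params,
                "items_in": items_in,
                "items_out": items_out,
                "wall_seconds": round(seconds, 3),
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "stage_seeds": self.stage_seeds,
                "stages": self.stages,
                "headline": self.headline,
            },
            indent=2,
            default=str,
        )


class _Timer:
    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.seconds = time.perf_counter() - self.t0


def _write_pcoa(res: diversity.PcoaResult, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# eigenvalues\t" + "\t".join(repr(v) for v in res.eigenvalues) + "\n")
        fh.write(
            "# proportion_explained\t" + "\t".join(repr(v) for v in res.proportion_explained) + "\n"
        )
        res.coordinates.to_csv(fh, sep="\t", index_label="sample_id")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage in order and write all outputs under ``config.out_dir``."""
    config.validate()
    seeds = config.stage_seeds()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(config), stage_seeds=seeds)

    # --- ingest or simulate -------------------------------------------------
    with _Timer() as t:
        otu_tree = None
        if config.simulate is not None:
            sim_cfg = simulate.SimConfig(seed=seeds["simulate"], **config.simulate)
            table, meta, host_tree, truth = simulate.simulate_dataset(sim_cfg)
            otu_tree = simulate.simulate_tree(table.n_otus, seeds["otu_tree"], names=table.otu_ids)
            truth.block_table().to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        else:
            table = io.read_otu_table(config.otu_table, config.orientation)
            meta = io.read_metadata(config.metadata)
            host_tree = io.read_newick(config.host_tree) if config.host_tree else None
            otu_tree = io.read_newick(config.otu_tree) if config.otu_tree else None
        meta.require_samples(table.sample_ids)
    report.add_stage(
        "ingest",
        params={"simulated": config.simulate is not None},
        items_in={},
        items_out={"samples": table.n_samples, "otus": table.n_otus},
        seconds=t.seconds,
    )

    # --- prevalence structure ----------------------------------------------
    prev = preprocess.prevalence_summary(table)
    prev.prevalence.to_csv(out / "prevalence.tsv", sep="\t", header=["prevalence"], index_label="otu_id")

    # --- rarefaction ---------------------------------------------------------
    with _Timer() as t:
        rarefied = preprocess.rarefy(table, config.rarefaction_depth, seeds["rarefy"])
    report.add_stage(
        "rarefy",
        params={"depth": config.rarefaction_depth, "seed": seeds["rarefy"]},
        items_in={"samples": table.n_samples, "otus": table.n_otus},
        items_out={
            "samples": rarefied.n_samples,
            "otus": rarefied.n_otus,
            "samples_dropped": table.n_samples - rarefied.n_samples,
        },
        seconds=t.seconds,
    )
    io.write_otu_table(rarefied, out / "rarefied.tsv")
    groups = meta.diet_groups(rarefied.sample_ids)

    # --- alpha diversity -----------------------------------------------------
    with _Timer() as t:
        alpha = diversity.alpha_diversity(rarefied, tree=otu_tree)
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", index_label="sample_id")
        rows = []
        for metric in alpha.columns:
            for ga, gb in itertools.combinations(sorted(groups.unique()), 2):
                x = alpha.loc[groups[groups == ga].index, metric]
                y = alpha.loc[groups[groups == gb].index, metric]
                if len(x) < 2 or len(y) < 2:
                    continue
                p = diversity.permutation_t_test(
                    x, y, n_permutations=config.alpha_test_permutations, seed=seeds["alpha_tests"]
                )
                rows.append({"metric": metric, "group_a": ga, "group_b": gb, "p_value": p})
        alpha_tests = pd.DataFrame(rows, columns=["metric", "group_a", "group_b", "p_value"])
        if len(alpha_tests):
            alpha_tests["p_adjusted"] = network.bh_adjust(alpha_tests["p_value"].to_numpy())
        alpha_tests.to_csv(out / "alpha_comparisons.tsv", sep="\t", index=False)
    report.add_stage(
        "alpha_diversity",
        params={"permutations": config.alpha_test_permutations, "seed": seeds["alpha_tests"]},
        items_in={"samples": rarefied.n_samples},
        items_out={"metrics": len(alpha.columns), "comparisons": len(alpha_tests)},
        seconds=t.seconds,
    )

    # --- beta diversity ------------------------------------------------------
    with _Timer() as t:
        bc = diversity.bray_curtis(rarefied)
        pd.DataFrame(bc.data, index=list(bc.ids), columns=list(bc.ids)).to_csv(
            out / "bray_curtis.tsv", sep="\t", index_label="sample_id"
        )
        pcoa_res = diversity.pcoa(bc)
        _write_pcoa(pcoa_res, out / "pcoa.tsv")
        perm = diversity.permanova(bc, groups, config.permanova_permutations, seeds["permanova"])
        pd.DataFrame([asdict(perm)]).to_csv(out / "permanova.tsv", sep="\t", index=False)
        io.write_newick(diversity.upgma(bc), out / "upgma.nwk")
    report.add_stage(
        "beta_diversity",
        params={"permutations": config.permanova_permutations, "seed": seeds["permanova"]},
        items_in={"samples": rarefied.n_samples},
        items_out={"axes": pcoa_res.coordinates.shape[1]},
        seconds=t.seconds,
    )

    # --- Mantel tests --------------------------------------------------------
    mantel_rows = []
    with _Timer() as t:
        diet_dm = diversity.diet_distance_matrix(meta, rarefied.sample_ids)
        res = diversity.mantel(bc, diet_dm, n_permutations=config.mantel_permutations, seed=seeds["mantel_diet"])
        mantel_rows.append({"predictor": "diet", **asdict(res)})
        if host_tree is not None:
            host_dm = diversity.host_patristic_distance_matrix(host_tree, meta, rarefied.sample_ids)
            res = diversity.mantel(
                bc, host_dm, n_permutations=config.mantel_permutations, seed=seeds["mantel_phylo"]
            )
            mantel_rows.append({"predictor": "phylogeny", **asdict(res)})
        mantel_df = pd.DataFrame(mantel_rows)
        mantel_df.to_csv(out / "mantel.tsv", sep="\t", index=False)
    report.add_stage(
        "mantel",
        params={"permutations": config.mantel_permutations},
        items_in={"samples": rarefied.n_samples},
        items_out={"predictors": len(mantel_rows)},
        seconds=t.seconds,
    )

    # --- co-occurrence network ----------------------------------------------
    with _Timer() as t:
        rel = preprocess.to_relative(rarefied)
        filtered, removed = preprocess.filter_low_abundance(
            rel, config.min_mean_relabund, criterion=config.abundance_criterion
        )
        corr = network.spearman_matrix(filtered)
        net = network.build_network(corr, config.rho_min, config.q_max)
        nodes_before = net.n_nodes
        pruned = network.prune_network(net, config.min_component_size)
        scs = network.extract_subcommunities(pruned, method=config.sc_method)
        io.write_network(pruned, out / "network_edges.tsv", format="edge-list")
        io.write_network(pruned, out / "network.graphml", format="graphml")
        pd.DataFrame(
            [{"otu_id": o, "sc_label": sc.label} for sc in scs for o in sc.members]
        ).to_csv(out / "sc_membership.tsv", sep="\t", index=False)
    report.add_stage(
        "network",
        params={
            "min_mean_relabund": config.min_mean_relabund,
            "rho_min": config.rho_min,
            "q_max": config.q_max,
            "min_component_size": config.min_component_size,
        },
        items_in={"otus": rel.n_otus},
        items_out={
            "otus_filtered": len(removed),
            "otus_kept": filtered.n_otus,
            "nodes_built": nodes_before,
            "nodes": pruned.n_nodes,
            "edges": pruned.n_edges,
            "subcommunities": len(scs),
        },
        seconds=t.seconds,
    )

    # --- SC sample statistics and group comparisons --------------------------
    with _Timer() as t:
        if scs:
            stats_ = network.sc_sample_stats(filtered, scs)
            stats_.long_format().to_csv(out / "sc_sample_stats.tsv", sep="\t", index=False)
            comparisons = network.compare_sc_groups(stats_, meta)
        else:
            comparisons = pd.DataFrame(
                columns=["group_a", "group_b", "sc_label", "metric", "statistic", "p_raw", "p_adjusted"]
            )
        comparisons.to_csv(out / "sc_comparisons.tsv", sep="\t", index=False)
    report.add_stage(
        "sc_statistics",
        params={"adjust": config.adjust_method},
        items_in={"subcommunities": len(scs), "samples": rarefied.n_samples},
        items_out={"comparisons": len(comparisons)},
        seconds=t.seconds,
    )

    report.headline = {
        "samples_analyzed": rarefied.n_samples,
        "otus_observed": int((rarefied.counts.sum(axis=0) > 0).sum()),
        "otus_after_filter": filtered.n_otus,
        "fraction_otus_prevalence_below_20pct": prev.fraction_below(0.2),
        "pc1_percent_variance": float(100 * pcoa_res.proportion_explained[0]),
        "permanova_r2": perm.r_squared,
        "permanova_p": perm.p_value,
        "mantel": {row["predictor"]: {"r": row["r"], "p": row["p_value"]} for row in mantel_rows},
        "network_nodes": pruned.n_nodes,
        "network_edges": pruned.n_edges,
        "n_subcommunities": len(scs),
        "sc_significant_comparisons": int((comparisons["p_adjusted"] < 0.05).sum()) if len(comparisons) else 0,
    }
    (out / "report.json").write_text(report.to_json(), encoding="utf-8")
    return report
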