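"""End-to-end pipeline: classify -> tier -> network -> modules -> concordance.

``run_analysis`` executes the whole chain on in-memory inputs and returns a
machine-readable report (all the per-stage counts and percentages) plus the
intermediate artifacts.  ``run_pipeline`` is the file-driven wrapper used by
the command line: it loads (or simulates) the inputs named in a
:class:`PipelineConfig`, runs the analysis, and serializes the report and
intermediates.  Every randomized stage takes its seed from the config, so a
fixed-seed run is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import concordance as cc
from . import core_model, funcnet, io, module_finder, reliability
from .core_model import ClassificationThresholds, DOWN, UP
from .synthworld import World, WorldConfig, generate_world

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of one pipeline run; round-trips through YAML."""

    # input: either a world directory written by the simulator...
    world_dir: Optional[str] = None
    # ...or a seed to simulate one on the fly
    simulate_seed: Optional[int] = None
    out_dir: Optional[str] = None

    up_min: float = 1.5
    down_max: float = 0.67
    reference_rule: str = "and"
    score_min: float = 0.0
    tau: float = module_finder.DEFAULT_TAU
    min_size: int = module_finder.DEFAULT_MIN_SIZE
    alpha_module: float = module_finder.DEFAULT_ALPHA
    detection_alpha: float = 0.05
    k: int = 5
    delta: float = cc.DEFAULT_DELTA
    kmeans_seed: int = 0
    path_pairs: str = "all"

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _round(x: Optional[float], digits: int = 6) -> Optional[float]:
    if x is None:
        return None
    return float(round(float(x), digits))


def run_analysis(
    abundance: pd.DataFrame,
    catalog: reliability.ReferenceCatalog,
    links: pd.DataFrame,
    annotations: Mapping[str, frozenset],
    intensities: pd.DataFrame,
    detection_p: pd.DataFrame,
    conditions: Mapping[str, str],
    config: PipelineConfig,
) -> Tuple[Dict, Dict]:
    """Run the full analysis on in-memory inputs.

    Returns ``(report, artifacts)``: the report is a JSON-serializable
    nested dict of every stage's counts and percentages; the artifacts dict
    holds the intermediate objects (classified table, tiers, networks,
    modules, profiles, partition) for serialization or further analysis.
    """
    thresholds = ClassificationThresholds(up_min=config.up_min, down_max=config.down_max)

    # 1. classification
    classified = core_model.classify_table(abundance, thresholds)
    summary = core_model.summarize_classes(classified)
    classes = dict(zip(classified["protein_id"], classified["regulation"]))

    # 2. reliability tiering
    tier_ref = reliability.assign_reference_tier(
        classified["protein_id"], catalog, rule=config.reference_rule
    )
    tiers = reliability.assign_link_tiers(classified["protein_id"], tier_ref, links)
    tier_report = reliability.reliability_report(tiers)

    # 3. functional network and major component
    net = funcnet.build_network(tiers.reliable, links, classes, score_min=config.score_min)
    major, excluded = funcnet.largest_component(net)

    # 4. link statistics
    link_summary, edge_table = funcnet.categorize_links(major)
    intra_fracs, inter_fracs = funcnet.link_fraction_samples(major)
    fraction_test = (
        funcnet.mann_whitney_u(intra_fracs, inter_fracs, alternative=funcnet.GREATER)
        if intra_fracs
        else None
    )
    paths = funcnet.shortest_path_samples(major, pairs=config.path_pairs)
    path_test = (
        funcnet.mann_whitney_u(
            paths.same_class, paths.opposite_class, alternative=funcnet.LESS
        )
        if paths.same_class and paths.opposite_class
        else None
    )

    # 5. module detection
    sim, order = module_finder.similarity_from_network(major)
    cluster_set = module_finder.upgma_cluster(
        sim, order, tau=config.tau, min_size=config.min_size
    )
    modules = module_finder.assemble_modules(
        cluster_set, annotations, classes, order, alpha=config.alpha_module
    )
    coverage = module_finder.module_coverage(modules, classes, order)

    # 6. concordance
    log2_expr = np.log2(intensities)
    normalized = cc.quantile_normalize(log2_expr)
    filtered, n_filtered = cc.detection_filter(
        normalized, detection_p, conditions, alpha=config.detection_alpha
    )
    mrna = cc.mrna_log2_ratios(filtered, conditions)
    profiles = cc.profile_table(classified, mrna)
    partition = cc.kmeans_partition(
        profiles, k=config.k, seed=config.kmeans_seed, delta=config.delta
    )
    profiles = cc.assign_groups(profiles, partition)
    module_expr = cc.module_expression_summary(modules, profiles)

    report = {
        "classification": {
            "n_total": summary.n_total,
            "n_up": summary.n_up,
            "n_down": summary.n_down,
            "n_unchanged": summary.n_unchanged,
            "percentages": summary.percentages(),
        },
        "reliability": {
            row["tier"]: {"count": int(row["count"]), "percent": row["percent"]}
            for _, row in tier_report.iterrows()
        },
        "network": {
            "n_nodes": net.number_of_nodes(),
            "n_edges": net.number_of_edges(),
            "major_component_nodes": major.number_of_nodes(),
            "major_component_edges": major.number_of_edges(),
            "n_excluded": len(excluded),
        },
        "links": {
            "n_intra": link_summary.n_intra,
            "n_inter": link_summary.n_inter,
            "n_other": link_summary.n_other,
            "n_regulatory": link_summary.n_regulatory,
            "intra_pct_of_regulatory": link_summary.intra_pct_of_regulatory,
            "mean_intra_fraction": _round(np.mean(intra_fracs)) if intra_fracs else None,
            "mean_inter_fraction": _round(np.mean(inter_fracs)) if inter_fracs else None,
            "fraction_test_p": _round(fraction_test.p_value, 12) if fraction_test else None,
        },
        "paths": {
            "n_same_class_pairs": len(paths.same_class),
            "n_opposite_class_pairs": len(paths.opposite_class),
            "mean_same_class": _round(np.mean(paths.same_class)) if paths.same_class else None,
            "mean_opposite_class": _round(np.mean(paths.opposite_class))
            if paths.opposite_class
            else None,
            "path_test_p": _round(path_test.p_value, 12) if path_test else None,
        },
        "modules": {
            "n_clusters": len(cluster_set.clusters),
            "n_unassigned": len(cluster_set.unassigned),
            "n_modules": len(modules),
            "n_up_modules": sum(1 for m in modules if m.regulation_label == UP),
            "n_down_modules": sum(1 for m in modules if m.regulation_label == DOWN),
            "coverage": coverage,
            "table": [
                {
                    "module_id": m.module_id,
                    "size": len(m.members),
                    "regulation_label": m.regulation_label,
                    "representative_term": m.representative_term,
                    "term_p": _round(m.term_p, 12),
                    "regulation_p": _round(m.regulation_p, 12),
                    "n_opposing": m.n_opposing,
                }
                for m in modules
            ],
        },
        "concordance": {
            "n_genes_filtered": n_filtered,
            "n_profiles": len(profiles),
            "group_sizes": partition.group_sizes(),
            "n_positive": partition.n_positive,
            "n_negative": partition.n_negative,
            "inertia": _round(partition.inertia),
            "module_expression": [
                {
                    "module_id": row["module_id"],
                    "regulation_label": row["regulation_label"],
                    "n": int(row["n"]),
                    "protein_mean": _round(row["protein_mean"], 4),
                    "protein_sd": _round(row["protein_sd"], 4)
                    if not math.isnan(row["protein_sd"])
                    else None,
                    "mrna_mean": _round(row["mrna_mean"], 4),
                    "mrna_sd": _round(row["mrna_sd"], 4)
                    if not math.isnan(row["mrna_sd"])
                    else None,
                    "protein_up": bool(row["protein_up"]),
                    "mrna_up": bool(row["mrna_up"]),
                }
                for _, row in module_expr.iterrows()
            ],
        },
    }
    artifacts = {
        "classified": classified,
        "tiers": tiers,
        "network": net,
        "major": major,
        "excluded": excluded,
        "edge_table": edge_table,
        "cluster_set": cluster_set,
        "modules": modules,
        "profiles": profiles,
        "partition": partition,
        "module_expression": module_expr,
    }
    return report, artifacts


def run_pipeline(config: PipelineConfig) -> Dict:
    """File-driven end-to-end run.

    Loads the input tables from ``config.world_dir`` (or simulates a world
    from ``config.simulate_seed``), runs :func:`run_analysis`, and — when
    ``config.out_dir`` is set — writes ``report.json`` plus the classified
    abundance, edge-category, module, and profile tables.  Any stage error
    is re-raised annotated with the stage name.
    """
    if config.world_dir is not None:
        base = Path(config.world_dir)
        with open(base / "manifest.json", encoding="utf-8") as fh:
            manifest = json.load(fh)
        paths = manifest["paths"]
        abundance = io.read_abundance(base / paths["abundance"])
        catalog = io.read_catalog(base / paths["catalog"])
        links = io.read_links(base / paths["links"])
        ann_df = io.read_annotations(base / paths["annotations"])
        intensities, detection_p = io.read_expression(
            base / paths["intensities"], base / paths["detection_p"]
        )
        conditions = manifest["conditions"]
    elif config.simulate_seed is not None:
        world = generate_world(WorldConfig(seed=config.simulate_seed))
        abundance, catalog, links = world.abundance, world.catalog, world.links
        ann_df = world.annotations
        intensities, detection_p = world.intensities, world.detection_p
        conditions = world.conditions
    else:
        raise ValueError("config needs either world_dir or simulate_seed")

    annotations: Dict[str, set] = {}
    for pid, term in zip(ann_df["protein_id"], ann_df["term_id"]):
        annotations.setdefault(pid, set()).add(term)
    annotations = {p: frozenset(t) for p, t in annotations.items()}

    try:
        report, artifacts = run_analysis(
            abundance,
            catalog,
            links,
            annotations,
            intensities,
            detection_p,
            conditions,
            config,
        )
    except Exception as exc:  # annotate failures with context for the CLI
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_abundance(artifacts["classified"], out / "classified.tsv")
        artifacts["edge_table"].to_csv(out / "edge_categories.tsv", sep="\t", index=False)
        io.write_modules(artifacts["modules"], out / "modules.tsv")
        io.write_profiles(artifacts["profiles"], out / "profiles.tsv")
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
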