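"""End-to-end pipeline orchestration: simulate -> survey -> drought ->
diversity -> stats -> guilds -> network, with a machine-readable report.

Every stage writes its tables under the output directory and contributes
a JSON-serializable section to the run report; identical configuration
and seeds yield byte-identical reports.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mosscrust import io as mio
from mosscrust import __version__
from mosscrust.community import (
    OtuTable,
    alpha_diversity,
    bray_curtis,
    core_and_exclusive,
    nmds,
    unweighted_unifrac,
    upgma,
)
from mosscrust.config import SimulationConfig
from mosscrust.drought import (
    classify_resistance,
    comprehensive_score,
    grey_relational_grades,
    membership_transform,
    replicate_means,
)
from mosscrust.guilds import assign_guilds, guild_profile
from mosscrust.network import build_network, network_metrics, select_top_features
from mosscrust.simulate import (
    generate_guild_rules,
    generate_microbiome,
    generate_physiology,
    generate_survey,
)
from mosscrust.stats import factor_taxon_heatmap, gradient_length_select, lefse, permanova
from mosscrust.survey import dominance_indices, select_candidates, summarize_dominants

ALL_STAGES = ("simulate", "survey", "drought", "diversity", "stats", "guilds", "network")

DROUGHT_COVARIATES = ["SOD", "Pro", "POD", "MP", "MDA"]


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "results/pipeline"
    stages: tuple[str, ...] = ALL_STAGES
    alpha: float = 0.05
    lda_cut: float = 2.0
    rho_cut: float = 0.6
    p_cut: float = 0.01
    top_k_dominants: int = 20
    top_n_genera: int = 50
    dca_boundary: float = 3.5
    n_perm: int = 999
    nmds_restarts: int = 20
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not 0 < self.alpha < 1 or not 0 < self.p_cut < 1:
            raise ValueError("alpha and p_cut must lie in (0, 1)")
        if not 0 < self.rho_cut < 1:
            raise ValueError("rho_cut must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.simulation)


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the requested stages in dependency order and write report.json."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {
            k: v
            for k, v in asdict(config).items()
            if k not in ("stages", "simulation")
        },
    }
    sim_cfg = config.simulation_config()
    state: dict = {}

    stage_fns = {
        "simulate": _stage_simulate,
        "survey": _stage_survey,
        "drought": _stage_drought,
        "diversity": _stage_diversity,
        "stats": _stage_stats,
        "guilds": _stage_guilds,
        "network": _stage_network,
    }
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        try:
            report[stage] = stage_fns[stage](config, sim_cfg, state, out)
        except Exception as exc:  # noqa: BLE001 - abort names stage and cause
            raise StageError(f"stage {stage!r} failed: {exc}") from exc

    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(_round_floats(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _require_sim(config, sim_cfg, state) -> None:
    if "microbiome" not in state:
        state["survey_sim"] = generate_survey(sim_cfg)
        state["physio_sim"] = generate_physiology(sim_cfg)
        state["microbiome"] = generate_microbiome(sim_cfg)
        state["guild_rules"] = generate_guild_rules(sim_cfg, state["microbiome"].taxonomy)


def _stage_simulate(config, sim_cfg, state, out: Path) -> dict:
    _require_sim(config, sim_cfg, state)
    sim = state["microbiome"]
    mio.write_survey_tsv(state["survey_sim"].dataset, out / "survey.tsv")
    mio.write_physiology_tsv(state["physio_sim"].values, out / "physiology.tsv")
    mio.write_otu_tsv(sim.table, out / "otu_counts.tsv")
    mio.write_taxonomy_tsv(sim.taxonomy, out / "taxonomy.tsv")
    mio.write_metadata_tsv(sim.metadata, out / "metadata.tsv")
    if sim.tree is not None:
        mio.write_tree_newick(sim.tree, out / "tree.nwk")
    state["guild_rules"].rules.to_csv(out / "guild_rules.tsv", sep="\t", index=False)
    return {
        "n_samples": len(sim.table.sample_ids),
        "n_features": len(sim.table.feature_ids),
        "n_survey_records": len(state["survey_sim"].dataset.records),
        "files": [
            "survey.tsv",
            "physiology.tsv",
            "otu_counts.tsv",
            "taxonomy.tsv",
            "metadata.tsv",
            "tree.nwk",
            "guild_rules.tsv",
        ],
    }


def _stage_survey(config, sim_cfg, state, out: Path) -> dict:
    _require_sim(config, sim_cfg, state)
    dataset = state["survey_sim"].dataset
    table = dominance_indices(dataset)
    table.to_csv(out / "dominance.tsv", sep="\t")
    top_k = min(config.top_k_dominants, len(table))
    summary = summarize_dominants(table, top_k)
    candidates = select_candidates(table, frequency_rank_cut=top_k, coverage_cut=None)
    return {
        "n_species_observed": len(table),
        "top_k": top_k,
        "sn_over_s_total": summary["sn_over_s_total"],
        "na_over_ta_total": summary["na_over_ta_total"],
        "top_species": summary["species"][:10],
        "candidates": candidates[:10],
    }


def _stage_drought(config, sim_cfg, state, out: Path) -> dict:
    _require_sim(config, sim_cfg, state)
    physio = state["physio_sim"]
    means = replicate_means(physio.values)
    z = membership_transform(means, physio.directions)
    scores = comprehensive_score(z)
    grades = grey_relational_grades(scores["score"], z.loc[scores.index])
    labels = classify_resistance(scores["score"])
    scores.assign(resistance_class=labels).to_csv(out / "drought_scores.tsv", sep="\t")
    grades.to_csv(out / "grey_relation.tsv", sep="\t")
    return {
        "ranking": list(scores.index),
        "scores": {sp: float(s) for sp, s in scores["score"].items()},
        "classes": labels.to_dict(),
        "index_grade_order": list(grades.index),
        "truth_ranking": physio.truth_ranking,
    }


def _stage_diversity(config, sim_cfg, state, out: Path) -> dict:
    _require_sim(config, sim_cfg, state)
    sim = state["microbiome"]
    alpha = alpha_diversity(
        sim.table, metrics=("chao1", "shannon", "goods_coverage", "faith_pd"), tree=sim.tree
    )
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
    bc = bray_curtis(sim.table)
    uf = unweighted_unifrac(sim.table, sim.tree)
    mio.write_distance_tsv(bc, out / "bray_curtis.tsv")
    mio.write_distance_tsv(uf, out / "unweighted_unifrac.tsv")
    ordination = nmds(uf, restarts=config.nmds_restarts, seed=config.seed)
    ordination.coordinates.to_csv(out / "nmds.tsv", sep="\t")
    dendro = upgma(uf)
    (out / "upgma.nwk").write_text(dendro.newick + "\n")
    groups = sim.metadata["moss_species"] + "-" + sim.metadata["desert_class"]
    venn = core_and_exclusive(sim.table, groups)
    with open(out / "venn_regions.json", "w") as fh:
        json.dump(
            {"|".join(k): v for k, v in venn.regions.items() if v > 0},
            fh, indent=2, sort_keys=True,
        )
    state["unifrac"] = uf
    state["bray"] = bc
    return {
        "alpha_mean": alpha.mean().to_dict(),
        "nmds_stress": ordination.stress,
        "core_otus": venn.core,
        "exclusive_otus": venn.exclusive,
    }


def _stage_stats(config, sim_cfg, state, out: Path) -> dict:
    _require_sim(config, sim_cfg, state)
    sim = state["microbiome"]
    dist = state["bray"] if "bray" in state else bray_curtis(sim.table)
    design = sim.metadata
    terms = DROUGHT_COVARIATES + ["desert_class", "moss_species", "desert_class:moss_species"]
    perm = permanova(dist, design, terms=terms, n_perm=config.n_perm, seed=config.seed)
    perm.to_csv(out / "permanova.tsv", sep="\t")
    markers = lefse(
        sim.table,
        sim.taxonomy,
        sim.metadata["moss_species"],
        alpha=config.alpha,
        lda_cut=config.lda_cut,
        seed=config.seed,
    )
    markers.to_csv(out / "biomarkers.tsv", sep="\t", index=False)
    choice = gradient_length_select(sim.table, boundary=config.dca_boundary)
    heat = factor_taxon_heatmap(
        sim.table,
        sim.metadata.drop(columns=["moss_species", "desert_class"]),
        taxonomy=sim.taxonomy,
        top_n=config.top_n_genera,
    )
    heat.rho.to_csv(out / "heatmap_rho.tsv", sep="\t")
    heat.stars.to_csv(out / "heatmap_stars.tsv", sep="\t")
    return {
        "permanova": {
            term: {"R2": float(row["R2"]), "p": float(row["p"])}
            for term, row in perm.iterrows()
            if term not in ("Residual", "Total")
        },
        "n_biomarkers": len(markers),
        "ordination_method": choice["method"],
        "dca_axis1_length": choice["axis1_length"],
    }


def _stage_guilds(config, sim_cfg, state, out: Path) -> dict:
    _require_sim(config, sim_cfg, state)
    sim = state["microbiome"]
    rules = state["guild_rules"]
    assignment = assign_guilds(sim.taxonomy, rules.rules, min_confidence="possible")
    profile = guild_profile(sim.table, assignment)
    profile.to_csv(out / "guild_profile.tsv", sep="\t")
    mean_profile = profile.mean().sort_values(ascending=False)
    return {
        "n_guilds": int((profile.columns != "unassigned").sum()),
        "mean_profile": mean_profile.to_dict(),
    }


def _stage_network(config, sim_cfg, state, out: Path) -> dict:
    _require_sim(config, sim_cfg, state)
    sim = state["microbiome"]
    genus_attrs = (
        sim.taxonomy.groupby("genus").first()[["phylum"]]
        if "genus" in sim.taxonomy.columns
        else None
    )
    top = select_top_features(sim.table, sim.taxonomy, rank="genus", n=config.top_n_genera)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = build_network(top, rho_cut=config.rho_cut, p_cut=config.p_cut, node_attrs=genus_attrs)
    net.edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
    metrics = network_metrics(net)
    metrics.node_table.to_csv(out / "network_nodes.tsv", sep="\t")
    summary = {
        "n_nodes": net.graph.number_of_nodes(),
        "n_edges": int(len(net.edges)),
        "n_positive": net.n_positive,
        "n_negative": net.n_negative,
        "average_path_length": metrics.average_path_length,
        "diameter": metrics.diameter,
        "transitivity": metrics.transitivity,
        "modularity": metrics.modularity,
        "n_major_modules": len(metrics.major_modules),
        "keystone_taxa": metrics.keystone_taxa,
    }
    with open(out / "network_metrics.json", "w") as fh:
        json.dump(_round_floats(summary), fh, indent=2, sort_keys=True)
    return summary
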