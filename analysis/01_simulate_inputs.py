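"""Generate the study's input files: quadrat survey, drought physiology,
OTU tables with taxonomy/metadata/tree, and a guild rule table.

The synthetic design mirrors the field study: 14 survey sites (185
quadrats), 7 candidate mosses x 5 physiological indexes, and 18 microbiome
samples = 2 moss species (Hyp, Hyo) x 3 karst desertification classes
(Ve, Se, Sl) x 3 composite replicates, with the moss-species community
effect stronger than the class effect. Everything downstream reads the
plain-text files written here.
"""

import sys
from pathlib import Path

from mosscrust import io as mio
from mosscrust.config import SimulationConfig
from mosscrust.simulate import (
    generate_guild_rules,
    generate_microbiome,
    generate_physiology,
    generate_survey,
)

OUT = Path("results/data")


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=seed)

    survey = generate_survey(cfg)
    mio.write_survey_tsv(survey.dataset, OUT / "survey.tsv")

    physio = generate_physiology(cfg)
    mio.write_physiology_tsv(physio.values, OUT / "physiology.tsv")
    (OUT / "physiology_truth.txt").write_text("\n".join(physio.truth_ranking) + "\n")

    micro = generate_microbiome(cfg)
    mio.write_otu_tsv(micro.table, OUT / "otu_counts.tsv")
    mio.write_taxonomy_tsv(micro.taxonomy, OUT / "taxonomy.tsv")
    mio.write_metadata_tsv(micro.metadata, OUT / "metadata.tsv")
    mio.write_tree_newick(micro.tree, OUT / "tree.nwk")

    rules = generate_guild_rules(cfg, micro.taxonomy)
    rules.rules.to_csv(OUT / "guild_rules.tsv", sep="\t", index=False)

    n_reads = micro.table.counts.to_numpy().sum()
    print(f"survey: {len(survey.dataset.records)} presence records over "
          f"{survey.dataset.total_quadrats} quadrats at {cfg.n_sites} sites")
    print(f"physiology: {cfg.n_physio_species} species x 5 indexes x {cfg.n_replicates} replicates")
    print(f"microbiome: {cfg.n_samples} samples x {cfg.n_features} OTUs, {n_reads:,} reads total")
    print(f"planted: {cfg.n_planted_biomarkers} biomarker genera (fold {cfg.biomarker_fold:g}), "
          f"{cfg.n_modules} co-abundance modules of {cfg.module_size} genera")
    print(f"inputs written under {OUT}/")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
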