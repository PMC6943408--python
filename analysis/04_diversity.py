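"""Alpha and beta diversity of the moss microbiome.

Per-sample Chao1, Shannon, Good's coverage and Faith PD; Bray-Curtis and
unweighted UniFrac distances; NMDS ordination (Kruskal stress-1); UPGMA
dendrogram; shared/exclusive OTU (Venn) decomposition over the six
species-by-class groups.
"""

import json
from pathlib import Path

from mosscrust import io as mio
from mosscrust.community import (
    alpha_diversity,
    bray_curtis,
    core_and_exclusive,
    nmds,
    read_newick,
    unweighted_unifrac,
    upgma,
)

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    table = mio.read_otu_tsv(DATA / "otu_counts.tsv")
    meta = mio.read_metadata_tsv(DATA / "metadata.tsv")
    tree = read_newick(DATA / "tree.nwk")

    alpha = alpha_diversity(
        table, ("chao1", "shannon", "goods_coverage", "faith_pd"), tree=tree
    )
    alpha.round(4).to_csv(OUT / "alpha_diversity.tsv", sep="\t")
    print(f"alpha diversity over {len(alpha)} samples: "
          f"Chao1 mean {alpha.chao1.mean():.0f}, Shannon mean {alpha.shannon.mean():.2f}, "
          f"Good's coverage min {100 * alpha.goods_coverage.min():.2f}%")

    bc = bray_curtis(table)
    uf = unweighted_unifrac(table, tree)
    mio.write_distance_tsv(bc, OUT / "bray_curtis.tsv")
    mio.write_distance_tsv(uf, OUT / "unweighted_unifrac.tsv")

    ordination = nmds(uf, restarts=20, seed=0)
    ordination.coordinates.round(4).to_csv(OUT / "nmds_coordinates.tsv", sep="\t")
    print(f"NMDS on unweighted UniFrac: stress {ordination.stress:.3f}")

    dendro = upgma(uf)
    (OUT / "upgma.nwk").write_text(dendro.newick + "\n")

    groups = meta["moss_species"] + "-" + meta["desert_class"]
    venn = core_and_exclusive(table, groups)
    with open(OUT / "venn_regions.json", "w") as fh:
        json.dump({"|".join(k): v for k, v in venn.regions.items() if v > 0},
                  fh, indent=2, sort_keys=True)
    print(f"core OTUs shared by all {len(venn.exclusive)} groups: {venn.core}; "
          f"exclusive counts {venn.exclusive}")


if __name__ == "__main__":
    main()
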