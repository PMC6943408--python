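"""Factor decomposition and biomarker discovery.

PERMANOVA partitions Bray-Curtis distances over the drought indexes, the
desertification class, the moss species and their interaction (sequential
SS, 999 permutations). LEfSe-style screening reports taxa enriched in one
moss species (KW p < 0.05, LDA score > 2.0). The DCA axis-1 gradient
length picks RDA or CCA, whose permutation tests rank the covariates; the
top-50 genera get a Spearman correlation heatmap against all factors.
"""

from pathlib import Path

from mosscrust import io as mio
from mosscrust.stats import (
    constrained_ordination,
    factor_taxon_heatmap,
    gradient_length_select,
    lefse,
    permanova,
)
from mosscrust.community import bray_curtis

DATA = Path("results/data")
OUT = Path("results")

TERMS = ["SOD", "Pro", "POD", "MP", "MDA",
         "desert_class", "moss_species", "desert_class:moss_species"]


def main() -> None:
    table = mio.read_otu_tsv(DATA / "otu_counts.tsv")
    taxonomy = mio.read_taxonomy_tsv(DATA / "taxonomy.tsv")
    meta = mio.read_metadata_tsv(DATA / "metadata.tsv")

    # one single-factor PERMANOVA per influence, plus the species-by-class
    # interaction from the two-factor sequential model
    import pandas as pd

    dist = bray_curtis(table)
    rows = []
    for term in TERMS[:-1]:
        one = permanova(dist, meta, terms=[term], n_perm=999, seed=0)
        rows.append(one.loc[term])
    both = permanova(
        dist, meta, terms=["desert_class", "moss_species", "desert_class:moss_species"],
        n_perm=999, seed=0,
    )
    rows.append(both.loc["desert_class:moss_species"])
    res = pd.DataFrame(rows)
    res.round(4).to_csv(OUT / "permanova.tsv", sep="\t")
    sp, cl = res.loc["moss_species"], res.loc["desert_class"]
    print(f"PERMANOVA (marginal): moss species R2={sp.R2:.3f} (p={sp.p:.3f}), "
          f"desertification class R2={cl.R2:.3f} (p={cl.p:.3f})")

    markers = lefse(table, taxonomy, meta["moss_species"], alpha=0.05, lda_cut=2.0, seed=0)
    markers.round(4).to_csv(OUT / "biomarkers.tsv", sep="\t", index=False)
    by_class = markers.groupby("enriched_class").size().to_dict()
    print(f"LEfSe: {len(markers)} biomarkers across "
          f"{markers.level.nunique()} taxonomic levels, enriched {by_class}")

    choice = gradient_length_select(table)
    print(f"DCA axis-1 gradient length {choice['axis1_length']:.3f} SD -> {choice['method']}")
    covs = meta.drop(columns=["moss_species", "desert_class"])
    ordn = constrained_ordination(table, covs, method=choice["method"], n_perm=199, seed=0)
    ordn["marginal"].round(4).to_csv(OUT / "ordination_covariates.tsv", sep="\t")
    sig = ordn["marginal"].query("p <= 0.05").sort_values("p")
    print(f"{choice['method']} covariates with p <= 0.05: {', '.join(sig.index) or 'none'}")

    heat = factor_taxon_heatmap(table, covs, taxonomy=taxonomy, top_n=50)
    heat.rho.round(3).to_csv(OUT / "heatmap_rho.tsv", sep="\t")
    heat.stars.to_csv(OUT / "heatmap_stars.tsv", sep="\t")
    n_sig = (heat.stars != "").to_numpy().sum()
    print(f"heatmap: {n_sig} genus-factor pairs starred of {heat.rho.size}")


if __name__ == "__main__":
    main()
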