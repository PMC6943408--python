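"""Plain-text readers and writers for the pipeline's tabular formats.

All tables are TSV. OTU counts are written features x samples with a
header row of sample ids; taxonomy as (feature_id, semicolon-delimited
7-rank lineage); trees as Newick.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from mosscrust.community import OtuTable
from mosscrust.simulate import TAXONOMY_RANKS


def write_survey_tsv(dataset, path) -> None:
    df = dataset.records.copy()
    if dataset.coverage is not None:
        df["coverage"] = df["species_id"].map(dataset.coverage)
    df.to_csv(path, sep="\t", index=False)


def write_physiology_tsv(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t", index=False)


def read_physiology_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"species", "index", "replicate", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"physiology table missing columns: {sorted(missing)}")
    return df


def write_taxonomy_tsv(taxonomy: pd.DataFrame, path) -> None:
    lineage = taxonomy[list(TAXONOMY_RANKS)].astype(str).agg(";".join, axis=1)
    pd.DataFrame({"feature_id": taxonomy.index, "lineage": lineage.values}).to_csv(
        path, sep="\t", index=False
    )


def read_taxonomy_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    parts = df["lineage"].str.split(";", expand=True)
    parts.columns = list(TAXONOMY_RANKS)[: parts.shape[1]]
    parts.index = pd.Index(df["feature_id"], name="feature_id")
    return parts


def write_metadata_tsv(metadata: pd.DataFrame, path) -> None:
    metadata.rename_axis("sample_id").to_csv(path, sep="\t")


def read_metadata_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tree_newick(tree, path) -> None:
    tree.write(str(path))


def write_otu_tsv(table: OtuTable, path) -> None:
    table.to_tsv(path)


def read_otu_tsv(path) -> OtuTable:
    return OtuTable.from_tsv(path)


def write_distance_tsv(dist, path) -> None:
    pd.DataFrame(dist.data, index=list(dist.ids), columns=list(dist.ids)).to_csv(path, sep="\t")
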