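"""Dominance indices of bryophyte quadrat surveys.

Four indices rank species by prevalence across a quadrat survey:

* species frequency = 100 * S_N / total quadrats,
* S_N / S   (quadrats with the species over total samples collected),
* S_N / N_a (quadrats with the species over sites with the species),
* N_a / T_a (sites with the species over total sites).

Note the mixed ratio S_N/S: S_N counts quadrats while S counts collected
samples; the survey this models collected 675 samples over 185 quadrats,
and its published table is consistent with this reading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SurveyDataset:
    """Presence records of species in quadrats nested in sites."""

    records: pd.DataFrame  # columns: site_id, quadrat_id, species_id
    total_quadrats: int
    total_samples: int  # S
    total_sites: int  # T_a
    coverage: pd.Series | None = None  # optional per-species cover fraction

    def __post_init__(self) -> None:
        required = {"site_id", "quadrat_id", "species_id"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")
        if self.total_samples < 0 or self.total_sites <= 0 or self.total_quadrats <= 0:
            raise ValueError("totals must be positive")
        n_pairs = self.records[["site_id", "quadrat_id"]].drop_duplicates().shape[0]
        if self.total_quadrats < n_pairs:
            raise ValueError(
                f"total_quadrats ({self.total_quadrats}) < distinct (site, quadrat) pairs ({n_pairs})"
            )

    @classmethod
    def from_tsv(
        cls, path, total_quadrats: int, total_samples: int, total_sites: int
    ) -> "SurveyDataset":
        df = pd.read_csv(path, sep="\t")
        coverage = None
        if "coverage" in df.columns:
            coverage = df.groupby("species_id")["coverage"].first()
        return cls(
            records=df[["site_id", "quadrat_id", "species_id"]],
            total_quadrats=total_quadrats,
            total_samples=total_samples,
            total_sites=total_sites,
            coverage=coverage,
        )


def species_frequency(dataset: SurveyDataset, species_id: str) -> float:
    """Percentage of quadrats in which *species_id* occurs."""
    sub = dataset.records[dataset.records["species_id"] == species_id]
    if sub.empty:
        warnings.warn(f"species {species_id!r} not observed in the survey", stacklevel=2)
        return 0.0
    s_n = sub[["site_id", "quadrat_id"]].drop_duplicates().shape[0]
    return 100.0 * s_n / dataset.total_quadrats


def dominance_indices(dataset: SurveyDataset) -> pd.DataFrame:
    """Per-species dominance table (full precision; round only for display).

    Columns: s_n, n_a, species_frequency, sn_over_s, sn_over_na,
    na_over_ta, plus coverage when the dataset carries it. A species seen
    in zero sites reports sn_over_na as missing.
    """
    if dataset.records.empty:
        cols = ["s_n", "n_a", "species_frequency", "sn_over_s", "sn_over_na", "na_over_ta"]
        return pd.DataFrame(columns=cols)
    uniq = dataset.records.drop_duplicates(["site_id", "quadrat_id", "species_id"])
    s_n = uniq.groupby("species_id").size().rename("s_n")
    n_a = uniq.groupby("species_id")["site_id"].nunique().rename("n_a")
    out = pd.concat([s_n, n_a], axis=1)
    out["species_frequency"] = 100.0 * out["s_n"] / dataset.total_quadrats
    out["sn_over_s"] = out["s_n"] / dataset.total_samples
    out["sn_over_na"] = np.where(out["n_a"] > 0, out["s_n"] / out["n_a"], np.nan)
    out["na_over_ta"] = out["n_a"] / dataset.total_sites
    if dataset.coverage is not None:
        out["coverage"] = dataset.coverage.reindex(out.index)
    return out.sort_values(["sn_over_s", "species_frequency"], ascending=False, kind="stable")


def summarize_dominants(table: pd.DataFrame, top_k: int) -> dict:
    """Top-k species by S_N/S with column totals of S_N/S and N_a/T_a.

    Ties at the cut break by frequency, then lexicographic species id.
    """
    if top_k > len(table):
        raise ValueError(f"top_k={top_k} exceeds number of species ({len(table)})")
    if top_k == 0:
        return {"species": [], "sn_over_s_total": 0.0, "na_over_ta_total": 0.0, "table": table.iloc[:0]}
    ranked = (
        table.sort_index(kind="stable")
        .sort_values("species_frequency", ascending=False, kind="stable")
        .sort_values("sn_over_s", ascending=False, kind="stable")
    )
    sel = ranked.iloc[:top_k]
    return {
        "species": list(sel.index),
        "sn_over_s_total": float(sel["sn_over_s"].sum()),
        "na_over_ta_total": float(sel["na_over_ta"].sum()),
        "table": sel,
    }


def select_candidates(
    table: pd.DataFrame,
    frequency_rank_cut: int | None = None,
    coverage_cut: float | None = None,
) -> list[str]:
    """Candidate dominant species: top-ranked by frequency and/or high coverage.

    Returns the union of the ``frequency_rank_cut`` most frequent species
    and the species with coverage >= ``coverage_cut`` (when supplied),
    sorted by descending frequency then id.
    """
    chosen: set[str] = set()
    if frequency_rank_cut is not None:
        ranked = table.sort_values(
            ["species_frequency", "sn_over_s"], ascending=False, kind="stable"
        )
        chosen |= set(ranked.index[:frequency_rank_cut])
    if coverage_cut is not None:
        if "coverage" not in table.columns:
            raise ValueError("coverage_cut requires a coverage column")
        chosen |= set(table.index[table["coverage"] >= coverage_cut])
    freq = table["species_frequency"]
    return sorted(chosen, key=lambda s: (-freq.get(s, 0.0), s))
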