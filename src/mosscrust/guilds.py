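"""Ecological guild (function group) annotation from user-supplied rule tables.

A rule table in the FAPROTAX/FUNGuild style maps a taxon name at a stated
rank to one or more guild labels with a confidence level (possible,
probable, highly probable). Assignment is case-insensitive exact match;
the deepest-rank matching rule wins; features with no surviving rule fall
into an ``unassigned`` residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from mosscrust.community import OtuTable

CONFIDENCE_ORDER = {"possible": 0, "probable": 1, "highly probable": 2}
#: Rank depth used to resolve conflicts between matching rules.
RANK_DEPTH = {r: i for i, r in enumerate(
    ("domain", "kingdom", "phylum", "class", "order", "family", "genus", "species")
)}

UNASSIGNED = "unassigned"


@dataclass
class GuildRuleTable:
    """Rules: columns rank, taxon, guild, confidence."""

    rules: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"rank", "taxon", "guild", "confidence"}
        missing = required - set(self.rules.columns)
        if missing:
            raise ValueError(f"rule table missing columns: {sorted(missing)}")
        if (self.rules["taxon"].astype(str).str.len() == 0).any():
            raise ValueError("empty taxon pattern in rule table")
        bad = set(self.rules["confidence"]) - set(CONFIDENCE_ORDER)
        if bad:
            raise ValueError(f"unknown confidence levels: {sorted(bad)}")

    @classmethod
    def from_tsv(cls, path) -> "GuildRuleTable":
        return cls(pd.read_csv(path, sep="\t"))


def assign_guilds(
    taxonomy: pd.DataFrame,
    rules: GuildRuleTable | pd.DataFrame,
    min_confidence: str = "possible",
) -> pd.Series:
    """Feature -> guild map: deepest-rank match wins, low-confidence rules ignored.

    Conflicting rules at the same rank and taxon resolve to the
    first-listed rule, with a warning. Unmatched features map to
    ``unassigned``.
    """
    if isinstance(rules, pd.DataFrame):
        rules = GuildRuleTable(rules)
    min_level = CONFIDENCE_ORDER[min_confidence]
    usable = rules.rules[
        rules.rules["confidence"].map(CONFIDENCE_ORDER) >= min_level
    ]
    # rule lookup: (rank, lowercase taxon) -> guild, first listed wins
    lookup: dict[tuple[str, str], str] = {}
    for _, row in usable.iterrows():
        key = (row["rank"], str(row["taxon"]).lower())
        if key in lookup:
            if lookup[key] != row["guild"]:
                warnings.warn(
                    f"conflicting rules for {key[1]!r} at rank {key[0]!r}; "
                    f"keeping first-listed {lookup[key]!r}",
                    stacklevel=2,
                )
            continue
        lookup[key] = row["guild"]
    ranked = sorted(
        {r for r, _ in lookup}, key=lambda r: RANK_DEPTH.get(r, -1), reverse=True
    )
    out = {}
    for feature, lineage in taxonomy.iterrows():
        guild = UNASSIGNED
        for rank in ranked:  # deepest rank first
            name = lineage.get(rank)
            if isinstance(name, str) and (rank, name.lower()) in lookup:
                guild = lookup[(rank, name.lower())]
                break
        out[feature] = guild
    return pd.Series(out, name="guild")


def guild_profile(
    table: OtuTable,
    assignment: pd.Series,
    drop_unassigned: bool = False,
) -> pd.DataFrame:
    """Per-sample guild relative abundances (rows sum to 1).

    With ``drop_unassigned`` the unassigned fraction is removed and the
    remaining guild fractions renormalized, preserving their ratios.
    """
    assignment = assignment.reindex(table.feature_ids).fillna(UNASSIGNED)
    agg = table.counts.T.groupby(assignment).sum().T
    if drop_unassigned and UNASSIGNED in agg.columns:
        agg = agg.drop(columns=UNASSIGNED)
        if (agg.sum(axis=1) == 0).any():
            raise ValueError("a sample has no assigned features; cannot renormalize")
    return agg.div(agg.sum(axis=1), axis=0)
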