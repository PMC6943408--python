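"""Fuzzy-membership drought-resistance scoring and grey relational analysis.

The subordinate (membership) function maps each physiological index to
[0, 1] by min-max normalization across species, inverted for harmful
indexes (membrane permeability MP, malondialdehyde MDA), so that larger
memberships always mean stronger drought resistance. A species'
comprehensive score is the arithmetic mean of its memberships; rank 1 is
the largest score. Deng's grey relational grade then ranks the indexes
by how closely each membership column tracks the comprehensive score.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


class DegenerateIndexError(ValueError):
    """An index column is constant across species, so min-max normalization is undefined."""


def electrolyte_leakage(ec1: float, ec2: float) -> float:
    """Membrane permeability as the percentage EC1/EC2 of electrical conductivities."""
    if ec2 <= 0:
        raise ValueError(f"EC2 must be > 0, got {ec2}")
    if ec1 > ec2:
        warnings.warn(
            f"EC1 ({ec1}) exceeds EC2 ({ec2}); leakage above 100% is physically suspect",
            stacklevel=2,
        )
    return 100.0 * ec1 / ec2


def replicate_means(values: pd.DataFrame) -> pd.DataFrame:
    """Species x index means from a long (species, index, replicate, value) table."""
    return values.pivot_table(index="species", columns="index", values="value", aggfunc="mean")


def membership_transform(
    values: pd.DataFrame,
    directions: dict[str, str],
    degenerate: str = "error",
) -> pd.DataFrame:
    """Min-max memberships per index column, direction-adjusted.

    beneficial: Z = (x - min) / (max - min); harmful: Z = (max - x) / (max - min).
    Each non-constant column attains both 0 and 1. A constant column raises
    :class:`DegenerateIndexError` unless ``degenerate='half'`` maps it to 0.5.
    """
    if len(values) < 2:
        raise ValueError("membership transform needs at least 2 species")
    unknown = set(values.columns) - set(directions)
    if unknown:
        raise ValueError(f"no direction for indexes: {sorted(unknown)}")
    out = {}
    for col in values.columns:
        x = values[col].astype(float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            if degenerate == "half":
                out[col] = pd.Series(0.5, index=x.index)
                continue
            raise DegenerateIndexError(f"index {col!r} is constant across species")
        z = (x - lo) / (hi - lo)
        if directions[col] == "harmful":
            z = 1.0 - z
        elif directions[col] != "beneficial":
            raise ValueError(f"direction must be 'beneficial' or 'harmful', got {directions[col]!r}")
        out[col] = z
    return pd.DataFrame(out)


def comprehensive_score(memberships: pd.DataFrame) -> pd.DataFrame:
    """Mean membership per species with ranks (1 = most drought resistant).

    Ties share the smallest applicable rank and are flagged; row order is
    by descending score with lexicographic species id as tiebreak.
    """
    if memberships.isna().any().any():
        raise ValueError("memberships contain missing values")
    score = memberships.mean(axis=1)
    out = pd.DataFrame({"score": score})
    out["rank"] = score.rank(ascending=False, method="min").astype(int)
    out["tied"] = score.duplicated(keep=False)
    return out.sort_index(kind="stable").sort_values("score", ascending=False, kind="stable")


def grey_relational_grades(
    reference: pd.Series,
    comparisons: pd.DataFrame,
    rho: float = 0.5,
) -> pd.DataFrame:
    """Deng's grey relational grade of each comparison column against the reference.

    With deviations D_i(k) = |x0(k) - xi(k)| and global extrema over all
    i, k, the coefficient is (D_min + rho * D_max) / (D_i(k) + rho * D_max)
    and the grade is its mean over k. Grades lie in (rho/(1+rho), 1];
    identical sequences grade 1. Indexes are ranked by descending grade.
    """
    if not 0 < rho <= 1:
        raise ValueError(f"rho must lie in (0, 1], got {rho}")
    if not reference.index.equals(comparisons.index):
        comparisons = comparisons.reindex(reference.index)
        if comparisons.isna().any().any():
            raise ValueError("reference and comparison sequences must share their index")
    delta = comparisons.sub(reference, axis=0).abs()
    d_min, d_max = float(delta.min().min()), float(delta.max().max())
    if d_max == 0:
        grades = pd.Series(1.0, index=comparisons.columns)
    else:
        xi = (d_min + rho * d_max) / (delta + rho * d_max)
        grades = xi.mean(axis=0)
    out = pd.DataFrame({"grade": grades})
    out["rank"] = grades.rank(ascending=False, method="min").astype(int)
    out.attrs["rho"] = rho
    return out.sort_values("grade", ascending=False, kind="stable")


def classify_resistance(
    scores: pd.Series, high_cut: float = 0.55, low_cut: float = 0.42
) -> pd.Series:
    """Label species high / intermediate / low by score thresholds (closed boundaries)."""
    if low_cut >= high_cut:
        raise ValueError("low_cut must be below high_cut")
    labels = pd.Series("intermediate", index=scores.index, name="resistance_class")
    labels[scores >= high_cut] = "high"
    labels[scores <= low_cut] = "low"
    return labels
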