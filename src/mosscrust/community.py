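"""OTU-table container, alpha/beta diversity, ordination, clustering and Venn regions.

Distances are returned as :class:`skbio.DistanceMatrix`; trees are
:class:`skbio.TreeNode` with leaves labelled by feature ids. Standard
metrics are delegated to scikit-bio / scipy; the Venn region
decomposition and the NMDS wrapper (Kruskal stress-1 over restarts) are
implemented here.
"""

from __future__ import annotations

import io
import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import alpha as skbio_alpha
from skbio.diversity import beta_diversity
from sklearn.manifold import smacof

ALPHA_METRICS = ("chao1", "shannon", "goods_coverage", "faith_pd")


class EmptySampleError(ValueError):
    """A sample with zero total count was passed where counts are required."""


@dataclass
class OtuTable:
    """Non-negative integer counts, samples x features."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValueError("sample and feature ids must be unique")
        values = df.to_numpy()
        if np.any(values < 0):
            raise ValueError("counts must be non-negative")
        if np.any(values.sum(axis=1) <= 0):
            bad = df.index[values.sum(axis=1) <= 0].tolist()
            raise EmptySampleError(f"samples with zero total counts: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.columns)

    def relative_abundance(self) -> pd.DataFrame:
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    # -- external interface: features x samples TSV, header row of sample ids
    def to_tsv(self, path) -> None:
        self.counts.T.rename_axis("feature_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "OtuTable":
        df = pd.read_csv(path, sep="\t", index_col=0).T.astype(int)
        df.index.name = None
        df.columns.name = None
        return cls(df)


def ensure_rooted(tree: TreeNode) -> TreeNode:
    """Resolve a multifurcating root with zero-length internal branches.

    Zero-length resolution leaves every branch-length metric (UniFrac,
    Faith PD) numerically unchanged, unlike rerooting.
    """
    if len(tree.children) <= 2:
        return tree
    tree = tree.copy()
    while len(tree.children) > 2:
        a, b = tree.children[-2], tree.children[-1]
        tree.remove(a)
        tree.remove(b)
        merged = TreeNode(length=0.0, children=[a, b])
        tree.append(merged)
    return tree


def alpha_diversity(
    table: OtuTable,
    metrics: tuple[str, ...] = ("chao1", "shannon", "goods_coverage"),
    tree: TreeNode | None = None,
) -> pd.DataFrame:
    """Per-sample alpha diversity.

    chao1 is bias-corrected, shannon uses the natural log,
    goods_coverage = 1 - F1/N, and faith_pd is the branch length spanning
    the observed leaves and the root (tree required).
    """
    unknown = set(metrics) - set(ALPHA_METRICS)
    if unknown:
        raise ValueError(f"unknown alpha metrics: {sorted(unknown)}")
    if "faith_pd" in metrics:
        if tree is None:
            raise ValueError("faith_pd requires a phylogenetic tree")
        tree = ensure_rooted(tree)
        leaves = {leaf.name for leaf in tree.tips()}
        missing = [f for f in table.feature_ids if f not in leaves]
        if missing:
            raise ValueError(f"features missing from tree: {missing[:5]}")
    out = {}
    counts = table.counts.to_numpy()
    for metric in metrics:
        if metric == "chao1":
            vals = [skbio_alpha.chao1(row, bias_corrected=True) for row in counts]
        elif metric == "shannon":
            vals = [skbio_alpha.shannon(row, base=math.e) for row in counts]
        elif metric == "goods_coverage":
            vals = [skbio_alpha.goods_coverage(row) for row in counts]
        else:  # faith_pd
            vals = [
                skbio_alpha.faith_pd(row, taxa=table.feature_ids, tree=tree)
                for row in counts
            ]
        out[metric] = vals
    return pd.DataFrame(out, index=table.sample_ids)


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity, d = 1 - 2 sum(min) / (sum x + sum y)."""
    return beta_diversity("braycurtis", table.counts.to_numpy(), ids=table.sample_ids)


def unweighted_unifrac(table: OtuTable, tree: TreeNode) -> DistanceMatrix:
    """Unweighted UniFrac: unique / (unique + shared) branch length, presence = count > 0."""
    tree = ensure_rooted(tree)
    return beta_diversity(
        "unweighted_unifrac",
        (table.counts.to_numpy() > 0).astype(int),
        ids=table.sample_ids,
        taxa=table.feature_ids,
        tree=tree,
    )


def _kruskal_stress1(dist: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against target dissimilarities."""
    from sklearn.isotonic import IsotonicRegression

    iu = np.triu_indices(dist.shape[0], k=1)
    d_emb = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))[iu]
    d_obs = dist[iu]
    order = np.argsort(d_obs, kind="stable")
    dhat = np.empty_like(d_emb)
    dhat[order] = IsotonicRegression().fit_transform(np.arange(order.size), d_emb[order])
    denom = float((d_emb**2).sum())
    if denom == 0:
        return 1.0
    return math.sqrt(float(((d_emb - dhat) ** 2).sum()) / denom)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame
    stress: float
    converged: bool


def nmds(
    dist: DistanceMatrix,
    dims: int = 2,
    restarts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Runs seeded SMACOF with monotone regression from ``restarts`` random
    starts and returns the lowest-stress configuration.
    """
    n = dist.shape[0]
    if n < dims + 1:
        raise ValueError(f"need at least dims+1={dims + 1} samples, got {n}")
    d = dist.data
    rng = np.random.default_rng(seed)
    best_coords, best_stress = None, np.inf
    for _ in range(restarts):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords, stress, n_iter = smacof(
                d,
                metric=False,
                n_components=dims,
                init=rng.normal(size=(n, dims)),
                n_init=1,
                max_iter=max_iter,
                eps=tol,
                normalized_stress=True,
                return_n_iter=True,
            )
        s1 = _kruskal_stress1(d, coords)
        if s1 < best_stress:
            best_coords, best_stress, best_iter = coords, s1, n_iter
    cols = [f"NMDS{i + 1}" for i in range(dims)]
    return OrdinationResult(
        coordinates=pd.DataFrame(best_coords, index=list(dist.ids), columns=cols),
        stress=best_stress,
        converged=best_iter < max_iter,
    )


@dataclass
class UpgmaResult:
    newick: str
    linkage: np.ndarray
    ids: list[str]

    def cophenetic(self) -> pd.DataFrame:
        coph = squareform(sch.cophenet(self.linkage))
        return pd.DataFrame(coph, index=self.ids, columns=self.ids)


def upgma(dist: DistanceMatrix) -> UpgmaResult:
    """Average-linkage (UPGMA) dendrogram; Newick branch lengths from merge heights."""
    ids = list(dist.ids)
    if len(ids) < 2:
        raise ValueError("UPGMA requires at least 2 samples")
    linkage = sch.linkage(squareform(dist.data, checks=False), method="average")
    tree = sch.to_tree(linkage)

    def _newick(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{ids[node.id]}:{length / 2:.10g}"
        left = _newick(node.left, node.dist)
        right = _newick(node.right, node.dist)
        return f"({left},{right}):{length / 2:.10g}"

    newick = f"({_newick(tree.left, tree.dist)},{_newick(tree.right, tree.dist)});"
    return UpgmaResult(newick=newick, linkage=linkage, ids=ids)


@dataclass
class VennResult:
    """Region decomposition of group OTU sets.

    ``regions`` maps a sorted tuple of group names to the number of OTUs
    present in exactly those groups; ``core`` is the all-groups region and
    ``exclusive`` the single-group regions.
    """

    regions: dict[tuple[str, ...], int]
    core: int
    exclusive: dict[str, int]
    group_totals: dict[str, int]


def core_and_exclusive(table: OtuTable, groups: pd.Series | dict) -> VennResult:
    """Shared/exclusive OTU decomposition across groups (presence = count > 0 in >= 1 sample)."""
    groups = pd.Series(groups)
    missing = set(table.sample_ids) - set(groups.index)
    if missing:
        raise ValueError(f"samples without a group: {sorted(missing)}")
    names = sorted(groups.unique())
    presence = {}
    for g in names:
        samples = groups.index[groups == g].intersection(table.counts.index)
        if len(samples) == 0:
            raise ValueError(f"group {g!r} has no samples")
        presence[g] = table.counts.loc[samples].sum(axis=0) > 0
    member = pd.DataFrame(presence)  # features x groups
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            mask = member[list(combo)].all(axis=1) & ~member[
                [g for g in names if g not in combo]
            ].any(axis=1)
            regions[combo] = int(mask.sum())
    core = regions.get(tuple(names), 0)
    exclusive = {g: regions[(g,)] for g in names}
    totals = {g: int(member[g].sum()) for g in names}
    return VennResult(regions=regions, core=core, exclusive=exclusive, group_totals=totals)


def aggregate_by_rank(
    table: OtuTable, taxonomy: pd.DataFrame, rank: str
) -> pd.DataFrame:
    """Sum counts over features per taxon at *rank* (unassigned pooled as 'unclassified')."""
    if rank not in taxonomy.columns:
        raise ValueError(f"taxonomy has no rank {rank!r}")
    labels = taxonomy.reindex(table.feature_ids)[rank].fillna("unclassified")
    labels = labels.replace("", "unclassified")
    return table.counts.T.groupby(labels).sum().T


def dominant_taxa(
    table: OtuTable,
    taxonomy: pd.DataFrame,
    rank: str = "phylum",
    threshold: float = 0.01,
) -> pd.Series:
    """Taxa whose mean relative abundance across samples exceeds *threshold* (strict >)."""
    agg = aggregate_by_rank(table, taxonomy, rank)
    rel = agg.div(agg.sum(axis=1), axis=0)
    mean_rel = rel.mean(axis=0).sort_values(ascending=False)
    return mean_rel[mean_rel > threshold]


def read_newick(path_or_str) -> TreeNode:
    """Read a Newick tree from a path or a literal string (underscores kept)."""
    if isinstance(path_or_str, str) and path_or_str.strip().endswith(";"):
        return TreeNode.read(io.StringIO(path_or_str), convert_underscores=False)
    return TreeNode.read(str(path_or_str), convert_underscores=False)
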