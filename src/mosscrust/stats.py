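"""Hypothesis-testing layer: ANOVA, multi-term PERMANOVA, LEfSe-style
biomarkers, DCA-selected constrained ordination, and Spearman
genus-factor correlation matrices.

PERMANOVA follows the adonis decomposition: the Gower-centered inner
product matrix of squared distances is partitioned by sequential (Type I)
sums of squares over user-ordered model terms (categorical factors,
continuous covariates, and ``A:B`` interactions), with p-values from free
permutation of sample labels and the add-one estimator.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as ss
from skbio import DistanceMatrix
from skbio.stats.ordination import cca as skbio_cca
from skbio.stats.ordination import rda as skbio_rda

from mosscrust.community import OtuTable, aggregate_by_rank

LEFSE_LEVELS = ("phylum", "class", "order", "family", "genus")


class AliasedDesignError(ValueError):
    """A model term is fully confounded with terms already in the design."""


# ---------------------------------------------------------------------------
# one-way ANOVA


def one_way_anova(values, groups) -> dict:
    """Classical one-way F test. Returns F, p, and df.

    When every group has zero within-group variance and means differ, p is
    reported as 0.0 with a ``degenerate`` flag.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in levels]
    if len(values) - len(levels) < 1:
        raise ValueError("need at least 2 total residual df")
    within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    if within == 0:
        means = [s.mean() for s in samples]
        if np.ptp(means) > 0:
            return {
                "F": math.inf,
                "p": 0.0,
                "df_between": len(levels) - 1,
                "df_within": len(values) - len(levels),
                "degenerate": True,
            }
    F, p = ss.f_oneway(*samples)
    return {
        "F": float(F),
        "p": float(p),
        "df_between": len(levels) - 1,
        "df_within": len(values) - len(levels),
        "degenerate": False,
    }


# ---------------------------------------------------------------------------
# PERMANOVA (adonis-style, sequential SS)


def _term_columns(design: pd.DataFrame, term: str) -> np.ndarray:
    """Model-matrix columns for a term: treatment-coded factors, raw covariates,
    or elementwise products for ``A:B`` interactions."""
    parts = term.split(":")
    blocks = []
    for part in parts:
        if part not in design.columns:
            raise KeyError(f"unknown design variable {part!r}")
        col = design[part]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)
            if dummies.shape[1] == 0:
                raise ValueError(f"factor {part!r} has a single level")
            blocks.append(dummies)
        else:
            blocks.append(col.to_numpy(dtype=float)[:, None])
    cols = blocks[0]
    for nxt in blocks[1:]:
        cols = np.concatenate(
            [cols[:, [i]] * nxt for i in range(cols.shape[1])], axis=1
        )
    return cols


def _hat(X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    # guard rank deficiency: drop numerically null columns
    r = np.linalg.matrix_rank(X)
    Q = Q[:, :r] if r < Q.shape[1] else Q
    return Q @ Q.T


def gower_center(dist: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Gower-centered inner-product matrix G = -(1/2) J D^2 J."""
    d = dist.data if isinstance(dist, DistanceMatrix) else np.asarray(dist, float)
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ (d**2) @ J


def permanova(
    dist: DistanceMatrix,
    design: pd.DataFrame,
    terms: list[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
    exact: bool = False,
) -> pd.DataFrame:
    """Sequential multi-term PERMANOVA on a distance matrix.

    Returns a table with one row per term plus Residual and Total:
    df, SumOfSqs, R2, F and the permutation p-value
    (1 + #{F_perm >= F_obs}) / (1 + n_perm). With ``exact=True`` every
    sample permutation is enumerated (small n only) and p is the exact
    tail proportion #{F_perm >= F_obs} / n! (the identity included).
    """
    ids = list(dist.ids)
    design = design.loc[ids]
    if terms is None:
        terms = [c for c in design.columns]
    n = len(ids)
    G = gower_center(dist)
    ss_total = float(np.trace(G))

    intercept = np.ones((n, 1))
    X = intercept
    rank_prev = 1
    H_prev = _hat(X)
    term_info = []
    for term in terms:
        X = np.concatenate([X, _term_columns(design, term)], axis=1)
        rank = np.linalg.matrix_rank(X)
        df = rank - rank_prev
        if df <= 0:
            raise AliasedDesignError(
                f"term {term!r} is aliased with earlier terms {terms[: len(term_info)]}"
            )
        H = _hat(X)
        term_info.append((term, df, H - H_prev))
        H_prev, rank_prev = H, rank
    H_full = H_prev
    df_resid = n - rank_prev
    R_mat = np.eye(n) - H_full

    def _stats(Gp: np.ndarray):
        ss_resid = float((R_mat * Gp).sum())
        rows = []
        for term, df, M in term_info:
            ss_term = float((M * Gp).sum())
            F = (ss_term / df) / (ss_resid / df_resid) if df_resid > 0 else math.inf
            rows.append((ss_term, F))
        return rows, ss_resid

    obs_rows, ss_resid = _stats(G)
    exceed = np.zeros(len(term_info))
    if exact:
        if n > 9:
            raise ValueError("exact enumeration is limited to n <= 9 samples")
        total = 0
        for p_idx in itertools.permutations(range(n)):
            total += 1
            perm_rows, _ = _stats(G[np.ix_(p_idx, p_idx)])
            for k, (_, Fp) in enumerate(perm_rows):
                if Fp >= obs_rows[k][1] - 1e-12:
                    exceed[k] += 1
        pvals = exceed / total
    elif n_perm > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            p_idx = rng.permutation(n)
            perm_rows, _ = _stats(G[np.ix_(p_idx, p_idx)])
            for k, (_, Fp) in enumerate(perm_rows):
                if Fp >= obs_rows[k][1] - 1e-12:
                    exceed[k] += 1
        pvals = (1 + exceed) / (1 + n_perm)
    else:
        pvals = np.full(len(term_info), np.nan)

    records = []
    for (term, df, _), (ss_term, F), p in zip(term_info, obs_rows, pvals):
        records.append((term, df, ss_term, ss_term / ss_total, F, p))
    records.append(("Residual", df_resid, ss_resid, ss_resid / ss_total, np.nan, np.nan))
    records.append(("Total", n - 1, ss_total, 1.0, np.nan, np.nan))
    return pd.DataFrame(
        records, columns=["term", "df", "SumOfSqs", "R2", "F", "p"]
    ).set_index("term")


# ---------------------------------------------------------------------------
# LEfSe-style biomarker discovery


def lefse(
    table: OtuTable,
    taxonomy: pd.DataFrame,
    classes: pd.Series,
    alpha: float = 0.05,
    lda_cut: float = 2.0,
    n_boot: int = 30,
    seed: int = 0,
    levels: tuple[str, ...] = LEFSE_LEVELS,
) -> pd.DataFrame:
    """Kruskal-Wallis screening plus discriminant effect sizes per taxonomic level.

    Abundances are aggregated per level on the relative scale x 1e6. Taxa
    with KW p < ``alpha`` get an effect size: the one-component
    discriminant of a single taxon is the taxon axis itself, so the score
    is log10 of the largest between-class separation of bootstrapped
    class means on the per-million scale, averaged over ``n_boot``
    within-class resamples. Reported biomarkers satisfy p < alpha and
    LDA score > ``lda_cut``, with the enriched class attached.
    """
    classes = classes.loc[table.sample_ids]
    level_names = classes.unique()
    if len(level_names) < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    rel = table.relative_abundance() * 1e6
    results = []
    n_tested = 0
    class_idx = {c: np.flatnonzero((classes == c).to_numpy()) for c in level_names}
    for level in levels:
        if level not in taxonomy.columns:
            continue
        labels = taxonomy.reindex(table.feature_ids)[level].fillna("unclassified")
        agg = rel.T.groupby(labels).sum().T  # samples x taxa at this level
        X = agg.to_numpy()
        for j, taxon in enumerate(agg.columns):
            x = X[:, j]
            if np.ptp(x) == 0:
                continue  # constant across samples: skipped
            n_tested += 1
            grouped = [x[class_idx[c]] for c in level_names]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    _, p = ss.kruskal(*grouped)
                except ValueError:
                    continue
            if not p < alpha:
                continue
            seps = np.empty(n_boot)
            for b in range(n_boot):
                boot_means = []
                for c in level_names:
                    idx = class_idx[c]
                    boot = x[idx[rng.integers(0, len(idx), len(idx))]]
                    boot_means.append(boot.mean())
                boot_means = np.asarray(boot_means)
                seps[b] = np.max(boot_means) - np.min(boot_means)
            effect = float(seps.mean())
            score = math.log10(effect) if effect > 0 else -math.inf
            if score > lda_cut:
                means = {c: x[class_idx[c]].mean() for c in level_names}
                enriched = max(means, key=means.get)
                results.append((taxon, level, enriched, float(p), score))
    out = (
        pd.DataFrame(results, columns=["taxon", "level", "enriched_class", "p", "lda_score"])
        .sort_values("lda_score", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    out.attrs["n_taxa_tested"] = n_tested
    return out


# ---------------------------------------------------------------------------
# DCA gradient length and RDA/CCA


def dca_axis1_gradient_length(table: OtuTable) -> float:
    """Axis-1 gradient length in SD units of species turnover.

    Correspondence-analysis axis 1 is rescaled so the abundance-weighted
    mean within-species variance of sample scores (the average species
    tolerance) is 1; the gradient length is then the range of sample
    scores. Lengths >= ~4 SD indicate complete species turnover.
    """
    Y = table.counts.to_numpy(dtype=float)
    if Y.shape[0] < 2:
        raise ValueError("gradient length requires at least 2 samples")
    total = Y.sum()
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    keep = c > 0
    P, c = P[:, keep], c[keep]
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    if sv[0] < 1e-12:
        return 0.0
    row_scores = U[:, 0] * sv[0] / np.sqrt(r)  # principal coordinates of samples
    col_scores = (P.T / c[:, None]) @ row_scores / sv[0]  # species optima (weighted averages / sv)
    # species tolerance: weighted variance of sample scores around each optimum
    W = P  # weights: joint abundance
    col_w = c
    diff2 = (row_scores[:, None] - col_scores[None, :]) ** 2
    tol2 = (W * diff2).sum(axis=0) / np.maximum(W.sum(axis=0), 1e-300)
    mean_tol2 = float((col_w * tol2).sum() / col_w.sum())
    if mean_tol2 <= 0:
        return 0.0
    scaled = row_scores / math.sqrt(mean_tol2)
    return float(scaled.max() - scaled.min())


def gradient_length_select(table: OtuTable, boundary: float = 3.5) -> dict:
    """Choose CCA when the DCA axis-1 gradient length >= ``boundary``, else RDA."""
    length = dca_axis1_gradient_length(table)
    return {"method": "CCA" if length >= boundary else "RDA", "axis1_length": length}


def _constrained_fraction(Y: np.ndarray, x: np.ndarray, weights: np.ndarray | None) -> float:
    """Fraction of (possibly row-weighted) inertia explained by one covariate."""
    if weights is None:
        xc = x - x.mean()
        denom = float(xc @ xc)
        if denom == 0:
            return 0.0
        fitted = np.outer(xc, xc @ Y) / denom
        return float((fitted**2).sum() / (Y**2).sum())
    w = weights
    xb = float(w @ x)
    xc = x - xb
    denom = float(w @ xc**2)
    if denom == 0:
        return 0.0
    proj = (w * xc) @ Y / denom
    fitted = np.outer(xc, proj)
    return float((w[:, None] * fitted**2).sum() / (w[:, None] * Y**2).sum())


def constrained_ordination(
    table: OtuTable,
    covariates: pd.DataFrame,
    method: str | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """RDA on Hellinger-transformed abundances or CCA on chi-square weights.

    When ``method`` is None the DCA gradient-length rule chooses it.
    Returns the scikit-bio ordination (axis eigenvalues / proportions) and
    a per-covariate table of marginal R2 with permutation p-values.
    """
    covariates = covariates.loc[table.sample_ids].astype(float)
    if covariates.isna().any().any():
        raise ValueError("covariates contain missing values")
    zero_var = [c for c in covariates.columns if covariates[c].std() == 0]
    if zero_var:
        raise ValueError(f"zero-variance covariates: {zero_var}")
    X = (covariates - covariates.mean()) / covariates.std()
    cond = np.linalg.cond(X.to_numpy())
    if cond > 1e6:
        warnings.warn(
            f"covariates nearly collinear (condition number {cond:.3g}): {list(covariates.columns)}",
            stacklevel=2,
        )
    if method is None:
        method = gradient_length_select(table)["method"]
    counts = table.counts.to_numpy(dtype=float)
    observed = counts.sum(axis=0) > 0  # never-observed features carry no inertia
    counts = counts[:, observed]
    feature_ids = [f for f, keep in zip(table.feature_ids, observed) if keep]
    if method == "RDA":
        rel = counts / counts.sum(axis=1, keepdims=True)
        Y = np.sqrt(rel)  # Hellinger
        Yc = Y - Y.mean(axis=0)
        ord_res = skbio_rda(
            pd.DataFrame(Y, index=table.sample_ids, columns=feature_ids),
            X,
        )
        weights = None
        Y_for_perm = Yc
    elif method == "CCA":
        ord_res = skbio_cca(
            pd.DataFrame(counts, index=table.sample_ids, columns=feature_ids),
            X,
        )
        total = counts.sum()
        r = counts.sum(axis=1) / total
        c = counts.sum(axis=0) / total
        keep = c > 0
        Q = (counts[:, keep] / total - np.outer(r, c[keep])) / np.sqrt(c[keep])[None, :]
        Y_for_perm = Q / r[:, None]  # row-standardized residuals, weighted by r below
        weights = r
    else:
        raise ValueError("method must be 'RDA' or 'CCA'")

    rng = np.random.default_rng(seed)
    rows = []
    for cov in covariates.columns:
        x = X[cov].to_numpy()
        r2_obs = _constrained_fraction(Y_for_perm, x, weights)
        exceed = 0
        for _ in range(n_perm):
            r2_p = _constrained_fraction(Y_for_perm, rng.permutation(x), weights)
            if r2_p >= r2_obs - 1e-15:
                exceed += 1
        rows.append((cov, r2_obs, (1 + exceed) / (1 + n_perm)))
    marginal = pd.DataFrame(rows, columns=["covariate", "R2", "p"]).set_index("covariate")
    return {"method": method, "ordination": ord_res, "marginal": marginal}


# ---------------------------------------------------------------------------
# Spearman helpers and the factor-taxon heatmap


def _exact_spearman_null(n: int) -> np.ndarray:
    """Exact null distribution of Spearman rho for untied samples of size n."""
    base = np.arange(1, n + 1, dtype=float)
    rhos = []
    denom = n * (n**2 - 1)
    for perm in itertools.permutations(range(n)):
        d2 = ((base - base[list(perm)]) ** 2).sum()
        rhos.append(1 - 6 * d2 / denom)
    return np.sort(np.asarray(rhos))


def spearman_matrix(X: pd.DataFrame, exact_max_n: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho and two-sided p over columns of X.

    Exact permutation p for n <= ``exact_max_n`` untied samples, otherwise
    the t-approximation (scipy default).
    """
    n = len(X)
    cols = list(X.columns)
    k = len(cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = ss.spearmanr(X.to_numpy())
        if np.shape(rho) != (k, k):
            # scipy collapses 2-column and degenerate inputs; go pairwise
            rho = np.eye(k)
            p = np.zeros((k, k))
            for i in range(k):
                for j in range(i + 1, k):
                    r_ij, p_ij = ss.spearmanr(X.iloc[:, i], X.iloc[:, j])
                    rho[i, j] = rho[j, i] = r_ij
                    p[i, j] = p[j, i] = p_ij
    if n <= exact_max_n:
        null = _exact_spearman_null(n)
        m = null.size
        for i in range(len(cols)):
            for j in range(len(cols)):
                if i == j:
                    continue
                r = rho[i, j]
                if np.isnan(r):
                    continue
                p[i, j] = np.count_nonzero(np.abs(null) >= abs(r) - 1e-12) / m
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def significance_stars(p: float) -> str:
    """Figure-style stars: * for 0.01 < p <= 0.05, ** for 0.001 < p <= 0.01, *** for p <= 0.001."""
    if np.isnan(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


@dataclass
class HeatmapResult:
    rho: pd.DataFrame  # genera x factors, clustered order
    p: pd.DataFrame
    stars: pd.DataFrame


def factor_taxon_heatmap(
    table: OtuTable,
    covariates: pd.DataFrame,
    taxonomy: pd.DataFrame | None = None,
    top_n: int = 50,
    taxa: list[str] | None = None,
    rank: str = "genus",
) -> HeatmapResult:
    """Spearman correlations of top-abundance genera against each factor.

    Uses the ``taxa`` list when supplied (e.g. LEfSe biomarkers), else the
    ``top_n`` most abundant taxa at ``rank``. Rows and columns are ordered
    by average-linkage clustering of the correlation matrix; constant
    genera yield missing correlations.
    """
    import scipy.cluster.hierarchy as sch

    if taxonomy is not None:
        abundance = aggregate_by_rank(table, taxonomy, rank)
    else:
        abundance = table.counts
    if taxa is None:
        totals = abundance.sum(axis=0)
        taxa = sorted(abundance.columns, key=lambda t: (-totals[t], t))[:top_n]
    abundance = abundance[list(taxa)]
    covariates = covariates.loc[table.sample_ids].astype(float)
    n_t, n_c = abundance.shape[1], covariates.shape[1]
    joint = pd.concat([abundance, covariates], axis=1)
    rho_all, p_all = spearman_matrix(joint, exact_max_n=10)
    rho = rho_all.iloc[:n_t, n_t:].copy()
    p = p_all.iloc[:n_t, n_t:].copy()
    const = abundance.std(axis=0) == 0
    rho.loc[const[const].index] = np.nan
    p.loc[const[const].index] = np.nan

    def _cluster_order(mat: pd.DataFrame, axis: int) -> list:
        data = mat.fillna(0).to_numpy()
        if axis == 1:
            data = data.T
        labels = list(mat.index if axis == 0 else mat.columns)
        if len(labels) < 3:
            return labels
        link = sch.linkage(data, method="average")
        return [labels[i] for i in sch.leaves_list(link)]

    row_order = _cluster_order(rho, 0)
    col_order = _cluster_order(rho, 1)
    rho = rho.loc[row_order, col_order]
    p = p.loc[row_order, col_order]
    stars = p.map(significance_stars)
    return HeatmapResult(rho=rho, p=p, stars=stars)
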