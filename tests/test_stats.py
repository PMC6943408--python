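"""ANOVA, PERMANOVA, LEfSe, gradient-length selection, constrained
ordination and Spearman heatmaps against analytic identities and
enumeration oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from mosscrust.community import OtuTable
from mosscrust.stats import (
    AliasedDesignError,
    constrained_ordination,
    dca_axis1_gradient_length,
    factor_taxon_heatmap,
    gradient_length_select,
    lefse,
    one_way_anova,
    permanova,
    significance_stars,
    spearman_matrix,
)


class TestOneWayAnova:
    def test_two_groups_equals_squared_t(self, rng):
        x = rng.normal(size=14)
        g = np.repeat(["a", "b"], 7)
        res = one_way_anova(x, g)
        t, p = ss.ttest_ind(x[:7], x[7:])
        assert res["F"] == pytest.approx(t**2)
        assert res["p"] == pytest.approx(p)

    def test_hand_computed_two_by_three(self):
        # groups of 3: textbook decomposition computed longhand in-line
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 9.0, 10.0])
        groups = np.repeat(["g1", "g2", "g3"], 3)
        grand = vals.mean()
        ss_between = sum(3 * (vals[i : i + 3].mean() - grand) ** 2 for i in (0, 3, 6))
        ss_within = sum(((vals[i : i + 3] - vals[i : i + 3].mean()) ** 2).sum() for i in (0, 3, 6))
        f_expected = (ss_between / 2) / (ss_within / 6)
        res = one_way_anova(vals, groups)
        assert res["F"] == pytest.approx(f_expected)

    def test_type_one_error_near_nominal(self, rng):
        rejections = 0
        for _ in range(200):
            x = rng.normal(size=18)
            g = np.repeat(["a", "b", "c"], 6)
            if one_way_anova(x, g)["p"] < 0.05:
                rejections += 1
        assert 0.02 <= rejections / 200 <= 0.09

    def test_degenerate_zero_variance(self):
        res = one_way_anova([1, 1, 2, 2], ["a", "a", "b", "b"])
        assert res["degenerate"] and res["p"] == 0.0


def _one_factor_pseudo_f(d, labels):
    """Classic one-way PERMANOVA statistic from within/total squared distances."""
    n = len(labels)
    ss_total = (d[np.triu_indices(n, 1)] ** 2).sum() / n
    ss_within = 0.0
    for g in set(labels):
        idx = np.flatnonzero(np.asarray(labels) == g)
        sub = d[np.ix_(idx, idx)]
        ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    a = len(set(labels))
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def test_equidistant_points_give_p_one(self):
        d = np.full((6, 6), 0.7)
        np.fill_diagonal(d, 0)
        design = pd.DataFrame({"g": list("aaabbb")}, index=[str(i) for i in range(6)])
        res = permanova(DistanceMatrix(d, ids=design.index), design, ["g"], n_perm=99, seed=0)
        assert res.loc["g", "p"] == pytest.approx(1.0)

    def test_exact_p_matches_exhaustive_enumeration(self, rng):
        pts = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(4, 1, (3, 2))])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(6)]
        design = pd.DataFrame({"g": list("aaabbb")}, index=ids)
        res = permanova(DistanceMatrix(d, ids=ids), design, ["g"], exact=True)

        f_obs = _one_factor_pseudo_f(d, list("aaabbb"))
        assert res.loc["g", "F"] == pytest.approx(f_obs)
        exceed = 0
        perms = list(itertools.permutations(range(6)))
        for p in perms:
            labels = np.array(list("aaabbb"))[list(p)]
            if _one_factor_pseudo_f(d, labels) >= f_obs - 1e-12:
                exceed += 1
        assert res.loc["g", "p"] == pytest.approx(exceed / len(perms))

    def test_r2_sums_to_one_with_interaction(self, microbiome_sim):
        from mosscrust.community import bray_curtis

        d = bray_curtis(microbiome_sim.table)
        res = permanova(
            d,
            microbiome_sim.metadata,
            ["desert_class", "moss_species", "desert_class:moss_species"],
            n_perm=9,
            seed=0,
        )
        terms = res.drop(index="Total")
        assert terms["R2"].sum() == pytest.approx(1.0)
        assert res.loc["Total", "SumOfSqs"] == pytest.approx(
            terms["SumOfSqs"].sum(), rel=1e-9
        )

    def test_agrees_with_skbio_one_factor(self, microbiome_sim):
        from mosscrust.community import bray_curtis

        d = bray_curtis(microbiome_sim.table)
        mine = permanova(d, microbiome_sim.metadata, ["moss_species"], n_perm=999, seed=1)
        theirs = skbio_permanova(d, microbiome_sim.metadata, column="moss_species", permutations=999)
        assert mine.loc["moss_species", "F"] == pytest.approx(theirs["test statistic"])

    def test_invariant_to_consistent_relabeling(self, rng):
        pts = rng.normal(size=(8, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(8)]
        labels = list("aabbaabb")
        design = pd.DataFrame({"g": labels}, index=ids)
        res1 = permanova(DistanceMatrix(d, ids=ids), design, ["g"], n_perm=199, seed=3)
        perm = rng.permutation(8)
        d2 = d[np.ix_(perm, perm)]
        ids2 = [ids[i] for i in perm]
        design2 = pd.DataFrame({"g": [labels[i] for i in perm]}, index=ids2)
        res2 = permanova(DistanceMatrix(d2, ids=ids2), design2, ["g"], n_perm=199, seed=3)
        assert res1.loc["g", "F"] == pytest.approx(res2.loc["g", "F"])
        assert res1.loc["g", "R2"] == pytest.approx(res2.loc["g", "R2"])

    def test_aliased_term_rejected(self):
        d = np.abs(np.subtract.outer(np.arange(6.0), np.arange(6.0)))
        ids = [str(i) for i in range(6)]
        design = pd.DataFrame({"g": list("aaabbb"), "same": list("aaabbb")}, index=ids)
        with pytest.raises(AliasedDesignError):
            permanova(DistanceMatrix(d, ids=ids), design, ["g", "same"], n_perm=9)


class TestLefse:
    def _toy(self, rng, shift=0.0):
        n = 18
        counts = rng.poisson(50, size=(n, 30)) + 1
        if shift:
            counts[:9, 0] = rng.poisson(50 * shift, 9) + 1
        samples = [f"s{i}" for i in range(n)]
        features = [f"f{j}" for j in range(30)]
        taxonomy = pd.DataFrame(
            {
                "phylum": ["P1"] * 15 + ["P2"] * 15,
                "genus": [f"G{j}" for j in range(30)],
            },
            index=features,
        )
        classes = pd.Series(np.repeat(["Hyp", "Hyo"], 9), index=samples)
        return OtuTable(pd.DataFrame(counts, index=samples, columns=features)), taxonomy, classes

    def test_identical_distributions_not_reported(self, rng):
        table, taxonomy, classes = self._toy(rng)
        res = lefse(table, taxonomy, classes, seed=0, levels=("phylum", "genus"))
        assert "G0" not in set(res.taxon)

    def test_strongly_shifted_feature_detected(self, rng):
        table, taxonomy, classes = self._toy(rng, shift=50.0)
        res = lefse(table, taxonomy, classes, seed=0, levels=("phylum", "genus"))
        row = res[(res.taxon == "G0") & (res.level == "genus")]
        assert len(row) == 1
        assert row.iloc[0].lda_score > 2.0
        assert row.iloc[0].enriched_class == "Hyp"

    def test_constant_taxon_skipped(self, rng):
        table, taxonomy, classes = self._toy(rng)
        counts = table.counts.copy()
        counts["f1"] = 0
        counts.iloc[0, 1] = 0  # stays constant zero
        res = lefse(OtuTable(counts), taxonomy, classes, seed=0, levels=("genus",))
        assert "G1" not in set(res.taxon)


class TestGradientLength:
    def _gradient_table(self, n_samples, turnover, rng, n_species=40):
        """Gaussian species responses along a 1-D gradient; turnover in SD units."""
        grad = np.linspace(0, turnover, n_samples)
        optima = np.linspace(-1, turnover + 1, n_species)
        mu = 200 * np.exp(-0.5 * (grad[:, None] - optima[None, :]) ** 2)
        counts = rng.poisson(mu) + (mu > 100).astype(int)
        counts[:, 0] += 1  # positive row sums
        return OtuTable(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(n_samples)],
                         columns=[f"f{j}" for j in range(n_species)])
        )

    def test_long_turnover_selects_cca(self, rng):
        table = self._gradient_table(20, 12.0, rng)
        choice = gradient_length_select(table)
        assert choice["axis1_length"] > 3.5
        assert choice["method"] == "CCA"

    def test_short_gradient_selects_rda(self, rng):
        table = self._gradient_table(20, 0.8, rng)
        choice = gradient_length_select(table)
        assert choice["method"] == "RDA"

    def test_boundary_is_closed(self, rng):
        table = self._gradient_table(15, 6.0, rng)
        length = dca_axis1_gradient_length(table)
        assert gradient_length_select(table, boundary=length)["method"] == "CCA"

    def test_single_sample_rejected(self):
        t = OtuTable(pd.DataFrame([[1, 2]], index=["s0"], columns=["f0", "f1"]))
        with pytest.raises(ValueError):
            dca_axis1_gradient_length(t)


class TestConstrainedOrdination:
    def _table_with_gradient(self, rng, n=16, p=25):
        grad = np.linspace(-1, 1, n)
        mu = 100 * np.exp(grad[:, None] * np.linspace(-1, 1, p)[None, :])
        counts = rng.poisson(mu) + 1
        table = OtuTable(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(n)],
                         columns=[f"f{j}" for j in range(p)])
        )
        return table, grad

    @pytest.mark.parametrize("method", ["RDA", "CCA"])
    def test_driving_covariate_attains_smallest_p(self, rng, method):
        table, grad = self._table_with_gradient(rng)
        covs = pd.DataFrame(
            {"driver": grad, "noise1": rng.normal(size=16), "noise2": rng.normal(size=16)},
            index=table.sample_ids,
        )
        res = constrained_ordination(table, covs, method=method, n_perm=199, seed=0)
        marg = res["marginal"]
        assert marg.loc["driver", "p"] == marg["p"].min()
        assert marg.loc["driver", "R2"] == marg["R2"].max()

    def test_axis_proportions_nonincreasing(self, rng):
        table, grad = self._table_with_gradient(rng)
        covs = pd.DataFrame({"driver": grad, "n1": rng.normal(size=16)}, index=table.sample_ids)
        res = constrained_ordination(table, covs, method="RDA", n_perm=9, seed=0)
        eig = np.asarray(res["ordination"].eigvals)
        assert np.all(eig >= -1e-9)
        constrained = eig[: covs.shape[1]]  # remaining axes are residual PCA
        assert np.all(np.diff(constrained) <= 1e-9)

    def test_zero_variance_covariate_rejected(self, rng):
        table, grad = self._table_with_gradient(rng)
        covs = pd.DataFrame({"flat": np.ones(16)}, index=table.sample_ids)
        with pytest.raises(ValueError):
            constrained_ordination(table, covs, method="RDA")

    def test_null_covariate_type_one_error(self, rng):
        """Permutation p for an unrelated covariate is roughly uniform."""
        rejections = 0
        n_sims = 100
        for k in range(n_sims):
            local = np.random.default_rng(k)
            table, grad = self._table_with_gradient(local, n=12, p=15)
            covs = pd.DataFrame({"noise": local.normal(size=12)}, index=table.sample_ids)
            res = constrained_ordination(table, covs, method="RDA", n_perm=99, seed=k)
            if res["marginal"].loc["noise", "p"] <= 0.05:
                rejections += 1
        assert 0.005 <= rejections / n_sims <= 0.12


class TestHeatmap:
    def test_perfect_monotone_pairs(self, rng):
        n = 18
        base = np.arange(1, n + 1, dtype=float)  # strictly monotone, no rank ties
        counts = pd.DataFrame(
            {"up": base * 7, "down": base[::-1] * 5},
            index=[f"s{i}" for i in range(n)],
        ).astype(int)
        covs = pd.DataFrame({"factor": base + rng.normal(0, 1e-9, n)}, index=counts.index)
        res = factor_taxon_heatmap(OtuTable(counts), covs, top_n=2)
        assert res.rho.loc["up", "factor"] == pytest.approx(1.0)
        assert res.rho.loc["down", "factor"] == pytest.approx(-1.0)
        assert res.stars.loc["up", "factor"] == "***"

    def test_p_matches_permutation_oracle(self, rng):
        n = 18
        x = rng.normal(size=n)
        y = 0.6 * x + rng.normal(size=n)
        rho, p = spearman_matrix(pd.DataFrame({"x": x, "y": y}))
        obs = abs(rho.loc["x", "y"])
        null = np.empty(20000)
        local = np.random.default_rng(0)
        ry = ss.rankdata(y)
        rx = ss.rankdata(x)
        for i in range(null.size):
            null[i] = np.corrcoef(rx, local.permutation(ry))[0, 1]
        p_mc = np.mean(np.abs(null) >= obs - 1e-12)
        assert p.loc["x", "y"] == pytest.approx(p_mc, abs=0.02)

    def test_exact_small_n_p_matches_enumeration(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        rho, p = spearman_matrix(pd.DataFrame({"x": x, "y": y}), exact_max_n=10)
        obs = rho.loc["x", "y"]
        count = 0
        perms = list(itertools.permutations(range(6)))
        for perm in perms:
            r = ss.spearmanr(x, [y[i] for i in perm]).statistic
            if abs(r) >= abs(obs) - 1e-12:
                count += 1
        assert p.loc["x", "y"] == pytest.approx(count / len(perms))

    def test_star_thresholds(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.01) == "**"
        assert significance_stars(0.001) == "***"
        assert significance_stars(0.2) == ""
        assert significance_stars(float("nan")) == ""

    def test_constant_genus_reported_missing(self, rng):
        counts = pd.DataFrame(
            {"flat": np.full(10, 5), "varies": rng.integers(1, 50, 10)},
            index=[f"s{i}" for i in range(10)],
        )
        covs = pd.DataFrame({"factor": rng.normal(size=10)}, index=counts.index)
        res = factor_taxon_heatmap(OtuTable(counts), covs, top_n=2)
        assert math.isnan(res.rho.loc["flat", "factor"])
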