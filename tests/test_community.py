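"""Diversity, distance, ordination and Venn computations against closed forms
and small exhaustive oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from skbio import DistanceMatrix

from mosscrust.community import (
    EmptySampleError,
    OtuTable,
    alpha_diversity,
    bray_curtis,
    core_and_exclusive,
    dominant_taxa,
    nmds,
    read_newick,
    unweighted_unifrac,
    upgma,
)


def _table(rows, samples=None, features=None):
    rows = np.asarray(rows)
    samples = samples or [f"s{i}" for i in range(rows.shape[0])]
    features = features or [f"f{i}" for i in range(rows.shape[1])]
    return OtuTable(pd.DataFrame(rows, index=samples, columns=features))


class TestAlphaDiversity:
    def test_chao1_closed_forms(self):
        # S_obs=10, F1=3, F2=2 -> 10 + 3*2/(2*3) = 11
        counts = [1, 1, 1, 2, 2, 3, 4, 5, 6, 7]
        t = _table([counts])
        assert alpha_diversity(t, ("chao1",)).iloc[0, 0] == pytest.approx(11.0)
        # no singletons -> chao1 = S_obs
        t2 = _table([[2, 3, 4, 5]])
        assert alpha_diversity(t2, ("chao1",)).iloc[0, 0] == pytest.approx(4.0)

    def test_shannon_equal_abundances(self):
        t = _table([[5, 5, 5, 5, 5, 5]])
        assert alpha_diversity(t, ("shannon",)).iloc[0, 0] == pytest.approx(math.log(6))

    def test_goods_coverage(self):
        counts = [1, 1] + [98]
        t = _table([counts])
        assert alpha_diversity(t, ("goods_coverage",)).iloc[0, 0] == pytest.approx(0.98)

    def test_faith_pd_manual_tree(self):
        tree = read_newick("((f0:1,f1:2):0.5,(f2:1,f3:1):0.5):0;")
        t = _table([[1, 0, 1, 0]], features=["f0", "f1", "f2", "f3"])
        # spans f0 (1) + its stem (0.5) + f2 (1) + its stem (0.5)
        got = alpha_diversity(t, ("faith_pd",), tree=tree).iloc[0, 0]
        assert got == pytest.approx(3.0)

    def test_faith_requires_tree_and_leaves(self, tiny_table):
        with pytest.raises(ValueError):
            alpha_diversity(tiny_table, ("faith_pd",))
        tree = read_newick("(f1:1,f2:1):0;")
        with pytest.raises(ValueError, match="missing"):
            alpha_diversity(tiny_table, ("faith_pd",), tree=tree)

    def test_empty_sample_rejected(self):
        with pytest.raises(EmptySampleError):
            _table([[0, 0, 0]])


class TestBrayCurtis:
    def test_identical_disjoint_and_formula(self):
        t = _table([[2, 2, 0], [2, 2, 0], [0, 0, 5], [0, 2, 2]])
        d = bray_curtis(t)
        assert d["s0", "s1"] == pytest.approx(0.0)
        assert d["s0", "s2"] == pytest.approx(1.0)
        assert d["s0", "s3"] == pytest.approx(0.5)  # 1 - 2*2/(4+4)


def _unifrac_oracle(tree_str, presence_a, presence_b, features):
    """Branch-by-branch enumeration of unweighted UniFrac."""
    tree = read_newick(tree_str)
    in_a = {f for f, p in zip(features, presence_a) if p}
    in_b = {f for f, p in zip(features, presence_b) if p}
    unique = total = 0.0
    for node in tree.traverse(include_self=False):
        tips = {t.name for t in node.tips()} or {node.name}
        la, lb = bool(tips & in_a), bool(tips & in_b)
        if la or lb:
            total += node.length
            if la != lb:
                unique += node.length
    return unique / total


class TestUnweightedUnifrac:
    TREE = "((f0:0.7,f1:2.1):0.4,(f2:1.3,f3:0.2):0.9):0;"

    def test_identical_presence_zero(self):
        t = _table([[3, 0, 2, 0], [1, 0, 9, 0]], features=["f0", "f1", "f2", "f3"])
        d = unweighted_unifrac(t, read_newick(self.TREE))
        assert d["s0", "s1"] == pytest.approx(0.0)

    def test_disjoint_star_tree_is_one(self):
        star = "(f0:1,f1:1,f2:1,f3:1):0;"
        t = _table([[1, 1, 0, 0], [0, 0, 1, 1]], features=["f0", "f1", "f2", "f3"])
        d = unweighted_unifrac(t, read_newick(star))
        assert d["s0", "s1"] == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "pa,pb",
        [((1, 0, 1, 0), (0, 1, 0, 1)), ((1, 1, 0, 0), (1, 0, 1, 0)), ((1, 1, 1, 0), (0, 0, 1, 1))],
    )
    def test_matches_branch_enumeration_oracle(self, pa, pb):
        features = ["f0", "f1", "f2", "f3"]
        t = _table([list(pa), list(pb)], features=features)
        d = unweighted_unifrac(t, read_newick(self.TREE))
        assert d["s0", "s1"] == pytest.approx(_unifrac_oracle(self.TREE, pa, pb, features))

    def test_counts_beyond_presence_do_not_matter(self, rng):
        features = ["f0", "f1", "f2", "f3"]
        a = np.array([[5, 0, 2, 1], [0, 3, 0, 4]])
        b = (a > 0) * rng.integers(1, 50, a.shape)
        da = unweighted_unifrac(_table(a, features=features), read_newick(self.TREE))
        db = unweighted_unifrac(_table(b, features=features), read_newick(self.TREE))
        assert da["s0", "s1"] == pytest.approx(db["s0", "s1"])


class TestNmds:
    def test_recovers_exact_planar_configuration(self, rng):
        pts = rng.random((7, 2)) * 5
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = nmds(DistanceMatrix(d), restarts=20, seed=0, max_iter=2000, tol=1e-10)
        assert res.stress <= 1e-3

    def test_stress_near_dense_gradient_oracle(self, rng):
        n = 6
        m = rng.random((n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        res = nmds(DistanceMatrix(d), restarts=20, seed=1)

        # oracle: dense multi-start gradient minimization of stress-1
        from mosscrust.community import _kruskal_stress1

        best = np.inf
        for k in range(30):
            x0 = np.random.default_rng(k).normal(size=n * 2)
            opt = minimize(
                lambda x: _kruskal_stress1(d, x.reshape(n, 2)), x0, method="Nelder-Mead",
                options={"maxiter": 3000, "fatol": 1e-10},
            )
            best = min(best, opt.fun)
        assert res.stress <= best + 1e-2

    def test_requires_enough_samples(self):
        d = DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            nmds(d, dims=2)


class TestUpgma:
    def test_two_samples_merge_at_distance(self):
        d = DistanceMatrix(np.array([[0, 0.8], [0.8, 0]]), ids=["a", "b"])
        res = upgma(d)
        assert res.cophenetic().loc["a", "b"] == pytest.approx(0.8)
        assert res.newick.count(",") == 1

    def test_three_point_topology(self):
        d = DistanceMatrix(
            np.array([[0, 0.2, 0.9], [0.2, 0, 0.8], [0.9, 0.8, 0]]), ids=list("ABC")
        )
        res = upgma(d)
        coph = res.cophenetic()
        assert coph.loc["A", "B"] == pytest.approx(0.2)
        assert coph.loc["A", "C"] == pytest.approx(0.85)  # mean of 0.9, 0.8

    def test_cophenetic_matches_stepwise_agglomeration(self, rng):
        n = 6
        m = rng.random((n, n)) + 0.1
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        got = upgma(DistanceMatrix(d)).cophenetic().to_numpy()
        expected = _stepwise_upgma(d)
        assert np.allclose(got, expected)

    def test_heights_nondecreasing(self, rng):
        n = 7
        m = rng.random((n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        res = upgma(DistanceMatrix(d))
        heights = res.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)


def _stepwise_upgma(d):
    """Independent hand agglomeration (size-weighted average linkage)."""
    n = d.shape[0]
    active = {i: [i] for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    coph = np.zeros_like(d)
    next_id = n
    members = {i: [i] for i in range(n)}
    while len(active) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: kv[1])
        for a in members[i]:
            for b in members[j]:
                coph[a, b] = coph[b, a] = h
        members[next_id] = members[i] + members[j]
        si, sj = len(members[i]), len(members[j])
        del active[i], active[j]
        new_dist = {}
        for (a, b), val in dist.items():
            if a in (i, j) or b in (i, j):
                continue
            new_dist[(a, b)] = val
        for k in active:
            di = dist[(min(i, k), max(i, k))]
            dj = dist[(min(j, k), max(j, k))]
            new_dist[(min(k, next_id), max(k, next_id))] = (si * di + sj * dj) / (si + sj)
        active[next_id] = True
        dist = new_dist
        next_id += 1
    return coph


class TestVenn:
    def test_region_counts_match_power_set_oracle(self, rng):
        n_groups = 6
        samples = [f"s{i}" for i in range(12)]
        groups = pd.Series([f"g{i % n_groups}" for i in range(12)], index=samples)
        counts = rng.integers(0, 3, (12, 40))
        counts[:, 0] = 1  # keep all row sums positive
        t = OtuTable(pd.DataFrame(counts, index=samples, columns=[f"f{j}" for j in range(40)]))
        res = core_and_exclusive(t, groups)
        # oracle: directly classify each OTU by its exact group-presence set
        presence = {
            g: (t.counts.loc[groups[groups == g].index].sum(axis=0) > 0) for g in groups.unique()
        }
        from collections import Counter

        regions = Counter()
        for f in t.feature_ids:
            key = tuple(sorted(g for g in presence if presence[g][f]))
            if key:
                regions[key] += 1
        for combo, count in regions.items():
            assert res.regions[combo] == count
        assert sum(res.regions.values()) == sum(regions.values())

    def test_core_and_exclusive_basics(self):
        counts = pd.DataFrame(
            {"everywhere": [1, 1, 1], "only_g0": [2, 0, 0], "pad": [1, 1, 1]},
            index=["s0", "s1", "s2"],
        )
        groups = pd.Series({"s0": "g0", "s1": "g1", "s2": "g2"})
        res = core_and_exclusive(OtuTable(counts), groups)
        assert res.core == 2  # everywhere + pad
        assert res.exclusive["g0"] == 1

    def test_core_monotone_as_groups_added(self, microbiome_sim):
        meta = microbiome_sim.metadata
        two = core_and_exclusive(microbiome_sim.table, meta["moss_species"])
        six = core_and_exclusive(
            microbiome_sim.table, meta["moss_species"] + "-" + meta["desert_class"]
        )
        assert six.core <= two.core

    def test_empty_group_rejected(self, tiny_table):
        groups = pd.Series({"s1": "a", "s2": "a", "s3": "a"})
        with pytest.raises(ValueError):
            core_and_exclusive(tiny_table, groups.drop("s3"))


class TestDominantTaxa:
    def test_single_taxon_and_threshold_boundary(self):
        taxonomy = pd.DataFrame(
            {"phylum": ["P1", "P1", "P2"]}, index=["f0", "f1", "f2"]
        )
        t = _table([[99, 0, 1], [98, 1, 1]], features=["f0", "f1", "f2"])
        res = dominant_taxa(t, taxonomy, rank="phylum", threshold=0.01)
        assert list(res.index) == ["P1"]  # P2 sits exactly at 1%: strict >
        lone = _table([[7]], features=["f0"])
        res2 = dominant_taxa(lone, taxonomy.iloc[:1], rank="phylum")
        assert res2["P1"] == pytest.approx(1.0)

    def test_recovers_known_mixture_weights(self, rng):
        taxonomy = pd.DataFrame({"phylum": [f"P{j}" for j in range(5)]},
                                index=[f"f{j}" for j in range(5)])
        weights = np.array([0.5, 0.3, 0.15, 0.04, 0.01])
        counts = np.tile((weights * 10000).astype(int), (4, 1))
        t = _table(counts, features=[f"f{j}" for j in range(5)])
        res = dominant_taxa(t, taxonomy, rank="phylum", threshold=0.05)
        assert set(res.index) == {"P0", "P1", "P2"}
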