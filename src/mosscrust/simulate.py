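"""Synthetic field-survey, physiology and microbiome data with known ground truth.

The generators emulate the sampling design of the study this package
models: a 14-site quadrat survey of a bryophyte species pool, a 7-species
x 5-index drought-physiology experiment, and an 18-sample microbiome
(2 moss species x 3 desertification classes x 3 composite replicates)
with a moss-species compositional effect stronger than the class effect,
planted differentially-abundant genera and planted co-abundance modules.
Every generator records the truth it embeds so downstream stages can be
tested for recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from mosscrust.community import OtuTable, read_newick
from mosscrust.config import DESERT_CLASSES, MOSS_SPECIES, SimulationConfig
from mosscrust.reference import BACTERIAL_GUILDS, FUNGAL_GUILDS
from mosscrust.survey import SurveyDataset

#: Directionality of the five drought-physiology indexes: membership of a
#: beneficial index rises with the raw value, of a harmful one falls.
INDEX_DIRECTIONS = {
    "MP": "harmful",
    "Pro": "beneficial",
    "MDA": "harmful",
    "SOD": "beneficial",
    "POD": "beneficial",
}

# Raw-value ranges (best -> worst species mean) per index; units: MP %,
# Pro mg/g FW, MDA nmol/g FW, SOD and POD activity units/g FW.
_PHYSIO_RANGES = {
    "MP": (20.0, 80.0),
    "Pro": (1.5, 0.1),
    "MDA": (2.0, 10.0),
    "SOD": (300.0, 100.0),
    "POD": (250.0, 50.0),
}

_PHYLA = (
    "Actinobacteria",
    "Proteobacteria",
    "Cyanobacteria",
    "Chloroflexi",
    "Acidobacteria",
    "Bacteroidetes",
    "Verrucomicrobia",
    "Firmicutes",
)

TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class SurveySim:
    dataset: SurveyDataset
    truth_ranking: list[str]  # species ids, most to least occupied (expected)
    expected_counts: pd.Series


def generate_survey(config: SimulationConfig) -> SurveySim:
    """Bernoulli-occupancy quadrat survey with a known expected-count ranking."""
    rng = config.rng("survey")
    probs = config.default_occupancy()  # (species, sites)
    species = [f"sp{i + 1:02d}" for i in range(config.n_species_pool)]
    sites = [f"site{i + 1:02d}" for i in range(config.n_sites)]
    records = []
    for s_idx, site in enumerate(sites):
        n_quadrats = config.quadrats_per_site[s_idx]
        present = rng.random((config.n_species_pool, n_quadrats)) < probs[:, [s_idx]]
        sp_idx, q_idx = np.nonzero(present)
        for i, q in zip(sp_idx, q_idx):
            records.append((site, f"{site}-q{q + 1:02d}", species[i]))
    df = pd.DataFrame(records, columns=["site_id", "quadrat_id", "species_id"])
    expected = pd.Series(
        (probs * np.asarray(config.quadrats_per_site)[None, :]).sum(axis=1),
        index=species,
        name="expected_quadrats",
    )
    ranking = list(expected.sort_values(ascending=False, kind="stable").index)
    coverage = pd.Series(
        np.clip(expected / expected.max() * 0.8 + rng.normal(0, 0.03, len(species)), 0, 1),
        index=species,
        name="coverage",
    )
    dataset = SurveyDataset(
        records=df,
        total_quadrats=int(sum(config.quadrats_per_site)),
        total_samples=len(df),
        total_sites=config.n_sites,
        coverage=coverage,
    )
    return SurveySim(dataset=dataset, truth_ranking=ranking, expected_counts=expected)


@dataclass
class PhysioSim:
    values: pd.DataFrame  # long: species, index, replicate, value
    directions: dict[str, str]
    truth_ranking: list[str]  # species ids, most to least drought resistant
    species_means: pd.DataFrame  # species x index configured means


def generate_physiology(config: SimulationConfig) -> PhysioSim:
    """Replicate physiology values with an embedded true drought-resistance ranking.

    Species quality is equally spaced; each index mean interpolates its
    best->worst range by quality, and replicate noise is sized so adjacent
    species means are ``physio_separation_sd`` replicate-SDs apart.
    """
    if config.n_physio_species < 2:
        raise ValueError("need at least 2 species")
    rng = config.rng("physiology")
    species = [f"moss{i + 1:02d}" for i in range(config.n_physio_species)]
    order = rng.permutation(config.n_physio_species)  # rank position of each species
    quality = np.empty(config.n_physio_species)
    denom = max(config.n_physio_species - 1, 1)
    quality[order] = 1 - np.arange(config.n_physio_species) / denom
    means = {}
    rows = []
    for index, (best, worst) in _PHYSIO_RANGES.items():
        mean_vals = best + (1 - quality) * (worst - best)
        means[index] = mean_vals
        gap = abs(worst - best) / denom
        sd = gap / config.physio_separation_sd if config.physio_separation_sd > 0 else 0.0
        for sp, mu in zip(species, mean_vals):
            noise = rng.normal(0, sd, config.n_replicates) if sd > 0 else np.zeros(config.n_replicates)
            for r, eps in enumerate(noise, start=1):
                rows.append((sp, index, r, mu + eps))
    values = pd.DataFrame(rows, columns=["species", "index", "replicate", "value"])
    truth = [species[i] for i in order]
    return PhysioSim(
        values=values,
        directions=dict(INDEX_DIRECTIONS),
        truth_ranking=truth,
        species_means=pd.DataFrame(means, index=species),
    )


def _make_taxonomy(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Hierarchical 7-rank taxonomy over features; returns features x ranks."""
    n_gen = config.n_genera
    genera = [f"Genus_{j + 1:03d}" for j in range(n_gen)]
    phylum_of = rng.choice(len(_PHYLA), size=n_gen)
    lineage_rows = {}
    for j, g in enumerate(genera):
        ph = _PHYLA[phylum_of[j]]
        cl = f"{ph}_c{rng.integers(1, 3)}"
        od = f"{cl}_o{rng.integers(1, 3)}"
        fa = f"{od}_f{rng.integers(1, 3)}"
        lineage_rows[g] = ("Bacteria", ph, cl, od, fa, g)
    # feature -> genus: reserved singleton genera first, rest spread randomly
    return lineage_rows, genera


@dataclass
class MicrobiomeSim:
    table: OtuTable
    taxonomy: pd.DataFrame  # features x TAXONOMY_RANKS
    metadata: pd.DataFrame  # samples x (moss_species, desert_class, covariates)
    tree: TreeNode | None
    truth: dict


def _random_coalescent_newick(labels: list[str], rng: np.random.Generator) -> str:
    """Random bifurcating rooted tree with exponential branch lengths."""
    nodes = [(lab, 0.0) for lab in labels]
    height = 0.0
    k = len(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        height += rng.exponential(1.0 / max(len(nodes), 1))
        (nwk_j, h_j) = nodes.pop(j)
        (nwk_i, h_i) = nodes.pop(i)
        merged = f"({nwk_i}:{height - h_i:.8g},{nwk_j}:{height - h_j:.8g})"
        nodes.append((merged, height))
    return nodes[0][0] + ":0.0;"


def generate_microbiome(
    config: SimulationConfig, include_tree: bool = True
) -> MicrobiomeSim:
    """Dirichlet-multinomial OTU counts with planted structure and truth record.

    Compositional shifts (moss species, desertification class) are applied
    on the log-relative-abundance scale and renormalized, so effect scales
    read as log-fold changes. Planted biomarker OTUs sit in dedicated
    singleton genera and differ ``biomarker_fold``-fold between the two
    moss species; planted co-abundance modules share a per-sample latent
    factor and are placed among the top-abundance genera.
    """
    if config.library_size_mean <= 0:
        raise ValueError("library_size_mean must be > 0")
    rng = config.rng("microbiome")
    n_feat = config.n_features
    n_mod_genera = config.n_modules * config.module_size
    n_pair_genera = 2 * config.n_coupled_pairs
    n_special = config.n_planted_biomarkers + n_mod_genera + n_pair_genera + 3
    if n_feat < n_special:
        raise ValueError("n_features too small for the planted structure")
    if config.n_genera < n_special + 10:
        raise ValueError("n_genera too small for the planted structure")

    features = [f"OTU_{i + 1:04d}" for i in range(n_feat)]
    lineage_rows, genera = _make_taxonomy(config, rng)

    # planted features occupy dedicated singleton genera
    bm_feats = list(range(config.n_planted_biomarkers))
    mod_feats = list(
        range(config.n_planted_biomarkers, config.n_planted_biomarkers + n_mod_genera)
    )
    pair_feats = list(
        range(mod_feats[-1] + 1 if mod_feats else config.n_planted_biomarkers,
              config.n_planted_biomarkers + n_mod_genera + n_pair_genera)
    )
    cov_feats = list(range(n_special - 3, n_special))
    genus_of = np.empty(n_feat, dtype=int)
    genus_of[:n_special] = np.arange(n_special)
    genus_of[n_special:] = rng.integers(n_special, config.n_genera, size=n_feat - n_special)

    taxonomy = pd.DataFrame(
        [
            lineage_rows[genera[genus_of[i]]] + (f"{genera[genus_of[i]]}_sp",)
            for i in range(n_feat)
        ],
        index=pd.Index(features, name="feature_id"),
        columns=list(TAXONOMY_RANKS),
    )

    # sample design
    n_reps = config.n_samples // (len(MOSS_SPECIES) * len(DESERT_CLASSES))
    samples, sp_lab, cl_lab = [], [], []
    for sp in MOSS_SPECIES:
        for cl in DESERT_CLASSES:
            for r in range(1, n_reps + 1):
                samples.append(f"{sp}_{cl}_{r}")
                sp_lab.append(sp)
                cl_lab.append(cl)
    sp_lab = np.array(sp_lab)
    cl_lab = np.array(cl_lab)

    # base composition
    # light-tailed base keeps any one genus from dominating the composition;
    # planted genera sit just inside the top-50 without swamping the total
    base = rng.normal(0.0, 1.0, n_feat)
    base[bm_feats] = rng.normal(2.0, 0.3, len(bm_feats))
    base[mod_feats] = rng.normal(3.7, 0.1, len(mod_feats))
    base[pair_feats] = rng.normal(3.7, 0.1, len(pair_feats))
    base[cov_feats] = rng.normal(3.7, 0.1, 3)

    # centered per-level shift vectors on a sparse support; planted biomarker
    # features are excluded so their fold change stays exactly as recorded
    planted_mask = np.zeros(n_feat, dtype=bool)
    planted_mask[bm_feats] = True

    def _level_shifts(levels: tuple[str, ...], scale: float) -> dict[str, np.ndarray]:
        support = (rng.random(n_feat) < config.effect_sparsity) & ~planted_mask
        raw = {lv: np.where(support, rng.normal(0.0, scale, n_feat), 0.0) for lv in levels}
        mean = np.mean([raw[lv] for lv in levels], axis=0)
        return {lv: raw[lv] - mean for lv in levels}

    species_shift = _level_shifts(MOSS_SPECIES, config.species_effect)
    class_shift = _level_shifts(DESERT_CLASSES, config.class_effect)

    # planted biomarkers: log-fold difference between the two species
    log_fold = math.log(config.biomarker_fold)
    bm_truth = []
    bm_shift = {sp: np.zeros(n_feat) for sp in MOSS_SPECIES}
    if log_fold != 0.0:
        for k, fidx in enumerate(bm_feats):
            enriched = MOSS_SPECIES[k % 2]
            bm_shift[enriched][fidx] += log_fold / 2
            other = MOSS_SPECIES[(k + 1) % 2]
            bm_shift[other][fidx] -= log_fold / 2
            bm_truth.append(
                {
                    "feature": features[fidx],
                    "genus": genera[genus_of[fidx]],
                    "enriched": enriched,
                    "log10_fold": math.log10(config.biomarker_fold),
                }
            )

    # covariates (drought indexes species-dependent; climate class-dependent)
    cov_rng = config.rng("covariates")
    sp_means = {
        "SOD": {"Hyp": 292.03, "Hyo": 229.18},
        "Pro": {"Hyp": 1.42, "Hyo": 1.16},
        "POD": {"Hyp": 180.0, "Hyo": 140.0},
        "MP": {"Hyp": 30.0, "Hyo": 40.0},
        "MDA": {"Hyp": 4.0, "Hyo": 5.5},
    }
    sp_sds = {"SOD": 15.0, "Pro": 0.08, "POD": 12.0, "MP": 3.0, "MDA": 0.4}
    cl_means = {
        "rain": {"Ve": 900.0, "Se": 1100.0, "Sl": 1300.0},
        "TEM": {"Ve": 17.0, "Se": 15.0, "Sl": 13.0},
        "sun": {"Ve": 1400.0, "Se": 1250.0, "Sl": 1100.0},
        "elevation": {"Ve": 1300.0, "Se": 1150.0, "Sl": 1000.0},
    }
    cl_sds = {"rain": 60.0, "TEM": 0.8, "sun": 60.0, "elevation": 60.0}
    meta = pd.DataFrame(
        {"moss_species": sp_lab, "desert_class": cl_lab}, index=pd.Index(samples, name="sample_id")
    )
    for cov, by_sp in sp_means.items():
        meta[cov] = [by_sp[s] for s in sp_lab] + cov_rng.normal(0, sp_sds[cov], len(samples))
    for cov, by_cl in cl_means.items():
        meta[cov] = [by_cl[c] for c in cl_lab] + cov_rng.normal(0, cl_sds[cov], len(samples))

    coupled = {"Pro": features[cov_feats[0]], "SOD": features[cov_feats[1]], "POD": features[cov_feats[2]]}

    # per-sample log composition; bounded (uniform, unit-SD) latent factors
    # keep the modules' compositional footprint from exploding in the tails
    half_width = math.sqrt(3.0)
    n_factors = config.n_modules + config.n_coupled_pairs
    all_factors = rng.uniform(-half_width, half_width, (n_factors, config.n_samples))
    if 0 < n_factors < config.n_samples:
        # factors are independent by design; enforce exact in-sample
        # orthogonality so chance correlations cannot merge planted blocks
        all_factors -= all_factors.mean(axis=1, keepdims=True)
        for i in range(n_factors):
            for j in range(i):
                prev = all_factors[j]
                all_factors[i] -= (all_factors[i] @ prev) / (prev @ prev) * prev
            sd = all_factors[i].std()
            if sd > 0:
                all_factors[i] /= sd
    factors = all_factors[: config.n_modules]
    pair_factors = all_factors[config.n_modules :]
    half = config.module_size // 2
    mod_signs = [
        np.array([1.0] * (config.module_size - half) + [-1.0] * half)
        for _ in range(config.n_modules)
    ]
    module_truth = {
        f"module_{m + 1}": [
            genera[genus_of[mod_feats[m * config.module_size + j]]]
            for j in range(config.module_size)
        ]
        for m in range(config.n_modules)
    }
    pair_truth = [
        (genera[genus_of[pair_feats[2 * k]]], genera[genus_of[pair_feats[2 * k + 1]]])
        for k in range(config.n_coupled_pairs)
    ]
    counts = np.zeros((config.n_samples, n_feat), dtype=np.int64)
    lib_sizes = np.maximum(
        rng.lognormal(math.log(config.library_size_mean) - 0.02, 0.2, config.n_samples), 100
    ).astype(np.int64)
    for s in range(config.n_samples):
        logp = base + species_shift[sp_lab[s]] + class_shift[cl_lab[s]] + bm_shift[sp_lab[s]]
        # sign-balanced co-abundance blocks: half the members respond up and
        # half down to the block's latent factor, centered so the block has
        # no common-mode shift and barely leaks into other taxa through
        # compositional closure
        for m in range(config.n_modules):
            sl = mod_feats[m * config.module_size : (m + 1) * config.module_size]
            delta = config.module_loading * mod_signs[m] * factors[m, s] + rng.normal(
                0, config.module_noise_sd, config.module_size
            )
            w = np.exp(base[sl])
            delta -= float((w * delta).sum() / w.sum())
            logp[sl] += delta
        for k in range(config.n_coupled_pairs):
            sl = pair_feats[2 * k : 2 * k + 2]
            delta = config.pair_loading * np.array([1.0, -1.0]) * pair_factors[
                k, s
            ] + rng.normal(0, config.module_noise_sd, 2)
            w = np.exp(base[sl])
            delta -= float((w * delta).sum() / w.sum())
            logp[sl] += delta
        for cov, feat in coupled.items():
            z = (meta[cov].iloc[s] - meta[cov].mean()) / meta[cov].std()
            logp[features.index(feat)] += config.covariate_coupling * z
        p = np.exp(logp - logp.max())
        p /= p.sum()
        alpha = np.maximum(p * config.dispersion, 1e-9)
        # planted module/pair/covariate taxa are modelled as tightly
        # host-associated: low overdispersion so their planted structure is
        # not drowned by sampling noise
        alpha[mod_feats] *= 20.0
        alpha[pair_feats] *= 20.0
        alpha[cov_feats] *= 20.0
        p_s = rng.dirichlet(alpha)
        counts[s] = rng.multinomial(lib_sizes[s], p_s)
    # guarantee positive totals (degenerate only at absurdly tiny libraries)
    for s in range(config.n_samples):
        if counts[s].sum() == 0:
            counts[s, int(np.argmax(base))] = 1

    table = OtuTable(pd.DataFrame(counts, index=samples, columns=features))
    tree = None
    if include_tree:
        tree_rng = config.rng("tree")
        tree = read_newick(_random_coalescent_newick(features, tree_rng))
    truth = {
        "biomarkers": bm_truth,
        "modules": module_truth,
        "pairs": pair_truth,
        "species_effect": config.species_effect,
        "class_effect": config.class_effect,
        "coupled_covariates": coupled,
        "coupled_genera": {cov: genera[genus_of[features.index(f)]] for cov, f in coupled.items()},
    }
    return MicrobiomeSim(table=table, taxonomy=taxonomy, metadata=meta, tree=tree, truth=truth)


def null_community_config(seed: int, **overrides) -> SimulationConfig:
    """Condition with no species- or class-linked community structure.

    Every channel tying the community to the design factors is off
    (compositional shifts, planted fold-changes, covariate coupling), so
    design labels are exchangeable; used for type-I-error calibration.
    """
    params = dict(
        species_effect=0.0, class_effect=0.0, biomarker_fold=1.0, covariate_coupling=0.0
    )
    params.update(overrides)
    return SimulationConfig(seed=seed, **params)


def planted_module_config(seed: int, **overrides) -> SimulationConfig:
    """Condition isolating the planted co-abundance modules.

    Species/class shifts and fold-change biomarkers are off so the
    co-occurrence structure is the planted modules plus satellites.
    """
    params = dict(species_effect=0.0, class_effect=0.0, biomarker_fold=1.0)
    params.update(overrides)
    return SimulationConfig(seed=seed, **params)


@dataclass
class GuildRuleSim:
    rules: pd.DataFrame  # rank, taxon, guild, confidence
    truth: dict[str, str]  # genus -> guild


def generate_guild_rules(
    config: SimulationConfig,
    taxonomy: pd.DataFrame,
    kingdom: str = "bacteria",
) -> GuildRuleSim:
    """Genus-level guild rules over a configured fraction of observed genera."""
    rng = config.rng("guilds")
    guilds = BACTERIAL_GUILDS if kingdom == "bacteria" else FUNGAL_GUILDS
    genera = sorted(taxonomy["genus"].dropna().unique())
    n_mapped = int(round(config.guild_fraction * len(genera)))
    mapped = list(rng.choice(genera, size=n_mapped, replace=False)) if n_mapped else []
    confidences = ("possible", "probable", "highly probable")
    rows, truth = [], {}
    for g in mapped:
        guild = guilds[int(rng.integers(len(guilds)))]
        conf = confidences[int(rng.integers(len(confidences)))]
        rows.append(("genus", g, guild, conf))
        truth[g] = guild
    rules = pd.DataFrame(rows, columns=["rank", "taxon", "guild", "confidence"])
    return GuildRuleSim(rules=rules, truth=truth)
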