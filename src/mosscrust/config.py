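"""Simulation configuration and seed management.

One master seed fans out to independent child generators per stage, so
each generator is reproducible on its own regardless of which stages a
caller runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


# Stable stage identifiers for seed fan-out; never reorder.
_STAGE_IDS = {
    "survey": 1,
    "physiology": 2,
    "microbiome": 3,
    "guilds": 4,
    "tree": 5,
    "covariates": 6,
}

#: Moss species codes of the two hosts the sequencing design crosses.
MOSS_SPECIES = ("Hyp", "Hyo")
#: Karst rocky desertification classes: very severely, severely, slightly.
DESERT_CLASSES = ("Ve", "Se", "Sl")


def _default_quadrat_counts(n_sites: int, total: int = 185) -> tuple[int, ...]:
    """Spread the survey's 185 quadrats over the sites as evenly as possible."""
    base = total // n_sites
    extra = total - base * n_sites
    return tuple(base + 1 if i < extra else base for i in range(n_sites))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic field survey, physiology and microbiome.

    Defaults reproduce the design of the study being modelled: 14 survey
    sites with 185 quadrats in total, 7 candidate moss species measured on
    5 physiological indexes, and 18 microbiome samples (2 moss species x 3
    desertification classes x 3 composite replicates) with ~2892 OTUs and
    a mean library of ~56,700 reads -- with the moss-species compositional
    shift stronger than the desertification-class shift.
    """

    seed: int = 0

    # --- survey ---
    n_sites: int = 14
    quadrats_per_site: int | Sequence[int] | None = None  # None -> 185 total
    n_species_pool: int = 30
    occupancy_probs: np.ndarray | None = None  # (n_species,) or (n_species, n_sites)

    # --- physiology ---
    n_physio_species: int = 7
    n_replicates: int = 3
    physio_separation_sd: float = 2.0  # adjacent-species mean gap in replicate SDs

    # --- microbiome ---
    n_samples: int = 18
    n_features: int = 2892
    n_genera: int = 534
    library_size_mean: int = 56728
    species_effect: float = 2.2  # log-fold scale of moss-species shift
    class_effect: float = 1.0   # log-fold scale of desertification-class shift
    effect_sparsity: float = 0.5  # fraction of features carrying each shift
    dispersion: float = 300.0   # Dirichlet concentration multiplier (overdispersion)
    n_planted_biomarkers: int = 20
    biomarker_fold: float = 100.0
    n_modules: int = 2
    module_size: int = 12
    module_loading: float = 1.2
    module_noise_sd: float = 0.25
    n_coupled_pairs: int = 6     # small satellite co-abundance pairs
    pair_loading: float = 1.5
    covariate_coupling: float = 1.0  # log-fold per SD of the coupled covariate

    # --- guild rules ---
    guild_fraction: float = 0.7

    def __post_init__(self) -> None:
        counts = {
            "n_sites": self.n_sites,
            "n_species_pool": self.n_species_pool,
            "n_physio_species": self.n_physio_species,
            "n_replicates": self.n_replicates,
            "n_samples": self.n_samples,
            "n_features": self.n_features,
            "n_genera": self.n_genera,
            "n_modules": self.n_modules,
            "module_size": self.module_size,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        if self.library_size_mean <= 0:
            raise ConfigurationError("library_size_mean must be > 0")
        if self.n_planted_biomarkers < 0 or self.n_coupled_pairs < 0:
            raise ConfigurationError("planted counts must be >= 0")
        if self.quadrats_per_site is None:
            self.quadrats_per_site = _default_quadrat_counts(self.n_sites)
        elif np.isscalar(self.quadrats_per_site):
            if self.quadrats_per_site < 1:
                raise ConfigurationError("quadrats_per_site must be >= 1")
            self.quadrats_per_site = tuple([int(self.quadrats_per_site)] * self.n_sites)
        else:
            self.quadrats_per_site = tuple(int(q) for q in self.quadrats_per_site)
            if len(self.quadrats_per_site) != self.n_sites:
                raise ConfigurationError("quadrats_per_site length must equal n_sites")
            if any(q < 1 for q in self.quadrats_per_site):
                raise ConfigurationError("quadrats_per_site entries must be >= 1")
        if self.occupancy_probs is not None:
            probs = np.asarray(self.occupancy_probs, dtype=float)
            if probs.ndim == 1:
                probs = np.tile(probs[:, None], (1, self.n_sites))
            if probs.shape != (self.n_species_pool, self.n_sites):
                raise ConfigurationError(
                    "occupancy_probs must be (n_species_pool,) or (n_species_pool, n_sites)"
                )
            if np.any(~np.isfinite(probs)) or np.any(probs < 0) or np.any(probs > 1):
                raise ConfigurationError("occupancy probabilities must lie in [0, 1]")
            self.occupancy_probs = probs
        if not 0 <= self.guild_fraction <= 1:
            raise ConfigurationError("guild_fraction must lie in [0, 1]")
        if not 0 <= self.effect_sparsity <= 1:
            raise ConfigurationError("effect_sparsity must lie in [0, 1]")
        if self.biomarker_fold <= 0:
            raise ConfigurationError("biomarker_fold must be > 0")
        if self.species_effect < 0 or self.class_effect < 0:
            raise ConfigurationError("effect scales must be >= 0")
        if self.n_samples % (len(MOSS_SPECIES) * len(DESERT_CLASSES)) != 0:
            raise ConfigurationError(
                "n_samples must be divisible by species x classes "
                f"({len(MOSS_SPECIES) * len(DESERT_CLASSES)})"
            )

    def rng(self, stage: str) -> np.random.Generator:
        """Child generator for *stage*, derived from the master seed."""
        if stage not in _STAGE_IDS:
            raise KeyError(f"unknown stage {stage!r}; one of {sorted(_STAGE_IDS)}")
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), _STAGE_IDS[stage]]))

    def default_occupancy(self) -> np.ndarray:
        """Geometric-decay occupancy profile giving a strict true ranking."""
        if self.occupancy_probs is not None:
            return self.occupancy_probs
        base = 0.45 * 0.87 ** np.arange(self.n_species_pool)
        return np.tile(base[:, None], (1, self.n_sites))
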