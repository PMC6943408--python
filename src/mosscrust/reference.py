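"""Bundled reference tables from the karst bryophyte field study this package models.

Two small printed tables travel with the package because they are inputs
to worked examples and cross-checks, not outputs of any computation here:

* the top-20 dominance table of the field survey (species frequency,
  S_N/S, S_N/N_a, N_a/T_a over 185 quadrats, 675 samples, 14 sites), and
* the drought-resistance membership table of the 7 candidate mosses
  (direction-adjusted memberships of MP, Pro, MDA, SOD and POD).

Known internal inconsistencies of the printed survey table are kept
as printed and flagged where relevant: the S_N/N_a column total is
printed as 49.865 although its entries sum to 56.501, and row 1 pairs a
frequency of 39.5 with S_N/S = 0.118, which no single quadrat count
reproduces. See ``docs/methods.md``.
"""

from __future__ import annotations

import pandas as pd

#: Survey-wide constants: samples collected, sites, quadrats.
TOTAL_SAMPLES = 675
TOTAL_SITES = 14
TOTAL_QUADRATS = 185

_DOMINANCE_ROWS = [
    ("Hypnum leptothallum", 39.5, 0.118, 6.636, 0.786),
    ("Didymodon fallax", 21.6, 0.059, 3.333, 0.857),
    ("Bryum recurvulum", 14.6, 0.040, 3.222, 0.357),
    ("Hyophila involuta", 13.5, 0.037, 5.400, 0.857),
    ("Thuidium kanedae", 13.5, 0.037, 3.571, 0.500),
    ("Hyophila javanica", 12.4, 0.034, 2.000, 0.643),
    ("Bryum argenteum", 11.9, 0.033, 2.556, 0.714),
    ("Trichostomum crispulum", 10.8, 0.030, 2.200, 0.643),
    ("Palamocladium euchloron", 10.8, 0.030, 2.500, 0.571),
    ("Didymodon constrictus var. constrictus", 9.7, 0.027, 2.143, 0.643),
    ("Barbula unguiculata", 8.1, 0.022, 1.875, 0.500),
    ("Anomodon viticulosus", 8.1, 0.022, 5.000, 0.214),
    ("Ptychomitrium gardneri", 8.1, 0.022, 1.875, 0.571),
    ("Meteorium polytrichum", 8.1, 0.022, 1.857, 0.571),
    ("Plagiomnium cuspidatum", 6.5, 0.018, 3.000, 0.286),
    ("Bryum funkii", 5.9, 0.016, 1.833, 0.429),
    ("Weissia breviseta", 5.4, 0.015, 1.667, 0.429),
    ("Racopilum cuspidigerum", 5.4, 0.015, 2.500, 0.286),
    ("Bryum algovicum", 4.3, 0.012, 1.333, 0.429),
    ("Eurhynchium eustegium", 4.3, 0.012, 2.000, 0.286),
]


def dominance_table() -> pd.DataFrame:
    """Top-20 dominance table of the survey, as printed (one row per species)."""
    return pd.DataFrame(
        _DOMINANCE_ROWS,
        columns=["species", "species_frequency", "sn_over_s", "sn_over_na", "na_over_ta"],
    ).set_index("species")


#: Printed column totals of the dominance table (S_N/N_a total as printed,
#: even though it is not the sum of the printed entries).
DOMINANCE_PRINTED_TOTALS = {"sn_over_s": 0.621, "sn_over_na": 49.865, "na_over_ta": 10.572}

_MEMBERSHIP_COLUMNS = [
    "H. leptothallum",
    "R. cuspidigerum",
    "H. involuta",
    "A. viticulosus",
    "P. cuspidatum",
    "T. kanedae",
    "M. polytrichum",
]

_MEMBERSHIP_ROWS = {
    "MP": [0.8346, 0.5984, 0.3226, 0.8035, 1.0000, 0.5258, 0.0000],
    "Pro": [1.0000, 0.4690, 0.0201, 0.2791, 0.2464, 0.8827, 0.0000],
    "MDA": [1.0000, 0.9877, 0.5825, 0.9767, 0.3315, 0.0000, 0.2864],
    "SOD": [0.9618, 1.0000, 0.8835, 0.0000, 0.2927, 0.3726, 0.6273],
    "POD": [0.3549, 0.5374, 1.0000, 0.3351, 0.1929, 0.0109, 0.0000],
}


def membership_table() -> pd.DataFrame:
    """Printed membership matrix of the 7 candidate mosses (species x index)."""
    return pd.DataFrame(_MEMBERSHIP_ROWS, index=_MEMBERSHIP_COLUMNS)


#: Printed comprehensive scores (averages of the five memberships) and ranks.
MEMBERSHIP_PRINTED_AVERAGES = pd.Series(
    [0.8303, 0.7185, 0.5617, 0.4789, 0.4127, 0.3584, 0.1827],
    index=_MEMBERSHIP_COLUMNS,
    name="average_membership",
)

#: Guild labels observed for bacteria (function-prediction stage).
BACTERIAL_GUILDS = (
    "photoautotrophy",
    "chemoheterotrophy",
    "nitrate_reduction",
    "methanotrophy",
    "human_pathogens",
)

#: Guild labels observed for fungi.
FUNGAL_GUILDS = (
    "plant_pathogen",
    "plant_saprotroph",
    "dung_saprotroph",
    "undefined_saprotroph",
    "endophyte",
    "ectomycorrhizal",
    "animal_pathogen",
    "fungal_parasite",
)
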