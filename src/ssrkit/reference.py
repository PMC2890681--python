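"""Published reference tables for the 40-variety commercial sugar-beet panel.

The package's running example is the standard characterisation of 40
diploid and triploid commercial sugar-beet varieties (30 plants each)
genotyped at 12 microsatellite loci.  The raw per-plant genotypes of that
survey were never deposited, but its summary tables are public and serve
two purposes here:

* as *inputs* — e.g. the variety/breeder/ploidy layout and the per-locus
  allele counts parameterise the default simulated panel, and the printed
  F-statistics columns feed internal-consistency checks; and
* as a realism yardstick for the synthetic-data generator.

``VARIETY_ROWS`` holds, per variety: breeder, ploidy, the per-locus
``(allele_count, rare_count)`` pairs and the printed row total.
``FSTAT_COLUMNS`` holds the per-locus F-statistics table: dominant-score
Fst among all / triploid / diploid varieties, and the codominant
re-analysis of the diploids (Fst, Fis, Fit, Ho, Hs, Ht), together with the
jackknifed multilocus means and standard errors.
"""

from __future__ import annotations

import pandas as pd

LOCI = [
    "bvv15", "bvv17", "bvv21", "bvv23", "bvv30", "bvv32",
    "bvv43", "bvv51", "bvv53", "bvv60", "bvv61", "bvv64",
]

#: per-locus allele-length range observed panel-wide (base pairs)
ALLELE_LENGTH_RANGES = {
    "bvv15": (201, 293), "bvv17": (135, 138), "bvv21": (236, 268),
    "bvv23": (92, 108), "bvv30": (136, 143), "bvv32": (133, 141),
    "bvv43": (257, 288), "bvv51": (240, 281), "bvv53": (174, 234),
    "bvv60": (252, 275), "bvv61": (213, 370), "bvv64": (224, 237),
}

#: panel-wide number of distinct alleles per locus (1200 plants)
PANEL_ALLELE_COUNTS = [11, 3, 5, 5, 4, 4, 9, 8, 10, 6, 21, 6]
PANEL_TOTAL_ALLELES = 92  # sum of the per-locus counts

#: panel-wide effective number of alleles per locus (1200 plants)
PANEL_EFFECTIVE_ALLELES = [2.7, 3.0, 2.2, 3.5, 2.2, 3.2, 2.6, 3.7, 3.1, 2.0, 3.1, 3.1]

#: expected heterozygosity per locus in the 316 codominantly scored diploids
DIPLOID_HE = [0.525, 0.626, 0.529, 0.686, 0.543, 0.672,
              0.700, 0.645, 0.589, 0.458, 0.659, 0.744]

# variety: (breeder, ploidy, ((allele_count, rare_count) x 12 loci), printed_total)
VARIETY_ROWS: dict[str, tuple[str, int, tuple[tuple[int, int], ...], int]] = {
    "A8106": ("Agrosem", 3, ((5, 1), (2, 0), (2, 0), (3, 0), (3, 0), (3, 0), (5, 2), (4, 0), (4, 0), (2, 0), (4, 1), (5, 0)), 42),
    "Ariana": ("KWS", 3, ((4, 1), (2, 0), (3, 0), (2, 0), (2, 0), (3, 1), (5, 0), (4, 1), (3, 1), (3, 0), (6, 1), (5, 0)), 42),
    "Aristo": ("Novartis", 2, ((4, 2), (2, 0), (2, 0), (4, 0), (3, 1), (2, 0), (2, 0), (4, 0), (2, 0), (2, 0), (6, 1), (4, 0)), 37),
    "Assist": ("SES", 3, ((5, 2), (2, 0), (3, 0), (4, 0), (3, 0), (3, 0), (3, 0), (4, 0), (4, 2), (2, 0), (5, 1), (4, 1)), 42),
    "Atlantis": ("VanderHave", 3, ((6, 0), (2, 0), (1, 0), (4, 1), (3, 0), (2, 0), (2, 0), (5, 1), (5, 0), (2, 0), (4, 2), (6, 0)), 42),
    "Aurelia": ("KWS", 3, ((3, 0), (1, 0), (1, 0), (4, 1), (2, 0), (2, 0), (3, 0), (4, 0), (2, 0), (3, 0), (3, 1), (6, 2)), 34),
    "Blenheim": ("VanderHave", 3, ((4, 1), (2, 0), (2, 0), (3, 1), (3, 0), (3, 0), (3, 2), (5, 0), (4, 0), (2, 0), (5, 0), (3, 1)), 39),
    "Brigitta": ("KWS", 2, ((3, 0), (2, 0), (2, 0), (1, 0), (2, 0), (1, 0), (3, 0), (4, 0), (4, 0), (2, 0), (4, 2), (2, 0)), 30),
    "Caramel": ("Kuhn", 3, ((5, 0), (2, 0), (1, 0), (4, 0), (2, 0), (2, 0), (2, 0), (4, 0), (4, 0), (2, 0), (2, 0), (3, 0)), 33),
    "Claudia": ("CFS", 3, ((4, 0), (2, 0), (2, 0), (3, 0), (3, 1), (3, 1), (5, 0), (5, 0), (6, 3), (2, 0), (6, 3), (5, 2)), 46),
    "Crestor": ("Novartis", 2, ((3, 0), (2, 0), (3, 0), (2, 0), (2, 0), (2, 0), (2, 0), (4, 0), (2, 0), (2, 0), (5, 1), (3, 1)), 32),
    "Cynthia": ("KWS", 3, ((4, 1), (2, 0), (2, 0), (4, 0), (2, 0), (3, 0), (3, 0), (5, 0), (4, 0), (2, 0), (3, 0), (3, 0)), 37),
    "DS3014": ("Danisco", 3, ((3, 0), (2, 0), (2, 0), (2, 0), (2, 0), (2, 0), (1, 0), (4, 0), (2, 0), (2, 0), (6, 3), (2, 0)), 30),
    "DS3030": ("Danisco", 3, ((4, 0), (2, 0), (2, 0), (3, 1), (2, 0), (3, 0), (3, 0), (3, 0), (4, 1), (2, 0), (5, 1), (3, 0)), 36),
    "Fortis": ("Hilleshog", 2, ((2, 0), (2, 0), (2, 0), (3, 0), (3, 0), (3, 0), (2, 0), (4, 1), (2, 0), (2, 0), (4, 1), (6, 0)), 35),
    "H66377": ("VanderHave", 3, ((5, 2), (2, 0), (2, 0), (4, 1), (3, 1), (3, 0), (4, 2), (4, 1), (3, 0), (2, 0), (5, 2), (6, 2)), 43),
    "H66411": ("VanderHave", 3, ((7, 0), (2, 0), (2, 0), (4, 0), (2, 0), (3, 0), (3, 1), (5, 0), (4, 0), (2, 0), (3, 0), (5, 1)), 42),
    "Helsinki": ("VanderHave", 3, ((6, 1), (2, 0), (2, 0), (3, 0), (3, 0), (3, 1), (1, 0), (5, 0), (4, 0), (2, 0), (4, 1), (3, 0)), 38),
    "HI0032": ("Novartis", 2, ((3, 1), (2, 0), (2, 0), (3, 0), (3, 1), (3, 0), (4, 0), (3, 0), (4, 1), (2, 0), (4, 0), (5, 0)), 38),
    "HM5432": ("Hilleshog", 3, ((6, 1), (2, 0), (2, 0), (3, 0), (2, 0), (3, 0), (4, 0), (4, 0), (3, 0), (3, 0), (3, 1), (5, 1)), 40),
    "KWS8123": ("KWS", 2, ((3, 1), (2, 0), (2, 0), (2, 0), (2, 0), (2, 1), (1, 0), (3, 0), (1, 0), (2, 0), (2, 1), (5, 1)), 27),
    "KWS9226": ("KWS", 3, ((5, 0), (1, 0), (1, 0), (2, 0), (2, 0), (2, 0), (4, 0), (3, 0), (3, 0), (3, 1), (4, 1), (4, 1)), 34),
    "Lenora": ("KWS", 2, ((4, 2), (2, 1), (2, 0), (2, 0), (2, 0), (1, 0), (1, 0), (3, 0), (3, 0), (2, 0), (3, 0), (1, 0)), 26),
    "Lion9909": ("LionSeeds", 3, ((5, 0), (2, 0), (2, 0), (4, 1), (2, 0), (3, 0), (3, 0), (4, 1), (5, 1), (2, 0), (6, 0), (4, 1)), 42),
    "Lion9912": ("LionSeeds", 3, ((6, 0), (2, 0), (2, 0), (3, 0), (2, 0), (3, 0), (2, 0), (4, 0), (5, 0), (2, 0), (5, 1), (3, 1)), 39),
    "Madonna": ("KWS", 2, ((3, 1), (1, 0), (2, 0), (2, 0), (2, 0), (2, 0), (2, 0), (4, 0), (3, 0), (2, 0), (4, 0), (2, 0)), 29),
    "MK9907": ("Kuhn", 3, ((4, 0), (2, 1), (2, 0), (2, 0), (3, 0), (3, 0), (3, 1), (5, 2), (4, 0), (3, 0), (4, 0), (4, 0)), 39),
    "Nemil": ("Novartis", 2, ((6, 2), (2, 0), (3, 0), (3, 0), (2, 0), (3, 0), (1, 0), (5, 2), (2, 0), (2, 0), (6, 2), (3, 1)), 38),
    "Opus": ("Dickman", 3, ((7, 0), (2, 0), (2, 0), (4, 0), (3, 0), (3, 0), (3, 0), (4, 0), (5, 0), (2, 0), (5, 1), (5, 2)), 45),
    "Oslo": ("VanderHave", 3, ((5, 0), (2, 0), (2, 0), (4, 0), (3, 0), (2, 0), (3, 0), (4, 0), (4, 0), (2, 0), (5, 0), (3, 0)), 39),
    "Princesse": ("Delitzsch", 3, ((3, 1), (2, 0), (2, 0), (4, 0), (2, 0), (2, 0), (4, 0), (5, 0), (3, 0), (2, 0), (5, 1), (4, 1)), 38),
    "Ravel": ("Kuhn", 3, ((4, 0), (2, 0), (2, 0), (4, 1), (3, 0), (2, 0), (1, 0), (5, 0), (4, 0), (2, 0), (4, 1), (4, 0)), 37),
    "Rebecca": ("KWS", 2, ((4, 2), (2, 0), (2, 0), (3, 0), (2, 0), (3, 0), (3, 0), (5, 1), (5, 2), (2, 0), (3, 0), (4, 0)), 38),
    "S1901": ("SES", 3, ((5, 0), (2, 0), (2, 0), (4, 0), (2, 0), (2, 0), (2, 1), (4, 0), (4, 0), (2, 0), (4, 1), (4, 1)), 37),
    "Stru2001": ("Strube", 2, ((3, 0), (2, 0), (1, 0), (1, 0), (1, 0), (2, 0), (1, 0), (3, 0), (3, 0), (2, 0), (4, 1), (2, 0)), 25),
    "Sylvester": ("VanderHave", 3, ((7, 2), (2, 0), (2, 0), (3, 0), (3, 0), (3, 0), (2, 1), (4, 0), (3, 0), (2, 0), (5, 2), (5, 0)), 41),
    "Tiara": ("KWS", 3, ((4, 0), (1, 0), (2, 0), (3, 1), (3, 0), (2, 0), (3, 0), (4, 0), (5, 0), (2, 0), (4, 0), (3, 0)), 36),
    "Toledo": ("Novartis", 3, ((4, 0), (2, 0), (2, 0), (4, 0), (2, 0), (2, 0), (3, 1), (4, 0), (4, 1), (2, 0), (6, 0), (3, 0)), 38),
    "Winner": ("Kuhn", 3, ((6, 0), (2, 0), (1, 0), (4, 0), (3, 0), (2, 0), (2, 0), (4, 0), (4, 0), (2, 0), (4, 1), (5, 1)), 39),
    "Winsor": ("Novartis", 3, ((4, 0), (2, 0), (2, 0), (3, 0), (2, 0), (3, 0), (4, 1), (5, 0), (4, 0), (2, 0), (6, 0), (4, 0)), 41),
}

#: per-locus F-statistics columns (jackknifed multilocus mean/SE in FSTAT_MEAN/SE)
FSTAT_COLUMNS = pd.DataFrame(
    {
        "fst_dominant_all": [0.095, 0.158, 0.181, 0.207, 0.037, 0.172, 0.168, 0.095, 0.132, 0.047, 0.119, 0.151],
        "fst_dominant_triploid": [0.079, 0.127, 0.168, 0.145, 0.015, 0.129, 0.107, 0.082, 0.106, 0.034, 0.094, 0.096],
        "fst_dominant_diploid": [0.140, 0.257, 0.239, 0.421, 0.119, 0.288, 0.279, 0.152, 0.208, 0.093, 0.195, 0.299],
        "fst_codominant": [0.135, 0.291, 0.257, 0.459, 0.204, 0.345, 0.291, 0.180, 0.274, 0.151, 0.198, 0.349],
        "fis_codominant": [-0.113, 0.729, 0.324, 0.820, -0.011, 0.408, 0.876, -0.152, -0.232, -0.355, 0.433, 0.582],
        "fit_codominant": [0.038, 0.808, 0.498, 0.903, 0.196, 0.613, 0.912, 0.055, 0.106, -0.150, 0.545, 0.728],
        "ho": [0.513, 0.122, 0.272, 0.069, 0.445, 0.271, 0.065, 0.615, 0.542, 0.533, 0.260, 0.206],
        "hs": [0.460, 0.453, 0.397, 0.383, 0.442, 0.455, 0.516, 0.533, 0.442, 0.394, 0.527, 0.504],
        "ht": [0.525, 0.623, 0.525, 0.683, 0.543, 0.670, 0.703, 0.641, 0.587, 0.457, 0.658, 0.744],
    },
    index=pd.Index(LOCI, name="locus"),
)

FSTAT_MEAN = {
    "fst_dominant_all": 0.133, "fst_dominant_triploid": 0.100,
    "fst_dominant_diploid": 0.232, "fst_codominant": 0.271,
    "fis_codominant": 0.282, "fit_codominant": 0.479,
    "ho": 0.326, "hs": 0.459, "ht": 0.613,
}
FSTAT_SE = {
    "fst_dominant_all": 0.014, "fst_dominant_triploid": 0.011,
    "fst_dominant_diploid": 0.027, "fst_codominant": 0.028,
    "fis_codominant": 0.124, "fit_codominant": 0.105,
}

#: differentiation between ploidy classes and among breeders (all plants)
PLOIDY_FST = 0.1327
BREEDER_FST = 0.0628
BREEDER_FST_SE = 0.0092


def variety_layout() -> pd.DataFrame:
    """(variety, breeder, ploidy) layout of the reference panel."""
    rows = [(v, b, p) for v, (b, p, _, _) in VARIETY_ROWS.items()]
    return pd.DataFrame(rows, columns=["variety", "breeder", "ploidy"]).set_index("variety")


def allele_count_table() -> pd.DataFrame:
    """Variety x locus allele counts with printed row totals."""
    df = pd.DataFrame(
        {v: [c for c, _ in pairs] for v, (_, _, pairs, _) in VARIETY_ROWS.items()},
        index=LOCI,
    ).T
    df["printed_total"] = [t for _, (_, _, _, t) in VARIETY_ROWS.items()]
    return df
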