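"""Published reference marker counts for the Aegilops-Triticum DArTseq panel.

These tables carry the published per-species SilicoDArT marker counts for
the wheat-relative panel (11 diploid Aegilops analyzers, 16 bread-wheat
relatives screened for subgenome homoeology, and 12 polyploid Aegilops
species). They serve as fixed inputs for exercising the package's
reporting arithmetic — specificity percentages, homoeology percentages and
analyzer selection — at the exact printed magnitudes.

Counts are stored as printed. Two homoeology cells are internally
inconsistent in the published source (shared + specific != total for
T. boeoticum/B and Ae. searsii/B); they are carried as-is and the
percentage, which depends on the total only, is unaffected.
"""

from __future__ import annotations

import pandas as pd

from .filters import round_half_up
from .io import SUBGENOME_LETTERS

# -- Diploid Aegilops analyzers: total markers and species-specific counts --

_DIPLOID_SPECIFICITY = [
    # species, total markers, species-specific markers
    ("Ae. mutica", 12238, 837),
    ("Ae. speltoides", 9330, 699),
    ("Ae. longissima", 18321, 761),
    ("Ae. sharonensis", 18205, 723),
    ("Ae. bicornis", 16465, 598),
    ("Ae. searsii", 15402, 1633),
    ("Ae. tauschii", 20288, 7420),
    ("Ae. caudata", 19086, 6514),
    ("Ae. comosa", 17377, 3941),
    ("Ae. uniaristata", 16719, 4003),
    ("Ae. umbellulata", 19523, 6627),
]


def diploid_specificity_counts() -> pd.DataFrame:
    """Published total / species-specific marker counts of the 11 diploid
    Aegilops analyzers, with the specific percentage recomputed through the
    package's rounding path (half-up, 2 decimals)."""
    df = pd.DataFrame(_DIPLOID_SPECIFICITY, columns=["species", "total", "specific"])
    df["specific_pct"] = [
        round_half_up(100.0 * s / t, 2) for t, s in zip(df["total"], df["specific"])
    ]
    return df.set_index("species")


# -- Homoeology of 16 wheat-relative diploids to the bread-wheat subgenomes --

#: Reference (bread wheat) per-subgenome marker counts: shared, specific, total.
HOMOEOLOGY_REFERENCE_TOTALS = {
    "A": (16901, 4688, 21589),
    "B": (13415, 7227, 20642),
    "D": (30187, 5167, 35354),
}

_HOMOEOLOGY = [
    # species, (A: shared, specific, total), (B: ...), (D: ...)
    ("T. urartu", (6114, 3672, 9786), (1249, 95, 1344), (2763, 93, 2856)),
    ("T. boeoticum", (5492, 753, 6245), (1369, 71, 1436), (2870, 59, 2929)),
    ("Ae. mutica", (1824, 1348, 3172), (2331, 1966, 4297), (4690, 2284, 6974)),
    ("Ae. speltoides", (1139, 1129, 2268), (2507, 4405, 6912), (3335, 1883, 5218)),
    ("Ae. longissima", (2301, 392, 2693), (3513, 755, 4268), (6831, 594, 7425)),
    ("Ae. sharonensis", (2294, 336, 2630), (3487, 769, 4256), (6799, 632, 7431)),
    ("Ae. bicornis", (2018, 379, 2397), (3026, 756, 3782), (6258, 638, 6896)),
    ("Ae. searsii", (1915, 156, 2071), (3610, 495, 3105), (5558, 265, 5823)),
    ("Ae. tauschii", (817, 99, 916), (934, 174, 1108), (8988, 7568, 16556)),
    ("Ae. caudata", (1849, 1120, 2969), (1955, 1013, 2968), (5321, 1848, 7169)),
    ("Ae. comosa", (1959, 1022, 2981), (2126, 1102, 3228), (5545, 1904, 7449)),
    ("Ae. uniaristata", (1805, 672, 2477), (2049, 724, 2773), (5155, 1254, 6409)),
    ("Ae. umbellulata", (2014, 928, 2942), (2055, 1017, 3072), (5174, 1653, 6827)),
    ("S. cereale", (699, 23, 722), (959, 64, 1023), (1840, 30, 1870)),
    ("D. villosum", (566, 20, 586), (793, 44, 837), (1538, 16, 1554)),
    ("H. vulgare", (291, 8, 299), (431, 19, 450), (824, 9, 833)),
]


def homoeology_counts() -> pd.DataFrame:
    """Published shared/specific/total homoeology counts of the 16 screened
    diploids, as a (subgenome, statistic) MultiIndex column frame."""
    columns = pd.MultiIndex.from_product([SUBGENOME_LETTERS, ("shared", "specific", "total")])
    rows = {
        species: [v for cell in cells for v in cell]
        for species, *cells in _HOMOEOLOGY
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns).rename_axis("species")


def homoeology_reference_totals() -> pd.Series:
    """Bread wheat's own per-subgenome marker totals (percentage denominators)."""
    return pd.Series({g: t for g, (_, _, t) in HOMOEOLOGY_REFERENCE_TOTALS.items()},
                     name="reference_total")


def homoeology_percentages() -> pd.DataFrame:
    """Homoeology percentages recomputed from the published counts through
    the package's rounding path (100 x total / reference total, 1 dp)."""
    counts = homoeology_counts()
    ref = homoeology_reference_totals()
    return pd.DataFrame({
        g: [round_half_up(100.0 * t / ref[g], 1) for t in counts[(g, "total")]]
        for g in SUBGENOME_LETTERS
    }, index=counts.index)


# -- Species-specific marker counts of the 12 polyploid Aegilops species --

_POLYPLOID_SPECIFIC = [
    # species, ploidy, reported genome formula, species-specific markers
    ("Ae. crassa", 6, "Dcr1 Dcr2 Xcr", 684),
    ("Ae. vavilovii", 6, "Dva Xva Sva", 2153),
    ("Ae. ventricosa", 4, "Dv Nv", 3027),
    ("Ae. cylindrica", 4, "CD", 4759),
    ("Ae. juvenalis", 6, "Xj Dj Uj", 187),
    ("Ae. kotschyi", 4, "Sk Uk", 2271),
    ("Ae. biuncialis", 4, "Ub Mb", 2601),
    ("Ae. triuncialis", 4, "Ct Ut", 2051),
    ("Ae. ovata", 4, "Ug Mg", 3163),
    ("Ae. triaristata", 6, "Un Xn Nn", 2215),
    ("Ae. columnaris", 4, "Uc Xc", 2470),
    ("Ae. variabilis", 4, "Sp Up", 2683),
]


def polyploid_specific_counts() -> pd.DataFrame:
    """Published species-specific marker counts of the 12 polyploid
    Aegilops species (the polyploid-differentiation screen)."""
    df = pd.DataFrame(_POLYPLOID_SPECIFIC,
                      columns=["species", "ploidy", "genome_formula", "specific"])
    return df.set_index("species")
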