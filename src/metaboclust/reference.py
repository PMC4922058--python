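"""Published summary tables of the 228-tumor breast cohort the defaults emulate.

The package is driven by a synthetic-cohort generator whose default
parameters reproduce the summary statistics published for a cohort of 228
untreated primary breast carcinomas profiled by HR-MAS MRS, gene-expression
arrays, and reverse-phase protein arrays (RPPA).  That cohort was clustered
into three "metabolic clusters" Mc1/Mc2/Mc3 (n = 58/58/112); the constants
below are the printed per-cluster metabolite levels, the clinical
characteristics table, and the PAM50/RPPA subtype distributions, all keyed
by cluster.

These tables are *inputs*: the generator samples from them, and the
association stage recomputes the published contingency statistics from them.
"""

from __future__ import annotations

import pandas as pd

CLUSTERS = ("Mc1", "Mc2", "Mc3")
CLUSTER_SIZES = {"Mc1": 58, "Mc2": 58, "Mc3": 112}

# ---------------------------------------------------------------------------
# Per-cluster metabolite levels (integrated peak areas from mean-normalized
# spectra, arbitrary units).  Columns: (mean, dispersion) per cluster, the
# published BH-adjusted Kruskal-Wallis p, and the published pairwise
# significance pattern.  The dispersion column was printed as "SE" but is
# interpreted as a per-cluster SD by default (see synthcohort.CohortConfig).
# ---------------------------------------------------------------------------

METABOLITE_LEVELS = pd.DataFrame.from_records(
    [
        # name, mc1_mean, mc1_sd, mc2_mean, mc2_sd, mc3_mean, mc3_sd, adj_p, pattern
        ("Beta-glucose", 30.0, 27.7, 71.7, 55.2, 32.3, 16.3, 3.62e-09, "Mc2 vs rest"),
        ("Ascorbate", 40.0, 17.1, 28.8, 8.6, 38.3, 13.6, 1.02e-05, "Mc2 vs rest"),
        ("Lactate", 259.5, 73.0, 229.4, 57.6, 303.6, 76.7, 4.98e-09, "Mc3 vs rest"),
        ("Tyrosine", 407.5, 56.5, 352.8, 82.6, 405.9, 62.4, 1.22e-04, "Mc2 vs rest"),
        ("Glycine", 187.0, 80.8, 152.3, 41.9, 195.7, 68.8, 1.04e-04, "Mc2 vs Mc3"),
        ("Myo-inositol", 163.7, 47.0, 217.7, 53.5, 196.1, 54.3, 9.44e-07, "all"),
        ("Taurine", 332.2, 122.7, 330.2, 84.0, 369.3, 99.3, 0.017, "Mc1 vs Mc3"),
        ("Scyllo-inositol", 55.0, 16.2, 94.7, 186.5, 62.5, 32.1, 0.138, "NS"),
        ("Glycerophosphocholine", 210.0, 91.6, 107.9, 33.6, 151.2, 48.4, 4.44e-12, "all"),
        ("Phosphocholine", 552.0, 131.1, 216.8, 66.8, 327.2, 69.9, 9.59e-33, "all"),
        ("Choline", 135.2, 44.6, 120.3, 37.7, 132.9, 42.2, 0.128, "NS"),
        ("Creatine", 149.9, 64.2, 93.2, 33.7, 136.0, 52.1, 1.41e-09, "Mc2 vs rest"),
        ("Glutathione", 57.5, 13.8, 50.9, 13.9, 58.1, 14.5, 0.011, "Mc2 vs Mc3"),
        ("Glutamine", 134.4, 41.3, 134.3, 30.2, 145.4, 43.6, 0.223, "NS"),
        ("Succinate", 58.0, 15.7, 53.6, 10.6, 62.2, 15.7, 0.003, "Mc2 vs Mc3"),
        ("Glutamate", 237.9, 61.3, 266.2, 63.3, 277.5, 61.2, 1.95e-04, "Mc1 vs rest"),
        ("Acetate", 32.7, 9.0, 48.4, 17.2, 40.3, 13.1, 7.89e-08, "all"),
        ("Alanine", 82.6, 36.6, 66.0, 24.9, 95.1, 33.8, 6.56e-07, "all"),
    ],
    columns=[
        "metabolite",
        "mc1_mean", "mc1_sd",
        "mc2_mean", "mc2_sd",
        "mc3_mean", "mc3_sd",
        "published_adj_p", "published_pattern",
    ],
).set_index("metabolite")

#: Literature chemical-shift assignment (ppm) of the quantified resonance of
#: each metabolite, chosen so that all integration windows are pairwise
#: disjoint and clear of the five lipid exclusion windows.
METABOLITE_PPM = {
    "Beta-glucose": 4.65,
    "Ascorbate": 4.52,
    "Lactate": 4.12,
    "Myo-inositol": 4.06,
    "Tyrosine": 3.94,
    "Glycine": 3.56,
    "Taurine": 3.43,
    "Scyllo-inositol": 3.35,
    "Glycerophosphocholine": 3.232,
    "Phosphocholine": 3.225,
    "Choline": 3.205,
    "Creatine": 3.03,
    "Glutathione": 2.95,
    "Glutamine": 2.45,
    "Succinate": 2.41,
    "Glutamate": 2.35,
    "Acetate": 1.92,
    "Alanine": 1.48,
}

#: Integration half-window (ppm).  Default 0.015; narrowed in the crowded
#: choline region (GPC/PCho 0.007 ppm apart) and for acetate, whose peak sits
#: 0.01 ppm from the 1.93-2.09 lipid exclusion window.
METABOLITE_HALF_WINDOW = {
    "Glycerophosphocholine": 0.003,
    "Phosphocholine": 0.003,
    "Choline": 0.009,
    "Acetate": 0.009,
}
DEFAULT_HALF_WINDOW = 0.015

# ---------------------------------------------------------------------------
# Clinical characteristics (counts per metabolic cluster).  "NA" rows carry
# the printed not-available counts; where a characteristic was typed on a
# subset only (receptor status), the per-variable NA count is the printed NA
# row.  Zero-count categories of the printed table (medullary, papillary,
# T0, T4) are kept here and dropped by the association stage.
# ---------------------------------------------------------------------------

CLINICAL_COUNTS: dict[str, dict[str, tuple[int, int, int]]] = {
    "histology": {
        "Ductal": (52, 37, 97),
        "Lobular": (4, 1, 16),
        "Medullary": (0, 0, 0),
        "DCIS": (0, 4, 0),
        "Metaplastic": (0, 1, 0),
        "Mucinous": (0, 2, 2),
        "Tubular": (1, 1, 2),
        "Mixed": (1, 0, 1),
        "Papillary": (0, 0, 0),
        "NA": (0, 2, 4),
    },
    "tumor_size": {
        "NA": (1, 3, 5),  # printed "Tx or NA"
        "T0": (0, 0, 0),
        "pTis": (0, 4, 0),
        "T1": (31, 28, 54),
        "T2": (24, 21, 48),
        "T3": (2, 2, 5),
        "T4": (0, 0, 0),
    },
    "grade": {
        "I": (8, 10, 13),
        "II": (20, 24, 49),
        "III": (30, 21, 46),
        "NA": (0, 3, 4),
    },
    "node_status": {
        "N0": (34, 36, 63),
        "N1(mi)": (3, 3, 2),
        "N1": (17, 13, 29),
        "N2": (2, 3, 9),
        "N3": (2, 1, 5),
        "NA": (0, 2, 4),
    },
    "her2": {
        "HER2+": (7, 7, 12),
        "HER2-": (51, 45, 96),
        "NA": (0, 6, 4),
    },
    "er": {
        "ER+": (49, 42, 87),
        "ER-": (9, 10, 21),
        "NA": (0, 6, 4),
    },
    "pr": {
        "PR+": (39, 36, 80),
        "PR-": (19, 16, 28),
        "NA": (0, 6, 4),
    },
}

# PAM50 (gene-expression) subtype distribution.  201 of 228 samples were
# array-profiled; samples missing from the printed per-cluster totals
# (58/58/112 vs 55/42/104) are folded into NA by the generator defaults.
PAM50_COUNTS: dict[str, tuple[int, int, int]] = {
    "Luminal A": (19, 18, 48),
    "Luminal B": (23, 5, 28),
    "Basal": (6, 5, 13),
    "Her2 enriched": (5, 7, 10),
    "Normal-like": (2, 7, 5),
    "NA": (4, 15, 8),
}

# RPPA (protein-expression) subtype distribution (217 of 228 profiled).
RPPA_COUNTS: dict[str, tuple[int, int, int]] = {
    "Reactive I": (4, 24, 15),
    "Reactive II": (3, 8, 25),
    "Basal": (16, 8, 23),
    "Her2": (5, 4, 9),
    "Luminal": (27, 11, 35),
    "NA": (3, 3, 5),
}

SUBTYPE_COUNTS = {"pam50": PAM50_COUNTS, "rppa": RPPA_COUNTS}


def counts_frame(counts: dict[str, tuple[int, int, int]]) -> pd.DataFrame:
    """Category x cluster count table as a DataFrame (includes NA rows)."""
    return pd.DataFrame.from_dict(counts, orient="index", columns=list(CLUSTERS))
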