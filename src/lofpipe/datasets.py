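"""Published worked-example tables bundled for demonstrations and checks.

Two small tables from a published two-breed cattle study accompany the
package as worked examples: the gene-level LOF cross-tabulation (30 genes
significant under at least one of the four gene-level tests, cohort A = the
larger-bodied breed, cohort B = the smaller) and the agricultural trait
summaries of the two breeds (7 adult females each).  Only the printed
numbers are stored; everything recomputable (odds ratios, intervals,
chi-squared statistics) is recomputed by the package at run time.
"""

from __future__ import annotations

import pandas as pd

# Gene, N.Marker, A1, A2, B1, B2, printed OR, printed CI low/high (None = "Null"),
# printed P_Chi
_GENE_ROWS = [
    ("CD48", 10, 2, 138, 32, 108, 0.049, 0.011, 0.209, 1.3e-06),
    ("ESPNL", 4, 18, 38, 44, 12, 0.129, 0.055, 0.302, 2.04e-05),
    ("PRCP", 8, 34, 78, 69, 43, 0.272, 0.156, 0.473, 6.47e-05),
    ("F2R", 8, 1, 111, 22, 90, 0.037, 0.005, 0.279, 8.83e-05),
    ("TCTN1", 9, 2, 124, 23, 103, 0.072, 0.017, 0.314, 0.000207),
    ("HPS1", 13, 19, 163, 49, 133, 0.316, 0.178, 0.563, 0.000995),
    ("VPS72", 3, 12, 30, 30, 12, 0.16, 0.062, 0.412, 0.001485),
    ("GPATCH3", 2, 16, 12, 28, 0, None, None, None, 0.001598),
    ("RPAP3", 4, 6, 50, 24, 32, 0.16, 0.059, 0.434, 0.002042),
    ("TTC27", 7, 2, 96, 18, 80, 0.093, 0.021, 0.411, 0.002578),
    ("TBL2", 4, 5, 51, 22, 34, 0.152, 0.052, 0.439, 0.002767),
    ("ALG12", 8, 28, 84, 55, 57, 0.345, 0.196, 0.608, 0.002969),
    ("NIF3L1", 4, 4, 52, 20, 36, 0.138, 0.044, 0.439, 0.003543),
    ("CLK1", 2, 3, 25, 16, 12, 0.09, 0.022, 0.369, 0.003736),
    ("LY86", 5, 0, 70, 12, 58, None, None, None, 0.004374),
    ("HSPA14", 4, 1, 55, 14, 42, 0.055, 0.007, 0.431, 0.004617),
    ("SMYD5", 2, 9, 19, 22, 6, 0.129, 0.039, 0.43, 0.006692),
    ("HCLS1", 2, 1, 27, 12, 16, 0.049, 0.006, 0.416, 0.006978),
    ("MAK16", 3, 3, 39, 16, 26, 0.125, 0.033, 0.472, 0.00933),
    ("TMEM242", 3, 9, 33, 24, 18, 0.205, 0.079, 0.533, 0.010545),
    ("NDUFB4", 4, 0, 56, 9, 47, None, None, None, 0.020472),
    ("TREM1", 8, 2, 110, 14, 98, 0.127, 0.028, 0.574, 0.021371),
    ("ARG2", 2, 0, 28, 8, 20, None, None, None, 0.025172),
    ("UMPS", 3, 3, 39, 14, 28, 0.154, 0.04, 0.586, 0.030324),
    ("SLC35A5", 3, 3, 39, 14, 28, 0.154, 0.04, 0.586, 0.030324),
    ("RPIA", 3, 0, 42, 8, 34, None, None, None, 0.031466),
    ("VAMP5", 2, 4, 24, 14, 14, 0.167, 0.046, 0.607, 0.042298),
    ("PRR5", 4, 2, 54, 12, 44, 0.136, 0.029, 0.639, 0.042755),
    ("ATP2A2", 2, 0, 28, 7, 21, None, None, None, 0.046012),
    ("TMEM19", 2, 0, 28, 7, 21, None, None, None, 0.046012),
]

#: number of genes the study's Bonferroni correction divided alpha by
N_GENES_TESTED = 2720


def gene_crosstab_table() -> pd.DataFrame:
    """The published gene-level cross-tabulation with printed OR/CI/P_Chi."""
    return pd.DataFrame(
        _GENE_ROWS,
        columns=[
            "gene", "n_marker", "a1", "a2", "b1", "b2",
            "or_printed", "ci_low_printed", "ci_high_printed", "p_chi_printed",
        ],
    )


# trait, cohort (A = larger breed, B = smaller), n, min, max, mean, sd,
# printed interval low/high
_TRAIT_ROWS = [
    ("height_at_withers_cm", "A", 7, 124.7, 130.4, 127.17, 2.2, 126.34, 128.0),
    ("body_length_cm", "A", 7, 140.7, 151.6, 146.03, 4.02, 144.51, 147.55),
    ("bust_size_cm", "A", 7, 170.5, 179.3, 174.26, 3.32, 173.01, 175.51),
    ("weight_kg", "A", 7, 379.1, 437.2, 410.2, 23.67, 401.25, 419.15),
    ("height_at_withers_cm", "B", 7, 110.6, 119.3, 115.31, 3.31, 114.06, 116.56),
    ("body_length_cm", "B", 7, 122.9, 129.5, 125.87, 2.11, 125.07, 126.67),
    ("bust_size_cm", "B", 7, 153.2, 160.2, 156.39, 2.39, 155.49, 157.29),
    ("weight_kg", "B", 7, 280.6, 293.7, 284.87, 4.43, 283.2, 286.54),
]


def trait_summary_table() -> pd.DataFrame:
    """Printed per-breed trait summary statistics (n, min, max, mean, SD, interval)."""
    return pd.DataFrame(
        _TRAIT_ROWS,
        columns=[
            "trait", "cohort", "n", "min", "max", "mean", "sd",
            "interval_low_printed", "interval_high_printed",
        ],
    )
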