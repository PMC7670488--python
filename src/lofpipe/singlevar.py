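"""Per-variant allelic association scan and genomic-inflation calibration.

Each variant contributes an allelic 2x2 table (minor vs major allele counts
split by cohort) tested with Fisher's exact test; the genomic-control
inflation factor lambda_gc is the median of the tests' implied 1-df
chi-squared statistics divided by the null chi-squared median 0.4549364.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: median of the chi-squared distribution with 1 df
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class InflationEstimate:
    lambda_gc: float
    n_tests: int

    def __post_init__(self) -> None:
        if not self.lambda_gc > 0:
            raise ValueError("lambda_gc must be positive")


def allelic_crosstab(
    dosages_a: np.ndarray, dosages_b: np.ndarray
) -> tuple[int, int, int, int]:
    """Allelic 2x2 table (a, b, c, d) from per-cohort dosage vectors.

    ``a`` counts minor alleles over the non-missing cohort-A genotypes and
    ``b = 2 * n_called_A - a``; ``c``/``d`` likewise for cohort B.  Missing
    genotypes are excluded from the denominators.
    """
    out = []
    for name, dos in (("A", dosages_a), ("B", dosages_b)):
        dos = np.asarray(dos, dtype=float)
        called = dos[~np.isnan(dos)]
        if called.size == 0:
            raise ValueError(f"cohort {name} has no called genotypes")
        minor = int(called.sum())
        out.extend([minor, 2 * called.size - minor])
    return tuple(out)  # type: ignore[return-value]


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability is no greater than the observed table's
    (standard relative tolerance on the comparison).  A zero margin makes
    every table certain: p = 1 with a warning.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be nonnegative")
    if min(a + b, c + d, a + c, b + d) == 0:
        warnings.warn("2x2 table has a zero margin; Fisher p = 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def genomic_inflation(p_values) -> InflationEstimate:
    """Genomic-control lambda from a p-value distribution.

    Each p is converted to its 1-df chi-squared quantile q = F^-1(1-p);
    lambda = median(q) / 0.4549364.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    q = stats.chi2.isf(p, 1)
    lam = float(np.median(q) / CHI2_1_MEDIAN)
    return InflationEstimate(lambda_gc=max(lam, np.finfo(float).tiny), n_tests=p.size)


def gc_correct(p_values, lambda_gc: float) -> np.ndarray:
    """Divide the implied chi-squared statistics by lambda and re-convert."""
    p = np.asarray(p_values, dtype=float)
    return stats.chi2.sf(stats.chi2.isf(p, 1) / lambda_gc, 1)


def run_single_variant_scan(
    gt, apply_gc: bool = False
) -> tuple[pd.DataFrame, InflationEstimate]:
    """Fisher exact scan over every variant of a QC'd GenotypeTable.

    Returns a results frame sorted by (chrom, pos) with the allele
    cross-tab and p_fisher per variant, plus the lambda_gc estimate over
    all tests.  With ``apply_gc`` a genomic-control-corrected ``p_gc``
    column is added; lambda itself is always reported.
    """
    dos_a = gt.cohort_dosage("A")
    dos_b = gt.cohort_dosage("B")
    rows = []
    for j, var in gt.variants.iterrows():
        a, b, c, d = allelic_crosstab(dos_a[:, j], dos_b[:, j])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = fisher_exact_two_sided(a, b, c, d)
        rows.append((var.variant_id, var.chrom, var.pos, a, b, c, d, p))
    res = pd.DataFrame(
        rows, columns=["variant_id", "chrom", "pos", "a", "b", "c", "d", "p_fisher"]
    ).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    if len(res) == 1:
        warnings.warn("lambda_gc from a single test is unstable", stacklevel=2)
    inflation = genomic_inflation(res["p_fisher"])
    if apply_gc:
        res["p_gc"] = gc_correct(res["p_fisher"].to_numpy(), inflation.lambda_gc)
    return res, inflation
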