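"""Differential expression with empirical-Bayes moderated t statistics.

TPM normalisation, per-gene two-group linear models on log2(TPM + 1)
(a log2(count + 1) mode is available), shrinkage of the per-gene residual
variances toward an empirical-Bayes prior (d0, s0^2) estimated by the
log-variance moment method, moderated t tests, an adaptive significance
threshold on |log2 FC| (mean + 2 SD of the absolute log2 fold changes),
Benjamini-Hochberg FDR, and hypergeometric gene-set overrepresentation.

The moderated variance is the convex combination

    s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g)

and the moderated t uses d0 + d_g degrees of freedom (a z-test when the
prior degrees of freedom are infinite).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .containers import ExpressionTable

logger = logging.getLogger(__name__)


def tpm_from_counts(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: per sample, length-normalised rates scaled to 1e6."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    rates = counts.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with all-zero counts: {list(zero.index)}")
    return rates.div(totals, axis=1) * 1e6


def tpm_table(expr: ExpressionTable) -> ExpressionTable:
    """Return a TPM-valued copy of an ExpressionTable (no-op if already TPM)."""
    if expr.is_tpm:
        return expr
    return ExpressionTable(
        values=tpm_from_counts(expr.values, expr.lengths),
        lengths=expr.lengths,
        samples=expr.samples,
        is_tpm=True,
    )


@dataclass
class GeneFit:
    lfc: float  # log2 fold change, cohort B minus A
    s2: float  # pooled residual variance
    df: int  # residual degrees of freedom


def fit_gene_models(
    expr: ExpressionTable, response: str = "log_tpm"
) -> pd.DataFrame:
    """Per-gene two-group linear model on the log scale.

    ``response="log_tpm"`` fits log2(TPM + 1); ``"log_count"`` fits
    log2(count + 1) on the raw counts.  Genes with zero values in every
    sample are dropped (logged).  Returns a frame indexed by gene with
    columns ``lfc`` (mean B - mean A), ``s2`` (pooled residual variance)
    and ``df`` (n_A + n_B - 2).
    """
    if response not in ("log_tpm", "log_count"):
        raise ValueError("response must be 'log_tpm' or 'log_count'")
    cols_a = expr.cohort_columns("A")
    cols_b = expr.cohort_columns("B")
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need at least two samples per cohort")
    values = tpm_table(expr).values if response == "log_tpm" else expr.values
    nonzero = (values != 0).any(axis=1)
    dropped = int((~nonzero).sum())
    if dropped:
        logger.info("dropping %d genes with all-zero expression", dropped)
    values = values[nonzero]
    logv = np.log2(values + 1.0)
    va = logv[cols_a].to_numpy()
    vb = logv[cols_b].to_numpy()
    na, nb = va.shape[1], vb.shape[1]
    lfc = vb.mean(axis=1) - va.mean(axis=1)
    ss = ((va - va.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (vb - vb.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = na + nb - 2
    return pd.DataFrame(
        {"lfc": lfc, "s2": ss / df, "df": df}, index=values.index
    )


@dataclass
class EbayesPrior:
    d0: float  # prior degrees of freedom, may be math.inf
    s0_sq: float

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValueError("d0 must be positive")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be positive")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (trigamma is monotone decreasing)."""
    return optimize.brentq(
        lambda y: special.polygamma(1, y) - x, 1e-8, 1e8, xtol=1e-12, rtol=1e-12
    )


def ebayes_moderate(
    variances, dgs
) -> tuple[EbayesPrior, np.ndarray]:
    """Estimate the variance prior (d0, s0^2) and return moderated variances.

    Moment method on e_g = ln s_g^2 - psi(d_g/2) + ln(d_g/2): the excess of
    var(e_g) over the mean of psi'(d_g/2) identifies psi'(d0/2), solved by
    monotone root finding (d0 = inf when there is no excess spread), and
    s0^2 = exp(mean(e_g) + psi(d0/2) - ln(d0/2)).  Genes with non-finite or
    non-positive variance are excluded from estimation but still moderated.
    """
    s2 = np.asarray(variances, dtype=float)
    dg = np.broadcast_to(np.asarray(dgs, dtype=float), s2.shape).copy()
    ok = np.isfinite(s2) & (s2 > 0) & (dg > 0)
    if not ok.any():
        raise ValueError("degenerate expression matrix: all variances zero")
    if ok.sum() < 10:
        raise ValueError("need at least 10 genes with positive variance")
    e = np.log(s2[ok]) - special.digamma(dg[ok] / 2.0) + np.log(dg[ok] / 2.0)
    excess = float(np.var(e, ddof=1) - np.mean(special.polygamma(1, dg[ok] / 2.0)))
    if excess <= 0:
        # no excess spread beyond sampling noise: complete shrinkage to the
        # geometric-mean variance (equal inputs shrink to the common value)
        d0 = math.inf
        s0_sq = float(np.exp(np.mean(np.log(s2[ok]))))
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(
            np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    prior = EbayesPrior(d0=d0, s0_sq=s0_sq)
    if math.isinf(d0):
        moderated = np.full_like(s2, s0_sq)
    else:
        s2_filled = np.where(np.isfinite(s2), s2, 0.0)
        moderated = (d0 * s0_sq + dg * s2_filled) / (d0 + dg)
    return prior, moderated


def moderated_t_tests(
    fits: pd.DataFrame,
    prior: EbayesPrior,
    n_a: int,
    n_b: int,
    moderated_s2: np.ndarray | None = None,
) -> pd.DataFrame:
    """Moderated t per gene: t~ = lfc / (s~ sqrt(1/n_A + 1/n_B)).

    Two-sided p from Student t with d0 + d_g degrees of freedom (normal
    when d0 is infinite).  ``moderated_s2`` can be supplied to avoid
    recomputation; otherwise the convex-combination formula is applied.
    """
    s2 = fits["s2"].to_numpy()
    dg = fits["df"].to_numpy(dtype=float)
    if moderated_s2 is None:
        if math.isinf(prior.d0):
            moderated_s2 = np.full_like(s2, prior.s0_sq)
        elif prior.d0 == 0:
            moderated_s2 = s2.copy()  # forced-ordinary mode
        else:
            moderated_s2 = (prior.d0 * prior.s0_sq + dg * s2) / (prior.d0 + dg)
    se = np.sqrt(moderated_s2 * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fits["lfc"].to_numpy() / se, 0.0)
    if math.isinf(prior.d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), prior.d0 + dg)
    p = np.minimum(p, 1.0)
    out = fits.copy()
    out["s2_moderated"] = moderated_s2
    out["t_mod"] = t
    out["p"] = p
    return out


def adaptive_lfc_threshold(lfcs) -> float:
    """mean(|lfc|) + 2 * sample SD(|lfc|) over all genes."""
    lfcs = np.abs(np.asarray(list(lfcs), dtype=float))
    if lfcs.size < 2:
        raise ValueError("need at least two genes")
    return float(lfcs.mean() + 2.0 * lfcs.std(ddof=1))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(list(pvals), dtype=float)
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def call_degs(
    results: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, int, int]:
    """Flag differentially expressed genes.

    ``significant``: raw p < alpha and |lfc| above the adaptive threshold
    computed on the full lfc vector; ``significant_fdr`` applies the same
    fold-change rule with the BH-adjusted p.  Returns the augmented frame
    and the (n_up, n_down) counts for the raw-p tier (direction = sign of
    lfc, cohort B relative to A).
    """
    out = results.copy()
    threshold = adaptive_lfc_threshold(out["lfc"])
    out["p_adj"] = bh_adjust(out["p"])
    big = out["lfc"].abs() > threshold
    out["significant"] = (out["p"] < alpha) & big
    out["significant_fdr"] = (out["p_adj"] < alpha) & big
    out.attrs["lfc_threshold"] = threshold
    n_up = int((out["significant"] & (out["lfc"] > 0)).sum())
    n_down = int((out["significant"] & (out["lfc"] < 0)).sum())
    return out, n_up, n_down


def run_de(
    expr: ExpressionTable, alpha: float = 0.05, response: str = "log_tpm"
) -> tuple[pd.DataFrame, EbayesPrior, int, int]:
    """Full DE stage: fits, moderation, tests, adaptive threshold, BH, flags."""
    fits = fit_gene_models(expr, response=response)
    prior, moderated = ebayes_moderate(fits["s2"], fits["df"])
    n_a = len(expr.cohort_columns("A"))
    n_b = len(expr.cohort_columns("B"))
    tested = moderated_t_tests(fits, prior, n_a, n_b, moderated_s2=moderated)
    flagged, n_up, n_down = call_degs(tested, alpha=alpha)
    return flagged, prior, n_up, n_down


def ora_hypergeometric(
    hit_genes, universe, gene_sets: dict[str, list[str]]
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of each gene set among the hits.

    Sets are intersected with the universe; the p-value is the upper tail
    P(overlap >= observed); BH adjustment across sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hit_genes)
    if not hits <= universe:
        raise ValueError("hit genes must be a subset of the universe")
    m_univ = len(universe)
    n_hits = len(hits)
    rows = []
    for name, members in gene_sets.items():
        in_univ = set(members) & universe
        overlap = len(in_univ & hits)
        # P(X >= overlap), X ~ Hypergeom(M=m_univ, n=|set|, N=n_hits)
        p = float(stats.hypergeom.sf(overlap - 1, m_univ, len(in_univ), n_hits))
        rows.append((name, len(in_univ), overlap, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].clip(lower=np.nextafter(0, 1)))
    else:
        out["p_adj"] = []
    return out.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
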