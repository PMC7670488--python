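"""Synthetic two-cohort study generator.

Emulates the statistical structure the downstream stages assume: two small
cohorts (7 + 7 by default) genotyped at loss-of-function (LOF) variants
grouped into genes plus a neutral background, with between-cohort allele
frequency differentiation under the Balding-Nichols model, and a gene x
sample RNA-seq count matrix with negative-binomial noise and planted
differential expression.

The Balding-Nichols model draws, for each variant with ancestral minor
allele frequency ``p`` and differentiation ``F`` (an Fst-like parameter),
independent per-cohort frequencies

    p_k ~ Beta(p (1-F)/F, (1-p)(1-F)/F),    k = A, B

so that E[p_k] = p and the expected Hudson Fst between the cohorts is F.
``F = 0`` means both cohorts share ``p`` exactly.  Genotypes are
Binomial(2, p_k) dosages of the minor allele; "planted" associated genes
have their cohort-B variant frequencies shifted by a configured amount.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io
from .containers import (
    ExpressionTable,
    GenotypeTable,
    StudyTruth,
    SyntheticStudy,
    variant_key,
)

#: functional class assigned to generated LOF variants
LOF_CLASS = "stopgain"
#: functional class assigned to the neutral background
NEUTRAL_CLASS = "synonymous SNV"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults are the study conditions the pipeline targets: two cohorts of
    7 diploid samples, ~1,200 LOF variants over 300 genes plus a 3,000
    variant neutral background, moderate between-breed differentiation
    (fst=0.1), and a 10,000-gene expression matrix with 100 planted
    differentially expressed genes at |log2FC| ~ N(3, 0.5) with random sign.
    """

    seed: int = 0
    n_per_cohort: int = 7
    n_genes_variant: int = 300
    lof_per_gene: float = 4.0  # Poisson mean of LOF variants per gene
    n_neutral_variants: int = 3000
    fst: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.02
    assoc_genes: tuple[tuple[str, float], ...] = ()  # (gene id, freq shift in B)
    n_genes_expr: int = 10_000
    n_de_genes: int = 100
    de_lfc_mean: float = 3.0
    de_lfc_sd: float = 0.5
    nb_dispersion: float = 0.1
    length_range: tuple[int, int] = (300, 5000)

    def __post_init__(self) -> None:
        counts = {
            "n_per_cohort": self.n_per_cohort,
            "n_genes_variant": self.n_genes_variant,
            "n_neutral_variants": self.n_neutral_variants,
            "n_genes_expr": self.n_genes_expr,
        }
        for name, value in counts.items():
            if value < 0 or (name == "n_per_cohort" and value < 1):
                raise ValueError(f"{name} must be positive, got {value}")
        if self.n_de_genes < 0 or self.n_de_genes > self.n_genes_expr:
            raise ValueError(
                f"n_de_genes ({self.n_de_genes}) must be in [0, n_genes_expr]"
            )
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must lie in [0, 1)")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must be a probability")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be a sub-interval of (0, 0.5]")
        if self.lof_per_gene <= 0:
            raise ValueError("lof_per_gene must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.de_lfc_sd < 0:
            raise ValueError("de_lfc_sd must be >= 0")
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ValueError("length_range must be a positive interval")


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def _cohort_frequencies(
    rng: np.random.Generator, p: np.ndarray, fst: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cohort frequencies under Balding-Nichols; fst=0 shares p exactly."""
    if fst == 0.0:
        return p.copy(), p.copy()
    scale = (1.0 - fst) / fst
    pa = rng.beta(p * scale, (1.0 - p) * scale)
    pb = rng.beta(p * scale, (1.0 - p) * scale)
    # Beta draws can touch 0/1 numerically; keep sites polymorphic in expectation
    eps = 1e-6
    return np.clip(pa, eps, 1 - eps), np.clip(pb, eps, 1 - eps)


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeTable, StudyTruth]:
    """Generate the two-cohort genotype table (LOF genes + neutral background).

    Deterministic under a fixed ``config`` (including seed).  Dosages count
    the globally rarer allele: after genotypes are drawn, any variant whose
    ALT frequency exceeds 0.5 in the combined sample has its alleles swapped,
    with ties at exactly 0.5 oriented to ALT.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_per_cohort

    genes = _gene_ids(config.n_genes_variant)
    shifts = dict(config.assoc_genes)
    unknown = set(shifts) - set(genes)
    if unknown:
        raise ValueError(f"assoc_genes reference unknown gene ids: {sorted(unknown)}")

    lof_counts = rng.poisson(config.lof_per_gene, size=config.n_genes_variant)
    lof_counts = np.maximum(lof_counts, 1)
    # planted genes must survive the >=2-variant gene filter to be testable
    for i, g in enumerate(genes):
        if g in shifts:
            lof_counts[i] = max(lof_counts[i], 2)

    gene_of: list[str | None] = []
    klass: list[str] = []
    for g, c in zip(genes, lof_counts):
        gene_of.extend([g] * int(c))
        klass.extend([LOF_CLASS] * int(c))
    gene_of.extend([None] * config.n_neutral_variants)
    klass.extend([NEUTRAL_CLASS] * config.n_neutral_variants)
    m = len(gene_of)

    lo, hi = config.maf_range
    p_anc = rng.uniform(lo, hi, size=m)
    pa, pb = _cohort_frequencies(rng, p_anc, config.fst)
    for j, g in enumerate(gene_of):
        if g is not None and g in shifts:
            pb[j] = np.clip(pb[j] + shifts[g], 0.01, 0.99)

    dos_a = rng.binomial(2, pa, size=(n, m)).astype(float)
    dos_b = rng.binomial(2, pb, size=(n, m)).astype(float)
    dosage = np.vstack([dos_a, dos_b])
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    # variant coordinates: one synthetic chromosome, increasing positions
    positions = np.cumsum(rng.integers(100, 1000, size=m))
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    ref = _BASES[ref_idx]
    alt = _BASES[alt_idx]

    # orient to the globally rarer allele (ties at 0.5 stay on ALT)
    with np.errstate(invalid="ignore"):
        n_called = (~np.isnan(dosage)).sum(axis=0)
        alt_freq = np.nansum(dosage, axis=0) / (2.0 * np.maximum(n_called, 1))
    flip = alt_freq > 0.5
    dosage[:, flip] = 2.0 - dosage[:, flip]
    ref[flip], alt[flip] = alt[flip].copy(), ref[flip].copy()

    variants = pd.DataFrame(
        {
            "variant_id": [
                variant_key("1", int(p), r, a) for p, r, a in zip(positions, ref, alt)
            ],
            "chrom": "1",
            "pos": positions.astype(int),
            "ref": ref,
            "alt": alt,
            "gene": gene_of,
            "func_class": klass,
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"A{i + 1}" for i in range(n)] + [f"B{i + 1}" for i in range(n)],
            "cohort": ["A"] * n + ["B"] * n,
        }
    )
    gt = GenotypeTable(samples=samples, variants=variants, dosage=dosage)
    truth = StudyTruth(assoc_genes=dict(shifts))
    return gt, truth


def simulate_expression(config: SimConfig) -> tuple[ExpressionTable, StudyTruth]:
    """Generate the gene x sample count matrix with planted DE genes.

    Baseline means are log-normal across genes; planted genes multiply the
    cohort-B mean by ``2**LFC`` with ``|LFC| ~ Normal(de_lfc_mean,
    de_lfc_sd)`` and random sign.  Counts are negative binomial with
    variance ``mu + dispersion * mu^2`` (Poisson in the dispersion -> 0
    limit).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_per_cohort
    genes = [f"E{i:05d}" for i in range(1, config.n_genes_expr + 1)]

    base_mean = rng.lognormal(mean=4.0, sigma=1.5, size=config.n_genes_expr)
    de_idx = rng.choice(config.n_genes_expr, size=config.n_de_genes, replace=False)
    lfc = rng.normal(config.de_lfc_mean, config.de_lfc_sd, size=config.n_de_genes)
    sign = rng.choice([-1.0, 1.0], size=config.n_de_genes)
    lfc = np.abs(lfc) * sign

    mean_a = np.tile(base_mean, (n, 1))
    mean_b = np.tile(base_mean, (n, 1))
    mean_b[:, de_idx] *= 2.0 ** lfc

    disp = max(config.nb_dispersion, 1e-8)
    size_param = 1.0 / disp

    def _nb(mu: np.ndarray) -> np.ndarray:
        return rng.negative_binomial(size_param, size_param / (size_param + mu))

    counts = np.vstack([_nb(mean_a), _nb(mean_b)]).T  # genes x samples
    lengths = rng.integers(config.length_range[0], config.length_range[1] + 1,
                           size=config.n_genes_expr)

    sample_ids = [f"A{i + 1}" for i in range(n)] + [f"B{i + 1}" for i in range(n)]
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "cohort": ["A"] * n + ["B"] * n}
    )
    values = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                          columns=sample_ids, dtype=float)
    expr = ExpressionTable(
        values=values,
        lengths=pd.Series(lengths.astype(float), index=values.index),
        samples=samples,
        is_tpm=False,
    )
    truth = StudyTruth(de_genes={genes[i]: float(l) for i, l in zip(de_idx, lfc)})
    return expr, truth


def simulate_study(config: SimConfig, out_dir: str | os.PathLike | None = None) -> SyntheticStudy:
    """Compose the genotype and expression generators; optionally write fixtures.

    When ``out_dir`` is given, writes ``genotypes.vcf``, ``annotation.tsv``,
    ``samples.tsv``, ``expression.tsv`` and ``truth.json`` there.
    """
    gt, truth_g = simulate_genotypes(config)
    expr, truth_e = simulate_expression(config)
    truth = StudyTruth(assoc_genes=truth_g.assoc_genes, de_genes=truth_e.de_genes)
    study = SyntheticStudy(genotypes=gt, expression=expr, truth=truth)
    if out_dir is not None:
        out = os.fspath(out_dir)
        os.makedirs(out, exist_ok=True)
        try:
            io.write_vcf(gt, os.path.join(out, "genotypes.vcf"))
            io.write_annotation(gt, os.path.join(out, "annotation.tsv"))
            io.write_samples(gt, os.path.join(out, "samples.tsv"))
            io.write_expression(expr, os.path.join(out, "expression.tsv"))
            with open(os.path.join(out, "truth.json"), "w") as fh:
                json.dump(dataclasses.asdict(truth), fh, indent=1, sort_keys=True)
        except OSError as exc:
            raise OSError(f"failed writing synthetic study to {out}: {exc}") from exc
    return study


def hudson_fst(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Hudson Fst estimate (ratio-of-sums) between two dosage matrices.

    Per variant: num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
    den = p1(1-p2) + p2(1-p1), with n the allele sample sizes; the estimate
    is sum(num)/sum(den) over variants with positive denominator.
    """
    def _freq(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        called = (~np.isnan(d)).sum(axis=0) * 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.nansum(d, axis=0) / called
        return p, called

    p1, n1 = _freq(np.asarray(dosage_a, dtype=float))
    p2, n2 = _freq(np.asarray(dosage_b, dtype=float))
    ok = (n1 > 1) & (n2 > 1)
    p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    if not keep.any():
        raise ValueError("no polymorphic variants for Fst estimation")
    return float(num[keep].sum() / den[keep].sum())
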