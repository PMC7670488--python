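"""Variant quality control and gene-level LOF set construction.

Reads genotypes, annotation and sample tables, applies the filter cascade
(call rate, minor allele frequency, per-cohort exact Hardy-Weinberg test)
and builds the per-gene loss-of-function variant sets used by the
gene-level association tests.  Every filter step is recorded in a
:class:`QcLedger` whose counts telescope.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from . import io
from .containers import GenotypeTable, GeneVariantSet, variant_key

logger = logging.getLogger(__name__)

#: the seven functional classes treated as loss-of-function, normalised form
LOF_CLASSES = frozenset(
    {
        "frameshiftinsertion",
        "frameshiftdeletion",
        "nonframeshiftinsertion",
        "nonframeshiftdeletion",
        "nonsynonymoussnv",
        "stopgain",
        "stoploss",
    }
)


def normalize_func_class(name: str | None) -> str | None:
    """Canonicalise a functional-class label (case/space/punctuation-blind).

    ``"no frame shift insertion"`` and ``"nonframeshift_insertion"`` both
    normalise to ``"nonframeshiftinsertion"``.
    """
    if name is None or (isinstance(name, float) and math.isnan(name)):
        return None
    out = "".join(ch for ch in str(name).lower() if ch.isalnum())
    return out.replace("no", "non", 1) if out.startswith("noframe") else out


def is_lof_class(name: str | None) -> bool:
    return normalize_func_class(name) in LOF_CLASSES


@dataclass
class QcLedger:
    """Ordered record of (filter, variants in, removed, out); counts telescope."""

    steps: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_removed: int) -> None:
        n_out = n_in - n_removed
        if self.steps and self.steps[-1][3] != n_in:
            raise ValueError(
                f"ledger does not telescope: step {name!r} starts at {n_in}, "
                f"previous ended at {self.steps[-1][3]}"
            )
        if n_removed < 0 or n_out < 0:
            raise ValueError(f"invalid counts for step {name!r}")
        self.steps.append((name, n_in, n_removed, n_out))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["filter", "variants_in", "removed", "variants_out"]
        )

    def write(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_study(
    vcf_path: str | os.PathLike,
    annotation_path: str | os.PathLike,
    samples_path: str | os.PathLike,
) -> tuple[GenotypeTable, QcLedger]:
    """Load a VCF + annotation TSV + samples TSV into a GenotypeTable.

    Multiallelic records are dropped and logged; genotypes are oriented to
    minor-allele dosage over the combined sample (ALT frequency > 0.5 means
    the complement ``2 - dosage`` is stored; ties at 0.5 keep ALT counted).
    Variants annotated to more than one gene are kept but stripped of their
    gene assignment (they cannot enter gene-level sets).
    """
    for p in (vcf_path, annotation_path, samples_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    samples = io.read_samples(samples_path)
    ann = io.read_annotation(annotation_path)

    vcf = VCF(os.fspath(vcf_path))
    vcf_samples = list(vcf.samples)
    known = set(samples["sample_id"])
    for s in vcf_samples:
        if s not in known:
            raise ValueError(f"VCF sample {s!r} missing from samples TSV")
    samples = (
        samples.set_index("sample_id").loc[vcf_samples].reset_index()
    )

    records, rows = [], []
    n_multi = 0
    n_total = 0
    for i, var in enumerate(vcf, start=1):
        n_total += 1
        try:
            alts = var.ALT
            if len(alts) != 1:
                n_multi += 1
                continue
            gts = var.genotypes  # [allele0, allele1, phased] per sample
            dos = np.array(
                [
                    np.nan if g[0] < 0 or g[1] < 0 else float(g[0] + g[1])
                    for g in gts
                ]
            )
            records.append(
                (
                    variant_key(var.CHROM, var.POS, var.REF, alts[0]),
                    var.CHROM,
                    var.POS,
                    var.REF,
                    alts[0],
                )
            )
            rows.append(dos)
        except Exception as exc:  # cyvcf2 raises opaque errors on bad records
            raise ValueError(f"malformed VCF record at data line {i}: {exc}") from exc

    variants = pd.DataFrame(
        records, columns=["variant_id", "chrom", "pos", "ref", "alt"]
    )
    dosage = (
        np.array(rows).T if rows else np.empty((len(vcf_samples), 0))
    )

    # annotation join; multi-gene variants lose their gene assignment
    gene_counts = ann.groupby("variant_id")["gene"].nunique()
    multi_gene = set(gene_counts[gene_counts > 1].index)
    if multi_gene:
        logger.info("%d variants map to multiple genes; gene assignment dropped",
                    len(multi_gene))
    ann_unique = ann[~ann["variant_id"].isin(multi_gene)].drop_duplicates("variant_id")
    variants = variants.merge(
        ann_unique[["variant_id", "gene", "func_class"]], on="variant_id", how="left"
    )
    variants.loc[variants["variant_id"].isin(multi_gene), "gene"] = None
    variants["gene"] = variants["gene"].where(pd.notna(variants["gene"]), None)

    # orient to the combined-sample minor allele
    if dosage.size:
        with np.errstate(invalid="ignore"):
            n_called = (~np.isnan(dosage)).sum(axis=0)
            alt_freq = np.nansum(dosage, axis=0) / (2.0 * np.maximum(n_called, 1))
        flip = alt_freq > 0.5
        dosage[:, flip] = 2.0 - dosage[:, flip]

    ledger = QcLedger()
    ledger.add("multiallelic_removed", n_total, n_multi)
    gt = GenotypeTable(samples=samples, variants=variants, dosage=dosage)
    return gt, ledger


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test by enumeration.

    Conditions on the observed allele counts and enumerates every attainable
    heterozygote count; the p-value is the total probability of
    configurations no more probable than the observed one.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    n = sum(counts)
    if n == 0:
        raise ValueError("empty cohort")
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_rare == 0:
        return 1.0  # monomorphic: single attainable configuration

    # log P(het | allele counts) up to a shared constant
    lgamma = math.lgamma

    def logprob(het: int) -> float:
        rare_hom = (n_rare - het) // 2
        common_hom = n - het - rare_hom
        return (
            het * math.log(2.0)
            - lgamma(rare_hom + 1)
            - lgamma(het + 1)
            - lgamma(common_hom + 1)
        )

    hets = range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    logs = np.array([logprob(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = probs[list(hets).index(n_het)]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def _cohort_genotype_counts(dos: np.ndarray) -> tuple[int, int, int]:
    called = dos[~np.isnan(dos)]
    return (
        int((called == 0).sum()),
        int((called == 1).sum()),
        int((called == 2).sum()),
    )


def apply_variant_qc(
    gt: GenotypeTable,
    call_rate_min: float = 0.90,
    maf_min: float = 0.01,
    hwe_alpha: float = 5e-8,
    hwe_mode: str = "both",
) -> tuple[GenotypeTable, QcLedger]:
    """Apply the call-rate / MAF / HWE filter cascade.

    A variant survives iff its call rate exceeds ``call_rate_min``, its
    combined-sample minor allele frequency is at least ``maf_min``, and it
    does not fail the exact HWE test at ``hwe_alpha`` in *both* cohorts
    (``hwe_mode="either"`` switches to excluding on a single-cohort
    failure).
    """
    if hwe_mode not in ("both", "either"):
        raise ValueError("hwe_mode must be 'both' or 'either'")
    for cohort in ("A", "B"):
        if not gt.cohort_mask(cohort).any():
            raise ValueError(f"cohort {cohort} is empty")

    ledger = QcLedger()
    n0 = gt.n_variants

    keep_cr = gt.call_rate() > call_rate_min
    ledger.add("call_rate", n0, int((~keep_cr).sum()))
    gt = gt.subset_variants(keep_cr)

    maf = gt.minor_allele_freq()
    maf = np.minimum(maf, 1.0 - maf)  # guard against post-subset re-orientation
    keep_maf = maf >= maf_min
    ledger.add("maf", gt.n_variants, int((~keep_maf).sum()))
    gt = gt.subset_variants(keep_maf)

    dos_a = gt.cohort_dosage("A")
    dos_b = gt.cohort_dosage("B")
    fails = np.zeros(gt.n_variants, dtype=bool)
    for j in range(gt.n_variants):
        ps = []
        for dos in (dos_a[:, j], dos_b[:, j]):
            counts = _cohort_genotype_counts(dos)
            ps.append(1.0 if sum(counts) == 0 else hwe_exact_test(*counts))
        if hwe_mode == "both":
            fails[j] = (ps[0] < hwe_alpha) and (ps[1] < hwe_alpha)
        else:
            fails[j] = (ps[0] < hwe_alpha) or (ps[1] < hwe_alpha)
    ledger.add("hwe", gt.n_variants, int(fails.sum()))
    gt = gt.subset_variants(~fails)
    return gt, ledger


def select_lof_gene_sets(
    gt: GenotypeTable,
    call_rate_min: float = 0.90,
    min_lof_per_gene: int = 2,
) -> list[GeneVariantSet]:
    """Build per-gene LOF variant sets.

    Keeps variants whose functional class is in the seven-class LOF list,
    with call rate above ``call_rate_min`` and a unique gene assignment;
    genes with at least ``min_lof_per_gene`` such variants are returned,
    sorted by gene id.
    """
    cr = gt.call_rate()
    sets: dict[str, list[str]] = {}
    for j, var in gt.variants.iterrows():
        if var.gene is None or (isinstance(var.gene, float) and math.isnan(var.gene)):
            continue
        if not is_lof_class(var.func_class):
            continue
        if cr[j] <= call_rate_min:
            continue
        sets.setdefault(str(var.gene), []).append(var.variant_id)
    out = [
        GeneVariantSet(gene=g, variant_ids=v)
        for g, v in sorted(sets.items())
        if len(v) >= min_lof_per_gene
    ]
    logger.info("selected %d genes with >=%d LOF variants", len(out), min_lof_per_gene)
    return out
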