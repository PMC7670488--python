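"""Readers and writers for the plain-text study formats.

Formats: VCF 4.2 with GT genotypes (biallelic SNP records, 1-based
positions), an annotation TSV (``variant_id`` as ``chrom:pos:ref:alt``,
``gene``, ``func_class``), a samples TSV (``sample_id``, ``cohort``) and an
expression TSV (``gene``, ``length``, one column per sample).  VCF reading
goes through :mod:`cyvcf2`; writing is a minimal GT-only emitter.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .containers import ExpressionTable, GenotypeTable

_GT_CODES = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(gt: GenotypeTable, path: str | os.PathLike) -> None:
    """Write a GenotypeTable as an uncompressed VCF 4.2 with GT fields.

    The dosage orientation is preserved as written: the counted (minor)
    allele is emitted as ALT, so reading the file back with
    :func:`lofpipe.qc.read_study` reproduces the dosage matrix exactly.
    """
    cols = "\t".join(gt.sample_ids)
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for chrom in pd.unique(gt.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        for j, var in gt.variants.iterrows():
            gts = "\t".join(
                "./." if np.isnan(d) else _GT_CODES[d] for d in gt.dosage[:, j]
            )
            fh.write(
                f"{var.chrom}\t{var.pos}\t{var.variant_id}\t{var.ref}\t{var.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_annotation(gt: GenotypeTable, path: str | os.PathLike) -> None:
    ann = gt.variants[["variant_id", "gene", "func_class"]].copy()
    ann.to_csv(path, sep="\t", index=False)


def write_samples(gt: GenotypeTable, path: str | os.PathLike) -> None:
    gt.samples.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | os.PathLike) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "gene": str})
    required = {"variant_id", "gene", "func_class"}
    if not required.issubset(ann.columns):
        raise ValueError(f"annotation TSV {path} must have columns {sorted(required)}")
    return ann


def read_samples(path: str | os.PathLike) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "cohort"}
    if not required.issubset(samples.columns):
        raise ValueError(f"samples TSV {path} must have columns {sorted(required)}")
    return samples[["sample_id", "cohort"]]


def write_expression(expr: ExpressionTable, path: str | os.PathLike) -> None:
    out = expr.values.copy()
    out.insert(0, "length", expr.lengths)
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_expression(
    path: str | os.PathLike, samples: pd.DataFrame, is_tpm: bool = False
) -> ExpressionTable:
    """Read a gene x sample expression TSV (``gene``, ``length``, samples...)."""
    tab = pd.read_csv(path, sep="\t", index_col="gene")
    if "length" not in tab.columns:
        raise ValueError(f"expression TSV {path} needs a 'length' column")
    lengths = tab.pop("length")
    known = set(samples["sample_id"])
    unknown = [c for c in tab.columns if c not in known]
    if unknown:
        raise ValueError(f"expression samples not in sample table: {unknown[:5]}")
    samples = samples[samples["sample_id"].isin(tab.columns)].reset_index(drop=True)
    tab = tab[list(samples["sample_id"])]
    return ExpressionTable(values=tab, lengths=lengths, samples=samples, is_tpm=is_tpm)


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT gene-set file: tab-separated name, description, members."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
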