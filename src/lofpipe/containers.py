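"""In-memory containers shared across the pipeline stages.

The central object is :class:`GenotypeTable`: a samples x variants matrix of
minor-allele dosages (0/1/2, NaN for missing) together with per-variant
metadata (position, alleles, gene and functional-class annotation) and
per-sample cohort labels.  Cohorts are labelled ``"A"`` and ``"B"``
throughout; the mapping from study-specific labels (breed names, case/control)
is done at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COHORTS = ("A", "B")

#: variant metadata columns every GenotypeTable carries
VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt", "gene", "func_class"]


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Canonical variant identifier ``chrom:pos:ref:alt`` (1-based pos)."""
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass
class GenotypeTable:
    """Samples x biallelic variants, oriented to minor-allele dosage.

    Parameters
    ----------
    samples
        DataFrame with columns ``sample_id`` and ``cohort`` (values in
        ``{"A", "B"}``), one row per sample, in matrix row order.
    variants
        DataFrame with :data:`VARIANT_COLUMNS`, one row per variant, in
        matrix column order.  ``pos`` is 1-based; ``gene``/``func_class``
        may be missing (NaN/None) for unannotated variants.
    dosage
        float array of shape ``(n_samples, n_variants)`` with values in
        ``{0, 1, 2}`` and ``NaN`` for missing genotypes.
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = self.samples.loc[~self.samples["cohort"].isin(COHORTS), "cohort"]
        if len(bad):
            raise ValueError(f"unknown cohort labels: {sorted(set(bad))}")
        if (self.variants["pos"] < 1).any():
            raise ValueError("variant positions must be 1-based (>= 1)")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosage values must be 0, 1, 2 or NaN")

    # -- basic dimensions ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.samples["sample_id"].to_numpy()

    def cohort_mask(self, cohort: str) -> np.ndarray:
        if cohort not in COHORTS:
            raise ValueError(f"unknown cohort {cohort!r}")
        return (self.samples["cohort"] == cohort).to_numpy()

    def cohort_dosage(self, cohort: str) -> np.ndarray:
        """Dosage rows for one cohort."""
        return self.dosage[self.cohort_mask(cohort), :]

    # -- per-variant summaries -------------------------------------------
    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing genotypes per variant."""
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def minor_allele_freq(self) -> np.ndarray:
        """Frequency of the counted (minor) allele over the combined sample.

        The table is oriented at construction so the counted allele is the
        globally rarer one; values can exceed 0.5 only if the table was
        subset after orientation.
        """
        with np.errstate(invalid="ignore"):
            n_called = (~np.isnan(self.dosage)).sum(axis=0)
            ac = np.nansum(self.dosage, axis=0)
            freq = np.where(n_called > 0, ac / (2.0 * np.maximum(n_called, 1)), np.nan)
        return freq

    # -- subsetting -------------------------------------------------------
    def subset_variants(self, mask_or_idx) -> "GenotypeTable":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeTable(
            samples=self.samples.reset_index(drop=True),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx].copy(),
        )

    def subset_samples(self, keep_ids) -> "GenotypeTable":
        keep = set(keep_ids)
        mask = self.samples["sample_id"].isin(keep).to_numpy()
        missing = keep - set(self.sample_ids)
        if missing:
            raise KeyError(f"unknown sample ids: {sorted(missing)}")
        return GenotypeTable(
            samples=self.samples[mask].reset_index(drop=True),
            variants=self.variants.reset_index(drop=True),
            dosage=self.dosage[mask, :].copy(),
        )

    def variant_index(self, variant_ids) -> np.ndarray:
        """Column indices for a list of variant ids (raises on unknown ids)."""
        lookup = pd.Index(self.variants["variant_id"])
        idx = lookup.get_indexer(list(variant_ids))
        if (idx < 0).any():
            bad = [v for v, i in zip(variant_ids, idx) if i < 0]
            raise KeyError(f"variants not in table: {bad[:5]}")
        return idx


@dataclass
class GeneVariantSet:
    """A gene and the LOF variants assigned to it after QC."""

    gene: str
    variant_ids: list[str]

    @property
    def n_markers(self) -> int:
        return len(self.variant_ids)


@dataclass
class ExpressionTable:
    """Gene x sample expression values with effective gene lengths.

    ``values`` is a DataFrame indexed by gene id with one column per sample;
    ``is_tpm`` records whether values are TPM (each column sums to 1e6) or
    raw read counts.  ``lengths`` are effective gene lengths in bp.
    """

    values: pd.DataFrame
    lengths: pd.Series
    samples: pd.DataFrame  # sample_id, cohort
    is_tpm: bool = False

    def __post_init__(self) -> None:
        if not self.lengths.index.equals(self.values.index):
            self.lengths = self.lengths.reindex(self.values.index)
        if self.lengths.isna().any():
            raise ValueError("every gene needs an effective length")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if list(self.values.columns) != list(self.samples["sample_id"]):
            raise ValueError("expression columns must match sample table order")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def cohort_columns(self, cohort: str) -> list[str]:
        if cohort not in COHORTS:
            raise ValueError(f"unknown cohort {cohort!r}")
        sel = self.samples.loc[self.samples["cohort"] == cohort, "sample_id"]
        return list(sel)


@dataclass
class StudyTruth:
    """Record of what the synthetic-data generator planted."""

    assoc_genes: dict[str, float] = field(default_factory=dict)  # gene -> freq shift
    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> signed log2 FC


@dataclass
class SyntheticStudy:
    genotypes: GenotypeTable
    expression: ExpressionTable
    truth: StudyTruth
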