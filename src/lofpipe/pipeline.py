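"""End-to-end orchestration: QC -> outliers -> scans -> structure -> DE.

A :class:`PipelineConfig` names the inputs and thresholds; ``run_pipeline``
executes the seven stages, writes every stage's outputs under the output
directory, and records a run manifest (config, seed, library versions,
SHA-256 checksums of every output) so a rerun with the same config and
seed is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__, diffexpr, geneassoc, io, popstruct, qc, singlevar

logger = logging.getLogger(__name__)

STAGES = (
    "qc",
    "outliers",
    "single_variant",
    "gene_assoc",
    "popstructure",
    "diffexpr",
    "report",
)


@dataclass
class PipelineConfig:
    vcf: str
    annotation: str
    samples: str
    expression: str | None = None
    gene_sets_gmt: str | None = None
    traits: str | None = None  # TSV: trait, cohort, value
    out_dir: str = "lofpipe_out"
    call_rate_min: float = 0.90
    maf_min: float = 0.01
    hwe_alpha: float = 5e-8
    hwe_mode: str = "both"
    min_lof_per_gene: int = 2
    alpha: float = 0.05
    outlier_n_sd: float = 3.0
    remove_outliers: bool = False  # detection always runs; removal is opt-in
    expression_is_tpm: bool = False
    de_response: str = "log_tpm"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.call_rate_min <= 1 and 0 <= self.maf_min <= 0.5):
            raise ValueError("thresholds out of range")
        if not (0 < self.alpha < 1 and 0 < self.hwe_alpha < 1):
            raise ValueError("alpha levels must lie in (0, 1)")
        if self.min_lof_per_gene < 1:
            raise ValueError("min_lof_per_gene must be >= 1")


@dataclass
class TraitSummary:
    trait: str
    cohort: str
    n: int
    min: float
    max: float
    mean: float
    sd: float
    interval_low: float
    interval_high: float


def standard_error_interval(mean: float, sd: float, n: int) -> tuple[float, float]:
    """mean +/- SD/sqrt(n), rounded to 2 decimals (one standard error)."""
    if n < 1 or sd < 0:
        raise ValueError("need n >= 1 and sd >= 0")
    se = sd / math.sqrt(n)
    return (round(mean - se, 2), round(mean + se, 2))


def summarize_traits(measurements: pd.DataFrame) -> list[TraitSummary]:
    """Per trait x cohort: n, min, max, mean, sample SD and mean +/- SD/sqrt(n).

    The interval is one standard error around the mean, rounded to two
    decimals (labelled "mean +/- SE" in the output).  Groups with fewer
    than two observations are skipped with a warning.
    """
    required = {"trait", "cohort", "value"}
    if not required.issubset(measurements.columns):
        raise ValueError(f"measurements need columns {sorted(required)}")
    out: list[TraitSummary] = []
    for (trait, cohort), grp in measurements.groupby(["trait", "cohort"], sort=True):
        vals = grp["value"].astype(float).to_numpy()
        if vals.size < 2:
            logger.warning("skipping %s/%s: fewer than 2 observations", trait, cohort)
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        se = sd / np.sqrt(vals.size)
        out.append(
            TraitSummary(
                trait=str(trait),
                cohort=str(cohort),
                n=int(vals.size),
                min=float(vals.min()),
                max=float(vals.max()),
                mean=mean,
                sd=sd,
                interval_low=round(mean - se, 2),
                interval_high=round(mean + se, 2),
            )
        )
    return out


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the run manifest (also written).

    Stage failures abort with the stage name; outputs written before the
    failure are retained for inspection.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    outputs: dict[str, str] = {}
    summary: dict = {"stages": list(STAGES)}

    def emit(name: str, writer) -> None:
        path = os.path.join(config.out_dir, name)
        writer(path)
        outputs[name] = path

    stage = "qc"
    try:
        gt, read_ledger = qc.read_study(config.vcf, config.annotation, config.samples)
        gt_qc, qc_ledger = qc.apply_variant_qc(
            gt,
            call_rate_min=config.call_rate_min,
            maf_min=config.maf_min,
            hwe_alpha=config.hwe_alpha,
            hwe_mode=config.hwe_mode,
        )
        full_ledger = qc.QcLedger(steps=read_ledger.steps + qc_ledger.steps)
        emit("qc_ledger.tsv", full_ledger.write)
        summary["qc"] = {
            "variants_in": gt.n_variants,
            "variants_out": gt_qc.n_variants,
        }

        stage = "outliers"
        pca = popstruct.pca_genotypes(gt_qc, k=min(2, gt_qc.n_samples - 1))
        flagged = popstruct.detect_outliers_pca(pca, n_sd=config.outlier_n_sd)
        summary["outliers"] = {"flagged": flagged, "removed": []}
        if config.remove_outliers and flagged:
            keep = [s for s in gt_qc.sample_ids if s not in set(flagged)]
            gt_qc = gt_qc.subset_samples(keep)
            summary["outliers"]["removed"] = flagged
            logger.info("removed flagged outliers: %s", flagged)

        stage = "single_variant"
        scan, inflation = singlevar.run_single_variant_scan(gt_qc, apply_gc=True)
        emit("single_variant.tsv", lambda p: scan.to_csv(p, sep="\t", index=False))
        summary["single_variant"] = {
            "n_tests": inflation.n_tests,
            "lambda_gc": inflation.lambda_gc,
            "min_p": float(scan["p_fisher"].min()),
        }

        stage = "gene_assoc"
        gene_sets = qc.select_lof_gene_sets(
            gt_qc,
            call_rate_min=config.call_rate_min,
            min_lof_per_gene=config.min_lof_per_gene,
        )
        if gene_sets:
            results, gene_inflation = geneassoc.run_gene_scan(
                gt_qc, gene_sets, alpha=config.alpha
            )
            frame = geneassoc.gene_results_frame(results)
            emit("gene_assoc.tsv", lambda p: frame.to_csv(p, sep="\t", index=False))
            summary["gene_assoc"] = {
                "n_genes": len(results),
                "lambda_gc": gene_inflation.lambda_gc,
                "bonferroni_threshold": geneassoc.bonferroni_threshold(
                    config.alpha, len(results)
                ),
                "significant": [r.gene for r in results if r.significant_bonferroni],
                "suggestive": [r.gene for r in results if r.suggestive],
            }
        else:
            summary["gene_assoc"] = {"n_genes": 0}

        stage = "popstructure"
        dist = popstruct.ibs_distance(gt_qc)
        emit("ibs_distance.tsv", dist.write)
        tree = popstruct.neighbor_joining(dist)
        emit("nj_tree.nwk", tree.write)
        pca2 = popstruct.pca_genotypes(gt_qc, k=min(2, gt_qc.n_samples - 1))
        emit("pca_coords.tsv", lambda p: pca2.coords.to_csv(p, sep="\t"))
        het = popstruct.observed_heterozygosity(gt_qc)
        emit(
            "heterozygosity.tsv",
            lambda p: pd.Series(het, name="heterozygosity")
            .rename_axis("cohort")
            .to_csv(p, sep="\t"),
        )
        summary["popstructure"] = {"heterozygosity": het}

        stage = "diffexpr"
        if config.expression:
            samples = io.read_samples(config.samples)
            expr = io.read_expression(
                config.expression, samples, is_tpm=config.expression_is_tpm
            )
            if config.remove_outliers and summary["outliers"]["removed"]:
                removed = set(summary["outliers"]["removed"])
                keep = expr.samples[~expr.samples["sample_id"].isin(removed)]
                expr = type(expr)(
                    values=expr.values[list(keep["sample_id"])],
                    lengths=expr.lengths,
                    samples=keep.reset_index(drop=True),
                    is_tpm=expr.is_tpm,
                )
            de, prior, n_up, n_down = diffexpr.run_de(
                expr, alpha=config.alpha, response=config.de_response
            )
            emit("de_results.tsv", lambda p: de.to_csv(p, sep="\t"))
            summary["diffexpr"] = {
                "n_genes": len(de),
                "lfc_threshold": de.attrs["lfc_threshold"],
                "d0": prior.d0 if np.isfinite(prior.d0) else "inf",
                "s0_sq": prior.s0_sq,
                "n_up": n_up,
                "n_down": n_down,
                "n_significant_fdr": int(de["significant_fdr"].sum()),
                "significant": list(de.index[de["significant"]]),
            }
            if config.gene_sets_gmt:
                sets = io.read_gmt(config.gene_sets_gmt)
                hits = list(de.index[de["significant"]])
                universe = list(de.index)
                ora = diffexpr.ora_hypergeometric(hits, universe, sets)
                emit("ora.tsv", lambda p: ora.to_csv(p, sep="\t", index=False))
                summary["ora"] = {"n_sets": len(ora)}
        else:
            summary["diffexpr"] = {"skipped": True}

        stage = "report"
        if config.traits:
            traits = pd.read_csv(config.traits, sep="\t")
            trait_rows = summarize_traits(traits)
            tframe = pd.DataFrame([dataclasses.asdict(t) for t in trait_rows])
            emit("trait_summary.tsv", lambda p: tframe.to_csv(p, sep="\t", index=False))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "versions": _versions(),
        "stages": list(STAGES),
        "summary": summary,
        "checksums": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest


def _versions() -> dict[str, str]:
    import scipy

    return {
        "lofpipe": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
    }
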