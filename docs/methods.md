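# Methods

`lofpipe` reimplements, as a tested library, the downstream analysis of a
two-breed cattle RNA-seq study design: variant quality control, single-variant
and gene-level loss-of-function (LOF) association testing, genomic-inflation
calibration, population structure, and differential expression. This note
records the models, the defaults and why, the numerical choices, and what the
synthetic data does and does not emulate.

## Study design and containers

Two cohorts, labelled A and B (in the motivating design: a larger-bodied and
a smaller-bodied breed, seven adult females each after outlier removal), are
genotyped at biallelic variants called from RNA-seq and quantified on a
gene × sample expression matrix. Genotypes are held as minor-allele dosages
(0/1/2, NaN missing) with the minor allele fixed once on the combined sample;
ties at frequency exactly 0.5 orient to ALT. Internally coordinates are
0-based in arrays; VCF I/O converts to and from 1-based positions.

## Variant QC

A variant survives iff

* call rate strictly above 0.90 (the strict reading; the two natural
  readings differ only at exactly 0.90),
* combined-sample MAF ≥ 0.01,
* it does not fail the exact Hardy–Weinberg test at p < 5e-8 in **both**
  cohorts (a switch allows either-cohort exclusion; "both" is the default).

The HWE test conditions on the allele counts and enumerates all heterozygote
counts of matching parity, summing the probabilities of configurations no
more probable than the observed one (a relative tolerance of 1e-12 guards
the ≤ comparison). Each step is recorded in a ledger whose counts telescope;
QC is idempotent by construction and the suite verifies it.

Gene-level sets keep variants in the seven-class LOF list (frameshift and
non-frameshift insertions/deletions, nonsynonymous SNVs, stop gains, stop
losses — a broad working definition of function-altering variants),
with call rate > 0.90 and a unique gene assignment; genes with ≥ 2 such
variants are tested. Multiallelic records are dropped at read time and
logged; variants annotated to several genes keep their genotypes but lose
the gene assignment.

## Single-variant scan and genomic control

Each variant's allelic 2×2 table (minor/major × cohort, missing genotypes
excluded from denominators) is tested with the two-sided Fisher exact test.
The genomic-control factor is

λ_gc = median(F⁻¹(1 − p_i)) / 0.4549364,

the median of the implied 1-df chi-squared quantiles over the null median.
λ is always reported; dividing the statistics by λ (genomic-control
correction) is available behind a flag but is not applied to downstream
gene selection. With few, discrete tests (Fisher at 14 samples) λ sits well
below 1; that deflation is a property of the test, not an error, and the
scan of a single variant is reported with a warning as unstable.

## Gene-level association

Per gene the minor-allele counts of its LOF variants are summed into a
cross-tabulation (A1, A2, B1, B2) and tested four ways.

**Collapsed chi-squared.** Pearson's statistic
N(A1·B2 − A2·B1)² / ((A1+A2)(B1+B2)(A1+B1)(A2+B2)) with 1 df, no continuity
correction (a Yates flag exists). A zero margin yields statistic 0 and p 1
with a warning. Pooling variants with unequal frequencies makes the test
mildly conservative (the pooled-variance denominator exceeds the true
variance of the collapsed count), which the calibration study quantifies:
empirical size ≈ 0.04 at nominal 0.05.

**Odds ratio with Woolf interval.** OR = A1·B2/(A2·B1);
CI = exp(ln OR ± 1.959964·√(1/A1 + 1/A2 + 1/B1 + 1/B2)). Any zero cell
makes OR and CI "Null" — no Haldane–Anscombe correction — which reproduces
every zero-cell row of the bundled published table exactly, and the 23
non-degenerate rows to all three printed decimals.

**Score tests.** Against the intercept-only binary null (μ̂ = mean(y),
residuals r = y − μ̂, V = μ̂(1−μ̂)I, P₀ = V − VX(X′VX)⁻¹X′V) with
Beta(1,25)-density MAF weights w:

* Burden: Q_B = (Σ_j w_j g_j′r)², a 1-df test with eigenvalue
  w′G′P₀Gw on the collapse;
* SKAT: Q = r′GW²G′r with null distribution Σλ_iχ²₁, λ_i the eigenvalues
  of WG′P₀GW;
* SKAT-O: Q_ρ = (1−ρ)Q_SKAT + ρQ_Burden over the grid
  {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}; the minimum per-ρ p-value is
  combined by the standard one-dimensional integration over the shared
  1-df component, with ρ = 1 mapped to 0.999 inside the integration and the
  result clamped to the theoretical sandwich
  [min p, |grid| · min p]. Single-point grids return the endpoint test
  exactly.

Missing dosages are mean-imputed per variant for the score tests only (the
cross-tabulation counts called alleles directly); no small-sample moment
adjustment is applied — a deliberate simplification at n = 14, and the
reason the type-I error study pins a conservative band ([0.02, 0.08] at
nominal 0.05) rather than exact calibration.

**Mixture tail probabilities.** `compute_quadform_pvalue` offers a
four-moment Liu-type match to a noncentral chi-squared (its default, fast
and accurate in the tail) and Imhof's exact inversion of the characteristic
function by adaptive quadrature. The reported SKAT/Burden/SKAT-O p-values
use the exact inversion: the Liu match is accurate to ~2e-3 for p ≤ 0.1 but
errs by up to ~1e-2 in the distribution body, while the inversion is
accurate to <1e-3 everywhere (verified against 10⁶-draw Monte Carlo).
Liu is retained inside the SKAT-O integrand, where it is smooth, fast and
averaged over the integration variable.

At 14 samples the permutation null of the score statistics is strongly
discrete (3,432 distinct label permutations); asymptotic and permutation
p-values agree closely (within 0.02) in the small-p regime that matters for
discovery, while in the distribution body the discreteness dominates. The
suite checks agreement on a strong-association toy and checks the
implementation against the Gaussian model null directly.

Multiple testing uses Bonferroni (α/number of genes tested) on the
chi-squared p, with a suggestive tier at p < 1e-4; λ_gc for the gene scan
is computed on the chi-squared column.

## Population structure

* **Distance:** 1 − mean IBS share over variants called in both samples,
  with per-variant share 1 − |g_i − g_j|/2.
* **PCA:** per variant, frequency p̂ = (1 + Σg)/(2 + 2n_called) (add-one
  posterior, plain MLE by flag); columns centered and scaled by
  √(2p̂(1−p̂)); missing entries 0 after centering; monomorphic columns
  dropped; SVD over samples; component signs stabilised so the first
  sample's coordinate is non-negative. Eigenvalues are s²/(n−1), so their
  sum equals the total variance of the normalised matrix.
* **Outliers:** samples with PC1 or PC2 at ≥ n_sd SDs (default 3) from the
  self-included cohort mean are flagged. With n samples no coordinate can
  exceed (n−1)/√n SDs, so at cohort size 7 the rule is deliberately
  conservative — a report, not a gatekeeper; removal is always an explicit
  opt-in pipeline action.
* **Neighbor joining:** Saitou–Nei with the Studier–Keppler Q criterion;
  ties broken by the lexicographically smallest leaf label under each
  candidate node; negative branch lengths clamped to zero with the deficit
  moved to the sister branch; unrooted output with a trifurcation at the
  last join, Newick with 6-decimal branch lengths. Exact on additive
  matrices (property-tested on random trees up to 12 leaves).
* **Heterozygosity:** per sample the fraction of called genotypes equal to
  1, averaged per cohort.

Merged multi-breed panels and their heterozygosity spectra depend on
external data; only the estimators are in scope here.

## Differential expression

TPM per sample: rate_g = count_g/length_g, scaled to sum to 10⁶. The
per-gene response is log2(TPM + 1) (pseudocount 1; a log2(count + 1) mode is
provided as an alternative convention).
Genes with zero counts in every sample are dropped and logged. A two-group
linear model gives lfc = mean(B) − mean(A) and the pooled residual variance
with d_g = n_A + n_B − 2 df.

Variances are shrunk by the log-variance moment method: with
e_g = ln s_g² − ψ(d_g/2) + ln(d_g/2), solve
ψ′(d₀/2) = var(e) − mean(ψ′(d_g/2)) by monotone root finding (d₀ = ∞ when
there is no excess spread, in which case s₀² is the geometric mean of the
raw variances and every gene shrinks fully to it);
s₀² = exp(mean(e) + ψ(d₀/2) − ln(d₀/2)) otherwise. The moderated variance
is the convex combination (d₀s₀² + d_g s_g²)/(d₀ + d_g) and the moderated t
uses d₀ + d_g df (normal when d₀ = ∞). Parameter recovery is verified by
simulation from the hierarchical model (scaled-inverse-chi-squared prior,
chi-squared sampling noise) at 5,000 genes.

Significance requires raw p < 0.05 **and** |lfc| above the adaptive
threshold mean(|lfc|) + 2·SD(|lfc|) computed over all genes (sample SD);
a second tier applies the same fold-change rule to the BH-adjusted p. The
threshold is always the formula, never a hard-coded constant. Overrepresentation of any
user-supplied gene sets (GMT) uses the upper-tail hypergeometric test with
BH across sets; database-backed annotation is out of scope.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
the biology of any particular dataset:

* **Genotypes:** Balding–Nichols — ancestral MAF uniform on (0.05, 0.5) by
  default, per-cohort frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) with
  F = 0.1 by default (two closely related but isolated breeds); genotypes
  Binomial(2, p_k); 300 LOF genes with Poisson(4) variants each (floored at
  1; planted genes floored at 2 so they remain testable) plus 3,000 neutral
  variants; 2% missingness. Planted associated genes shift the cohort-B
  frequency by a configured amount, clipped to [0.01, 0.99]. All planted
  LOF variants carry one functional class ("stopgain"); class diversity is
  cosmetic for the tests.
* **Expression:** log-normal baseline means, negative-binomial counts with
  dispersion 0.1 (Poisson in the dispersion → 0 limit, floored at 1e-8),
  uniform gene lengths on [300, 5000] bp; 100 of 10,000 genes planted with
  |log2FC| ~ N(3, 0.5) and random sign by default.

Not emulated: linkage disequilibrium, read-level noise, library-composition
effects, batch structure, sex chromosomes. Passing tests therefore
demonstrate correctness of the statistics under the assumed sampling model,
not robustness to those real-data features.

Recovery and power studies plant **rare** LOF variants (ancestral MAF
restricted to (0.05, 0.2)): with common variants the global minor-allele
orientation flips any variant whose combined frequency crosses 0.5, which
cancels the collapsed-count signal within a gene (measured: power 0.56 vs
0.96 at a +0.3 shift). Rare variants are the regime the Beta(1,25)
weighting and the LOF design assume.

Problem sizes used by the bundled studies (chosen once as the study
conditions): 500 null genes for chi-squared calibration, 50 seeds for
planted-gene top-rank recovery, 10,000 permutations for the score-test
oracle, 5,000 genes for variance-prior recovery, 20 seeds × 2,000 genes for
DE recovery, random trees of 5–12 leaves for NJ.

## Determinism

Every generator consumes a single `numpy` Generator seeded from the config;
identical config and seed give byte-identical outputs, and the pipeline
manifest records SHA-256 checksums of every output so reruns are
verifiable. Expression uses a seed sequence derived from (seed, 1) so the
genotype and expression streams are independent.

## Known limitations

* The score tests use asymptotic null distributions at n = 14 without a
  small-sample adjustment; they are conservative, as the calibration study
  shows, and the collapsed chi-squared is the primary ranking statistic.
* The collapsed chi-squared treats pooled alleles as independent draws;
  within-individual dependence is handled by the HWE assumption, not
  modelled.
* The outlier rule cannot flag anything at cohort sizes below ~12 (by
  design, see above).
* Fisher's exact test and λ_gc interact: at tiny sample sizes λ is far
  below 1 and should be read as test discreteness, not as evidence about
  confounding.
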