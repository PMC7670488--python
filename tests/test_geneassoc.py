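"""Gene-level tests: crosstab, chi-squared, Woolf OR, SKAT family, quadform."""

import numpy as np
import pytest
from scipy import stats

from lofpipe import datasets
from lofpipe.containers import GeneVariantSet
from lofpipe.geneassoc import (
    CrossTab2x2,
    DEFAULT_RHO_GRID,
    beta_maf_weights,
    bonferroni_threshold,
    burden_test,
    compute_quadform_pvalue,
    fit_null_model,
    gene_crosstab,
    odds_ratio_woolf,
    pearson_chi2,
    run_gene_scan,
    skat_test,
    skato_test,
)
from lofpipe import SimConfig, simulate_genotypes, qc
from .conftest import make_genotype_table


def toy_assoc(seed=20, m=5, shift=0.45):
    """14x5 dosage toy with a strong cohort-B frequency shift."""
    rng = np.random.default_rng(seed)
    p_a = rng.uniform(0.05, 0.15, m)
    G = np.vstack(
        [rng.binomial(2, p_a, (7, m)), rng.binomial(2, p_a + shift, (7, m))]
    ).astype(float)
    y = np.array([0.0] * 7 + [1.0] * 7)
    null = fit_null_model(y)
    w = beta_maf_weights(np.clip(G.mean(0) / 2, 1e-6, 1 - 1e-6))
    return G, null, w


class TestGeneCrosstab:
    def test_hand_count(self):
        # A: (0,1), (0,0); B: (2,1), (1,0) over two variants
        gt = make_genotype_table(
            [[0, 1], [0, 0], [2, 1], [1, 0]], "AABB", genes=["g", "g"]
        )
        ct = gene_crosstab(gt, GeneVariantSet("g", list(gt.variants["variant_id"])))
        assert ct.cells() == (1, 7, 4, 4)

    def test_all_zero_dosages(self):
        gt = make_genotype_table(np.zeros((4, 3)), "AABB", genes=["g"] * 3)
        ct = gene_crosstab(gt, GeneVariantSet("g", list(gt.variants["variant_id"])))
        assert ct.cells() == (0, 12, 0, 12)

    def test_margin_identity_without_missingness(self):
        cfg = SimConfig(seed=8, n_genes_variant=20, missing_rate=0.0,
                        n_neutral_variants=0)
        gt, _ = simulate_genotypes(cfg)
        for gs in qc.select_lof_gene_sets(gt):
            ct = gene_crosstab(gt, gs)
            assert ct.a1 + ct.a2 == ct.b1 + ct.b2 == 2 * 7 * gs.n_markers


class TestPearsonChi2:
    def test_balanced_table(self):
        stat, p = pearson_chi2(CrossTab2x2(10, 10, 10, 10))
        assert stat == 0 and p == 1

    def test_closed_form_cd48(self):
        stat, p = pearson_chi2(CrossTab2x2(2, 138, 32, 108))
        expected = 280 * (2 * 108 - 138 * 32) ** 2 / (140 * 140 * 34 * 246)
        assert stat == pytest.approx(expected)
        assert stat == pytest.approx(30.13, abs=0.01)

    def test_closed_form_gpatch3(self):
        stat, _ = pearson_chi2(CrossTab2x2(16, 12, 28, 0))
        assert stat == pytest.approx(15.27, abs=0.01)

    def test_matches_textbook_expected_counts_form(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            cells = rng.integers(1, 60, 4)
            ct = CrossTab2x2(*map(int, cells))
            stat, p = pearson_chi2(ct)
            obs = np.array(ct.cells()).reshape(2, 2)
            exp_stat = stats.chi2_contingency(obs, correction=False)[0]
            assert stat == pytest.approx(exp_stat, rel=1e-10)

    def test_yates_flag_reduces_statistic(self):
        ct = CrossTab2x2(2, 138, 32, 108)
        assert pearson_chi2(ct, yates=True)[0] < pearson_chi2(ct)[0]

    def test_zero_margin(self):
        with pytest.warns(UserWarning):
            stat, p = pearson_chi2(CrossTab2x2(0, 5, 0, 5))
        assert (stat, p) == (0.0, 1.0)


class TestOddsRatioWoolf:
    def test_unit_table_closed_form(self):
        ci = odds_ratio_woolf(CrossTab2x2(1, 1, 1, 1))
        assert ci.or_value == pytest.approx(1.0)
        # SE = 2 exactly -> bounds exp(+/- 2 * 1.959964)
        assert ci.ci_low == pytest.approx(np.exp(-2 * 1.959964), rel=1e-9)
        assert ci.ci_high == pytest.approx(np.exp(2 * 1.959964), rel=1e-9)

    def test_published_table_regression_all_rows(self):
        """All 23 non-Null published rows reproduce OR and CI to 3 decimals;
        the 7 zero-cell rows are Null."""
        import pandas as pd

        table = datasets.gene_crosstab_table()
        n_null = n_ok = 0
        for row in table.itertuples():
            ci = odds_ratio_woolf(CrossTab2x2(row.a1, row.a2, row.b1, row.b2))
            if pd.isna(row.or_printed):
                assert ci.is_null, row.gene
                n_null += 1
            else:
                assert round(ci.or_value, 3) == pytest.approx(row.or_printed), row.gene
                assert round(ci.ci_low, 3) == pytest.approx(row.ci_low_printed), row.gene
                assert round(ci.ci_high, 3) == pytest.approx(row.ci_high_printed), row.gene
                n_ok += 1
        assert (n_ok, n_null) == (23, 7)


class TestBonferroni:
    def test_published_threshold(self):
        thr = bonferroni_threshold(0.05, 2720)
        assert float(f"{thr:.3g}") == 1.84e-5

    @pytest.mark.parametrize("alpha,n,expected", [(0.05, 1, 0.05), (0.01, 100, 1e-4)])
    def test_simple(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected)


class TestQuadform:
    def test_single_lambda_exact_chi2(self):
        q = 5.3
        assert compute_quadform_pvalue(q, [1.0]) == pytest.approx(
            float(stats.chi2.sf(q, 1)), rel=1e-12
        )

    def test_three_unit_lambdas_chi2_3(self):
        assert compute_quadform_pvalue(7.8147, [1, 1, 1]) == pytest.approx(0.05, abs=1e-3)
        assert compute_quadform_pvalue(
            7.8147, [1, 1, 1], method="imhof"
        ) == pytest.approx(0.05, abs=1e-3)

    def test_negative_q_p_one(self):
        assert compute_quadform_pvalue(-1.0, [1.0, 2.0]) == 1.0

    def test_monte_carlo_accuracy(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            lam = rng.uniform(0.2, 3.0, rng.integers(2, 8))
            draws = (rng.standard_normal((200_000, lam.size)) ** 2 * lam).sum(1)
            for qtl in (0.9, 0.95, 0.99):
                q = np.quantile(draws, qtl)
                p_mc = (draws > q).mean()
                err_im = abs(compute_quadform_pvalue(q, lam, method="imhof") - p_mc)
                assert err_im < 0.005
                err_liu = abs(compute_quadform_pvalue(q, lam) - p_mc)
                assert err_liu < 0.005


class TestScoreTests:
    def test_single_variant_burden_equals_skat(self):
        G, null, w = toy_assoc(m=1)
        assert burden_test(G, null, w) == pytest.approx(
            skat_test(G, null, w), rel=1e-12
        )

    def test_identical_columns_collapse(self):
        rng = np.random.default_rng(4)
        g = rng.binomial(2, 0.2, 14).astype(float)
        G = np.tile(g[:, None], (1, 4))
        y = np.array([0.0] * 7 + [1.0] * 7)
        null = fit_null_model(y)
        w = np.array([0.5, 1.0, 1.5, 2.0])
        p_multi = burden_test(G, null, w)
        p_single = burden_test(g[:, None], null, np.array([w.sum()]))
        assert p_multi == pytest.approx(p_single, rel=1e-10)

    def test_zero_genotypes_p_one(self):
        null = fit_null_model(np.array([0.0] * 7 + [1.0] * 7))
        G = np.zeros((14, 3))
        w = np.ones(3)
        assert skat_test(G, null, w) == 1.0
        with pytest.warns(UserWarning):
            assert burden_test(G, null, w) == 1.0
        assert skato_test(G, null, w) == 1.0

    def test_skat_permutation_oracle(self):
        """Asymptotic SKAT p within 0.02 of a 10,000-permutation p."""
        G, null, w = toy_assoc()
        p_asym = skat_test(G, null, w)
        Gw = G * w
        q0 = float(((Gw.T @ null.residuals) ** 2).sum())
        rng = np.random.default_rng(99)
        y = null.y
        hits = 0
        B = 10_000
        for _ in range(B):
            yp = rng.permutation(y)
            r = yp - yp.mean()
            hits += ((Gw.T @ r) ** 2).sum() >= q0
        assert abs(p_asym - hits / B) < 0.02

    def test_skat_type_one_error_band(self):
        """Null phenotype over 500 synthetic genes: empirical size in [0.02, 0.08]
        at alpha 0.05 (asymptotics at n=14 are conservative)."""
        null = fit_null_model(np.array([0.0] * 7 + [1.0] * 7))
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(500):
            m = rng.integers(2, 9)
            G = rng.binomial(2, rng.uniform(0.05, 0.4, m), (14, m)).astype(float)
            w = beta_maf_weights(np.clip(G.mean(0) / 2, 1e-6, 1 - 1e-6))
            hits += skat_test(G, null, w) < 0.05
        assert 0.02 <= hits / 500 <= 0.08

    def test_planted_gene_burden_power(self):
        hits = 0
        for seed in range(20):
            G, null, w = toy_assoc(seed=seed, shift=0.3)
            hits += burden_test(G, null, w) < 0.05
        assert hits >= 11  # majority of seeds


class TestSkatO:
    def test_endpoint_reduction_skat(self):
        G, null, w = toy_assoc()
        assert skato_test(G, null, w, rho_grid=[0.0]) == skat_test(G, null, w)

    def test_endpoint_reduction_burden(self):
        G, null, w = toy_assoc()
        assert skato_test(G, null, w, rho_grid=[1.0]) == burden_test(G, null, w)

    def test_sandwich_property(self):
        for seed in (20, 21, 22, 23):
            G, null, w = toy_assoc(seed=seed, shift=0.25)
            p_o = skato_test(G, null, w)
            p_min = min(skat_test(G, null, w), burden_test(G, null, w))
            assert p_min <= p_o + 1e-12
            assert p_o <= min(1.0, p_min * len(DEFAULT_RHO_GRID)) + 1e-12

    def test_skato_permutation_oracle(self):
        """Min-p SKAT-O statistic: asymptotic combined p within 0.02 of the
        permutation p of the min-p statistic (Liu p per rho, fixed eigenvalues)."""
        G, null, w = toy_assoc()
        p_asym = skato_test(G, null, w)
        m = G.shape[1]
        Gw = G * w
        Z = np.sqrt(null.variance) * (Gw - Gw.mean(0, keepdims=True))
        K = Z.T @ Z
        lam_per_rho = []
        for rho in DEFAULT_RHO_GRID:
            a = np.sqrt(1 - rho)
            b = (np.sqrt(1 - rho + m * rho) - a) / m
            Rh = a * np.eye(m) + b * np.ones((m, m))
            lam = np.linalg.eigvalsh(Rh @ K @ Rh)
            lam_per_rho.append(lam[lam > lam.max() * 1e-10])

        def min_p(r):
            s = Gw.T @ r
            qs, qb = float((s**2).sum()), float(s.sum() ** 2)
            return min(
                compute_quadform_pvalue((1 - rho) * qs + rho * qb, lam)
                for rho, lam in zip(DEFAULT_RHO_GRID, lam_per_rho)
            )

        t_obs = min_p(null.residuals)
        rng = np.random.default_rng(7)
        B = 10_000
        hits = 0
        for _ in range(B):
            yp = rng.permutation(null.y)
            hits += min_p(yp - yp.mean()) <= t_obs
        assert abs(p_asym - hits / B) < 0.02


class TestGeneScan:
    def test_row_count_and_flags(self):
        cfg = SimConfig(seed=9, n_genes_variant=15, n_neutral_variants=0,
                        missing_rate=0.0)
        gt, _ = simulate_genotypes(cfg)
        sets = qc.select_lof_gene_sets(gt)
        results, inflation = run_gene_scan(gt, sets)
        assert len(results) == len(sets)
        thr = bonferroni_threshold(0.05, len(sets))
        for r in results:
            assert np.isfinite(r.p_chi)
            assert r.significant_bonferroni == (r.p_chi < thr)
            for p in (r.p_burden, r.p_skat, r.p_skato):
                assert 0 < p <= 1
        assert inflation.n_tests == len(sets)

    def test_planted_gene_ranks_first(self):
        top = 0
        for seed in range(50):
            cfg = SimConfig(seed=seed, fst=0.0, missing_rate=0.0,
                            n_genes_variant=100, lof_per_gene=5,
                            maf_range=(0.05, 0.2), n_neutral_variants=0,
                            assoc_genes=(("G0050", 0.5),))
            gt, _ = simulate_genotypes(cfg)
            results, _ = run_gene_scan(gt, qc.select_lof_gene_sets(gt),
                                       score_tests=False)
            top += results[0].gene == "G0050"
        assert top >= 40

    def test_null_familywise_error(self):
        any_hit = 0
        for seed in range(30):
            cfg = SimConfig(seed=3000 + seed, fst=0.0, missing_rate=0.0,
                            n_genes_variant=100, n_neutral_variants=0)
            gt, _ = simulate_genotypes(cfg)
            results, _ = run_gene_scan(gt, qc.select_lof_gene_sets(gt),
                                       score_tests=False)
            any_hit += any(r.significant_bonferroni for r in results)
        assert any_hit / 30 <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 30)
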