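"""Differential expression: TPM, moderation, adaptive threshold, BH, ORA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lofpipe import SimConfig, simulate_expression
from lofpipe.containers import ExpressionTable
from lofpipe.diffexpr import (
    EbayesPrior,
    adaptive_lfc_threshold,
    bh_adjust,
    call_degs,
    ebayes_moderate,
    fit_gene_models,
    moderated_t_tests,
    ora_hypergeometric,
    run_de,
    tpm_from_counts,
)


def make_expr(values, cohorts, lengths=None):
    values = np.asarray(values, dtype=float)
    genes = [f"g{i}" for i in range(values.shape[0])]
    counts = {"A": 0, "B": 0}
    ids = []
    for c in cohorts:
        counts[c] += 1
        ids.append(f"{c}{counts[c]}")
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=ids)
    lengths = pd.Series(
        lengths if lengths is not None else np.full(len(genes), 1000.0),
        index=frame.index,
    )
    samples = pd.DataFrame({"sample_id": ids, "cohort": list(cohorts)})
    return ExpressionTable(values=frame, lengths=lengths, samples=samples)


class TestTpm:
    def test_two_gene_example(self):
        counts = pd.DataFrame({"s1": [10.0, 10.0]}, index=["g1", "g2"])
        lengths = pd.Series([1000.0, 2000.0], index=["g1", "g2"])
        tpm = tpm_from_counts(counts, lengths)
        assert tpm["s1"].tolist() == pytest.approx([666666.6667, 333333.3333], rel=1e-6)

    def test_single_gene_full_million(self):
        counts = pd.DataFrame({"s1": [7.0]}, index=["g1"])
        tpm = tpm_from_counts(counts, pd.Series([500.0], index=["g1"]))
        assert tpm.iloc[0, 0] == pytest.approx(1e6)

    def test_scale_invariance_and_column_sums(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 500, (50, 4)).astype(float))
        counts.iloc[0] += 1  # avoid an all-zero sample
        lengths = pd.Series(rng.integers(200, 3000, 50).astype(float))
        t1 = tpm_from_counts(counts, lengths)
        t2 = tpm_from_counts(counts * 2, lengths)
        assert np.allclose(t1, t2)
        assert np.allclose(t1.sum(axis=0), 1e6, atol=1e-3)

    def test_all_zero_sample_error(self):
        counts = pd.DataFrame({"bad": [0.0, 0.0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="bad"):
            tpm_from_counts(counts, pd.Series([100.0, 100.0], index=["g1", "g2"]))


class TestGeneFits:
    def test_zero_variance_groups(self):
        # log2 values (1,1) vs (3,3): lfc 2, pooled variance 0
        expr = make_expr([[2**1 - 1, 2**1 - 1, 2**3 - 1, 2**3 - 1]], "AABB")
        fits = fit_gene_models(expr, response="log_count")
        assert fits.loc["g0", "lfc"] == pytest.approx(2.0)
        assert fits.loc["g0", "s2"] == 0.0

    def test_hand_pooled_variance(self):
        # log2 responses A=(0,2), B=(1,3): lfc 1, s2 = 2, df 2
        vals = [[2**0 - 1, 2**2 - 1, 2**1 - 1, 2**3 - 1]]
        fits = fit_gene_models(make_expr(vals, "AABB"), response="log_count")
        assert fits.loc["g0", "lfc"] == pytest.approx(1.0)
        assert fits.loc["g0", "s2"] == pytest.approx(2.0)
        assert fits.loc["g0", "df"] == 2

    def test_identical_groups_zero_lfc(self):
        expr = make_expr([[5, 7, 5, 7]], "AABB")
        fits = fit_gene_models(expr, response="log_count")
        assert fits.loc["g0", "lfc"] == 0.0

    def test_all_zero_genes_dropped(self):
        expr = make_expr([[1, 2, 3, 4], [0, 0, 0, 0]], "AABB")
        fits = fit_gene_models(expr, response="log_count")
        assert list(fits.index) == ["g0"]


class TestEbayes:
    def test_equal_variances_shrink_to_common(self):
        s2 = np.full(50, 3.0)
        prior, mod = ebayes_moderate(s2, np.full(50, 10.0))
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(3.0)
        assert np.allclose(mod, 3.0)

    def test_parameter_recovery_hierarchical(self):
        """sigma_g^2 ~ s0^2 d0 / chi2_d0 (d0=8, s0^2=4), s_g^2 ~ sigma_g^2
        chi2_12/12 over 5000 genes: moment estimates land in the stated bands."""
        rng = np.random.default_rng(42)
        n, d0, s0, dg = 5000, 8.0, 4.0, 12
        sigma2 = s0 * d0 / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(dg, n) / dg
        prior, _ = ebayes_moderate(s2, np.full(n, float(dg)))
        assert 6.0 <= prior.d0 <= 10.0
        assert 3.6 <= prior.s0_sq <= 4.4

    def test_outlier_variance_moderated_between(self):
        s2 = np.array([2.0] * 30 + [50.0])
        prior, mod = ebayes_moderate(s2, np.full(31, 8.0))
        assert prior.s0_sq < mod[-1] < 50.0
        # convex combination bounds for every gene
        assert np.all(mod >= np.minimum(s2, prior.s0_sq) - 1e-9)
        assert np.all(mod <= np.maximum(s2, prior.s0_sq) + 1e-9)

    def test_all_zero_variances_error(self):
        with pytest.raises(ValueError):
            ebayes_moderate(np.zeros(20), np.full(20, 4.0))


class TestModeratedT:
    def _fits(self, lfcs, s2, df=4):
        return pd.DataFrame({"lfc": lfcs, "s2": s2, "df": df})

    def test_zero_lfc_p_one(self):
        fits = self._fits([0.0], [1.0])
        out = moderated_t_tests(fits, EbayesPrior(4.0, 1.0), 3, 3)
        assert out["p"].iloc[0] == 1.0

    def test_infinite_prior_matches_z_test(self):
        fits = self._fits([1.0, -0.5], [1.0, 1.0])
        out = moderated_t_tests(fits, EbayesPrior(math.inf, 2.0), 4, 4)
        z = np.array([1.0, -0.5]) / np.sqrt(2.0 * (1 / 4 + 1 / 4))
        assert out["p"].to_numpy() == pytest.approx(2 * stats.norm.sf(np.abs(z)))

    def test_ordinary_t_reduction(self):
        # with the prior weight forced to zero the moderated t is the pooled
        # two-sample t
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 5), rng.normal(1, 1, 5)
        s2 = (a.var(ddof=1) * 4 + b.var(ddof=1) * 4) / 8
        fits = self._fits([b.mean() - a.mean()], [s2], df=8)
        out = moderated_t_tests(fits, EbayesPrior(1e-300, 1.0), 5, 5,
                                moderated_s2=np.array([s2]))
        t_ref, p_ref = stats.ttest_ind(b, a, equal_var=True)
        assert out["t_mod"].iloc[0] == pytest.approx(t_ref)
        # df = d0 + dg ~= 8 when d0 ~= 0
        assert out["p"].iloc[0] == pytest.approx(p_ref, rel=1e-6)


class TestAdaptiveThreshold:
    @pytest.mark.parametrize(
        "lfcs,expected",
        [
            ([1, 1, 1], 1.0),
            ([0, 0, 0, 4], 5.0),
            ([-2, 2], 2.0),
        ],
    )
    def test_examples(self, lfcs, expected):
        assert adaptive_lfc_threshold(lfcs) == pytest.approx(expected)

    def test_needs_two_genes(self):
        with pytest.raises(ValueError):
            adaptive_lfc_threshold([1.0])


class TestBhAdjust:
    def test_hand_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_and_equal(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert bh_adjust([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 0.0])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_dominates_and_monotone(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_sorted_adjusted_values_stable_under_readjustment(self):
        # once every adjusted value equals p*m/rank monotonely, the step-up
        # leaves an already-flat vector unchanged
        flat = [0.2, 0.2, 0.2, 0.2]
        assert bh_adjust(flat) == pytest.approx(flat)


class TestCallDegs:
    def _results(self, lfcs, ps):
        return pd.DataFrame({"lfc": lfcs, "p": ps})

    def test_alpha_zero_no_calls(self):
        res, up, down = call_degs(self._results([3, -3, 0.1], [1e-9, 1e-9, 0.5]),
                                  alpha=0.0)
        assert up == down == 0 and not res["significant"].any()

    def test_direction_counts(self):
        # many quiet genes keep the adaptive threshold below the two plants
        lfcs = [5.0, -5.0] + [0.1] * 18
        ps = [0.001, 0.001] + [0.9] * 18
        res, up, down = call_degs(self._results(lfcs, ps))
        assert (up, down) == (1, 1)
        assert res["p_adj"].ge(res["p"]).all()

    def test_null_data_error_control(self):
        ok = 0
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_genes_expr=1000, n_de_genes=0)
            expr, _ = simulate_expression(cfg)
            de, _, up, down = run_de(expr)
            ok += (up + down) <= 0.05 * len(de)
        assert ok >= 9

    def test_planted_recovery_and_fdp(self):
        tp = fp = total = 0
        for seed in range(20):
            cfg = SimConfig(seed=seed, n_genes_expr=2000, n_de_genes=100,
                            de_lfc_mean=4.0, de_lfc_sd=0.5)
            expr, truth = simulate_expression(cfg)
            de, _, _, _ = run_de(expr)
            called = set(de.index[de["significant"]])
            planted = set(truth.de_genes)
            tp += len(called & planted)
            fp += len(called - planted)
            total += len(planted)
        assert tp / total >= 0.80
        assert fp / max(tp + fp, 1) <= 0.10


class TestOra:
    def test_enumeration_oracle(self):
        # universe 20, set of 5, 5 hits, overlap 3
        universe = [f"u{i}" for i in range(20)]
        gene_set = universe[:5]
        hits = universe[2:5] + universe[10:12]  # overlap exactly 3
        res = ora_hypergeometric(hits, universe, {"s": gene_set})
        expected = sum(
            math.comb(5, k) * math.comb(15, 5 - k) / math.comb(20, 5)
            for k in range(3, 6)
        )
        assert res.loc[0, "p"] == pytest.approx(expected)
        assert res.loc[0, "overlap"] == 3

    def test_full_set_hit_attains_min_p(self):
        universe = [f"u{i}" for i in range(30)]
        sets = {"full": universe[:6], "other": universe[10:16]}
        res = ora_hypergeometric(universe[:6], universe, sets)
        assert res.iloc[0]["set"] == "full"
        assert res.iloc[0]["p"] < res.iloc[1]["p"]

    def test_zero_overlap_large_p(self):
        universe = [f"u{i}" for i in range(25)]
        res = ora_hypergeometric(universe[:5], universe, {"s": universe[20:]})
        assert res.loc[0, "p"] >= 0.5

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            ora_hypergeometric(["x"], ["a", "b"], {"s": ["a"]})
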