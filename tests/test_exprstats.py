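"""Expression statistics: closed-form oracles and threshold semantics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from anchornet import exprstats
from anchornet.exprstats import (
    GeneSignature,
    bh_adjust,
    cna_gain_fraction,
    compare_overlap_distributions,
    consensus_signature,
    correlate_anchor,
    differential_expression,
    fisher_enrichment,
    meta_combine,
    multiset_intersection_test,
    residualize_covariates,
)


def de_table(genes, logfc, p):
    fdr = bh_adjust(np.asarray(p))
    return pd.DataFrame({"logFC": logfc, "p": p, "fdr": fdr}, index=genes)


class TestResidualize:
    def test_orthogonal_covariate_leaves_gene_unchanged(self, rng):
        n = 40
        cov = pd.DataFrame({"batch": np.repeat([0.0, 1.0], n // 2)},
                           index=[f"s{i}" for i in range(n)])
        # gene orthogonal to batch: identical halves
        half = rng.normal(size=n // 2)
        mat = pd.DataFrame([np.concatenate([half, half])], index=["g1"],
                           columns=cov.index)
        out = residualize_covariates(mat, cov)
        np.testing.assert_allclose(out.loc["g1"], mat.loc["g1"], atol=1e-10)

    def test_batch_effect_fully_removed(self, rng):
        n = 60
        batch = np.repeat([0.0, 1.0], n // 2)
        cov = pd.DataFrame({"batch": batch}, index=[f"s{i}" for i in range(n)])
        gene = 2.0 * batch + rng.normal(size=n)
        mat = pd.DataFrame([gene], index=["g"], columns=cov.index)
        out = residualize_covariates(mat, cov)
        assert abs(np.corrcoef(out.loc["g"], batch)[0, 1]) < 1e-10

    def test_constant_covariate_dropped_with_warning(self, rng):
        cov = pd.DataFrame(
            {"c": np.ones(10)}, index=[f"s{i}" for i in range(10)]
        )
        mat = pd.DataFrame([rng.normal(size=10)], index=["g"], columns=cov.index)
        with pytest.warns(UserWarning, match="constant covariate"):
            out = residualize_covariates(mat, cov)
        assert out.shape == mat.shape


class TestDifferentialExpression:
    def test_three_vs_three_matches_closed_form(self):
        mat = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], index=["g"],
            columns=list("abcdef"),
        )
        out = differential_expression(mat, ["a", "b", "c"], ["d", "e", "f"],
                                      equal_var=True)
        # hand-computed pooled two-sample t: means 2 and 5, s_p^2 = 1
        t_expected = (2.0 - 5.0) / math.sqrt(1.0 * (1 / 3 + 1 / 3))
        p_expected = 2 * stats.t.sf(abs(t_expected), df=4)
        assert out.loc["g", "t_stat"] == pytest.approx(t_expected, abs=1e-10)
        assert out.loc["g", "p"] == pytest.approx(p_expected, abs=1e-10)
        assert out.loc["g", "logFC"] == pytest.approx(-3.0)

    def test_identical_groups_zero_logfc(self, rng):
        vals = rng.normal(size=4)
        mat = pd.DataFrame([np.concatenate([vals, vals])], index=["g"],
                           columns=list("abcdwxyz"))
        out = differential_expression(mat, list("abcd"), list("wxyz"))
        assert out.loc["g", "logFC"] == 0.0

    def test_degenerate_zero_variance_flagged(self):
        mat = pd.DataFrame([[1.0] * 6, [1, 2, 1, 5, 6, 5]],
                           index=["flat", "ok"], columns=list("abcdef"))
        out = differential_expression(mat, list("abc"), list("def"))
        assert out.loc["flat", "p"] == 1.0
        assert bool(out.loc["flat", "degenerate"])
        assert not bool(out.loc["ok", "degenerate"])

    def test_rejects_overlapping_or_tiny_groups(self, rng):
        mat = pd.DataFrame([rng.normal(size=4)], index=["g"],
                           columns=list("abcd"))
        with pytest.raises(ValueError):
            differential_expression(mat, ["a"], ["b", "c"])
        with pytest.raises(ValueError):
            differential_expression(mat, ["a", "b"], ["b", "c"])


class TestBH:
    def test_all_equal_pvalues_are_fixed_point(self):
        out = bh_adjust(np.full(20, 0.05))
        np.testing.assert_allclose(out, 0.05)

    def test_order_preserving(self, rng):
        p = rng.uniform(size=100)
        fdr = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-15).all()

    def test_bounds(self, rng):
        p = rng.uniform(size=200)
        fdr = bh_adjust(p)
        assert (fdr >= p - 1e-15).all() and (fdr <= 1.0).all()


class TestMetaCombine:
    def test_two_cohort_sum_of_neglog10(self):
        tabs = {
            "a": de_table(["g"], [0.39], [6.70e-14]),
            "b": de_table(["g"], [0.80], [1.04e-87]),
        }
        out = meta_combine(tabs)
        assert out.loc["g", "score"] == pytest.approx(100.16, abs=0.01)
        assert not out.loc["g", "discordant"]

    def test_p_of_one_contributes_zero(self):
        tabs = {
            "a": de_table(["g"], [1.0], [0.01]),
            "b": de_table(["g"], [1.0], [1.0]),
        }
        out = meta_combine(tabs)
        assert out.loc["g", "score"] == pytest.approx(2.0)

    def test_monotone_in_each_pvalue(self):
        base = meta_combine({"a": de_table(["g"], [1.0], [0.05])})
        lower = meta_combine({"a": de_table(["g"], [1.0], [0.01])})
        assert lower.loc["g", "score"] > base.loc["g", "score"]

    def test_discordant_directions_flagged(self):
        tabs = {
            "a": de_table(["g"], [0.5], [0.01]),
            "b": de_table(["g"], [-0.5], [0.01]),
        }
        assert bool(meta_combine(tabs).loc["g", "discordant"])

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            out = meta_combine({"a": de_table(["g"], [1.0], [0.0])})
        assert np.isfinite(out.loc["g", "score"])


class TestConsensusSignature:
    def make_tables(self, spec):
        """spec: list of dicts gene -> (logFC, fdr)."""
        tabs = []
        for d in spec:
            genes = list(d)
            tabs.append(pd.DataFrame(
                {"logFC": [d[g][0] for g in genes],
                 "p": [d[g][1] for g in genes],
                 "fdr": [d[g][1] for g in genes]},
                index=genes,
            ))
        return tabs

    def test_two_of_three_included_one_of_three_excluded(self):
        hit, miss = (-0.6, 0.01), (-0.6, 0.9)
        tabs = self.make_tables([
            {"g2of3": hit, "g1of3": hit},
            {"g2of3": hit, "g1of3": miss},
            {"g2of3": miss, "g1of3": miss},
        ])
        sig = consensus_signature(tabs, 0.05, 1.3, 2)
        assert "g2of3" in sig.down
        assert "g1of3" not in sig.down and "g1of3" not in sig.up

    def test_directions_tallied_independently(self):
        up, down = (0.6, 0.01), (-0.6, 0.01)
        tabs = self.make_tables([{"g": up}, {"g": up}, {"g": down}])
        sig = consensus_signature(tabs, 0.05, 1.3, 2)
        assert "g" in sig.up and "g" not in sig.down

    def test_fold_change_cut_is_linear_scale(self):
        # logFC 0.3 is linear FC 1.23 < 1.3 -> excluded
        tabs = self.make_tables([{"g": (0.3, 0.001)}] * 3)
        sig = consensus_signature(tabs, 0.05, 1.3, 2)
        assert "g" not in sig.up
        # logFC 0.45 is linear FC 1.37 > 1.3 -> included
        tabs = self.make_tables([{"g": (0.45, 0.001)}] * 3)
        assert "g" in consensus_signature(tabs, 0.05, 1.3, 2).up

    def test_monotone_in_min_support(self, rng):
        spec = []
        genes = [f"g{i}" for i in range(30)]
        for _ in range(4):
            spec.append({
                g: (float(rng.normal()), float(rng.uniform(0, 0.1)))
                for g in genes
            })
        tabs = self.make_tables(spec)
        prev_up, prev_dn = None, None
        for ms in (1, 2, 3, 4):
            sig = consensus_signature(tabs, 0.05, 1.3, ms)
            if prev_up is not None:
                assert sig.up <= prev_up and sig.down <= prev_dn
            prev_up, prev_dn = sig.up, sig.down

    def test_min_support_exceeding_tables_rejected(self):
        tabs = self.make_tables([{"g": (0.5, 0.01)}])
        with pytest.raises(ValueError):
            consensus_signature(tabs, 0.05, 1.3, 2)

    def test_signature_type_invariants(self):
        with pytest.raises(ValueError):
            GeneSignature(frozenset("a"), frozenset("a"))
        with pytest.raises(ValueError):
            GeneSignature(frozenset("a"), frozenset("b"), fc_cutoff=1.0)


class TestCorrelateAnchor:
    def test_monotone_transform_gives_rho_one(self, rng):
        x = rng.normal(size=30)
        mat = pd.DataFrame([x, np.exp(x)], index=["anchor", "g"],
                           columns=[f"s{i}" for i in range(30)])
        out = correlate_anchor(mat, "anchor")
        assert out.loc["g", "rho"] == pytest.approx(1.0)

    def test_rho_exactly_at_cutoff_fails_strict_inequality(self):
        # permutation pair with Spearman rho exactly 0.2
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [3.0, 4.0, 1.0, 2.0, 5.0]
        assert stats.spearmanr(x, y).statistic == pytest.approx(0.2)
        mat = pd.DataFrame([x, y], index=["anchor", "g"],
                           columns=[f"s{i}" for i in range(5)])
        out = correlate_anchor(mat, "anchor")
        assert out.loc["g", "rho"] == pytest.approx(0.2)
        assert not bool(out.loc["g", "passes"])

    def test_matches_rank_then_pearson_oracle(self, rng):
        n = 40
        x = rng.normal(size=n)
        mat_rows = [x] + [rng.normal(size=n) for _ in range(50)]
        mat = pd.DataFrame(mat_rows,
                           index=["anchor"] + [f"g{i}" for i in range(50)],
                           columns=[f"s{i}" for i in range(n)])
        out = correlate_anchor(mat, "anchor")
        rx = stats.rankdata(x)
        for i in range(50):
            expected = np.corrcoef(rx, stats.rankdata(mat.loc[f"g{i}"]))[0, 1]
            assert out.loc[f"g{i}", "rho"] == pytest.approx(expected, abs=1e-12)

    def test_constant_gene_excluded_with_flag(self, rng):
        mat = pd.DataFrame(
            [rng.normal(size=10), np.ones(10)], index=["anchor", "flat"],
            columns=[f"s{i}" for i in range(10)],
        )
        out = correlate_anchor(mat, "anchor")
        assert bool(out.loc["flat", "constant"])
        assert not bool(out.loc["flat", "passes"])


class TestFisherEnrichment:
    def test_matches_direct_hypergeometric_sum(self):
        universe = set(range(100))
        a, b = set(range(10)), set(range(5, 15))
        res = fisher_enrichment(a, b, universe)
        direct = sum(
            math.comb(10, i) * math.comb(90, 10 - i) / math.comb(100, 10)
            for i in range(5, 11)
        )
        assert res["p"] == pytest.approx(direct, abs=1e-10)
        assert res["fold_enrichment"] == pytest.approx(5.0)

    def test_expected_overlap_gives_fe_one(self):
        universe = set(range(100))
        a = set(range(20))
        b = set(range(15, 25)) | set(range(80, 90))  # overlap 5 = 20*20/100...
        res = fisher_enrichment(a, b, universe)
        assert res["overlap"] == 5
        assert res["fold_enrichment"] == pytest.approx(
            5 * 100 / (len(a) * len(b))
        )

    def test_zero_overlap_p_is_one(self):
        res = fisher_enrichment(set(range(5)), set(range(10, 15)),
                                set(range(50)))
        assert res["p"] == pytest.approx(1.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(set(), {"a"}, {"a", "b"})


class TestMultisetIntersection:
    def test_two_sets_match_hypergeometric(self):
        universe = set(range(60))
        a, b = set(range(12)), set(range(6, 20))
        res = multiset_intersection_test([a, b], universe, n_mc=100, seed=1)
        k = len(a & b)
        expected = float(stats.hypergeom.sf(k - 1, 60, len(a), len(b)))
        assert res["p"] == pytest.approx(expected, abs=1e-10)

    def test_zero_observed_gives_p_one(self):
        res = multiset_intersection_test(
            [set(range(5)), set(range(10, 15))], set(range(100)), n_mc=100
        )
        assert res["p"] == 1.0

    def test_three_nested_sets_extreme(self):
        s = set(range(10))
        res = multiset_intersection_test(
            [s, s, s], set(range(1000)), n_mc=500, seed=3
        )
        assert res["observed"] == 10
        assert res["p"] <= 1 / 501 + 1e-12

    def test_small_n_mc_rejected(self):
        with pytest.raises(ValueError):
            multiset_intersection_test([{1}, {2}], {1, 2}, n_mc=10)


class TestCnaGainFraction:
    def make_segments(self, rows):
        return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "call"])

    def test_two_of_three_overlapping(self):
        segs = self.make_segments([
            ("s1", "chr1", 900, 1100, "GAIN"),
            ("s2", "chr1", 950, 1050, "AMP"),
            ("s3", "chr1", 5000, 6000, "GAIN"),
        ])
        res = cna_gain_fraction(segs, tss=1000, window=100)
        assert res["fraction"] == pytest.approx(2 / 3)

    def test_boundary_segment_counted_closed_interval(self):
        # segment ending exactly at tss - window touches the window
        segs = self.make_segments([("s1", "chr1", 500, 900, "GAIN")])
        res = cna_gain_fraction(segs, tss=1000, window=100)
        assert res["n_gain"] == 1
        # one base further out -> excluded
        segs = self.make_segments([("s1", "chr1", 500, 899, "GAIN")])
        assert cna_gain_fraction(segs, tss=1000, window=100)["n_gain"] == 0

    def test_loss_calls_ignored(self):
        segs = self.make_segments([("s1", "chr1", 900, 1100, "LOSS")])
        res = cna_gain_fraction(segs, tss=1000, window=100)
        assert res["fraction"] == 0.0


class TestCompareOverlapDistributions:
    def test_identical_samples_d_zero(self, rng):
        x = rng.normal(size=30)
        res = compare_overlap_distributions(x, x)
        assert res["D"] == 0.0

    def test_disjoint_supports_d_one(self):
        res = compare_overlap_distributions(np.arange(50), np.arange(100, 150))
        assert res["D"] == 1.0

    def test_matches_ecdf_enumeration(self, rng):
        a = rng.normal(size=200)
        b = rng.normal(loc=0.5, size=150)
        res = compare_overlap_distributions(a, b)
        grid = np.concatenate([a, b])
        d_brute = max(
            abs((a <= t).mean() - (b <= t).mean()) for t in grid
        )
        assert res["D"] == pytest.approx(d_brute, abs=1e-12)

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_overlap_distributions([1.0], [1.0, 2.0])
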