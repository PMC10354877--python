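"""Welch ANOVA, studentized range, Games-Howell, screens."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dualtcr import (
    GroupSummary,
    cluster_screen,
    games_howell,
    gene_usage_table,
    studentized_range_sf,
    tabulate_clones,
    welch_anova,
)
from dualtcr.clonotype import CloneSizeSample
from dualtcr.stats import welch_t_test


def _groups(specs):
    rng = np.random.default_rng(42)
    out = []
    for label, n, mu, sd in specs:
        out.append(GroupSummary.from_values(label, rng.normal(mu, sd, n)))
    return out


class TestWelchAnova:
    def test_identical_means_give_zero_F(self):
        groups = [
            GroupSummary("a", 10, 5.0, 2.0),
            GroupSummary("b", 12, 5.0, 3.0),
            GroupSummary("c", 9, 5.0, 1.0),
        ]
        res = welch_anova(groups)
        assert res.F == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_k2_equals_squared_welch_t(self):
        a, b = _groups([("a", 12, 0.0, 1.0), ("b", 17, 0.7, 2.5)])
        res = welch_anova([a, b])
        t, df, p = welch_t_test(a, b)
        assert res.F == pytest.approx(t**2, abs=1e-12)
        assert res.df2 == pytest.approx(df, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-12)

    def test_hand_evaluated_three_group_fixture(self):
        """Direct evaluation of the Welch formulas on fixed summaries."""
        groups = [
            GroupSummary("g1", 10, 2.0, 1.0),
            GroupSummary("g2", 12, 3.0, 4.0),
            GroupSummary("g3", 15, 2.5, 2.25),
        ]
        w = [10 / 1.0, 12 / 4.0, 15 / 2.25]
        W = sum(w)
        grand = (w[0] * 2.0 + w[1] * 3.0 + w[2] * 2.5) / W
        num = sum(wi * (m - grand) ** 2 for wi, m in zip(w, (2.0, 3.0, 2.5))) / 2
        lam = sum((1 - wi / W) ** 2 / (n - 1) for wi, n in zip(w, (10, 12, 15)))
        F_expected = num / (1 + 2 * 1 / 8 * lam)
        df2_expected = 8 / (3 * lam)
        res = welch_anova(groups)
        assert res.F == pytest.approx(F_expected, rel=1e-12)
        assert res.df2 == pytest.approx(df2_expected, rel=1e-12)

    def test_matches_pingouin_reference(self):
        """Independent library implementation agrees on raw data."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        frames = []
        for lab, n, mu, sd in (("a", 10, 0, 1), ("b", 12, 0.8, 2), ("c", 15, 0.3, 0.5)):
            frames.append(pd.DataFrame({"g": lab, "y": rng.normal(mu, sd, n)}))
        df = pd.concat(frames)
        groups = [GroupSummary.from_values(l, g["y"].to_numpy()) for l, g in df.groupby("g")]
        res = welch_anova(groups)
        ref = pg.welch_anova(dv="y", between="g", data=df)
        assert res.F == pytest.approx(float(ref["F"][0]), rel=1e-10)
        assert res.df2 == pytest.approx(float(ref["ddof2"][0]), rel=1e-10)
        assert res.p == pytest.approx(float(ref["p_unc"][0]), rel=1e-10)

    def test_balanced_equal_variance_relation_to_classical_anova(self):
        """With exactly equal sizes and sample variances, Welch's F equals
        classical F divided by its 1 + O(1/n) small-sample correction, so
        the two converge as n grows."""
        rng = np.random.default_rng(1)
        k, n = 3, 4000
        vals = []
        for m in (0.0, 0.05, 0.1):
            v = rng.normal(0, 1.0, n)
            vals.append((v - v.mean()) / v.std(ddof=1) + m)  # exact variance 1
        groups = [GroupSummary.from_values(str(i), v) for i, v in enumerate(vals)]
        res = welch_anova(groups)
        F_classic, _ = sps.f_oneway(*vals)
        lam = (k - 1) ** 2 / (k * (n - 1))
        correction = 1 + 2 * (k - 2) / (k**2 - 1) * lam
        assert res.F * correction == pytest.approx(F_classic, rel=1e-9)
        assert res.F == pytest.approx(F_classic, rel=1e-3)

    def test_zero_variance_is_error(self):
        groups = [GroupSummary("a", 5, 1.0, 0.0), GroupSummary("b", 5, 2.0, 1.0)]
        with pytest.raises(ValueError, match="variance"):
            welch_anova(groups)

    def test_single_group_is_error(self):
        with pytest.raises(ValueError):
            welch_anova([GroupSummary("a", 5, 1.0, 1.0)])


class TestStudentizedRange:
    def test_q_zero_gives_one(self):
        assert studentized_range_sf(0.0, 5, 10.0) == 1.0

    def test_k2_reduces_to_two_sided_t(self):
        for q, df in ((1.2, 7.0), (3.3, 25.0), (5.0, 4.0)):
            expected = 2.0 * sps.t.sf(q / math.sqrt(2.0), df)
            assert studentized_range_sf(q, 2, df) == pytest.approx(expected, abs=1e-9)

    def test_agrees_with_scipy_grid(self):
        for q in (0.5, 1.5, 3.0, 6.0):
            for k in (2, 3, 10, 20):
                for df in (2.0, 5.0, 60.0, 500.0):
                    mine = studentized_range_sf(q, k, df)
                    ref = sps.studentized_range.sf(q, k, df)
                    assert mine == pytest.approx(ref, abs=1e-7), (q, k, df)

    def test_monotone_in_q_and_k(self):
        qs = np.linspace(0.1, 8, 12)
        vals = [studentized_range_sf(q, 4, 15.0) for q in qs]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
        ks = [2, 3, 5, 8, 12]
        vals_k = [studentized_range_sf(3.0, k, 15.0) for k in ks]
        assert all(b >= a - 1e-12 for a, b in zip(vals_k, vals_k[1:]))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            studentized_range_sf(float("nan"), 3, 10)
        with pytest.raises(ValueError):
            studentized_range_sf(1.0, 1, 10)
        with pytest.raises(ValueError):
            studentized_range_sf(1.0, 3, 0.0)


class TestGamesHowell:
    def test_identical_groups_not_significant(self):
        a = GroupSummary("a", 10, 5.0, 2.0)
        b = GroupSummary("b", 10, 5.0, 2.0)
        (res,) = games_howell([a, b])
        assert res.mean_diff == 0.0
        assert res.p_adj == pytest.approx(1.0)
        assert res.significance_stars == "ns"

    def test_pair_order_symmetry(self):
        a, b = _groups([("a", 12, 0.0, 1.0), ("b", 15, 1.0, 2.0)])
        (res_ab,) = games_howell([a, b])
        (res_ba,) = games_howell([b, a])
        assert res_ab.p_adj == pytest.approx(res_ba.p_adj, abs=1e-12)
        assert res_ab.mean_diff == pytest.approx(-res_ba.mean_diff)

    def test_k2_reduces_to_welch_t(self):
        a, b = _groups([("a", 14, 0.0, 1.0), ("b", 11, 0.9, 2.0)])
        (res,) = games_howell([a, b])
        _, _, p = welch_t_test(a, b)
        assert res.p_adj == pytest.approx(p, abs=1e-6)

    def test_three_group_fixture_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        frames = []
        for lab, n, mu, sd in (("a", 10, 0, 1), ("b", 12, 0.8, 2), ("c", 15, 0.3, 0.5)):
            frames.append(pd.DataFrame({"g": lab, "y": rng.normal(mu, sd, n)}))
        df = pd.concat(frames)
        groups = [GroupSummary.from_values(l, g["y"].to_numpy()) for l, g in df.groupby("g")]
        mine = {frozenset(r.pair): r for r in games_howell(groups)}
        ref = pg.pairwise_gameshowell(dv="y", between="g", data=df)
        for _, row in ref.iterrows():
            r = mine[frozenset((row["A"], row["B"]))]
            assert r.p_adj == pytest.approx(row["pval"], abs=1e-6)
            assert r.df == pytest.approx(row["df"], rel=1e-9)

    @pytest.mark.parametrize(
        "p,stars", [(0.2, "ns"), (0.04, "*"), (0.009, "**"), (0.0005, "***")]
    )
    def test_star_thresholds(self, p, stars):
        from dualtcr.stats import GamesHowellResult

        r = GamesHowellResult(("a", "b"), 1.0, 1.0, 1.0, 10.0, p)
        assert r.significance_stars == stars


def _sample(label, cls, sizes):
    return CloneSizeSample(label=label, allele_class=cls, sizes=np.asarray(sizes, float))


class TestClusterScreen:
    def test_fold_one_never_flagged(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(3, 50) + 1.0
        rows = cluster_screen(
            [_sample("c1", "SINGLE", base), _sample("c1", "DUAL_BETA", base + 0.0)]
        )
        assert not any(r.flagged for r in rows)

    def test_large_fold_without_significance_not_flagged(self):
        rows = cluster_screen(
            [
                _sample("c1", "SINGLE", [1, 1, 2, 1]),
                _sample("c1", "DUAL_BETA", [1, 20]),  # huge fold, n=2, no power
            ]
        )
        (row,) = rows
        assert row.fold > 2
        assert not row.flagged

    def test_undersized_cluster_reported_untestable(self):
        rows = cluster_screen(
            [_sample("c1", "SINGLE", [1, 2, 1]), _sample("c1", "DUAL_ALPHA", [4])]
        )
        (row,) = rows
        assert not row.testable and not row.flagged

    def test_expanded_cluster_flagged(self):
        rng = np.random.default_rng(1)
        single = rng.geometric(1 / 1.5, 300).astype(float)
        dual = rng.geometric(1 / 5.0, 80).astype(float)
        rows = cluster_screen(
            [
                _sample("Trm", "SINGLE", single),
                _sample("Trm", "DUAL_BETA", dual),
                _sample("naive", "SINGLE", single),
                _sample("naive", "DUAL_BETA", rng.geometric(1 / 1.5, 80).astype(float)),
            ]
        )
        by = {(r.cluster, r.dual_class): r for r in rows}
        assert by[("Trm", "DUAL_BETA")].flagged
        assert not by[("naive", "DUAL_BETA")].flagged


class TestGeneUsage:
    def test_columns_sum_to_one_and_dual_counts_both_genes(self):
        from dualtcr import CellChainProfile, ChainDescriptor

        def chain(locus, v, cdr3):
            j = "TRAJ1" if locus == "TRA" else "TRBJ1-1"
            return ChainDescriptor(locus, v, j, cdr3, umis=5)

        cells = [
            CellChainProfile("a", (chain("TRA", "TRAV1", "AAA"),), (chain("TRB", "TRBV1", "CCC"),)),
            CellChainProfile("b", (chain("TRA", "TRAV2", "GGG"),), (chain("TRB", "TRBV1", "TTT"),)),
            CellChainProfile(
                "c",
                (chain("TRA", "TRAV1", "ACA"),),
                (chain("TRB", "TRBV2", "CAC"), chain("TRB", "TRBV21-1", "GAG")),
            ),
        ]
        table = tabulate_clones(cells)
        usage = gene_usage_table(table, "TRB")
        value_cols = [c for c in ("SINGLE", "DUAL_BETA") if c in usage.columns]
        for col in value_cols:
            assert usage[col].sum() == pytest.approx(1.0)
        # the dual-beta clone contributes both its beta V genes
        assert usage.loc["TRBV2", "DUAL_BETA"] == pytest.approx(0.5)
        assert usage.loc["TRBV21-1", "DUAL_BETA"] == pytest.approx(0.5)
        assert bool(usage.loc["TRBV21-1", "pseudogene"]) is True

    def test_bad_locus_rejected(self, small_profiles):
        table = tabulate_clones(small_profiles)
        with pytest.raises(ValueError):
            gene_usage_table(table, "IGH")
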