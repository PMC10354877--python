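"""Clonotype keys, clone tables, and clone-size samples."""

import numpy as np
import pytest

from dualtcr import (
    AlleleClass,
    CellChainProfile,
    ChainDescriptor,
    clone_counts_by_stratum,
    clone_key,
    clone_size_samples,
    tabulate_clones,
)


def _chain(locus, v, cdr3, umis=5):
    j = "TRAJ1" if locus == "TRA" else "TRBJ1-1"
    return ChainDescriptor(locus, v, j, cdr3, umis=umis)


def _cell(barcode, alphas, betas, **meta):
    alphas = tuple(sorted(alphas, key=lambda c: (-c.umis, c.cdr3_nt)))
    betas = tuple(sorted(betas, key=lambda c: (-c.umis, c.cdr3_nt)))
    return CellChainProfile(barcode, alphas, betas, metadata=meta)


A1 = _chain("TRA", "TRAV1", "AAA", 9)
A2 = _chain("TRA", "TRAV2", "GGG", 3)
B1 = _chain("TRB", "TRBV1", "CCC", 8)
B2 = _chain("TRB", "TRBV2", "TTT", 2)


class TestCloneKey:
    def test_chain_order_does_not_matter(self):
        c1 = _cell("x", [A1, A2], [B1])
        c2 = _cell("y", [A2, A1], [B1])
        assert clone_key(c1) == clone_key(c2)

    def test_umis_do_not_enter_key(self):
        hot = _cell("x", [_chain("TRA", "TRAV1", "AAA", 99)], [B1])
        cold = _cell("y", [_chain("TRA", "TRAV1", "AAA", 1)], [B1])
        assert clone_key(hot) == clone_key(cold)

    def test_dual_and_single_never_share_key(self):
        dual = _cell("x", [A1, A2], [B1])
        single = _cell("y", [A1], [B1])
        assert clone_key(dual) != clone_key(single)

    def test_excluded_cells_have_no_key(self):
        multi = _cell("x", [A1, A2], [B1, B2])
        with pytest.raises(ValueError, match="excluded"):
            clone_key(multi)
        assert clone_key(multi, allow_excluded=True)

    def test_drop_secondary_keeps_top_chain_only(self):
        dual = _cell("x", [A1, A2], [B1])
        single = _cell("y", [A1], [B1])
        assert clone_key(dual, drop_secondary=True) == clone_key(single)

    def test_six_cell_fixture_forms_four_clones(self):
        cells = [
            _cell("c1", [A1], [B1]),
            _cell("c2", [A1], [B1]),
            _cell("c3", [A1, A2], [B1]),
            _cell("c4", [A2, A1], [B1]),
            _cell("c5", [A1], [B2]),
            _cell("c6", [A2], [B2]),
        ]
        assert len({clone_key(c) for c in cells}) == 4


class TestTabulate:
    def test_two_clones_sizes_six_and_four(self):
        cells = [_cell(f"s{i}", [A1], [B1]) for i in range(6)]
        cells += [_cell(f"d{i}", [A1, A2], [B1]) for i in range(4)]
        table = tabulate_clones(cells)
        assert sorted(table.df["n_cells"]) == [4, 6]
        assert table.n_cells == 10

    def test_excluded_and_incomplete_left_out(self):
        cells = [
            _cell("ok", [A1], [B1]),
            _cell("multi", [A1, A2], [B1, B2]),
            _cell("incomplete", [A1], []),
        ]
        table = tabulate_clones(cells)
        assert table.n_cells == 1

    def test_tissue_counts_sum_to_total(self, small_profiles):
        table = tabulate_clones(small_profiles)
        tissue_sum = table.df[["n_P", "n_N", "n_T"]].sum(axis=1)
        assert (tissue_sum == table.df["n_cells"]).all()

    def test_unique_clones_not_more_than_cells(self, small_profiles):
        table = tabulate_clones(small_profiles)
        assert table.n_clones <= table.n_cells


class TestCountsByStratum:
    def test_spanning_clone_counted_in_each_tissue(self):
        cells = [
            _cell("a", [A1], [B1], tissue="P"),
            _cell("b", [A1], [B1], tissue="P"),  # clone A: P only
            _cell("c", [A2], [B1], tissue="P"),
            _cell("d", [A2], [B1], tissue="T"),  # clone B: P and T
            _cell("e", [A1], [B2], tissue="T"),  # clone C: T only
        ]
        counts = clone_counts_by_stratum(tabulate_clones(cells))
        assert counts.loc["SINGLE", "P"] == 2
        assert counts.loc["SINGLE", "T"] == 2
        assert counts.loc["SINGLE", "N"] == 0

    def test_simulator_truth_exact_recovery(self, small_sim, small_profiles):
        """Non-doublet cells regroup into exactly the generator's clones."""
        table, truth = small_sim
        clones = tabulate_clones(small_profiles)
        clean = truth.df[~truth.df["is_doublet"]]
        assert clones.n_cells == len(clean)
        assert clones.n_clones == clean["clone_id"].nunique()
        # per-clone sizes match the truth's clone sizes as a multiset
        assert sorted(clones.df["n_cells"]) == sorted(
            clean.groupby("clone_id").size().tolist()
        )


class TestCloneSizeSamples:
    def test_within_stratum_sizes(self):
        cells = [_cell(f"p{i}", [A1], [B1], tissue="P") for i in range(3)]
        cells += [_cell(f"t{i}", [A1], [B1], tissue="T") for i in range(2)]
        table = tabulate_clones(cells)
        samples = {
            (s.label, s.allele_class): s
            for s in clone_size_samples(table, [("tissue", "P"), ("tissue", "T")])
        }
        assert samples[("tissue:P", "SINGLE")].sizes.tolist() == [3.0]
        assert samples[("tissue:T", "SINGLE")].sizes.tolist() == [2.0]

    def test_all_singletons_mean_one(self):
        cells = [_cell(f"x{i}", [_chain("TRA", "TRAV1", f"A{i}")], [B1], tissue="P") for i in range(5)]
        table = tabulate_clones(cells)
        (sample,) = [
            s for s in clone_size_samples(table, [("tissue", "P")]) if s.allele_class == "SINGLE"
        ]
        assert sample.mean == 1.0

    def test_undersized_stratum_flagged_untestable(self):
        cells = [_cell("x", [A1], [B1], tissue="P")]
        table = tabulate_clones(cells)
        (sample,) = [
            s for s in clone_size_samples(table, [("tissue", "P")]) if s.allele_class == "SINGLE"
        ]
        assert not sample.testable

    def test_merged_tissue_equals_sum_of_parts(self, small_profiles):
        """Mean size in merged N+T is reproducible from unmerged tables."""
        table = tabulate_clones(small_profiles)
        merged = clone_size_samples(table, [("tissue", ("N", "T"))])
        for s in merged:
            cls = s.allele_class
            sub = table.df[table.df["allele_class"] == cls]
            manual = (sub["n_N"] + sub["n_T"])
            manual = manual[manual > 0]
            assert np.isclose(s.mean, manual.mean())
            assert s.n == len(manual)

    def test_mean_times_count_equals_cells(self, small_profiles):
        table = tabulate_clones(small_profiles)
        for s in clone_size_samples(table, [("tissue", "P"), ("tissue", "N"), ("tissue", "T")]):
            sub = table.df[table.df["allele_class"] == s.allele_class]
            tissue = s.label.split(":")[1]
            assert s.mean * s.n == pytest.approx(sub[f"n_{tissue}"].sum())


class TestDropSecondaryMerging:
    def test_forced_merge_with_single_clone(self):
        cells = [
            _cell("s1", [A1], [B1]),
            _cell("d1", [A1, A2], [B1]),
            _cell("d2", [A1, A2], [B1]),
        ]
        full = tabulate_clones(cells)
        dropped = tabulate_clones(cells, drop_secondary=True)
        assert full.n_clones == 2
        assert dropped.n_clones == 1
        assert dropped.df["n_cells"].iloc[0] == 3

    def test_unique_clone_count_never_increases(self, small_profiles):
        full = tabulate_clones(small_profiles)
        dropped = tabulate_clones(small_profiles, drop_secondary=True)
        assert dropped.n_clones <= full.n_clones
        assert dropped.n_cells == full.n_cells
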