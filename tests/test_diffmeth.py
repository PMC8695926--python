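import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

import methvar as mv
from methvar.diffmeth import DmrRegion, dmrs_to_bed

from conftest import make_sites


def enumeration_pvalue(x, y):
    """Brute-force two-sided exact Wilcoxon p over all rank labelings."""
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    w_obs = ranks[: len(x)].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, len(x))]
    sums = np.asarray(sums)
    lower = np.mean(sums <= w_obs + 1e-9)
    upper = np.mean(sums >= w_obs - 1e-9)
    return min(1.0, 2 * min(lower, upper))


class TestWilcoxon:
    def test_fully_separated_small_groups(self):
        res = mv.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.statistic == 6.0
        assert res.p_value == pytest.approx(0.1, abs=1e-12)  # 2/C(6,3)
        assert res.method == "exact"

    def test_identical_multisets_give_p_one(self):
        res = mv.wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(101)
        for _ in range(60):
            n_x, n_y = rng.integers(2, 9, size=2)
            x = rng.normal(size=n_x)
            y = rng.normal(size=n_y)
            res = mv.wilcoxon_rank_sum(x, y)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(enumeration_pvalue(x, y), abs=1e-12)

    def test_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        y = rng.normal(0.8, size=25)
        res = mv.wilcoxon_rank_sum(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.method == "normal"
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_all_identical_values_degenerate(self):
        res = mv.wilcoxon_rank_sum([1.0] * 25, [1.0] * 25)
        assert res.p_value == 1.0 and res.degenerate

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mv.wilcoxon_rank_sum([], [1.0])


class TestKruskalWallis:
    def test_hand_computed_h(self):
        res = mv.kruskal_wallis([(1, 2, 3), (4, 5, 6), (7, 8, 9)])
        assert res.statistic == pytest.approx(7.2, abs=1e-12)
        assert res.p_value == pytest.approx(scipy.stats.chi2.sf(7.2, 2), abs=1e-12)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(3)
        groups = [rng.integers(0, 5, size=12).astype(float) for _ in range(4)]
        res = mv.kruskal_wallis(groups)
        ref = scipy.stats.kruskal(*groups)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_two_groups_equals_squared_z_wilcoxon(self):
        """Algebraic identity: KW with k=2 is the squared tie-corrected
        normal Wilcoxon statistic (no continuity correction)."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.integers(0, 8, size=rng.integers(3, 12)).astype(float)
            y = rng.integers(0, 8, size=rng.integers(3, 12)).astype(float)
            if np.unique(np.concatenate([x, y])).size == 1:
                continue
            kw = mv.kruskal_wallis([x, y])
            w = mv.wilcoxon_rank_sum(x, y, exact_limit=0, continuity=False)
            assert kw.p_value == pytest.approx(w.p_value, abs=1e-9)

    def test_group_order_invariance(self):
        groups = [(1.0, 4.0), (2.0, 5.0), (3.0, 6.0)]
        a = mv.kruskal_wallis(groups)
        b = mv.kruskal_wallis(groups[::-1])
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_all_identical_values_degenerate(self):
        res = mv.kruskal_wallis([(1.0, 1.0), (1.0, 1.0)])
        assert res.p_value == 1.0 and res.degenerate

    def test_insufficient_groups_rejected(self):
        with pytest.raises(ValueError):
            mv.kruskal_wallis([(1.0, 2.0)])


def brute_force_bh(p):
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, i in enumerate(order):
        candidates = [
            p[j] * m / (pos + 1)
            for pos, j in enumerate(order)
            if pos >= rank_pos
        ]
        q[i] = min(1.0, min(candidates))
    return q


class TestBenjaminiHochberg:
    def test_equally_spaced_pvalues_all_collapse(self):
        q = mv.benjamini_hochberg([0.01, 0.02, 0.03, 0.04, 0.05])
        assert np.allclose(q, 0.05)

    def test_single_pvalue_unchanged(self):
        assert mv.benjamini_hochberg([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        assert np.allclose(mv.benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mv.benjamini_hochberg([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_q_dominates_p_and_matches_brute_force(self, p):
        q = mv.benjamini_hochberg(p)
        assert (q >= np.asarray(p) - 1e-12).all()
        assert np.allclose(q, brute_force_bh(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30), st.integers(0, 10**6))
    def test_order_invariance(self, p, seed):
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(p))
        q = mv.benjamini_hochberg(p)
        q_perm = mv.benjamini_hochberg(list(np.asarray(p)[perm]))
        assert np.allclose(q[perm], q_perm, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    def test_sorting_p_sorts_q(self, p):
        q = mv.benjamini_hochberg(sorted(p))
        assert (np.diff(q) >= -1e-12).all()


class TestDifferentialGenes:
    @staticmethod
    def labeled_matrix(rows, groups):
        df = pd.DataFrame(rows).T
        df.index.name = "gene_id"
        df.columns = [f"s{i}" for i in range(df.shape[1])]
        labels = pd.Series(groups, index=df.columns)
        return mv.MethylationMatrix(df, pd.Series(5, index=df.index)), labels

    def test_single_gene_q_equals_p(self):
        m, labels = self.labeled_matrix(
            {"g": [0.1, 0.2, 0.15, 0.7, 0.8, 0.75]}, ["a"] * 3 + ["b"] * 3
        )
        res, skipped = mv.differential_genes(m, labels, test="wilcoxon", alpha=0.05)
        assert not skipped
        assert res.loc[0, "q_value"] == pytest.approx(res.loc[0, "p_value"])
        assert res.loc[0, "p_value"] == pytest.approx(0.1, abs=1e-12)

    def test_low_count_genes_skipped_and_excluded_from_m(self):
        m, labels = self.labeled_matrix(
            {
                "ok": [0.1, 0.2, 0.7, 0.8],
                "sparse": [0.1, np.nan, 0.7, np.nan],
            },
            ["a", "a", "b", "b"],
        )
        res, skipped = mv.differential_genes(m, labels, test="wilcoxon")
        assert skipped == ["sparse"]
        assert list(res["gene_id"]) == ["ok"]

    def test_group_means_reported(self):
        m, labels = self.labeled_matrix(
            {"g": [0.1, 0.3, 0.6, 0.8]}, ["a", "a", "b", "b"]
        )
        res, _ = mv.differential_genes(m, labels, test="wilcoxon")
        assert res.loc[0, "mean_a"] == pytest.approx(0.2)
        assert res.loc[0, "mean_b"] == pytest.approx(0.7)

    def test_wilcoxon_needs_exactly_two_groups(self):
        m, labels = self.labeled_matrix(
            {"g": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]}, ["a", "a", "b", "b", "c", "c"]
        )
        with pytest.raises(ValueError, match="exactly 2"):
            mv.differential_genes(m, labels, test="wilcoxon")

    def test_unknown_test_rejected(self):
        m, labels = self.labeled_matrix({"g": [0.1, 0.2, 0.7, 0.8]}, ["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="unknown test"):
            mv.differential_genes(m, labels, test="anova")

    def test_alpha_one_flags_every_tested_gene(self, small_matrix, small_dataset):
        labels = small_dataset.samples.set_index("sample_id")["tissue"]
        res, _ = mv.differential_genes(small_matrix, labels, test="wilcoxon", alpha=1.0)
        assert res["significant"].all()


class TestOverlapGenes:
    def test_plain_set_arithmetic(self):
        inter, a_only, b_only = mv.overlap_genes({"A", "B", "C"}, {"B", "C", "D"})
        assert inter == {"B", "C"} and a_only == 1 and b_only == 1

    def test_disjoint_and_identical(self):
        assert mv.overlap_genes({"A"}, {"B"})[0] == set()
        inter, a_only, b_only = mv.overlap_genes({"A", "B"}, {"A", "B"})
        assert inter == {"A", "B"} and a_only == 0 and b_only == 0


class TestPerCpGProfile:
    @staticmethod
    def fixture_tables():
        def t(ratios):
            return make_sites(
                [("s1", 10 * (i + 1), "+", "CpG", int(r * 10), 10) for i, r in enumerate(ratios)]
            )

        return {
            "a1": t([0.0, 0.2, 0.4]),
            "a2": t([0.2, 0.4, 0.6]),
            "b1": t([1.0, 0.8, 0.6]),
        }

    GENE = mv.GeneModel("g", "s1", 1, 100)

    def test_track_equals_hand_computed_group_means(self):
        labels = {"a1": "A", "a2": "A", "b1": "B"}
        track = mv.per_cpg_profile(self.GENE, self.fixture_tables(), labels)
        assert np.allclose(track["A"], [0.1, 0.3, 0.5])
        assert np.allclose(track["B"], [1.0, 0.8, 0.6])

    def test_single_group_is_per_cpg_mean(self):
        labels = {"a1": "A", "a2": "A", "b1": "A"}
        track = mv.per_cpg_profile(self.GENE, self.fixture_tables(), labels)
        assert np.allclose(track["A"], [0.4, 0.4666666667, 0.5333333333])

    def test_no_qualifying_sites_rejected(self):
        labels = {"a1": "A", "a2": "A", "b1": "B"}
        gene = mv.GeneModel("g", "s1", 1000, 2000)
        with pytest.raises(ValueError, match="no qualifying"):
            mv.per_cpg_profile(gene, self.fixture_tables(), labels)


class TestScanDmrs:
    @staticmethod
    def tracks(deltas):
        pos = [10 * (i + 1) for i in range(len(deltas))]
        return pd.DataFrame({"A": 0.5, "B": [0.5 + d for d in deltas]}, index=pos)

    def test_single_block_detected(self):
        deltas = [0.0] * 3 + [0.3] * 6 + [0.0] * 3
        regions = mv.scan_dmrs(self.tracks(deltas))
        assert len(regions) == 1
        r = regions[0]
        assert r.n_cpgs == 6
        assert (r.start, r.end) == (40, 90)
        assert r.mean_abs_difference == pytest.approx(0.3)

    def test_no_signal_no_regions(self):
        assert mv.scan_dmrs(self.tracks([0.05] * 10)) == []

    def test_two_runs_split_by_long_gap(self):
        deltas = [0.3] * 5 + [0.0] * 3 + [0.3] * 5
        regions = mv.scan_dmrs(self.tracks(deltas), max_gap=2)
        assert len(regions) == 2
        merged = mv.scan_dmrs(self.tracks(deltas), max_gap=3)
        assert len(merged) == 1 and merged[0].n_cpgs == 10

    def test_short_runs_discarded(self):
        deltas = [0.3] * 4 + [0.0] * 6
        assert mv.scan_dmrs(self.tracks(deltas), min_sites=5) == []

    def test_regions_never_overlap(self):
        rng = np.random.default_rng(2)
        deltas = rng.choice([0.0, 0.3], size=60)
        regions = mv.scan_dmrs(self.tracks(list(deltas)), min_sites=2)
        for r1, r2 in zip(regions, regions[1:]):
            assert r1.end < r2.start

    def test_orientation_reversal_mirrors_regions(self):
        deltas = [0.0] * 2 + [0.3] * 7 + [0.0] * 4 + [0.3] * 6
        tr = self.tracks(deltas)
        fwd = mv.scan_dmrs(tr)
        rev = tr.iloc[::-1]
        rev.index = tr.index  # same positions, reversed CpG order
        mirrored = mv.scan_dmrs(rev)
        n = len(deltas)
        expected = sorted(
            (tr.index[n - 1 - tr.index.get_loc(r.end)], tr.index[n - 1 - tr.index.get_loc(r.start)])
            for r in fwd
        )
        assert sorted((r.start, r.end) for r in mirrored) == expected

    def test_misaligned_tracks_rejected(self):
        a = pd.Series([0.5, 0.5], index=[10, 20])
        b = pd.Series([0.8, 0.8], index=[10, 30])
        with pytest.raises(ValueError, match="aligned"):
            mv.scan_dmrs({"A": a, "B": b})

    def test_bed_output_is_half_open(self, tmp_path):
        regions = [DmrRegion("s1", 40, 90, 6, 0.3, ("A", "B"))]
        path = tmp_path / "dmrs.bed"
        dmrs_to_bed(regions, path)
        assert path.read_text().split("\t")[:3] == ["s1", "39", "90"]


class TestAmpliconConcordance:
    def test_identical_tracks(self):
        t = pd.Series([0.1, 0.5, 0.9, 0.3], index=[10, 20, 30, 40])
        res = mv.amplicon_concordance(t, t.copy())
        assert res.pearson_r == pytest.approx(1.0)
        assert res.mean_abs_diff == pytest.approx(0.0)
        assert res.n_shared_cpgs == 4

    def test_constant_offset(self):
        t = pd.Series([0.1, 0.5, 0.8], index=[10, 20, 30])
        res = mv.amplicon_concordance(t, t + 0.1)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.mean_abs_diff == pytest.approx(0.1)

    def test_anticorrelated_tracks(self):
        t = pd.Series([0.1, 0.5, 0.9], index=[10, 20, 30])
        res = mv.amplicon_concordance(t, 1 - t)
        assert res.pearson_r == pytest.approx(-1.0)

    def test_only_shared_positions_used(self):
        a = pd.Series([0.1, 0.5, 0.9, 0.2], index=[10, 20, 30, 40])
        b = pd.Series([0.1, 0.5, 0.9, 0.7], index=[10, 20, 30, 99])
        res = mv.amplicon_concordance(a, b)
        assert res.n_shared_cpgs == 3
        assert res.mean_abs_diff == pytest.approx(0.0)

    def test_too_few_shared_positions_rejected(self):
        a = pd.Series([0.1, 0.5], index=[10, 20])
        with pytest.raises(ValueError, match="shared"):
            mv.amplicon_concordance(a, a)
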