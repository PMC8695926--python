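import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from scipy.spatial import procrustes

import methvar as mv


def matrix_of(array, prefix="s"):
    """Gene x sample matrix from a plain array (genes rows)."""
    array = np.asarray(array, dtype=float)
    df = pd.DataFrame(
        array,
        index=pd.Index([f"g{i}" for i in range(array.shape[0])], name="gene_id"),
        columns=[f"{prefix}{j}" for j in range(array.shape[1])],
    )
    return mv.MethylationMatrix(df, pd.Series(5, index=df.index))


def random_matrix(rng, n_genes=30, n_samples=10):
    return matrix_of(rng.uniform(0.05, 0.95, size=(n_genes, n_samples)))


class TestPcaEmbed:
    def test_duplicated_samples_are_coincident(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.2, 0.8, size=(20, 4))
        m = matrix_of(np.hstack([base, base[:, [0]]]))
        emb = mv.pca_embed(m, k=2)
        assert np.allclose(emb.coordinates[0], emb.coordinates[4], atol=1e-10)

    def test_two_shifted_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0.3, 0.5, size=(40, 12))
        base[:20, 6:] += 0.3  # half the genes shifted in half the samples
        emb = mv.pca_embed(matrix_of(base), k=2)
        labels = pd.Series(["a"] * 6 + ["b"] * 6, index=emb.sample_ids)
        pc1 = emb.coordinates[:, 0]
        assert (pc1[:6].mean() - pc1[6:].mean()) ** 2 > (pc1.var() / 2)

    def test_variance_explained_is_valid_and_ordered(self):
        emb = mv.pca_embed(random_matrix(np.random.default_rng(2)), k=3)
        ve = emb.variance_explained
        assert ve.sum() <= 1 + 1e-9
        assert (np.diff(ve) <= 1e-12).all()
        assert ((0 <= ve) & (ve <= 1)).all()

    def test_gene_order_and_row_shift_invariance(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng)
        emb = mv.pca_embed(m, k=2)
        perm = m.values.sample(frac=1.0, random_state=5)
        emb_perm = mv.pca_embed(mv.MethylationMatrix(perm, m.n_cpgs_used), k=2)
        # centering removes any constant added to a gene row
        shifted = m.values.copy()
        shifted.iloc[0] = shifted.iloc[0] - 0.03
        emb_shift = mv.pca_embed(mv.MethylationMatrix(shifted, m.n_cpgs_used), k=2)
        for other in (emb_perm,):
            for axis in range(2):
                dot = np.dot(emb.coordinates[:, axis], other.coordinates[:, axis])
                assert np.allclose(
                    emb.coordinates[:, axis] * np.sign(dot),
                    other.coordinates[:, axis],
                    atol=1e-8,
                )
        _, _, disparity = procrustes(emb.coordinates, emb_shift.coordinates)
        assert disparity < 1e-3

    def test_genes_with_missing_values_dropped(self):
        rng = np.random.default_rng(4)
        m = random_matrix(rng)
        values = m.values.copy()
        values.iloc[0, 0] = np.nan
        emb = mv.pca_embed(mv.MethylationMatrix(values, m.n_cpgs_used), k=2)
        ref = mv.pca_embed(
            mv.MethylationMatrix(m.values.iloc[1:], m.n_cpgs_used.iloc[1:]), k=2
        )
        assert np.allclose(np.abs(emb.coordinates), np.abs(ref.coordinates), atol=1e-8)

    def test_k_beyond_rank_rejected(self):
        m = matrix_of(np.tile([[0.2], [0.4], [0.6]], (1, 4)))  # rank 0 after centering
        with pytest.raises(ValueError, match="rank"):
            mv.pca_embed(m, k=2)


class TestMdsEmbed:
    def test_equilateral_configuration_for_equidistant_samples(self):
        # three samples pairwise equidistant -> equilateral triangle
        x = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float) * 0.5
        emb = mv.mds_embed(matrix_of(x.T), k=2)
        d = scipy.spatial.distance.pdist(emb.coordinates)
        assert np.allclose(d, d[0], atol=1e-8)

    def test_identical_samples_coincide(self):
        m = matrix_of(np.tile(np.random.default_rng(0).uniform(size=(10, 1)), (1, 4)))
        emb = mv.mds_embed(m, k=1)
        assert np.allclose(emb.coordinates, emb.coordinates[0], atol=1e-8)

    def test_full_dimensional_embedding_reproduces_distances(self):
        rng = np.random.default_rng(6)
        m = random_matrix(rng, n_genes=20, n_samples=7)
        emb = mv.mds_embed(m, k=6)
        d_in = scipy.spatial.distance.pdist(m.values.to_numpy().T)
        d_out = scipy.spatial.distance.pdist(emb.coordinates)
        assert np.allclose(d_in, d_out, atol=1e-8)

    def test_matches_pca_configuration(self):
        rng = np.random.default_rng(7)
        m = random_matrix(rng)
        pca = mv.pca_embed(m, k=2)
        mds = mv.mds_embed(m, k=2)
        _, _, disparity = procrustes(pca.coordinates, mds.coordinates)
        assert disparity < 1e-10

    def test_matches_skbio_pcoa(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.ordination import pcoa

        rng = np.random.default_rng(8)
        m = random_matrix(rng, n_genes=15, n_samples=6)
        d = scipy.spatial.distance.squareform(
            scipy.spatial.distance.pdist(m.values.to_numpy().T)
        )
        ref = pcoa(DistanceMatrix(d, ids=m.sample_ids), method="eigh")
        mine = mv.mds_embed(m, k=2)
        _, _, disparity = procrustes(
            ref.samples.to_numpy()[:, :2], mine.coordinates
        )
        assert disparity < 1e-9


class TestSeparationScore:
    def test_tight_far_clusters_score_high(self):
        rng = np.random.default_rng(9)
        coords = np.vstack(
            [rng.normal(0, 0.01, size=(10, 2)), rng.normal(5, 0.01, size=(10, 2))]
        )
        emb = mv.Embedding([f"s{i}" for i in range(20)], coords, None, "pca")
        labels = {f"s{i}": ("a" if i < 10 else "b") for i in range(20)}
        assert mv.separation_score(emb, labels) > 0.9

    def test_random_labels_on_one_cloud_score_near_zero(self):
        scores = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            coords = rng.normal(size=(30, 2))
            emb = mv.Embedding([f"s{i}" for i in range(30)], coords, None, "pca")
            labels = {f"s{i}": ("a" if rng.random() < 0.5 else "b") for i in range(30)}
            if len(set(labels.values())) < 2:
                continue
            scores.append(mv.separation_score(emb, labels))
        assert max(abs(s) for s in scores) < 0.15

    def test_single_group_rejected(self):
        emb = mv.Embedding(["s0", "s1"], np.zeros((2, 2)), None, "pca")
        with pytest.raises(ValueError):
            mv.separation_score(emb, {"s0": "a", "s1": "a"})


class TestChisqEnrichment:
    def test_hand_computed_table(self):
        res = mv.chisq_enrichment(10, 90, 20, 80)
        assert res.chi2 == pytest.approx(3.9216, abs=5e-5)
        assert res.fold_enrichment == pytest.approx(0.5)

    def test_equal_proportions_give_zero(self):
        res = mv.chisq_enrichment(10, 90, 20, 180)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.fold_enrichment == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_transposition_symmetry(self):
        a = mv.chisq_enrichment(7, 13, 21, 59)
        b = mv.chisq_enrichment(7, 21, 13, 59)
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            mv.chisq_enrichment(0, 0, 5, 5)

    def test_exhaustive_small_tables_match_scipy(self):
        for a, b, c, d in itertools.product(range(0, 7), repeat=4):
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            mine = mv.chisq_enrichment(a, b, c, d)
            ref = scipy.stats.chi2_contingency([[a, b], [c, d]], correction=False)
            assert mine.chi2 == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)


class TestWelchT:
    def test_identical_groups(self):
        res = mv.welch_t_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_large_standardized_difference(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1e-6, size=4)
        b = 1 + rng.normal(0, 1e-6, size=4)
        assert mv.welch_t_compare(a, b).p_value < 1e-6

    def test_zero_variance_equal_means_degenerate(self):
        res = mv.welch_t_compare([1.0, 1.0], [1.0, 1.0])
        assert res.p_value == 1.0 and res.degenerate

    def test_matches_scipy_on_random_fixtures(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            a = rng.normal(size=rng.integers(3, 15))
            b = rng.normal(0.4, 1.7, size=rng.integers(3, 15))
            mine = mv.welch_t_compare(a, b)
            ref = scipy.stats.ttest_ind(a, b, equal_var=False)
            assert mine.t == pytest.approx(ref.statistic, rel=1e-10)
            assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-10)
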