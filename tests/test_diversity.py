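"""Alpha/beta diversity closed forms, ordination, aggregation, screens."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dustbiome import (
    aggregate_taxa,
    alpha_diversity,
    bray_curtis,
    chao1,
    correlation_screen,
    pcoa,
    shannon,
)
from dustbiome.datatypes import CovariateTable, OtuTable
from dustbiome.diversity import DissimilarityMatrix


def _table(counts, taxonomy=None):
    counts = np.atleast_2d(np.asarray(counts))
    return OtuTable(
        otu_ids=[f"O{i}" for i in range(counts.shape[0])],
        sample_ids=[f"S{j}" for j in range(counts.shape[1])],
        counts=counts,
        taxonomy=taxonomy,
    )


class TestChao1:
    def test_no_singletons_equals_observed(self):
        assert chao1([5, 3, 2, 7]) == 4.0

    def test_classic_branch_hand_value(self):
        # S_obs=5, F1=2, F2=1 -> 5 + 4/2 = 7
        assert chao1([1, 1, 2, 5, 9]) == 7.0

    def test_bias_corrected_branch_hand_value(self):
        # S_obs=3, F1=2, F2=0 -> 3 + 2*1/2 = 4
        assert chao1([1, 1, 5]) == 4.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            chao1([0, 0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 50), min_size=1, max_size=60).filter(
        lambda x: sum(x) > 0))
    def test_never_below_observed_richness(self, counts):
        assert chao1(counts) >= np.sum(np.asarray(counts) > 0)


class TestShannon:
    def test_uniform_is_log_richness(self):
        assert shannon([3] * 10) == pytest.approx(np.log(10), abs=1e-12)

    def test_single_otu_zero(self):
        assert shannon([42]) == 0.0

    def test_hand_value(self):
        assert shannon([2, 1, 1]) == pytest.approx(1.039721, abs=1e-6)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 30), min_size=2, max_size=40).filter(
        lambda x: sum(x) > 0))
    def test_uniform_maximizes_entropy(self, counts):
        s_obs = int(np.sum(np.asarray(counts) > 0))
        assert shannon(counts) <= np.log(s_obs) + 1e-12 if s_obs else True


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        d = bray_curtis(_table([[4, 4], [2, 2]]))
        assert d.matrix[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        d = bray_curtis(_table([[5, 0], [0, 3]]))
        assert d.matrix[0, 1] == 1.0

    def test_hand_value(self):
        d = bray_curtis(_table([[6, 2], [2, 2]]))
        assert d.matrix[0, 1] == pytest.approx(1.0 / 3.0, abs=1e-6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounds_symmetry_identity_reorder(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 40, (12, 5))
        counts[:, 0] += 1  # keep every sample non-empty
        counts[0, :] += 1
        d = bray_curtis(_table(counts))
        M = d.matrix
        assert np.all((M >= 0) & (M <= 1))
        np.testing.assert_allclose(M, M.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(M), 0.0, atol=1e-12)
        perm = rng.permutation(5)
        d2 = bray_curtis(_table(counts[:, perm]))
        np.testing.assert_allclose(d2.matrix, M[np.ix_(perm, perm)], atol=1e-12)


class TestPcoa:
    def _euclidean_dm(self, pts):
        from scipy.spatial.distance import pdist, squareform

        return DissimilarityMatrix(
            [f"S{i}" for i in range(len(pts))], squareform(pdist(pts))
        )

    def test_recovers_planar_configuration(self, rng):
        """Procrustes oracle: PCoA of Euclidean distances re-embeds the points."""
        from scipy.spatial import procrustes

        pts = rng.normal(size=(10, 2))
        ord_ = pcoa(self._euclidean_dm(pts), n_axes=2)
        _, _, disparity = procrustes(pts, ord_.coordinates)
        assert disparity < 1e-8

    def test_equilateral_triangle_equal_eigenvalues(self):
        D = np.ones((3, 3)) - np.eye(3)
        ord_ = pcoa(DissimilarityMatrix(["a", "b", "c"], D), n_axes=2)
        assert ord_.eigenvalues[0] == pytest.approx(ord_.eigenvalues[1], rel=1e-9)

    def test_collinear_points_one_axis(self, rng):
        pts = np.column_stack([np.linspace(0, 1, 6), np.zeros(6)])
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            ord_ = pcoa(self._euclidean_dm(pts), n_axes=3)
        assert ord_.pct_explained[0] == pytest.approx(100.0, abs=1e-6)

    def test_matches_skbio_on_random_matrix(self, rng):
        """Independent cross-check against scikit-bio's implementation."""
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.ordination import pcoa as skbio_pcoa

        counts = rng.integers(1, 50, (30, 8))
        d = bray_curtis(_table(counts))
        ours = pcoa(d, n_axes=3)
        theirs = skbio_pcoa(SkbioDM(d.matrix, d.sample_ids), number_of_dimensions=3)
        for k in range(3):
            a = ours.coordinates[:, k]
            b = theirs.samples.iloc[:, k].to_numpy()
            assert abs(abs(np.corrcoef(a, b)[0, 1]) - 1.0) < 1e-8

    def test_euclidean_embeddable_no_negative_eigenvalues(self, rng):
        pts = rng.normal(size=(9, 4))
        ord_ = pcoa(self._euclidean_dm(pts), n_axes=3)
        assert ord_.eigenvalues.min() > -1e-9


class TestAggregateTaxa:
    def test_single_phylum(self):
        tax = ["k__B;p__Proteobacteria"] * 3
        out = aggregate_taxa(_table([[3, 1], [2, 2], [5, 7]], tax), "phylum")
        assert out.shape == (1, 2)
        np.testing.assert_allclose(out.loc["Proteobacteria"], 1.0)

    def test_all_unclassified(self):
        tax = ["k__B;p__unclassified", "unclassified"]
        out = aggregate_taxa(_table([[3, 1], [2, 2]], tax), "phylum")
        np.testing.assert_allclose(out.loc["unclassified"], 1.0)

    def test_other_bucket_sums_tail_exactly(self, rng):
        n_genera = 40
        tax = [f"k__B;p__P;c__;o__;f__;g__G{i}" for i in range(n_genera)]
        counts = rng.integers(1, 100, (n_genera, 4))
        out = aggregate_taxa(_table(counts, tax), "genus", top_n=30)
        rel = counts / counts.sum(axis=0)
        mean_ab = rel.mean(axis=1)
        tail = np.argsort(mean_ab)[::-1][30:]
        np.testing.assert_allclose(
            out.loc["other"].to_numpy(), rel[tail].sum(axis=0), atol=1e-12
        )

    def test_columns_sum_to_one(self, rng):
        tax = [f"k__B;p__P{i % 6}" for i in range(30)]
        out = aggregate_taxa(_table(rng.integers(0, 50, (30, 5)) + 1, tax), "phylum")
        np.testing.assert_allclose(out.sum(axis=0), 1.0, atol=1e-9)

    def test_unknown_rank_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            aggregate_taxa(_table([[1, 1]], ["k__B"]), "clade")


class TestCorrelationScreen:
    def _cov(self, values, names=("Ca",), kind="element", n=None):
        values = np.atleast_2d(np.asarray(values, float))
        if values.shape[0] == 1:
            values = values.T
        ids = [f"S{j}" for j in range(values.shape[0])]
        return CovariateTable(ids, list(names), values, kind)

    def test_proportional_otu_perfect_correlation(self):
        # constant depth makes O0's relative abundance exactly linear in the
        # covariate, so r = 1 up to float error
        cov_vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        o0 = (10 * cov_vals).astype(int)
        counts = np.vstack([o0, 600 - o0])
        res = correlation_screen(_table(counts), self._cov(cov_vals))
        row = res.table[(res.table.otu_id == "O0")].iloc[0]
        assert row.r == pytest.approx(1.0, abs=1e-12)
        assert row.significant

    def test_constant_otu_skipped_with_note(self, rng):
        # all proportions constant across samples -> every OTU is skipped
        counts = np.vstack([
            np.array([10, 20, 30, 40, 50, 60]),
            np.array([10, 20, 30, 40, 50, 60]),
            np.array([20, 40, 60, 80, 100, 120]),
        ])
        with pytest.warns(UserWarning, match="constant OTUs"):
            res = correlation_screen(
                _table(counts), self._cov(rng.normal(size=6))
            )
        assert len(res.table) == 0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            correlation_screen(
                _table(np.ones((3, 3), dtype=int)), self._cov([1.0, 2.0, 3.0])
            )

    def test_null_fraction_near_alpha(self, rng):
        """Independent OTUs: significant fraction calibrates to alpha."""
        n_otus, n_samp = 1000, 9
        counts = rng.integers(1, 200, (n_otus, n_samp))
        res = correlation_screen(_table(counts), self._cov(rng.normal(size=n_samp)))
        frac = res.table["significant"].mean()
        se = np.sqrt(0.05 * 0.95 / len(res.table))
        assert abs(frac - 0.05) < 4 * se + 0.01

    def test_linked_otus_recovered(self, rng):
        """Strong linear links at n=9 are detected with high power."""
        from dustbiome.simulate import gen_otu_table

        cov_vals = np.linspace(0, 1, 9)
        table, truth = gen_otu_table(
            300, 9, 20, cov_vals, effect_size=1.2, depth=50_000, seed=77
        )
        res = correlation_screen(_table(table.counts), self._cov(cov_vals))
        sig = set(res.table[res.table.significant].otu_id)
        linked = {f"O{int(o.split('_')[1]) - 1}" for o in truth.linked_otus}
        assert len(sig & linked) >= 16

    def test_strongest_flag_unique_per_otu(self, rng):
        counts = rng.integers(1, 100, (40, 8))
        cov = self._cov(rng.normal(size=(8, 3)), names=("Ca", "Ni", "Zn"))
        res = correlation_screen(_table(counts), cov)
        per_otu = res.table[res.table.strongest].groupby("otu_id").size()
        assert (per_otu <= 1).all()
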