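import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from planktonscape.data_io import OTUTable
from planktonscape.diversity import (
    DistanceMatrix,
    bray_curtis_matrix,
    margalef_index,
    nmds,
    one_way_anova,
    permanova,
    shannon_index,
)


class TestShannon:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([5, 5], np.log(2)),
            ([10, 0, 0], 0.0),
            ([2, 1, 1], 1.039721),  # -[.5 ln .5 + 2*.25 ln .25]
        ],
    )
    def test_closed_forms(self, counts, expected):
        assert shannon_index(counts) == pytest.approx(expected, abs=1e-6)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            shannon_index([0, 0])

    @given(st.lists(st.integers(1, 1000), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_log_richness(self, counts):
        h = shannon_index(counts)
        assert 0 <= h <= np.log(len(counts)) + 1e-12

    def test_maximal_iff_equal(self):
        assert shannon_index([7, 7, 7]) == pytest.approx(np.log(3))
        assert shannon_index([8, 7, 6]) < np.log(3)

    def test_concentration_decreases_h(self, rng):
        # moving mass onto fewer taxa strictly lowers H
        counts = np.array([10, 10, 10, 10])
        concentrated = np.array([25, 10, 5, 0])
        assert shannon_index(concentrated) < shannon_index(counts)


class TestMargalef:
    def test_single_taxon_is_zero(self):
        assert margalef_index([10]) == 0.0

    def test_closed_form(self):
        # S=5 taxa, N=100 reads: (5-1)/ln(100)
        assert margalef_index([96, 1, 1, 1, 1]) == pytest.approx(4 / np.log(100))

    def test_small_n_near_e_squared(self):
        # S=3, N=8 requires no special-casing
        assert margalef_index([6, 1, 1]) == pytest.approx(2 / np.log(8))

    def test_too_few_individuals(self):
        with pytest.raises(ValueError, match="at least 2"):
            margalef_index([1])


class TestBrayCurtis:
    def _table(self, cols):
        arr = np.array(cols).T
        return OTUTable([f"o{i}" for i in range(arr.shape[0])],
                        [f"s{j}" for j in range(arr.shape[1])], arr)

    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([3, 1], [3, 1], 0.0),
            ([3, 0], [0, 5], 1.0),
            ([3, 1], [1, 3], 0.5),
        ],
    )
    def test_closed_forms(self, x, y, expected):
        d = bray_curtis_matrix(self._table([x, y]), relative=False)
        assert d.values[0, 1] == pytest.approx(expected)

    def test_zero_total_sample_errors(self):
        with pytest.raises(ValueError, match="zero total"):
            bray_curtis_matrix(self._table([[1, 2], [0, 0]]))

    def test_matches_brute_force_double_loop(self, rng):
        for _ in range(10):
            counts = rng.integers(0, 40, size=(15, 6))
            counts[0] += 1
            t = OTUTable([f"o{i}" for i in range(15)], [f"s{j}" for j in range(6)], counts)
            d = bray_curtis_matrix(t, relative=False).values
            x = counts.astype(float)
            for i in range(6):
                for j in range(6):
                    expected = 1 - 2 * np.minimum(x[:, i], x[:, j]).sum() / (
                        x[:, i].sum() + x[:, j].sum()
                    )
                    assert d[i, j] == pytest.approx(expected, abs=1e-12)
            assert np.all((d >= 0) & (d <= 1))


class TestNMDS:
    def test_equilateral_triangle_embeds_exactly(self):
        d = DistanceMatrix(["a", "b", "c"], np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.0]]))
        res = nmds(d, k=2, seed=0)
        assert res.stress < 0.02

    def test_deterministic_under_seed(self, small_neutral_dataset):
        bc = bray_curtis_matrix(small_neutral_dataset.table)
        sub = bc.subset(bc.labels[:12])
        a = nmds(sub, k=2, seed=5)
        b = nmds(sub, k=2, seed=5)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)
        assert a.stress == b.stress

    def test_stress_nonincreasing_in_k(self, rng):
        from scipy.spatial.distance import pdist, squareform

        for rep in range(5):
            pts = rng.normal(size=(9, 4))
            d = DistanceMatrix([f"s{i}" for i in range(9)],
                               squareform(pdist(pts)))
            s1 = nmds(d, k=1, seed=rep).stress
            s2 = nmds(d, k=2, seed=rep).stress
            assert s2 <= s1 + 1e-6

    def test_invalid_k(self):
        d = DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0.0]]))
        with pytest.raises(ValueError):
            nmds(d, k=2)


class TestPermanova:
    def test_separated_clusters_saturate_significance(self, rng):
        pts = np.vstack([rng.normal(0, 0.1, (6, 3)), rng.normal(5, 0.1, (6, 3))])
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix([f"s{i}" for i in range(12)], squareform(pdist(pts)))
        res = permanova(d, ["a"] * 6 + ["b"] * 6, n_perm=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_singleton_group_rejected(self):
        d = DistanceMatrix(["a", "b", "c"], np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.0]]))
        with pytest.raises(ValueError, match="at least 2 members"):
            permanova(d, ["g1", "g1", "g2"])

    def test_statistic_matches_scikit_bio(self, rng):
        # independent oracle: scikit-bio's PERMANOVA pseudo-F on the same input
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import permanova as skbio_permanova

        pts = rng.normal(size=(12, 4))
        from scipy.spatial.distance import pdist, squareform

        vals = squareform(pdist(pts))
        labels = [f"s{i}" for i in range(12)]
        groups = ["a", "b", "c"] * 4
        ours = permanova(DistanceMatrix(labels, vals), groups, n_perm=99, seed=0)
        theirs = skbio_permanova(SkbioDM(vals, ids=labels), grouping=groups,
                                 permutations=0)
        assert ours.statistic == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_label_permutation_leaves_null_invariant(self, rng):
        from scipy.spatial.distance import pdist, squareform

        pts = rng.normal(size=(12, 3))
        d = DistanceMatrix([f"s{i}" for i in range(12)], squareform(pdist(pts)))
        g = np.array(["a", "b"] * 6)
        r1 = permanova(d, g, n_perm=99, seed=7)
        r2 = permanova(d, g, n_perm=99, seed=7)
        assert r1.p_value == r2.p_value


class TestOneWayAnova:
    def test_identical_groups_give_zero_f(self):
        res = one_way_anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.statistic == pytest.approx(0.0)

    def test_matches_textbook_decomposition(self):
        # brute-force sums of squares on a hand-sized 2x3 layout
        values = np.array([4.0, 6.0, 8.0, 10.0, 12.0, 14.0])
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        res = one_way_anova(values, groups)
        grand = values.mean()
        ss_between = sum(
            3 * (values[groups == g].mean() - grand) ** 2 for g in ("a", "b")
        )
        ss_within = sum(
            ((values[groups == g] - values[groups == g].mean()) ** 2).sum()
            for g in ("a", "b")
        )
        f_expected = (ss_between / 1) / (ss_within / 4)
        assert res.statistic == pytest.approx(f_expected, rel=1e-12)
        assert res.df == (1, 4)

    def test_null_f_near_one_on_average(self, rng):
        fs = []
        for _ in range(200):
            vals = rng.normal(size=12)
            fs.append(one_way_anova(vals, ["a", "b", "c"] * 4).statistic)
        assert np.mean(fs) == pytest.approx(1.0, abs=0.35)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            one_way_anova([1, 1, 2, 2], ["a", "a", "b", "b"])
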