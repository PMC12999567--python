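import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rhizoeval import (
    DistanceMatrix,
    FeatureTable,
    bray_curtis,
    pcoa,
    permanova,
    rarefy,
    simpson_index,
    wilcoxon_rank_sum,
)
from rhizoeval.diversity import _permanova_f

from conftest import random_table


def table_from(cols: dict) -> FeatureTable:
    n = len(next(iter(cols.values())))
    idx = pd.Index([f"t{i}" for i in range(n)], name="taxon_id")
    return FeatureTable(pd.DataFrame(cols, index=idx))


class TestRarefy:
    def test_sample_at_depth_unchanged(self):
        t = table_from({"s1": [6, 4], "s2": [3, 3]})
        out = rarefy(t, depth=6, seed=0)
        assert out.counts["s2"].tolist() == [3, 3]

    def test_column_sums_equal_depth(self):
        rng = np.random.default_rng(1)
        t = random_table(rng, n_taxa=30, n_samples=10, max_count=80)
        out = rarefy(t, seed=3)
        depth = int(t.sample_totals().min())
        assert (out.sample_totals() == depth).all()

    def test_depth_above_sample_total_names_sample(self):
        t = table_from({"big": [50, 50], "small": [2, 1]})
        with pytest.raises(ValueError, match="small"):
            rarefy(t, depth=10)

    def test_hypergeometric_expectation(self):
        # taxon at proportion 0.6, depth 100: mean rarefied count ~ 60
        t = table_from({"s": [600, 400], "pad": [600, 400]})
        draws = [rarefy(t, depth=100, seed=s).counts.loc["t0", "s"] for s in range(1000)]
        q, d, n = 0.6, 100, 1000
        se_draw = np.sqrt(d * q * (1 - q) * (1000 - d) / (1000 - 1))
        assert np.mean(draws) == pytest.approx(d * q, abs=3 * se_draw / np.sqrt(n))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        t = random_table(rng)
        assert rarefy(t, seed=9).counts.equals(rarefy(t, seed=9).counts)


class TestSimpson:
    def test_single_taxon_is_one(self):
        assert simpson_index(table_from({"s": [9]}))["s"] == 1.0

    @pytest.mark.parametrize("k", [2, 4, 10])
    def test_equal_abundances_give_reciprocal_k(self, k):
        t = table_from({"s": [5] * k})
        assert simpson_index(t)["s"] == pytest.approx(1 / k)

    def test_hand_computed_value(self):
        # (1^2 + 2^2 + 3^2) / 6^2 = 14/36
        assert simpson_index(table_from({"s": [1, 2, 3]}))["s"] == pytest.approx(14 / 36)

    @given(st.lists(st.integers(1, 100), min_size=2, max_size=8),
           st.integers(2, 20))
    def test_invariant_to_count_scaling(self, counts, scale):
        t1 = table_from({"s": counts})
        t2 = table_from({"s": [c * scale for c in counts]})
        assert simpson_index(t1)["s"] == pytest.approx(simpson_index(t2)["s"])

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            simpson_index(table_from({"s": [0, 0]}))


class TestBrayCurtis:
    def test_identical_samples_distance_zero(self):
        dm = bray_curtis(table_from({"a": [3, 5], "b": [3, 5]}))
        assert dm.values[0, 1] == 0.0

    def test_disjoint_supports_distance_one(self):
        dm = bray_curtis(table_from({"a": [4, 0], "b": [0, 7]}))
        assert dm.values[0, 1] == 1.0

    def test_hand_computed_value(self):
        # |2-1| + |0-1| over (2+1) + (0+1) = 2/4
        dm = bray_curtis(table_from({"a": [2, 0], "b": [1, 1]}))
        assert dm.values[0, 1] == pytest.approx(0.5)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(4)
        dm = bray_curtis(random_table(rng, max_count=30, n_taxa=6))
        assert dm.values.min() >= 0 and dm.values.max() <= 1

    def test_matches_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio.diversity import beta_diversity

        rng = np.random.default_rng(8)
        t = random_table(rng, n_taxa=15, n_samples=6)
        ours = bray_curtis(t)
        ref = beta_diversity("braycurtis", t.counts.to_numpy().T, ids=t.sample_ids)
        assert np.allclose(ours.values, ref.data, atol=1e-12)


class TestPcoa:
    def test_two_points_single_axis(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0.0, 3.0], [3.0, 0.0]]))
        res = pcoa(dm)
        coords = res.coordinates
        assert abs(coords.iloc[0, 0] - coords.iloc[1, 0]) == pytest.approx(3.0)
        assert res.proportion_explained[0] == pytest.approx(100.0)

    def test_equilateral_triangle_splits_evenly(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(DistanceMatrix(("a", "b", "c"), d))
        assert res.proportion_explained[:2] == pytest.approx([50.0, 50.0])

    def test_reconstructs_euclidean_distances(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(7, 2))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(tuple("abcdefg"), d))
        rec = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(rec, d, atol=1e-9)

    def test_axes_ordered_by_eigenvalue(self):
        rng = np.random.default_rng(1)
        t = random_table(rng, n_taxa=10, n_samples=8)
        res = pcoa(bray_curtis(t))
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert res.proportion_explained.sum() == pytest.approx(100.0)


class TestPermanova:
    def _toy(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(5, 1, (3, 2))])
        from scipy.spatial.distance import pdist, squareform

        return DistanceMatrix(tuple("abcdef"), squareform(pdist(pts)))

    def test_f_matches_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import permanova as sk_permanova

        dm = self._toy()
        groups = ["g1"] * 3 + ["g2"] * 3
        ours = permanova(dm, groups, n_perm=99, seed=0)
        ref = sk_permanova(SkDM(dm.values, ids=list(dm.ids)), groups, permutations=99)
        assert ours.f == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_f_matches_direct_formula(self):
        # independent oracle: explicit double loop over Anderson's sums
        dm = self._toy()
        codes = np.array([0, 0, 0, 1, 1, 1])
        d2 = dm.values**2
        n, a = 6, 2
        ss_t = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
        ss_w = 0.0
        for g in (0, 1):
            idx = np.where(codes == g)[0]
            ss_w += sum(d2[i, j] for i in idx for j in idx if i < j) / len(idx)
        f_oracle = ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))
        assert _permanova_f(d2, codes, 2) == pytest.approx(f_oracle, rel=1e-12)

    def test_exhaustive_permutation_minimum_for_separated_groups(self):
        dm = self._toy()
        codes = np.array([0, 0, 0, 1, 1, 1])
        d2 = dm.values**2
        f_obs = _permanova_f(d2, codes, 2)
        count = sum(
            _permanova_f(d2, np.array(perm), 2) >= f_obs - 1e-12
            for perm in itertools.permutations(codes)
        )
        # only permutations reproducing the partition reach F_obs
        assert count / 720 == pytest.approx(72 / 720)
        res = permanova(dm, ["g1"] * 3 + ["g2"] * 3, n_perm=999, seed=1)
        assert res.p == pytest.approx(72 / 720, abs=0.03)

    def test_p_floor_and_relabel_invariance(self):
        dm = self._toy()
        r1 = permanova(dm, ["x"] * 3 + ["y"] * 3, n_perm=99, seed=5)
        r2 = permanova(dm, ["blue"] * 3 + ["red"] * 3, n_perm=99, seed=5)
        assert r1.p == r2.p and r1.f == r2.f
        assert r1.p >= 1 / 100

    def test_single_sample_group_rejected(self):
        dm = self._toy()
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(dm, ["a", "b", "b", "b", "b", "b"])


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        x = [3.0, 3.0, 5.0, 5.0, 7.0]
        _, p = wilcoxon_rank_sum(x, x)
        assert p == pytest.approx(1.0)

    def test_fully_separated_exact_p(self):
        _, p = wilcoxon_rank_sum([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert p == pytest.approx(2 / 252)

    def test_complete_separation_u_zero(self):
        u, _ = wilcoxon_rank_sum([1, 2], [3, 4])
        assert u == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])
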