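"""Community statistics: transforms, Bray-Curtis, PERMANOVA, chi-squared,
and the stratified metric permutation test."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bluffbeach.stats import (
    StatsError,
    bray_curtis,
    chi_square_independence,
    holm_adjust,
    pairwise_permanova,
    permanova,
    permutation_metric_test,
    rare_taxa_filter,
    transform_abundance,
)


def _df(arr, taxa=None):
    arr = np.asarray(arr, dtype=float)
    taxa = taxa or [f"t{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=taxa)


class TestTransforms:
    def test_zero_matrix_unchanged(self):
        m = _df(np.zeros((3, 4)))
        for method in ("log1", "sqrt"):
            assert (transform_abundance(m, method).to_numpy() == 0).all()

    def test_log1_and_sqrt_values(self):
        m = _df([[3.0, 4.0]])
        assert transform_abundance(m, "log1").iloc[0, 0] == pytest.approx(np.log(4.0))
        assert transform_abundance(m, "sqrt").iloc[0, 1] == pytest.approx(2.0)

    def test_negative_values_rejected(self):
        with pytest.raises(StatsError):
            transform_abundance(_df([[-1.0]]), "log1")


class TestRareTaxaFilter:
    def test_taxon_below_threshold_everywhere_dropped(self):
        m = _df([[2.0, 98.0], [2.0, 98.0]], taxa=["rare", "common"])
        assert list(rare_taxa_filter(m).columns) == ["common"]

    def test_single_sample_qualification_keeps_taxon(self):
        m = _df([[50.0, 50.0], [0.0, 100.0]], taxa=["patchy", "common"])
        assert list(rare_taxa_filter(m).columns) == ["patchy", "common"]

    def test_matches_exhaustive_relative_abundance_check(self, rng):
        m = _df(rng.integers(0, 30, size=(3, 4)).astype(float))
        kept = set(rare_taxa_filter(m).columns)
        expected = set()
        for j in m.columns:
            for i in m.index:
                total = m.loc[i].sum()
                if total > 0 and m.loc[i, j] / total >= 0.03:
                    expected.add(j)
        assert kept == expected

    def test_idempotent(self, rng):
        m = _df(rng.integers(0, 50, size=(5, 8)).astype(float))
        once = rare_taxa_filter(m)
        pd.testing.assert_frame_equal(once, rare_taxa_filter(once))

    def test_all_dropped_raises(self):
        m = _df([[1.0, 99.0]], taxa=["a", "b"])
        with pytest.raises(StatsError):
            rare_taxa_filter(m, threshold=1.1)


class TestBrayCurtis:
    def test_identical_rows_distance_zero(self):
        d = bray_curtis(_df([[1, 2, 3], [1, 2, 3]]))
        assert d[0, 1] == 0.0

    def test_disjoint_support_distance_one(self):
        d = bray_curtis(_df([[5, 0, 0], [0, 3, 2]]))
        assert d[0, 1] == 1.0

    def test_hand_computed_value(self):
        d = bray_curtis(_df([[1, 2, 0], [0, 2, 2]]))
        assert d[0, 1] == pytest.approx(3 / 7)

    def test_all_zero_pair_convention(self):
        d = bray_curtis(_df([[0, 0], [0, 0], [1, 1]]))
        assert d[0, 1] == 0.0 and d[0, 2] == 1.0

    def test_metric_axioms_and_column_order_invariance(self, rng):
        x = rng.gamma(1.0, 2.0, size=(6, 5))
        d = bray_curtis(x)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= 0).all() and (d <= 1).all()
        perm = rng.permutation(5)
        assert np.allclose(bray_curtis(x[:, perm]), d)

    def test_matches_scipy_reference(self, rng):
        from scipy.spatial.distance import braycurtis as scipy_bc

        x = rng.gamma(1.0, 2.0, size=(5, 7))
        d = bray_curtis(x)
        for i, k in itertools.combinations(range(5), 2):
            assert d[i, k] == pytest.approx(scipy_bc(x[i], x[k]))


def _brute_force_permanova(d, labels):
    """Independent O(n^2)-loop pseudo-F oracle."""
    n = len(labels)
    groups = sorted(set(labels))
    a = len(groups)
    ss_t = sum(d[i, k] ** 2 for i in range(n) for k in range(i + 1, n)) / n
    ss_w = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_w += sum(
            d[i, k] ** 2 for i in idx for k in idx if i < k
        ) / len(idx)
    ss_a = ss_t - ss_w
    return (ss_a / (a - 1)) / (ss_w / (n - a))


class TestPermanova:
    def test_pseudo_f_matches_brute_force(self, rng):
        x = rng.gamma(1.0, 1.0, size=(9, 4))
        d = bray_curtis(x)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = permanova(d, labels, permutations=99, seed=0)
        assert res.pseudo_f == pytest.approx(_brute_force_permanova(d, labels))
        assert res.ss_between + res.ss_within == pytest.approx(res.ss_total)

    def test_pseudo_f_matches_scikit_bio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as skbio_permanova

        x = rng.gamma(1.0, 1.0, size=(10, 5))
        d = bray_curtis(x)
        labels = ["a"] * 5 + ["b"] * 5
        res = permanova(d, labels, permutations=99, seed=0)
        ref = skbio_permanova(skbio.DistanceMatrix(d), grouping=labels, permutations=9)
        assert res.pseudo_f == pytest.approx(ref["test statistic"])

    def test_exact_enumeration_matches_brute_force(self, rng):
        x = rng.gamma(1.0, 1.0, size=(6, 3))
        d = bray_curtis(x)
        labels = ["a", "a", "a", "b", "b", "b"]
        res = permanova(d, labels, permutations="exact")
        f_obs = _brute_force_permanova(d, labels)
        count = 0
        for perm in itertools.permutations(range(6)):
            f = _brute_force_permanova(d, [labels[i] for i in perm])
            if f >= f_obs - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / 720)
        assert res.n_permutations == 720

    def test_separated_clouds_minimal_p(self, rng):
        a = rng.normal(0.0, 0.01, size=(10, 3)) + 1.0
        b = rng.normal(0.0, 0.01, size=(10, 3)) + 50.0
        d = bray_curtis(np.vstack([a, b]))
        res = permanova(d, ["a"] * 10 + ["b"] * 10, permutations=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_fixed_seed_reproducible(self, rng):
        d = bray_curtis(rng.gamma(1, 1, size=(8, 4)))
        labels = ["a"] * 4 + ["b"] * 4
        r1 = permanova(d, labels, permutations=199, seed=5)
        r2 = permanova(d, labels, permutations=199, seed=5)
        assert r1.p_value == r2.p_value

    def test_strata_respected(self, rng):
        # within-stratum permutation keeps stratum compositions fixed; a
        # stratum-confounded effect cannot look significant
        d = bray_curtis(rng.gamma(1, 1, size=(8, 4)))
        labels = ["a", "a", "b", "b"] * 2
        strata = ["r1"] * 4 + ["r2"] * 4
        res = permanova(d, labels, permutations=199, strata=strata, seed=2)
        assert res.p_value >= 1 / 200

    def test_singleton_group_rejected(self, rng):
        d = bray_curtis(rng.gamma(1, 1, size=(4, 3)))
        with pytest.raises(StatsError, match="size"):
            permanova(d, ["a", "a", "a", "b"], permutations=99)

    def test_inconsistent_strata_rejected(self, rng):
        d = bray_curtis(rng.gamma(1, 1, size=(4, 3)))
        with pytest.raises(StatsError):
            permanova(d, ["a", "a", "b", "b"], permutations=99, strata=["r1"] * 3)


class TestPairwisePermanova:
    def test_identical_groups_high_p(self, rng):
        base = rng.gamma(2.0, 1.0, size=(1, 4))
        x = np.vstack([base + rng.normal(0, 0.01, 4) for _ in range(8)])
        d = bray_curtis(np.abs(x))
        res = pairwise_permanova(d, ["a"] * 4 + ["b"] * 4, permutations=199, seed=3)
        assert res.loc[0, "p_value"] > 0.05

    def test_pair_subset_equals_global_on_pair(self, rng):
        x = rng.gamma(1.0, 1.0, size=(12, 5))
        d = bray_curtis(x)
        labels = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        res = pairwise_permanova(d, labels, pairs=[("a", "b")], permutations=99, seed=0)
        idx = np.flatnonzero(np.isin(labels, ["a", "b"]))
        direct = permanova(d[np.ix_(idx, idx)], labels[idx], permutations=99, seed=0)
        assert res.loc[0, "pseudo_f"] == pytest.approx(direct.pseudo_f)


class TestChiSquare:
    def test_table_equal_to_expected_gives_zero(self):
        assert chi_square_independence([[10, 20], [20, 40]])[0] == pytest.approx(0.0)
        assert chi_square_independence([[10, 20], [20, 40]])[2] == pytest.approx(1.0)

    def test_diagonal_2x2(self):
        chi2, df, _ = chi_square_independence([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)
        assert df == 1

    def test_feeding_counts_hand_oracle(self):
        # independently hand-computed Pearson value on the observed feeding
        # table (see also the acceptance suite)
        chi2, df, p = chi_square_independence([[1, 0, 4, 6], [15, 7, 6, 6]])
        assert chi2 == pytest.approx(10.686, abs=1e-3)
        assert df == 3
        assert p == pytest.approx(0.01355, abs=1e-4)

    def test_matches_scipy_reference(self, rng):
        from scipy.stats import chi2_contingency

        obs = rng.integers(1, 40, size=(3, 4))
        chi2, df, p = chi_square_independence(obs)
        ref = chi2_contingency(obs, correction=False)
        assert chi2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_zero_margin_rejected(self):
        with pytest.raises(StatsError, match="margin"):
            chi_square_independence([[0, 0], [1, 2]])


class TestHolm:
    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 6)
        ref = multipletests(p, method="holm")[1]
        assert holm_adjust(p) == pytest.approx(ref)


class TestPermutationMetricTest:
    def _design(self, reps=1):
        # ``reps`` sites per treatment per region; with reps=1 the stratified
        # pairwise relabeling grid is coarse (2^5 swaps per pair)
        treatments = np.tile(np.repeat(["a", "b", "c", "d"], reps), 5)
        regions = np.repeat([f"r{i}" for i in range(5)], 4 * reps)
        return treatments, regions

    def test_all_equal_values_give_p_one(self):
        treatments, regions = self._design()
        res = permutation_metric_test(
            np.ones(20), treatments, strata=regions, permutations=199, seed=0
        )
        assert (res["p_value"] == 1.0).all()

    def test_huge_effect_detected(self, rng):
        treatments, regions = self._design(reps=2)
        v = rng.normal(0, 1, treatments.size)
        v[treatments == "a"] += 50.0
        res = permutation_metric_test(v, treatments, strata=regions, permutations=999, seed=0)
        pa = res[(res["group_a"] == "a") | (res["group_b"] == "a")]
        assert (pa["p_value"] < 0.05).all()

    def test_small_treatment_rejected(self):
        with pytest.raises(StatsError):
            permutation_metric_test([1.0, 2.0, 3.0], ["a", "a", "b"], permutations=99)
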