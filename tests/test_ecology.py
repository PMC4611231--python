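"""Rarefaction, diversity, ordination, ANOSIM, SIMPER, weighted UniFrac."""

import math

import numpy as np
import pandas as pd
import pytest
import skbio
from scipy.spatial.distance import pdist, squareform
from scipy.stats import hypergeom

from ribotide import (
    ValidationError,
    alpha_diversity,
    anosim,
    bray_curtis,
    nmds,
    rarefaction_curve,
    rarefy,
    simper,
    weighted_unifrac,
)
from ribotide.containers import CountTable
from ribotide.io import parse_newick
from conftest import random_count_table


class TestRarefy:
    def test_sample_at_depth_unchanged(self):
        t = CountTable.from_arrays(["s"], ["a", "b"], np.array([[3, 2]]))
        out = rarefy(t, 5, seed=1)
        assert out.df.loc["s"].tolist() == [3, 2]

    def test_forced_subsample(self):
        t = CountTable.from_arrays(["s"], ["a", "b"], np.array([[10, 0]]))
        out = rarefy(t, 5, seed=1)
        assert out.df.loc["s"].tolist() == [5, 0]

    def test_hypergeometric_mean(self):
        t = CountTable.from_arrays(["s"], ["a", "b"], np.array([[50, 50]]))
        draws = [rarefy(t, 10, seed=s).df.loc["s", "a"] for s in range(500)]
        assert np.mean(draws) == pytest.approx(5.0, abs=0.25)

    def test_row_sums_exact_and_shallow_samples_dropped(self):
        t = CountTable.from_arrays(
            ["s1", "s2"], ["a", "b"], np.array([[80, 40], [3, 1]])
        )
        out = rarefy(t, 50, seed=0)
        assert out.sample_ids == ["s1"]
        assert out.sample_totals().tolist() == [50]

    def test_depth_above_all_samples_is_error(self):
        t = CountTable.from_arrays(["s1"], ["a"], np.array([[10]]))
        with pytest.raises(ValidationError):
            rarefy(t, 11)

    def test_same_seed_idempotent_at_same_depth(self):
        t = random_count_table(np.random.default_rng(3))
        once = rarefy(t, 100, seed=9)
        twice = rarefy(once, 100, seed=9)
        assert once == twice


class TestRarefactionCurve:
    def test_depth_equal_total_gives_full_richness(self):
        t = CountTable.from_arrays(["s"], list("abc"), np.array([[5, 3, 2]]))
        curve = rarefaction_curve(t, [10], replicates=5, seed=0)
        assert curve.loc[10, "s"] == 3

    def test_depth_one_gives_one(self):
        t = CountTable.from_arrays(["s"], list("ab"), np.array([[5, 5]]))
        curve = rarefaction_curve(t, [1], replicates=20, seed=0)
        assert curve.loc[1, "s"] == 1.0

    def test_closed_form_hypergeometric_expectation(self):
        # {A:99, B:1} at depth 10: E[richness] = 1 + P(B drawn) = 1.1
        t = CountTable.from_arrays(["s"], ["A", "B"], np.array([[99, 1]]))
        expected = 1 + (1 - hypergeom(100, 1, 10).pmf(0))
        curve = rarefaction_curve(t, [10], replicates=4000, seed=1)
        assert curve.loc[10, "s"] == pytest.approx(expected, abs=0.02)

    def test_monotone_in_depth_in_expectation(self):
        t = random_count_table(np.random.default_rng(5), depth=300)
        curve = rarefaction_curve(t, [10, 50, 150], replicates=40, seed=2)
        for sid in t.sample_ids:
            vals = curve[sid].dropna().to_numpy()
            assert (np.diff(vals) >= -0.25).all()  # small MC slack


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        t = CountTable.from_arrays(["s1", "s2"], ["a"], np.array([[5], [5]]))
        assert bray_curtis(t)["s1", "s2"] == 0.0

    def test_disjoint_samples_one(self):
        t = CountTable.from_arrays(
            ["s1", "s2"], ["a", "b"], np.array([[1, 0], [0, 1]])
        )
        assert bray_curtis(t)["s1", "s2"] == 1.0

    def test_hand_value(self):
        t = CountTable.from_arrays(
            ["s1", "s2"], ["a", "b"], np.array([[2, 1], [1, 1]])
        )
        assert bray_curtis(t)["s1", "s2"] == pytest.approx(0.2)

    def test_matches_scipy(self, rng):
        t = random_count_table(rng)
        mine = bray_curtis(t).data
        ref = squareform(pdist(t.values, metric="braycurtis"))
        np.testing.assert_allclose(mine, ref, atol=1e-12)

    def test_all_zero_sample_rejected(self):
        t = CountTable.from_arrays(["s1", "s2"], ["a"], np.array([[1], [0]]))
        with pytest.raises(ValidationError):
            bray_curtis(t)


class TestNmds:
    def test_recovers_exact_euclidean_configuration(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [2, 2.5]])
        dm = skbio.DistanceMatrix(squareform(pdist(pts)), ids=list("abcd"))
        res = nmds(dm, k=2, seed=0)
        assert res.stress < 0.01

    def test_two_samples_one_dimension_zero_stress(self):
        dm = skbio.DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ids=["a", "b"])
        res = nmds(dm, k=1, seed=0)
        assert res.stress == pytest.approx(0.0, abs=1e-8)

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(7, 3))
        dm = skbio.DistanceMatrix(squareform(pdist(pts)),
                                  ids=[f"s{i}" for i in range(7)])
        a = nmds(dm, k=2, seed=4)
        b = nmds(dm, k=2, seed=4)
        assert a.stress == b.stress
        np.testing.assert_array_equal(a.coordinates.values, b.coordinates.values)

    def test_stress_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(8, 2))
        d = squareform(pdist(pts))
        dm = skbio.DistanceMatrix(d, ids=[f"s{i}" for i in range(8)])
        dm2 = skbio.DistanceMatrix(d**1.7, ids=[f"s{i}" for i in range(8)])
        s1 = nmds(dm, k=2, seed=0).stress
        s2 = nmds(dm2, k=2, seed=0).stress
        assert s1 == pytest.approx(s2, abs=0.02)

    def test_k_too_large_rejected(self):
        dm = skbio.DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ids=["a", "b"])
        with pytest.raises(ValidationError):
            nmds(dm, k=2)


class TestAnosim:
    def test_perfect_separation_r_one(self, toy_table, toy_groups):
        dm = bray_curtis(toy_table)
        res = anosim(dm, toy_groups, n_permutations=99, seed=0)
        assert res.R == pytest.approx(1.0)

    def test_singleton_group_rejected(self, toy_table):
        groups = pd.Series({"s1": "X", "s2": "X", "s3": "Y", "s4": "Z"})
        dm = bray_curtis(toy_table)
        with pytest.raises(ValidationError):
            anosim(dm, groups)

    def test_matches_skbio_statistic(self, rng):
        t = random_count_table(rng, n_samples=8)
        groups = pd.Series(
            {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
        )
        dm = bray_curtis(t)
        mine = anosim(dm, groups, n_permutations=99, seed=0)
        ref = skbio.stats.distance.anosim(
            dm, groups.loc[list(dm.ids)].to_numpy(), permutations=99
        )
        assert mine.R == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_exhaustive_two_plus_two_oracle(self):
        # 4 samples in 2+2 groups: only 3 distinct pair partitions exist, so
        # the permutation p converges to the enumeration p.
        rng = np.random.default_rng(21)
        d = squareform(pdist(rng.normal(size=(4, 3))))
        ids = ["a", "b", "c", "d"]
        dm = skbio.DistanceMatrix(d, ids=ids)
        obs = anosim(dm, pd.Series(dict(zip(ids, "XXYY"))), 20000, seed=0)
        rs = []
        for pair in [("a", "b"), ("a", "c"), ("a", "d")]:
            labels = {i: ("X" if i in pair else "Y") for i in ids}
            rs.append(anosim(dm, pd.Series(labels), 5, seed=0).R)
        exact_p = np.mean([r >= obs.R - 1e-12 for r in rs])
        assert obs.p_value == pytest.approx(exact_p, abs=0.02)

    def test_null_r_centered_at_zero(self):
        rng = np.random.default_rng(3)
        r_vals = []
        for _ in range(60):
            d = squareform(pdist(rng.normal(size=(10, 4))))
            ids = [f"s{i}" for i in range(10)]
            dm = skbio.DistanceMatrix(d, ids=ids)
            labels = pd.Series(dict(zip(ids, list("AAAAABBBBB"))))
            r_vals.append(anosim(dm, labels, n_permutations=9, seed=1).R)
        assert abs(np.mean(r_vals)) < 0.08


class TestSimper:
    def test_single_differing_feature_100pct(self):
        t = CountTable.from_arrays(
            ["s1", "s2"], ["f1", "f2"], np.array([[5, 5], [1, 5]])
        )
        groups = pd.Series({"s1": "A", "s2": "B"})
        out = simper(t, groups, "A", "B")
        top = out.iloc[0]
        assert top["feature_id"] == "f1"
        assert top["contribution_pct"] == pytest.approx(100.0)

    def test_hand_toy_contributions(self):
        t = CountTable.from_arrays(
            ["s1", "s2"], ["f1", "f2"], np.array([[2, 1], [1, 1]])
        )
        groups = pd.Series({"s1": "A", "s2": "B"})
        out = simper(t, groups, "A", "B").set_index("feature_id")
        assert out.loc["f1", "mean_contribution"] == pytest.approx(0.2)
        assert out.loc["f2", "mean_contribution"] == pytest.approx(0.0)

    def test_conservation_identity_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            t = random_count_table(rng, n_samples=7, n_features=9)
            groups = pd.Series(
                {s: ("A" if i < 3 else "B") for i, s in enumerate(t.sample_ids)}
            )
            out = simper(t, groups, "A", "B")
            dm = bray_curtis(t)
            between = [
                dm[a, b]
                for a in t.sample_ids[:3]
                for b in t.sample_ids[3:]
            ]
            assert out["mean_contribution"].sum() == pytest.approx(
                np.mean(between), abs=1e-9
            )
            assert out["contribution_pct"].sum() == pytest.approx(100.0)

    def test_identical_group_names_rejected(self, toy_table, toy_groups):
        with pytest.raises(ValidationError):
            simper(toy_table, toy_groups, "X", "X")


def naive_unifrac(table, tree, normalized):
    """Exhaustive per-branch oracle: leaf-set sums recomputed per branch."""
    totals = table.sample_totals()
    n = table.shape[0]
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for node in tree.traverse(include_self=False):
        leaves = {t.name for t in node.tips()} or {node.name}
        p = np.array(
            [
                sum(
                    table.df.loc[s, f]
                    for f in table.feature_ids
                    if f in leaves
                )
                / totals[s]
                for s in table.sample_ids
            ]
        )
        length = node.length or 0.0
        num += length * np.abs(p[:, None] - p[None, :])
        den += length * (p[:, None] + p[None, :])
    if normalized:
        with np.errstate(invalid="ignore"):
            out = np.where(den > 0, num / np.where(den > 0, den, 1), 0.0)
    else:
        out = num
    np.fill_diagonal(out, 0.0)
    return out


class TestWeightedUnifrac:
    TREE = "((A:0.5,B:1):0.7,(C:0.2,D:0.9):0.3);"

    def test_identical_relative_profiles_zero_despite_depths(self):
        t = CountTable.from_arrays(
            ["s1", "s2"], list("AB"), np.array([[10, 30], [1, 3]])
        )
        dm = weighted_unifrac(t, parse_newick(self.TREE))
        assert dm["s1", "s2"] == pytest.approx(0.0, abs=1e-12)

    def test_star_tree_equals_bray_curtis_on_relative_abundances(self, rng):
        feats = [f"L{i}" for i in range(6)]
        nwk = "(" + ",".join(f"{f}:1" for f in feats) + ");"
        counts = rng.integers(1, 40, size=(4, 6))
        t = CountTable.from_arrays([f"s{i}" for i in range(4)], feats, counts)
        wu = weighted_unifrac(t, parse_newick(nwk), normalized=True)
        rel = t.relative_abundance().to_numpy()
        bc = squareform(pdist(rel, metric="braycurtis"))
        np.testing.assert_allclose(wu.data, bc, atol=1e-12)

    def test_disjoint_samples_on_star_tree_distance_one(self):
        nwk = "(A:1,B:1);"
        t = CountTable.from_arrays(
            ["s1", "s2"], list("AB"), np.array([[7, 0], [0, 9]])
        )
        wu = weighted_unifrac(t, parse_newick(nwk), normalized=True)
        assert wu["s1", "s2"] == pytest.approx(1.0)

    def test_matches_naive_oracle(self, rng):
        t = CountTable.from_arrays(
            ["s1", "s2", "s3"], list("ABCD"),
            rng.integers(0, 25, size=(3, 4)) + np.array([1, 0, 0, 0]),
        )
        tree = parse_newick(self.TREE)
        for normalized in (True, False):
            mine = weighted_unifrac(t, tree, normalized=normalized)
            ref = naive_unifrac(t, tree, normalized)
            np.testing.assert_allclose(mine.data, ref, atol=1e-9)

    def test_matches_skbio(self, rng):
        counts = rng.integers(0, 25, size=(3, 4))
        counts[:, 0] += 1
        t = CountTable.from_arrays(["s1", "s2", "s3"], list("ABCD"), counts)
        tree = parse_newick(self.TREE)
        mine = weighted_unifrac(t, tree, normalized=True)
        ref = skbio.diversity.beta_diversity(
            "weighted_unifrac", counts, ids=["s1", "s2", "s3"],
            taxa=list("ABCD"), tree=parse_newick(self.TREE), normalized=True,
        )
        np.testing.assert_allclose(mine.data, ref.data, atol=1e-12)

    def test_feature_missing_from_tree_rejected(self):
        t = CountTable.from_arrays(["s1"], ["A", "Z"], np.array([[1, 2]]))
        with pytest.raises(ValidationError, match="Z"):
            weighted_unifrac(t, parse_newick(self.TREE))


class TestAlphaDiversity:
    def test_even_three_features(self):
        t = CountTable.from_arrays(["s"], list("ABC"), np.array([[1, 1, 1]]))
        out = alpha_diversity(t)
        assert out.loc["s", "richness"] == 3
        assert out.loc["s", "shannon"] == pytest.approx(math.log(3))

    def test_single_feature_zero_entropy(self):
        t = CountTable.from_arrays(["s"], ["A"], np.array([[9]]))
        assert alpha_diversity(t).loc["s", "shannon"] == 0.0

    def test_uneven_two_features(self):
        t = CountTable.from_arrays(["s"], list("AB"), np.array([[3, 1]]))
        expected = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))
        assert alpha_diversity(t).loc["s", "shannon"] == pytest.approx(expected)

    def test_empty_sample_flagged(self):
        t = CountTable.from_arrays(["s"], ["A"], np.array([[0]]))
        out = alpha_diversity(t)
        assert out.loc["s", "richness"] == 0
        assert bool(out.loc["s", "undefined"])
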