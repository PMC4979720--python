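import math
import random

import numpy as np
import pandas as pd
import pytest

from hostshift.dissim import dissimilarity_matrix
from hostshift.phylo import parse_newick
from hostshift.shift_test import (
    exact_null,
    observed_statistic,
    p_two_tailed,
    permutation_null,
    run_full_test,
    summarize,
)

from conftest import random_binary_newick
from test_dissim import make_matrix


def two_by_two(d_ab=1.0, h_ab=0.5):
    labs = ["A", "B"]
    X = pd.DataFrame([[0, d_ab], [d_ab, 0]], index=labs, columns=labs, dtype=float)
    H = pd.DataFrame([[0, h_ab], [h_ab, 0]], index=labs, columns=labs, dtype=float)
    return X, H


class TestObservedStatistic:
    def test_single_pair(self):
        X, H = two_by_two()
        assert observed_statistic(X, H) == pytest.approx(0.5)

    def test_zero_dissimilarity_annihilates(self):
        X, H = two_by_two(h_ab=0.0)
        assert observed_statistic(X, H) == 0.0

    def test_three_tip_hand_sum(self):
        labs = ["A", "B", "C"]
        X = pd.DataFrame(
            [[0, 2, 4], [2, 0, 4], [4, 4, 0]], index=labs, columns=labs, dtype=float
        )
        H = pd.DataFrame(
            [[0, 0, 2 / 3], [0, 0, 2 / 3], [2 / 3, 2 / 3, 0]],
            index=labs,
            columns=labs,
        )
        assert observed_statistic(X, H) == pytest.approx(16 / 3)

    def test_label_mismatch_lists_difference(self):
        X, H = two_by_two()
        H.index = H.columns = ["A", "Z"]
        with pytest.raises(ValueError, match="Z"):
            observed_statistic(X, H)

    def test_relabeling_invariance(self, rng):
        tree = parse_newick(random_binary_newick(rng, 6))
        hosts = [f"h{i}" for i in range(6)]
        sets = {
            lab: set(rng.sample(hosts, rng.randint(1, 4))) for lab in tree.tip_labels
        }
        m = make_matrix(sets, hosts)
        X = tree.patristic_matrix()
        H = dissimilarity_matrix(m, family="jaccard", component="total")
        s1 = observed_statistic(X, H)
        order = list(reversed(X.index))
        s2 = observed_statistic(X.loc[order, order], H.loc[order, order])
        assert s1 == pytest.approx(s2)

    def test_node_mode_hand_example(self):
        # ((A:1,B:1):1,C:2): node {A,B}: X=2, H=H_AB; root: pairs (A,C),(B,C)
        tree = parse_newick("((A:1,B:1):1,C:2);")
        X = tree.patristic_matrix()
        labs = list(X.index)
        H = pd.DataFrame(0.2, index=labs, columns=labs)
        H.loc["A", "C"] = H.loc["C", "A"] = 0.8
        H.loc["B", "C"] = H.loc["C", "B"] = 0.4
        for lab in labs:
            H.loc[lab, lab] = 0.0
        expect = 2.0 * 0.2 + 4.0 * 0.6  # (mean X, mean H) per node
        got = observed_statistic(X, H, mode="node", tree=tree)
        assert got == pytest.approx(expect)


class TestSummarize:
    def test_hand_summary(self):
        res = summarize(3.0, np.array([1.0, 2.0, 3.0]))
        assert res.null_mean == pytest.approx(2.0)
        assert res.null_sd == pytest.approx(1.0)
        assert res.ses == pytest.approx(1.0)
        assert res.sign == "+"

    def test_degenerate_null(self):
        res = summarize(5.0, np.full(100, 5.0))
        assert math.isnan(res.ses) and res.sign == "0" and res.p_two_tailed == 1.0

    def test_observed_beyond_all_nulls(self):
        null = np.arange(10_000, dtype=float)
        res = summarize(10_001.0, null)
        assert res.p_two_tailed == pytest.approx(2 / 10_001)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            summarize(1.0, np.array([]))

    def test_p_always_positive_and_capped(self):
        null = np.zeros(9) + np.arange(9)
        for obs in (-5.0, 4.0, 50.0):
            p = p_two_tailed(obs, null)
            assert 0 < p <= 1


def random_instance(seed, n=None, hosts_n=6):
    rng = random.Random(seed)
    n = n or rng.randint(4, 7)
    tree = parse_newick(random_binary_newick(rng, n))
    hosts = [f"h{i}" for i in range(hosts_n)]
    sets = {lab: set(rng.sample(hosts, rng.randint(1, 4))) for lab in tree.tip_labels}
    return tree, make_matrix(sets, hosts)


class TestNullDistributions:
    def test_identical_host_sets_freeze_statistic(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        m = make_matrix({lab: {"h1", "h2"} for lab in "ABC"}, ["h1", "h2", "h3"])
        X = tree.patristic_matrix()
        H = dissimilarity_matrix(m, family="jaccard", component="total")
        obs = observed_statistic(X, H)
        null = permutation_null(X, m, None, n_perm=50, seed=3)
        assert np.allclose(null, obs)

    def test_exact_null_counts(self):
        tree, m = random_instance(0, n=4)
        vals = exact_null(tree.patristic_matrix(), m)
        assert len(vals) == 24

    def test_exact_null_refuses_large_n(self):
        tree, m = random_instance(1, n=9, hosts_n=8)
        with pytest.raises(ValueError, match="exact enumeration"):
            exact_null(tree.patristic_matrix(), m)

    def test_duplicate_host_sets_collapse_support(self):
        tree = parse_newick(random_binary_newick(random.Random(5), 4))
        labs = list(tree.tip_labels)
        sets = {labs[0]: {"h1"}, labs[1]: {"h1"}, labs[2]: {"h1"}, labs[3]: {"h2"}}
        m = make_matrix(sets, ["h1", "h2"])
        vals = exact_null(tree.patristic_matrix(), m)
        # only the placement of the odd species matters: ≤ 4 distinct values
        assert len(np.unique(np.round(vals, 12))) <= 4

    def test_permutation_determinism(self):
        tree, m = random_instance(7)
        X = tree.patristic_matrix()
        a = permutation_null(X, m, None, n_perm=200, seed=11)
        b = permutation_null(X, m, None, n_perm=200, seed=11)
        c = permutation_null(X, m, None, n_perm=200, seed=12)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_three_tip_null_converges_to_exact_support(self):
        tree, m = random_instance(2, n=3)
        X = tree.patristic_matrix()
        exact = np.sort(np.unique(np.round(exact_null(X, m), 10)))
        mc = np.sort(np.unique(np.round(permutation_null(X, m, None, n_perm=500, seed=1), 10)))
        assert set(mc) <= set(exact)
        assert len(mc) == len(exact)  # 500 draws hit all ≤6 support points

    @pytest.mark.parametrize("seed", range(6))
    def test_monte_carlo_p_matches_exact(self, seed):
        """MC two-tailed p within 3 binomial SEs of the enumeration p."""
        tree, m = random_instance(200 + seed)
        X = tree.patristic_matrix()
        H = dissimilarity_matrix(m, family="jaccard", component="total")
        obs = observed_statistic(X, H)
        ex = exact_null(X, m)
        p_exact = p_two_tailed(obs, ex, exact=True)
        n_perm = 1500
        mc = permutation_null(X, m, None, n_perm=n_perm, seed=seed)
        p_mc = p_two_tailed(obs, mc)
        q = min(max(p_exact / 2, 1e-6), 0.5)
        se = 2 * math.sqrt(q * (1 - q) / n_perm)
        assert abs(p_mc - p_exact) <= 3 * se + 2 / (n_perm + 1)


class TestRunFullTest:
    def test_six_results_on_shared_draws(self):
        tree, m = random_instance(31, n=6)
        host_tree = parse_newick(
            "((h0:1,h1:1):1,((h2:1,h3:1):1,(h4:1,h5:1):1):1);"
        )
        res = run_full_test(tree, host_tree, m, n_perm=99, seed=5)
        assert len(res) == 6
        keys = {(r.family, r.component) for r in res}
        assert len(keys) == 6
        for r in res:
            assert r.n_permutations == 99 and r.seed == 5
            assert 0 < r.p_two_tailed <= 1

    def test_exclude_taxon(self):
        tree, m = random_instance(32, n=6)
        drop = m.herbivores[0]
        res = run_full_test(
            tree, None, m, families=("jaccard",), components=("total",),
            n_perm=49, seed=1, exclude=(drop,),
        )
        assert res[0].extra["n_taxa"] == 5

    def test_node_mode_runs(self):
        tree, m = random_instance(33, n=5)
        res = run_full_test(
            tree, None, m, families=("jaccard",), components=("turnover",),
            mode="node", n_perm=49, seed=1,
        )
        assert res[0].statistic_mode == "node"

    def test_requires_three_taxa(self):
        tree, m = random_instance(34, n=4)
        keep = m.herbivores[:2]
        with pytest.raises(ValueError, match="3"):
            run_full_test(tree, None, m.subset(keep), families=("jaccard",),
                          components=("total",), n_perm=9, seed=1)
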