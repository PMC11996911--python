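import io
import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from ecoassembly import (CommunityTable, beta_mntd, beta_nti, classify_pair,
                         classify_pairs, partition_processes, rc_bray)
from ecoassembly.assembly import PROCESSES

from conftest import random_table_and_tree


def brute_force_beta_mntd(table, tree, abundance_weighted=True):
    """Independent oracle: enumerate all tip-pair distances and take
    per-taxon minima over the partner community."""
    otus = table.otu_ids
    coph = {}
    for a, b in itertools.product(otus, repeat=2):
        coph[a, b] = 0.0 if a == b else tree.find(a).distance(tree.find(b))
    n = table.shape[0]
    out = np.zeros((n, n))
    counts = table.df
    for i, j in itertools.combinations(range(n), 2):
        si, sj = table.sample_ids[i], table.sample_ids[j]
        pa = [o for o in otus if counts.loc[si, o] > 0]
        pb = [o for o in otus if counts.loc[sj, o] > 0]
        if abundance_weighted:
            wa = counts.loc[si, pa] / counts.loc[si, pa].sum()
            wb = counts.loc[sj, pb] / counts.loc[sj, pb].sum()
        else:
            wa = pd.Series(1 / len(pa), index=pa)
            wb = pd.Series(1 / len(pb), index=pb)
        term_a = sum(wa[o] * min(coph[o, p] for p in pb) for o in pa)
        term_b = sum(wb[o] * min(coph[o, p] for p in pa) for o in pb)
        out[i, j] = out[j, i] = 0.5 * (term_a + term_b)
    return out


class TestBetaMntd:
    def test_identical_communities_zero(self, five_tip_tree):
        df = pd.DataFrame([[3, 1, 0, 2, 0]] * 2, index=["a", "b"],
                          columns=list("ABCDE"))
        m = beta_mntd(CommunityTable(df), five_tip_tree)
        assert m["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_star_tree_disjoint_singletons(self, star_tree):
        df = pd.DataFrame([[5, 0, 0, 0], [0, 7, 0, 0]], index=["a", "b"],
                          columns=list("ABCD"))
        m = beta_mntd(CommunityTable(df), star_tree)
        assert m["a", "b"] == pytest.approx(3.0)  # 2 * pendant length

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force_oracle(self, weighted):
        rng = np.random.default_rng(12345)
        for _ in range(100):
            table, tree = random_table_and_tree(rng)
            fast = beta_mntd(table, tree, abundance_weighted=weighted).data
            slow = brute_force_beta_mntd(table, tree,
                                         abundance_weighted=weighted)
            np.testing.assert_allclose(fast, slow, atol=1e-10)


class TestBetaNti:
    def test_star_tree_degenerate_null_is_nan(self, star_tree):
        df = pd.DataFrame([[5, 2, 0, 0], [0, 0, 3, 3]], index=["a", "b"],
                          columns=list("ABCD"))
        z = beta_nti(CommunityTable(df), star_tree, reps=100, seed=0)
        assert np.isnan(z.loc["a", "b"])

    def test_invariant_to_tip_renaming_and_column_order(self):
        rng = np.random.default_rng(5)
        table, tree = random_table_and_tree(rng, n_tips=8, n_samples=4)
        z1 = beta_nti(table, tree, reps=100, seed=9)

        # rename every taxon consistently in both tree and table
        mapping = {f"T{i}": f"X{i}" for i in range(8)}
        tree2 = tree.copy()
        for tip in tree2.tips():
            tip.name = mapping[tip.name]
        df2 = table.df.rename(columns=mapping)
        # also permute the OTU columns
        df2 = df2[list(df2.columns[::-1])]
        z2 = beta_nti(CommunityTable(df2), tree2, reps=100, seed=9)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-9)

    def test_reps_floor_enforced(self, five_tip_tree):
        df = pd.DataFrame([[1, 1, 0, 0, 0], [0, 0, 1, 1, 0]],
                          index=["a", "b"], columns=list("ABCDE"))
        with pytest.raises(ValueError):
            beta_nti(CommunityTable(df), five_tip_tree, reps=50, seed=0)


class TestRcBray:
    def test_extreme_pairs_hit_bounds(self):
        # two near-identical samples and one disjoint sample
        rng = np.random.default_rng(0)
        base = rng.integers(10, 60, size=8)
        df = pd.DataFrame(0, index=["a", "b", "c"],
                          columns=[f"O{i}" for i in range(16)])
        df.iloc[0, :8] = base
        df.iloc[1, :8] = base + rng.integers(0, 3, size=8)
        df.iloc[2, 8:] = rng.integers(10, 60, size=8)
        rc = rc_bray(CommunityTable(df), reps=100, seed=1)
        assert rc.loc["a", "b"] <= -0.95   # far more similar than null
        assert rc.loc["a", "c"] >= 0.95    # far less similar than null
        assert (rc.to_numpy() >= -1).all() and (rc.to_numpy() <= 1).all()

    def test_reproducible_under_seed(self, small_table):
        a = rc_bray(small_table, reps=100, seed=3)
        b = rc_bray(small_table, reps=100, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestClassification:
    # truth table spanning all five processes and both boundary sides
    @pytest.mark.parametrize("bnti,rc,expected", [
        (2.5, 0.1, "heterogeneous_selection"),
        (2.0, -0.99, "heterogeneous_selection"),   # closed bound, RC ignored
        (-2.5, 0.99, "homogeneous_selection"),     # RC ignored
        (-2.0, 0.0, "homogeneous_selection"),
        (1.99, 0.99, "dispersal_limitation"),
        (0.5, 0.96, "dispersal_limitation"),
        (0.5, -0.99, "homogenizing_dispersal"),
        (-1.99, -0.96, "homogenizing_dispersal"),
        (0.5, 0.95, "drift"),                      # strict RC threshold
        (0.5, -0.95, "drift"),
        (0.0, 0.2, "drift"),
    ])
    def test_truth_table(self, bnti, rc, expected):
        assert classify_pair(bnti, rc) == expected

    def test_nan_is_undetermined(self):
        assert classify_pair(float("nan"), 0.5) == "undetermined"


class TestPartition:
    def _pairs(self, labels):
        return pd.DataFrame({
            "sample_i": [f"s{i}" for i in range(len(labels))],
            "sample_j": [f"t{i}" for i in range(len(labels))],
            "beta_mntd": 0.0, "beta_nti": 0.0, "rc_bray": 0.0,
            "process": labels})

    def test_all_drift(self):
        part = partition_processes(self._pairs(["drift"] * 10))
        assert part.loc[0, "drift"] == pytest.approx(1.0)
        assert part.loc[0, "n_pairs"] == 10

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        labels = rng.choice(PROCESSES, size=40).tolist()
        part = partition_processes(self._pairs(labels))
        assert part[list(PROCESSES)].sum(axis=1).iloc[0] == pytest.approx(
            1.0, abs=1e-12)

    def test_undetermined_excluded(self):
        part = partition_processes(
            self._pairs(["drift"] * 4 + ["undetermined"]))
        assert part.loc[0, "n_pairs"] == 4

    def test_within_group_pairs_only(self):
        pairs = pd.DataFrame({
            "sample_i": ["a1", "a2", "a1"],
            "sample_j": ["a2", "b1", "b1"],
            "beta_mntd": 0.0, "beta_nti": 0.0, "rc_bray": 0.0,
            "process": ["drift", "drift", "drift"]})
        groups = pd.Series({"a1": "A", "a2": "A", "b1": "B"})
        part = partition_processes(pairs, groups)
        assert part["n_pairs"].sum() == 1  # only the within-A pair
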