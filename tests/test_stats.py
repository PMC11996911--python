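import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from ecoassembly import (CommunityTable, ValidationError, anosim,
                         bray_curtis, group_difference_tests, mantel, pcoa,
                         permanova, procrustes, spearman_heatmap, vpa,
                         ordination_regression)
from ecoassembly.stats import pca_ordination


def euclid_dm(points, ids=None):
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


class TestPermanova:
    def test_perfect_separation(self):
        pts = np.vstack([np.zeros((4, 2)), np.full((4, 2), 10.0)])
        pts += np.random.default_rng(0).normal(0, 1e-6, pts.shape)
        dm = euclid_dm(pts)
        md = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 4}, index=list(dm.ids))
        res = permanova(dm, md, "g", permutations=199, seed=0)
        assert res.loc[0, "R2"] > 0.99
        # permutations that reproduce the same two-group partition tie
        # with the observed F, so the attainable floor is ~2/C(8,4)
        assert res.loc[0, "p_value"] < 0.05

    def test_one_way_matches_brute_force_decomposition(self):
        # hand-sized Euclidean case: SS_total and SS_within from the
        # definition (sums of squared distances / group sizes)
        pts = np.array([[0.0], [1.0], [4.0], [5.0]])
        dm = euclid_dm(pts)
        groups = ["a", "a", "b", "b"]
        md = pd.DataFrame({"g": groups}, index=list(dm.ids))
        d2 = squareform(pdist(pts)) ** 2
        n = 4
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        for lab in ("a", "b"):
            idx = [i for i, g in enumerate(groups) if g == lab]
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ss_among = ss_total - ss_within
        f_expected = (ss_among / 1) / (ss_within / 2)
        res = permanova(dm, md, "g", permutations=99, seed=0)
        assert res.loc[0, "SS"] == pytest.approx(ss_among, abs=1e-10)
        assert res.loc[0, "pseudo_F"] == pytest.approx(f_expected, abs=1e-10)

    def test_one_way_matches_skbio(self, small_table):
        dm = bray_curtis(small_table)
        md = pd.DataFrame({"g": ["x", "x", "y", "y"]},
                          index=small_table.sample_ids)
        mine = permanova(dm, md, "g", permutations=99, seed=0)
        ref = skbio_permanova(dm, md, column="g", permutations=99, seed=0)
        assert mine.loc[0, "pseudo_F"] == pytest.approx(
            float(ref["test statistic"]), rel=1e-10)

    def test_two_factor_r2_sums_to_one(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, size=(12, 20))
        tab = CommunityTable(pd.DataFrame(
            counts, index=[f"s{i}" for i in range(12)],
            columns=[f"O{j}" for j in range(20)]))
        md = pd.DataFrame({"A": ["a"] * 6 + ["b"] * 6,
                           "B": (["x"] * 3 + ["y"] * 3) * 2},
                          index=tab.sample_ids)
        res = permanova(bray_curtis(tab), md, ["A", "B"],
                        permutations=99, seed=0)
        assert res["R2"].sum() == pytest.approx(1.0, abs=1e-9)
        assert set(res["term"]) == {"A", "B", "A:B", "Residual"}

    def test_singleton_level_rejected(self):
        dm = euclid_dm(np.arange(3.0)[:, None])
        md = pd.DataFrame({"g": ["a", "a", "b"]}, index=list(dm.ids))
        with pytest.raises(ValidationError):
            permanova(dm, md, "g")


class TestAnosim:
    def test_perfect_separation_r_one(self):
        pts = np.vstack([np.zeros((4, 2)), np.full((4, 2), 5.0)])
        pts += np.random.default_rng(0).normal(0, 1e-3, pts.shape)
        res = anosim(euclid_dm(pts), ["a"] * 4 + ["b"] * 4,
                     permutations=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_tiny_case_matches_hand_ranks(self):
        # 4 samples on a line: distances 1,2,3 ranks computed by hand
        pts = np.array([[0.0], [1.0], [10.0], [11.0]])
        dm = euclid_dm(pts)
        groups = ["a", "a", "b", "b"]
        # distances: (ab)=1, (cd)=1 within; 10,11,9,10 between
        # ranks: within {1.5, 1.5}, between {3.5, 5.5, 2 -> ...}
        d = dm.condensed_form()
        from scipy.stats import rankdata
        ranks = rankdata(d)
        within = [0, 5]  # index pairs (0,1) and (2,3) in condensed order
        between = [1, 2, 3, 4]
        r = (ranks[between].mean() - ranks[within].mean()) / (len(d) / 2)
        res = anosim(dm, groups, permutations=99, seed=0)
        assert res.statistic == pytest.approx(r, abs=1e-12)


class TestMantel:
    def test_identity_r_one(self):
        rng = np.random.default_rng(0)
        dm = euclid_dm(rng.normal(size=(6, 2)))
        res = mantel(dm, dm, permutations=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_affine_transform_r_one(self):
        rng = np.random.default_rng(0)
        dm = euclid_dm(rng.normal(size=(6, 2)))
        dm2 = DistanceMatrix(dm.data * 3.0 + (1 - np.eye(6)) * 0.7,
                             ids=list(dm.ids))
        res = mantel(dm, dm2, permutations=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_constant_matrix_rejected(self):
        dm = euclid_dm(np.random.default_rng(0).normal(size=(4, 2)))
        const = DistanceMatrix(1 - np.eye(4), ids=list(dm.ids))
        with pytest.raises(ValidationError):
            mantel(dm, const)


class TestProcrustes:
    def test_similarity_transform_m2_zero(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(7, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        b = 3.2 * a @ rot + np.array([5.0, -2.0])
        res = procrustes(a, b, permutations=99, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.extras["correlation"] == pytest.approx(1.0)

    def test_three_point_case_matches_grid_search(self):
        a = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        b = np.array([[0.5, 0.1], [0.2, 1.0], [1.5, 0.3]])
        res = procrustes(a, b, permutations=99, seed=0)

        # oracle: explicit minimization over rotation angle and scale on
        # normalized configurations (reflection included)
        def norm(x):
            x = x - x.mean(axis=0)
            return x / np.sqrt((x ** 2).sum())

        na, nb = norm(a), norm(b)
        best = np.inf
        for refl in (1, -1):
            nb_r = nb @ np.diag([1, refl])
            for theta in np.linspace(0, 2 * np.pi, 2_000_001):
                rot = np.array([[np.cos(theta), -np.sin(theta)],
                                [np.sin(theta), np.cos(theta)]])
                proj = nb_r @ rot
                scale = (na * proj).sum()  # optimal scale, unit-trace configs
                best = min(best, ((na - scale * proj) ** 2).sum())
        assert res.statistic == pytest.approx(best, abs=1e-6)

    def test_m2_invariant_to_common_rotation(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(6, 2)), rng.normal(size=(6, 2))
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        r1 = procrustes(a, b, permutations=99, seed=0).statistic
        r2 = procrustes(a @ rot, b @ rot, permutations=99, seed=0).statistic
        assert r1 == pytest.approx(r2, abs=1e-10)


class TestVpa:
    def _community(self, seed=0, n=16):
        rng = np.random.default_rng(seed)
        grad = np.linspace(-1, 1, n)
        counts = rng.poisson(
            20 * np.exp(-(grad[:, None] - np.linspace(-1, 1, 12)) ** 2))
        tab = CommunityTable(pd.DataFrame(
            counts + 1, index=[f"s{i}" for i in range(n)],
            columns=[f"O{j}" for j in range(12)]))
        return tab, grad, rng

    def test_identical_blocks_share_everything(self):
        tab, grad, rng = self._community()
        x = pd.DataFrame({"v": grad, "w": rng.normal(size=len(grad))},
                         index=tab.sample_ids)
        res = vpa(tab, {"b1": x, "b2": x.copy()})
        shared = res.fractions[frozenset(["b1", "b2"])]
        unique1 = res.fractions[frozenset(["b1"])]
        assert abs(unique1) < 1e-9
        assert shared > 0.1

    def test_true_gradient_dominates_residual(self):
        tab, grad, rng = self._community()
        b1 = pd.DataFrame({"grad": grad}, index=tab.sample_ids)
        b2 = pd.DataFrame({"noise": rng.normal(size=len(grad))},
                          index=tab.sample_ids)
        res = vpa(tab, {"env": b1, "noise": b2})
        assert res.fractions[frozenset(["env"])] > res.residual

    def test_noise_predictors_near_zero(self):
        tab, grad, rng = self._community(seed=3)
        b1 = pd.DataFrame(rng.normal(size=(16, 2)), index=tab.sample_ids,
                          columns=["n1", "n2"])
        b2 = pd.DataFrame(rng.normal(size=(16, 2)), index=tab.sample_ids,
                          columns=["n3", "n4"])
        res = vpa(tab, {"a": b1, "b": b2})
        total = 1 - res.residual
        assert abs(total) < 0.25

    def test_inclusion_exclusion_identity(self):
        tab, grad, rng = self._community(seed=4)
        blocks = {k: pd.DataFrame(rng.normal(size=(16, 2)),
                                  index=tab.sample_ids,
                                  columns=[f"{k}1", f"{k}2"])
                  for k in ("x", "y", "z")}
        res = vpa(tab, blocks)
        assert sum(res.fractions.values()) + res.residual == pytest.approx(
            1.0, abs=1e-9)
        full = res.combined[frozenset(["x", "y", "z"])]
        # all seven fractions rebuild the full-model adjusted R2
        assert sum(res.fractions.values()) == pytest.approx(full, abs=1e-9)
        # the unique fraction of x is adjR2(full) - adjR2(without x)
        assert res.fractions[frozenset(["x"])] == pytest.approx(
            full - res.combined[frozenset(["y", "z"])], abs=1e-9)


class TestOrdinationRegression:
    def test_axis_equal_to_variable_r2_one(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        dm = euclid_dm(pts)
        ords = pcoa(dm)
        soil = pd.DataFrame({"v": ords.samples.iloc[:, 0],
                             "noise": rng.normal(size=10)},
                            index=ords.samples.index)
        res = ordination_regression(ords, soil)
        top = res.set_index("variable")
        assert top.loc["v", "R2"] == pytest.approx(1.0, abs=1e-10)

    def test_planted_effect_order_recovered(self):
        rng = np.random.default_rng(1)
        axis = np.linspace(-1, 1, 30)
        soil = pd.DataFrame({
            "strong": 0.8 * axis + rng.normal(0, 0.2, 30),
            "weak": 0.2 * axis + rng.normal(0, 0.2, 30)},
            index=[f"s{i}" for i in range(30)])
        ords = pca_ordination(pd.DataFrame({"a": axis}, index=soil.index))
        res = ordination_regression(ords, soil)
        assert list(res["variable"]) == ["strong", "weak"]


class TestGroupTests:
    def test_exact_ranksum_p(self):
        values = pd.Series([1, 2, 3, 4, 5, 6.0],
                           index=[f"s{i}" for i in range(6)])
        groups = ["a", "a", "a", "b", "b", "b"]
        res = group_difference_tests(values, groups)
        # exhaustive enumeration: 2 of C(6,3)=20 assignments are as
        # extreme -> two-sided p = 0.1
        assert res.loc[0, "p_value"] == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        values = pd.Series([5.0] * 6, index=[f"s{i}" for i in range(6)])
        res = group_difference_tests(values, ["a"] * 3 + ["b"] * 3)
        assert res.loc[0, "p_value"] == 1.0

    def test_kruskal_three_groups_and_bh(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            {"f1": rng.normal(size=9), "f2": rng.normal(size=9)},
            index=[f"s{i}" for i in range(9)])
        res = group_difference_tests(values, ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
                                     test="kruskal_wallis", mtc="BH")
        assert "q_value" in res.columns
        assert (res["q_value"] >= res["p_value"] - 1e-12).all()


class TestSpearmanHeatmap:
    def test_monotone_extremes(self):
        idx = [f"s{i}" for i in range(6)]
        taxa = pd.DataFrame({"up": [1, 2, 3, 4, 5, 6],
                             "down": [6, 5, 4, 3, 2, 1]}, index=idx,
                            dtype=float)
        soil = pd.DataFrame({"pH": [4, 5, 6, 7, 8, 9.0]}, index=idx)
        res = spearman_heatmap(taxa, soil).set_index(["taxon", "variable"])
        assert res.loc[("up", "pH"), "rho"] == pytest.approx(1.0)
        assert res.loc[("down", "pH"), "rho"] == pytest.approx(-1.0)

    def test_tied_case_matches_manual_ranks(self):
        from scipy.stats import rankdata
        idx = [f"s{i}" for i in range(5)]
        a = pd.DataFrame({"t": [1.0, 2.0, 2.0, 3.0, 4.0]}, index=idx)
        b = pd.DataFrame({"v": [2.0, 2.0, 5.0, 7.0, 7.0]}, index=idx)
        res = spearman_heatmap(a, b)
        ra, rb = rankdata(a["t"]), rankdata(b["v"])
        expected = np.corrcoef(ra, rb)[0, 1]
        assert res.loc[0, "rho"] == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_flagged_na(self):
        idx = [f"s{i}" for i in range(5)]
        a = pd.DataFrame({"t": [1.0, 1.0, 1.0, 1.0, 1.0]}, index=idx)
        b = pd.DataFrame({"v": [1.0, 2.0, 3.0, 4.0, 5.0]}, index=idx)
        res = spearman_heatmap(a, b)
        assert np.isnan(res.loc[0, "rho"])
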