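import numpy as np
import pandas as pd
import pytest

from proteopath.graphical_regression import PathwayScores
from proteopath.io import ValidationError
from proteopath.stratify import (
    aberration_scores,
    avatar_links,
    cluster_composition,
    cluster_samples,
    pairwise_correlations,
    status_contrast,
)


def ps(sample_ids, pathway, k_rows, lineage="l"):
    return PathwayScores(samples=list(sample_ids), pathway=pathway, lineage=lineage,
                         k=np.asarray(k_rows, dtype=float))


class TestAberration:
    def test_values_are_one_minus_k0(self):
        scores = [
            ps(["s1", "s2"], "pw1", [[0.2, 0.5, 0.3], [0.0, 1.0, 0.0]]),
            ps(["s1", "s2"], "pw2", [[1.0, 0.0, 0.0], [0.1, 0.8, 0.1]]),
        ]
        ab = aberration_scores(scores)
        assert ab.loc["s1", "pw1"] == pytest.approx(0.5)
        assert ab.loc["s2", "pw1"] == pytest.approx(0.0)
        assert ab.loc["s1", "pw2"] == pytest.approx(1.0)
        # aberration + k0 = 1 exactly
        assert np.allclose(ab.loc["s2"], 1.0 - np.array([1.0, 0.8]))

    def test_missing_combination_rejected(self):
        scores = [
            ps(["s1", "s2"], "pw1", [[0.2, 0.5, 0.3], [0.0, 1.0, 0.0]]),
            ps(["s1"], "pw2", [[1.0, 0.0, 0.0]]),
        ]
        with pytest.raises(ValidationError, match="pw2"):
            aberration_scores(scores)


class TestPairwiseCorrelations:
    def _mats(self):
        pat = pd.DataFrame([[0.1, 0.5, 0.9], [0.9, 0.5, 0.1]], index=["p1", "p2"],
                           columns=["a", "b", "c"])
        cl = pd.DataFrame([[0.2, 0.6, 1.0], [0.5, 0.5, 0.5]], index=["c1", "c2"],
                          columns=["a", "b", "c"])
        return pat, cl

    def test_identical_and_negated_vectors(self):
        pat, cl = self._mats()
        r = pairwise_correlations(pat, cl)
        assert r.loc["p1", "c1"] == pytest.approx(1.0)
        assert r.loc["p2", "c1"] == pytest.approx(-1.0)

    def test_constant_vector_flagged_undefined(self):
        pat, cl = self._mats()
        r = pairwise_correlations(pat, cl)
        assert np.isnan(r.loc["p1", "c2"]) and np.isnan(r.loc["p2", "c2"])

    def test_pathway_mismatch_rejected(self):
        pat, cl = self._mats()
        with pytest.raises(ValidationError):
            pairwise_correlations(pat, cl[["b", "a", "c"]])


class TestAvatarLinks:
    def _corr(self, values):
        pat_idx = [f"p{i}" for i in range(values.shape[0])]
        cl_idx = [f"c{i}" for i in range(values.shape[1])]
        corr = pd.DataFrame(values, index=pat_idx, columns=cl_idx)
        lin = pd.Series("LIN", index=pat_idx + cl_idx)
        return corr, lin

    def test_eighty_percent_links(self):
        vals = np.full((2, 5), 0.95)
        vals[0, 0] = vals[0, 1] = 0.1  # 8 of 10 pairs qualify
        corr, lin = self._corr(vals)
        out = avatar_links(corr, lin, lin)
        assert out.loc[0, "percent_pairs"] == pytest.approx(80.0)
        assert bool(out.loc[0, "linked"])

    def test_seventy_percent_does_not_link(self):
        vals = np.full((2, 5), 0.95)
        vals[0, :3] = 0.1  # 7 of 10
        corr, lin = self._corr(vals)
        out = avatar_links(corr, lin, lin)
        assert out.loc[0, "percent_pairs"] == pytest.approx(70.0)
        assert not bool(out.loc[0, "linked"])

    def test_magnitude_rule_and_undefined_exclusion(self):
        vals = np.array([[-0.95, np.nan], [-0.92, np.nan]])
        corr, lin = self._corr(vals)
        out = avatar_links(corr, lin, lin)
        assert out.loc[0, "n_pairs"] == 2 and out.loc[0, "n_undefined"] == 2
        assert bool(out.loc[0, "linked"])  # |r| >= 0.9 on all defined pairs

    def test_symmetry_under_system_swap(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(-1, 1, size=(6, 4))
        corr, _ = self._corr(vals)
        lin_p = pd.Series(["A"] * 3 + ["B"] * 3, index=corr.index)
        lin_c = pd.Series(["x"] * 2 + ["y"] * 2, index=corr.columns)
        fwd = avatar_links(corr, lin_p, lin_c)
        rev = avatar_links(corr.T, lin_c, lin_p)
        merged = fwd.merge(
            rev,
            left_on=["patient_lineage", "cellline_lineage"],
            right_on=["cellline_lineage", "patient_lineage"],
        )
        assert np.allclose(merged["percent_pairs_x"], merged["percent_pairs_y"])


class TestClustering:
    def _planted(self, K, n=30, P=8, seed=0):
        rng = np.random.default_rng(seed)
        cent = rng.normal(0, 3, size=(K, P))
        X = np.vstack([c + rng.normal(0, 1, size=(n, P)) for c in cent])
        labels = np.repeat(np.arange(K), n)
        idx = [f"s{i:03d}" for i in range(len(X))]
        return pd.DataFrame(X, index=idx), labels

    def test_three_planted_groups_recovered(self):
        ab, truth = self._planted(3, seed=1)
        res = cluster_samples(ab, k_max=8, gap_B=50, seed=0)
        assert res.K == 3
        # perfect agreement up to label permutation
        ct = pd.crosstab(res.labels.to_numpy(), truth)
        assert (ct.max(axis=1) == ct.sum(axis=1)).all()

    def test_near_identical_samples_single_cluster(self):
        rng = np.random.default_rng(2)
        base = np.array([0.1, 0.9, 0.4, 0.6])
        ab = pd.DataFrame(base + rng.uniform(-5e-7, 5e-7, size=(20, 4)),
                          index=[f"s{i}" for i in range(20)])
        res = cluster_samples(ab, k_max=5, gap_B=30, seed=0)
        assert res.K == 1

    def test_determinism_and_row_order_invariance(self):
        ab, _ = self._planted(2, seed=3)
        res1 = cluster_samples(ab, k_max=6, gap_B=30, seed=5)
        res2 = cluster_samples(ab.sample(frac=1.0, random_state=0), k_max=6, gap_B=30, seed=5)
        assert res1.K == res2.K
        assert res1.labels.sort_index().equals(res2.labels.sort_index())

    def test_constant_rows_removed_with_warning(self):
        ab, _ = self._planted(2, seed=4)
        ab.loc["flat"] = 0.5
        with pytest.warns(UserWarning, match="constant"):
            res = cluster_samples(ab, k_max=6, gap_B=20, seed=0)
        assert "flat" not in res.labels.index


class TestComposition:
    def _result(self):
        ab, _ = TestClustering()._planted(2, n=10, seed=6)
        return cluster_samples(ab, k_max=4, gap_B=20, seed=0)

    def test_fractions(self):
        res = self._result()
        ann = pd.DataFrame(
            {"lineage": ["lungA"] * 10 + ["lungB"] * 10,
             "system": ["patient"] * 10 + ["cell_line"] * 10},
            index=res.labels.index,
        )
        comp = cluster_composition(res, ann)
        # fractions of each lineage sum to 1 across clusters
        sums = comp.groupby("lineage")["fraction_of_lineage"].sum()
        assert np.allclose(sums, 1.0)
        pure = comp[comp["lineage"] == "lungA"].iloc[0]
        assert pure["cluster_patient_fraction"] + pure["cluster_cellline_fraction"] == pytest.approx(1.0)


class TestStatusContrast:
    def _result_two_clusters(self):
        ab = pd.DataFrame(
            np.vstack([np.tile([0.9, 0.1, 0.1, 0.1], (50, 1)),
                       np.tile([0.1, 0.9, 0.9, 0.9], (50, 1))])
            + np.random.default_rng(0).normal(0, 0.01, (100, 4)),
            index=[f"s{i:03d}" for i in range(100)],
        )
        return cluster_samples(ab, k_max=4, gap_B=20, seed=0)

    def test_opposite_statuses_highly_significant(self):
        res = self._result_two_clusters()
        c1, c2 = sorted(res.labels.unique())[:2]
        statuses = pd.Series(
            ["suppressed" if res.labels[s] == c1 else "activated" for s in res.labels.index],
            index=res.labels.index,
        )
        out = status_contrast(statuses, res, (c1, c2))
        assert out["p_value"] < 1e-6
        assert np.allclose(out["percentages"].sum(axis=0), 100.0)

    def test_identical_statuses_not_significant(self):
        res = self._result_two_clusters()
        c1, c2 = sorted(res.labels.unique())[:2]
        statuses = pd.Series("neutral", index=res.labels.index)
        out = status_contrast(statuses, res, (c1, c2))
        assert out["chi2"] == pytest.approx(0.0, abs=1e-9)
        assert out["p_value"] == pytest.approx(1.0)
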