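import numpy as np
import pandas as pd
import pytest

from proteopath.bart import BartClassifier
from proteopath.drugpredict import (
    binarize_response,
    cv_auc,
    fit_drug_model,
    pathway_pair_synergy,
    predict_patients,
    top_predictor_summary,
)
from proteopath.io import DrugResponsePanel

PATHWAYS = [f"pw{i}" for i in range(12)]


def make_aberration(n=60, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.uniform(0, 1, (n, len(PATHWAYS))), columns=PATHWAYS,
                        index=[f"c{i:03d}" for i in range(n)])


def driven_response(ab, driver="pw3", weight=3.0, noise=0.5, seed=0):
    rng = np.random.default_rng(seed)
    latent = weight * ab[driver] + rng.normal(0, noise, len(ab))
    return (latent > latent.median()).astype(int)


class TestBinarize:
    def test_median_split_with_ties_resistant(self):
        panel = DrugResponsePanel(
            pd.DataFrame({"d": [1.0, 2.0, 3.0, 4.0, 5.0]}, index=[f"c{i}" for i in range(5)])
        )
        out = binarize_response(panel)
        assert out.values["d"].tolist() == [1.0, 1.0, 0.0, 0.0, 0.0]

    def test_binary_panel_passes_through(self):
        panel = DrugResponsePanel(
            pd.DataFrame({"d": [0.0, 1.0]}, index=["c1", "c2"]), binary=True
        )
        assert binarize_response(panel) is panel

    def test_constant_drug_dropped(self):
        panel = DrugResponsePanel(
            pd.DataFrame({"d": [2.0] * 12, "e": np.arange(12.0)},
                         index=[f"c{i}" for i in range(12)])
        )
        out = binarize_response(panel)
        assert out.drugs == ["e"]


class TestFitDrugModel:
    def test_nine_profiles_skipped(self):
        ab = make_aberration(n=9)
        resp = pd.Series([0, 1] * 4 + [0], index=ab.index)
        assert fit_drug_model(ab, resp, drug="d") is None

    def test_single_class_skipped(self):
        ab = make_aberration(n=20)
        resp = pd.Series(1, index=ab.index)
        assert fit_drug_model(ab, resp, drug="d") is None

    def test_planted_driver_is_top_predictor_and_deterministic(self):
        ab = make_aberration(n=60, seed=1)
        resp = driven_response(ab, driver="pw3", noise=0.0, seed=1)
        m1 = fit_drug_model(ab, resp, drug="d", seed=2)
        m2 = fit_drug_model(ab, resp, drug="d", seed=2)
        assert m1.importance.idxmax() == "pw3"
        assert np.allclose(m1.importance.to_numpy(), m2.importance.to_numpy())
        assert np.isclose(m1.importance.sum(), 1.0)

    def test_importance_permutation_equivariance(self):
        ab = make_aberration(n=40, seed=3)
        resp = driven_response(ab, driver="pw5", seed=3)
        m = fit_drug_model(ab, resp, drug="d", seed=4)
        perm = list(reversed(PATHWAYS))
        m_perm = fit_drug_model(ab[perm], resp, drug="d", seed=4)
        assert np.allclose(
            m.importance.reindex(PATHWAYS).to_numpy(),
            m_perm.importance.reindex(PATHWAYS).to_numpy(),
            atol=0.06,
        )


class TestCvAuc:
    def test_perfectly_separable_response(self):
        ab = make_aberration(n=40, seed=5)
        resp = (ab["pw0"] > ab["pw0"].median()).astype(int)
        auc = cv_auc(ab, resp, seed=0)
        assert auc > 0.95

    def test_null_response_near_chance(self):
        ab = make_aberration(n=60, seed=6)
        rng = np.random.default_rng(6)
        resp = pd.Series(rng.integers(0, 2, len(ab)), index=ab.index)
        auc = cv_auc(ab, resp, seed=0)
        assert 0.3 < auc < 0.7


class TestSummaries:
    def _models(self):
        models = []
        for i, (top, auc) in enumerate([("pw1", 0.9), ("pw1", 0.88), ("pw2", 0.95), ("pw3", 0.5)]):
            imp = pd.Series(0.02, index=PATHWAYS)
            imp[top] = 0.5
            imp["pw4"] = 0.3
            imp /= imp.sum()
            ab = make_aberration(n=12, seed=i)
            resp = pd.Series([0, 1] * 6, index=ab.index)
            m = fit_drug_model(ab, resp, drug=f"d{i}", trees=5, draws=60, burn=20, seed=i)
            m.cv_auc = auc
            m.importance = imp
            models.append(m)
        return models

    def test_top_predictor_proportions_and_transform(self):
        out = top_predictor_summary(self._models(), auc_cutoff=0.85).set_index("pathway")
        assert out.loc["pw1", "proportion"] == pytest.approx(2 / 3)
        assert out.loc["pw2", "proportion"] == pytest.approx(1 / 3)
        assert out.loc["pw1", "log1p_proportion"] == pytest.approx(np.log(1 + 2 / 3))
        # all-top case: proportions sum to 1
        assert out["proportion"].sum() == pytest.approx(1.0)

    def test_no_qualifying_drugs_empty(self):
        models = self._models()
        for m in models:
            m.cv_auc = 0.2
        assert top_predictor_summary(models).empty

    def test_synergy_pair_counts_sum_to_qualifying_models(self):
        out = pathway_pair_synergy(self._models(), auc_cutoff=0.85)
        assert out["count"].sum() == 3
        top_pair = out.sort_values("count", ascending=False).iloc[0]
        assert {top_pair["pathway_a"], top_pair["pathway_b"]} == {"pw1", "pw4"}


class TestPredictPatients:
    def test_probabilities_and_monotonicity_in_driver(self):
        ab = make_aberration(n=60, seed=8)
        resp = driven_response(ab, driver="pw2", noise=0.2, seed=8)
        m = fit_drug_model(ab, resp, lineage="cl_lung", drug="d", seed=9)
        sweep = pd.DataFrame(
            np.tile(np.full(len(PATHWAYS), 0.5), (11, 1)), columns=PATHWAYS,
            index=[f"p{i:02d}" for i in range(11)],
        )
        sweep["pw2"] = np.linspace(0, 1, 11)
        lineages = pd.Series("LUNG", index=sweep.index)
        probs, rate = predict_patients(m, sweep, lineages, {"LUNG": "cl_lung"})
        assert probs.between(0, 1).all() and 0 <= rate <= 1
        # predicted sensitivity never decreases along the driver sweep (tolerance for MC noise)
        diffs = np.diff(probs.to_numpy())
        assert diffs.min() > -0.05
        assert probs.iloc[-1] > probs.iloc[0]

    def test_unmapped_lineage_rejected(self):
        ab = make_aberration(n=20, seed=9)
        resp = driven_response(ab, seed=9)
        m = fit_drug_model(ab, resp, lineage="cl_skin", drug="d", seed=1)
        lineages = pd.Series("LUNG", index=ab.index)
        with pytest.raises(Exception, match="map"):
            predict_patients(m, ab, lineages, {"LUNG": "cl_other"})

    def test_pathway_mismatch_rejected(self):
        ab = make_aberration(n=20, seed=10)
        resp = driven_response(ab, seed=10)
        m = fit_drug_model(ab, resp, lineage="cl", drug="d", seed=1)
        lineages = pd.Series("LUNG", index=ab.index)
        with pytest.raises(Exception, match="mismatch"):
            predict_patients(m, ab[list(reversed(PATHWAYS))], lineages, {"LUNG": "cl"})


class TestBartUnit:
    def test_requires_both_classes(self):
        X = np.random.default_rng(0).uniform(0, 1, (20, 3))
        with pytest.raises(ValueError):
            BartClassifier(n_trees=5, n_draws=50, n_burn=10).fit(X, np.zeros(20, dtype=int))

    def test_train_point_probabilities_track_labels(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (50, 4))
        y = (X[:, 0] > 0.5).astype(int)
        m = BartClassifier(n_trees=20, n_draws=400, n_burn=100, random_state=0).fit(X, y)
        p = m.predict_proba(X)[:, 1]
        assert p[y == 1].mean() > 0.7 and p[y == 0].mean() < 0.3
        assert np.array_equal(m.predict(X), (p > 0.5).astype(int))
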