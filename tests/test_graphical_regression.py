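import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from proteopath.graphical_regression import (
    MCMCSettings,
    aggregate_pathway_scores,
    call_edges,
    exact_posterior_oracle,
    fit_cancer_network,
    score_cross_system,
    score_samples,
    SampleScores,
    _argmax_status,
)
from proteopath.io import ValidationError
from proteopath.synthetic import simulate_lineage, simulate_network

from conftest import study_from_matrix

FAST = MCMCSettings(iterations=4000, burn_in=1000, seed=7)


def chain_study(n=300, seed=0):
    # 3-protein chain A-B-C with partial correlations 0.5
    omega = np.array([[1.0, -0.5, 0.0], [-0.5, 1.3, -0.5], [0.0, -0.5, 1.0]])
    rng = np.random.default_rng(seed)
    X = rng.multivariate_normal(np.zeros(3), np.linalg.inv(omega), size=n)
    return study_from_matrix(X, proteins=list("ABC"))


class TestFit:
    def test_chain_recovered(self):
        net = fit_cancer_network(chain_study(), FAST, pathway="pw")
        prot = net.proteins
        assert net.ppi[prot.index("A"), prot.index("B")] > 0.9
        assert net.ppi[prot.index("B"), prot.index("C")] > 0.9
        assert net.ppi[prot.index("A"), prot.index("C")] < 0.5

    def test_null_data_ppi_near_prior(self):
        rng = np.random.default_rng(1)
        study = study_from_matrix(rng.standard_normal((300, 5)))
        net = fit_cancer_network(study, MCMCSettings(iterations=8000, burn_in=2000, seed=1))
        oracle = exact_posterior_oracle(study, FAST)
        iu = np.triu_indices(5, 1)
        assert np.abs(net.ppi[iu] - oracle[iu]).max() < 0.05
        assert np.abs(net.ppi[iu] - FAST.prior_inclusion).max() < 0.15 + 0.2  # loose sanity

    def test_insufficient_samples_rejected(self):
        rng = np.random.default_rng(0)
        study = study_from_matrix(rng.standard_normal((5, 3)))
        with pytest.raises(ValidationError, match="insufficient samples"):
            fit_cancer_network(study, FAST)

    def test_zero_variance_protein_named(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 3))
        X[:, 1] = 2.0
        with pytest.raises(ValidationError, match="P1"):
            fit_cancer_network(study_from_matrix(X), FAST)

    def test_mcmc_determinism(self):
        study = chain_study(n=100, seed=3)
        a = fit_cancer_network(study, FAST)
        b = fit_cancer_network(study, FAST)
        assert np.array_equal(a.ppi, b.ppi)
        assert np.array_equal(a.coef, b.coef)


class TestOracle:
    def test_perfect_correlation_certain_edge(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(100)
        X = np.column_stack([x, x + 1e-6 * rng.standard_normal(100)])
        ppi = exact_posterior_oracle(study_from_matrix(X), FAST)
        assert ppi[0, 1] > 0.99

    def test_protein_limit_enforced(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValidationError, match="oracle"):
            exact_posterior_oracle(study_from_matrix(rng.standard_normal((50, 6))), FAST)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gibbs_matches_enumeration(self, seed):
        # sampler and exact enumeration agree on 4-protein slices
        truth = simulate_network(4, 0.4, seed=seed)
        X, _ = simulate_lineage(truth, 150, seed=seed)
        study = study_from_matrix(X)
        mc = MCMCSettings(iterations=20000, burn_in=5000, seed=seed)
        net = fit_cancer_network(study, mc)
        oracle = exact_posterior_oracle(study, mc)
        assert np.abs(net.ppi - oracle).max() < 0.05


class TestCallEdges:
    def _net(self, val):
        net = fit_cancer_network(chain_study(n=50), FAST, pathway="pw")
        net.ppi = np.array([[0.0, val], [val, 0.0]])
        net.proteins = ["A", "B"]
        return net

    def test_strictly_above_threshold_included(self):
        assert call_edges(self._net(0.51)) == {("A", "B")}

    def test_exactly_at_threshold_excluded(self):
        assert call_edges(self._net(0.5)) == set()

    def test_all_zero_matrix_empty(self):
        assert call_edges(self._net(0.0)) == set()

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            call_edges(self._net(0.6), threshold=1.5)


class TestScoring:
    def test_sample_at_predictive_mean_is_neutral_and_symmetric(self):
        study = chain_study(n=200, seed=5)
        net = fit_cancer_network(study, FAST)
        center = study_from_matrix(net.center[None, :], proteins=net.proteins)
        ss = score_samples(net, center)
        p_plus, p_zero, p_minus = ss.p[0, :, 0], ss.p[0, :, 1], ss.p[0, :, 2]
        assert np.allclose(p_plus, p_minus, atol=1e-12)
        assert (p_zero > p_plus).all()

    def test_large_positive_shift_scores_activated(self):
        truth = simulate_network(5, 0.0, seed=1)
        Xb, _ = simulate_lineage(truth, 200, seed=1)
        net = fit_cancer_network(study_from_matrix(Xb), FAST)
        shifted = net.center + 5.0 * net.scale * np.sqrt(net.sigma2)
        ss = score_samples(net, study_from_matrix(shifted[None, :], start=900))
        assert (ss.p[0, :, 0] > 0.95).all()

    def test_triples_sum_to_one(self):
        study = chain_study(n=120, seed=8)
        net = fit_cancer_network(study, FAST)
        ss = score_samples(net, study)
        assert np.allclose(ss.p.sum(axis=2), 1.0, atol=1e-12)

    def test_cross_system_scoring_is_score_samples_on_training_slice(self):
        study = chain_study(n=100, seed=9)
        net = fit_cancer_network(study, FAST)
        a = score_samples(net, study)
        b = score_cross_system(net, study)
        assert np.array_equal(a.p, b.p)

    def test_shifting_a_neutral_sample_moves_mass_upward(self):
        study = chain_study(n=200, seed=10)
        net = fit_cancer_network(study, FAST)
        base = study_from_matrix(net.center[None, :], proteins=net.proteins)
        shifted = study_from_matrix((net.center + net.scale)[None, :], proteins=net.proteins, start=1)
        p0 = score_samples(net, base).p[0]
        p1 = score_samples(net, shifted).p[0]
        assert (p1[:, 0] >= p0[:, 0] - 1e-12).all() and p1[:, 0].mean() > p0[:, 0].mean()

    def test_missing_protein_rejected(self):
        study = chain_study(n=100)
        net = fit_cancer_network(study, FAST)
        with pytest.raises(ValidationError, match="mismatch"):
            score_samples(net, study.slice(proteins=["A", "B"]))


class TestAggregation:
    def test_single_protein_passthrough_and_tie_rule(self):
        ss = SampleScores(
            samples=["s1"], proteins=["A"], pathway="pw", lineage="l",
            p=np.array([[[0.2, 0.5, 0.3]]]),
        )
        ps = aggregate_pathway_scores(ss)
        assert np.allclose(ps.k[0], [0.2, 0.5, 0.3])
        assert ps.status[0] == "neutral"

    def test_exact_tie_resolves_to_neutral(self):
        ss = SampleScores(
            samples=["s1"], proteins=["A", "B"], pathway="pw", lineage="l",
            p=np.array([[[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]]),
        )
        ps = aggregate_pathway_scores(ss)
        assert np.allclose(ps.k[0], [0.5, 0.5, 0.0])
        assert ps.status[0] == "neutral"

    def test_argmax_status_labels(self):
        assert _argmax_status(np.array([0.6, 0.3, 0.1])) == "activated"
        assert _argmax_status(np.array([0.1, 0.3, 0.6])) == "suppressed"
        assert _argmax_status(np.array([0.45, 0.1, 0.45])) == "neutral"

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.floats(0.01, 1), st.floats(0.01, 1), st.floats(0.01, 1)),
                    min_size=1, max_size=6))
    def test_simplex_conservation_property(self, raw):
        # pathway triples remain on the simplex for any per-protein simplex input
        arr = np.array(raw, dtype=float)
        arr = arr / arr.sum(axis=1, keepdims=True)
        ss = SampleScores(
            samples=["s"], proteins=[f"P{i}" for i in range(len(raw))],
            pathway="pw", lineage="l", p=arr[None, :, :],
        )
        ps = aggregate_pathway_scores(ss)
        assert ps.k.min() >= 0 and ps.k.max() <= 1
        assert np.allclose(ps.k.sum(axis=1), 1.0, atol=1e-8)
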