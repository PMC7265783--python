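"""Cancer-specific network inference and sample-specific pathway scoring.

The population model for one lineage x pathway slice is a node-wise Bayesian
graphical regression: each standardized protein is regressed on all other
pathway proteins with spike-and-slab selection,

    x_i = sum_{k != i} gamma_ik beta_ik x_k + eps_i,
    gamma_ik ~ Bernoulli(pi),  beta_ik | sigma2 ~ N(0, tau2 sigma2),
    sigma2 ~ Inverse-Gamma(a, b).

The posterior inclusion probability (PPI) of the directed pair (i, k) is the
posterior frequency of gamma_ik; the undirected edge PPI is, by default, the
maximum over the two directions. Deconvolution to sample scores asks, per
sample and protein, whether the observed value sits in the upper tail (+),
lower tail (-) or bulk (0) of its posterior-predictive distribution given the
sample's other proteins; pathway-level scores average the per-protein triples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr
from sklearn.base import BaseEstimator

from ._gibbs import gibbs_node, log_marginal_likelihood
from .io import ExpressionStudy, ValidationError

__all__ = [
    "MCMCSettings",
    "CancerNetwork",
    "SampleScores",
    "PathwayScores",
    "BayesianGraphicalRegression",
    "fit_cancer_network",
    "exact_posterior_oracle",
    "call_edges",
    "score_samples",
    "score_cross_system",
    "aggregate_pathway_scores",
]

MIN_SAMPLES = 10


@dataclass(frozen=True)
class MCMCSettings:
    """Gibbs sampler settings for the graphical regression."""

    iterations: int = 20_000
    burn_in: int = 5_000
    seed: int = 0
    prior_inclusion: float = 0.2
    tau2: float = 1.0
    ig_a: float = 2.0
    ig_b: float = 1.0
    symmetrize: str = "max"  # max | mean | and


@dataclass
class CancerNetwork:
    """Fitted lineage x pathway network.

    ``ppi`` holds symmetrized posterior edge-inclusion probabilities, ``coef``
    the directed posterior-mean regression coefficients (row = response node),
    ``sigma2`` the per-node posterior-mean residual variance, and ``center`` /
    ``scale`` the training-slice standardization reused when scoring samples
    from another system.
    """

    lineage: str
    pathway: str
    proteins: list[str]
    ppi: np.ndarray
    coef: np.ndarray
    sigma2: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    n_samples: int
    sampler_meta: MCMCSettings
    system: str = "patient"

    def __post_init__(self) -> None:
        p = len(self.proteins)
        if self.ppi.shape != (p, p):
            raise ValidationError("ppi shape mismatch")
        if not np.allclose(self.ppi, self.ppi.T):
            raise ValidationError("ppi must be symmetric")
        if np.any(np.diag(self.ppi) != 0):
            raise ValidationError("ppi diagonal must be zero")
        if self.ppi.min() < 0 or self.ppi.max() > 1:
            raise ValidationError("ppi entries must lie in [0, 1]")
        if not np.all(np.isfinite(self.coef)):
            raise ValidationError("coef must be finite")


@dataclass
class SampleScores:
    """Per sample x protein status triples (p+, p0, p-), each row-triple on the simplex."""

    samples: list[str]
    proteins: list[str]
    pathway: str
    lineage: str
    p: np.ndarray  # (n_samples, n_proteins, 3) -> (+, 0, -)

    def __post_init__(self) -> None:
        sums = self.p.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValidationError("sample score triples must sum to 1")
        if self.p.min() < -1e-12 or self.p.max() > 1 + 1e-12:
            raise ValidationError("sample scores must lie in [0, 1]")


STATUSES = ("activated", "neutral", "suppressed")


@dataclass
class PathwayScores:
    """Aggregated per-sample pathway triples (k+, k0, k-) with argmax status."""

    samples: list[str]
    pathway: str
    lineage: str
    k: np.ndarray  # (n_samples, 3) -> (+, 0, -)
    status: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.allclose(self.k.sum(axis=1), 1.0, atol=1e-8):
            raise ValidationError("pathway score triples must sum to 1")
        if not self.status:
            self.status = [_argmax_status(row) for row in self.k]

    @property
    def aberration(self) -> np.ndarray:
        """Network aberration score k+ + k- = 1 - k0."""
        return self.k[:, 0] + self.k[:, 2]


def _argmax_status(triple: np.ndarray) -> str:
    """Argmax of (k+, k0, k-); any tie involving the maximum resolves to neutral."""
    kp, k0, km = triple
    m = max(kp, k0, km)
    winners = [s for s, v in zip(("activated", "neutral", "suppressed"), (kp, k0, km)) if v == m]
    return winners[0] if len(winners) == 1 else "neutral"


def _standardize(X: np.ndarray, proteins: list[str]):
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    zero = np.where(scale == 0)[0]
    if zero.size:
        raise ValidationError(f"zero-variance protein: {proteins[zero[0]]}")
    return (X - center) / scale, center, scale


class BayesianGraphicalRegression(BaseEstimator):
    """Spike-and-slab node-wise graphical regression, scikit-learn style.

    ``fit(X)`` learns the network over the columns of ``X`` (one lineage x
    pathway slice, samples in rows); ``transform(X)`` returns the per-sample,
    per-protein status triples stacked as ``(n_samples, n_proteins, 3)``.

    Parameters
    ----------
    iterations, burn_in, random_state : Gibbs chain length and seed.
    prior_inclusion : Bernoulli prior on each directed edge indicator.
    tau2 : slab variance multiplier (relative to the noise variance).
    ig_a, ig_b : Inverse-Gamma prior on the node noise variance.
    symmetrize : how directed PPIs combine into an undirected edge
        probability: ``max`` (default), ``mean`` or ``and`` (product).
    tail_cutoff : ``c``; number of predictive standard deviations a value
        must exceed for the activated/suppressed tail mass.
    """

    def __init__(
        self,
        iterations: int = 20_000,
        burn_in: int = 5_000,
        prior_inclusion: float = 0.2,
        tau2: float = 1.0,
        ig_a: float = 2.0,
        ig_b: float = 1.0,
        symmetrize: str = "max",
        tail_cutoff: float = 1.0,
        random_state: int = 0,
    ):
        self.iterations = iterations
        self.burn_in = burn_in
        self.prior_inclusion = prior_inclusion
        self.tau2 = tau2
        self.ig_a = ig_a
        self.ig_b = ig_b
        self.symmetrize = symmetrize
        self.tail_cutoff = tail_cutoff
        self.random_state = random_state

    # -- fitting -------------------------------------------------------------

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if n < MIN_SAMPLES:
            raise ValidationError(f"insufficient samples: {n} < {MIN_SAMPLES}")
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        proteins = [str(i) for i in range(p)]
        Z, center, scale = _standardize(X, proteins)
        ppi_dir = np.zeros((p, p))
        coef = np.zeros((p, p))
        sigma2 = np.zeros(p)
        for i in range(p):
            others = [j for j in range(p) if j != i]
            Xo = np.ascontiguousarray(Z[:, others])
            y_i = np.ascontiguousarray(Z[:, i])
            G = Xo.T @ Xo
            g = Xo.T @ y_i
            ppi_i, coef_i, sig_i = gibbs_node(
                G,
                g,
                float(y_i @ y_i),
                n,
                self.tau2,
                self.ig_a,
                self.ig_b,
                self.prior_inclusion,
                self.iterations,
                self.burn_in,
                (int(self.random_state) * 1_000_003 + i) % 2_147_483_647,
            )
            ppi_dir[i, others] = ppi_i
            coef[i, others] = coef_i
            sigma2[i] = sig_i
        self.ppi_directed_ = ppi_dir
        self.ppi_ = symmetrize_ppi(ppi_dir, self.symmetrize)
        self.coef_ = coef
        self.sigma2_ = sigma2
        self.center_ = center
        self.scale_ = scale
        self.n_samples_ = n
        self.n_features_in_ = p
        return self

    # -- deconvolution --------------------------------------------------------

    def transform(self, X) -> np.ndarray:
        """Per-sample, per-protein (p+, p0, p-) triples under the fitted model.

        The standardized predictive residual of protein i in sample j is
        ``z = (x_ij - mu_ij) / s_i`` with ``mu_ij`` the fitted node regression
        mean and ``s_i`` the posterior-mean predictive standard deviation; the
        triple is ``(Phi(z - c), Phi(c - z) - Phi(-c - z), Phi(-z - c))``.
        """
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "ppi_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"expected {self.n_features_in_} proteins, got {X.shape[1]}"
            )
        Z = (X - self.center_) / self.scale_
        mu = Z @ self.coef_.T
        s = np.sqrt(self.sigma2_)
        z = (Z - mu) / s
        c = self.tail_cutoff
        p_plus = ndtr(z - c)
        p_minus = ndtr(-z - c)
        p_zero = 1.0 - p_plus - p_minus
        return np.stack([p_plus, p_zero, p_minus], axis=2)


def symmetrize_ppi(ppi_directed: np.ndarray, rule: str = "max") -> np.ndarray:
    if rule == "max":
        out = np.maximum(ppi_directed, ppi_directed.T)
    elif rule == "mean":
        out = 0.5 * (ppi_directed + ppi_directed.T)
    elif rule == "and":
        out = ppi_directed * ppi_directed.T
    else:
        raise ValueError(f"unknown symmetrization rule {rule!r}")
    np.fill_diagonal(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# Functional surface over ExpressionStudy slices
# ---------------------------------------------------------------------------


def _slice_matrix(study_slice: ExpressionStudy) -> tuple[np.ndarray, list[str], list[str]]:
    return study_slice.values.to_numpy(float), study_slice.samples, study_slice.proteins


def fit_cancer_network(
    study_slice: ExpressionStudy,
    mcmc: MCMCSettings = MCMCSettings(),
    lineage: str | None = None,
    pathway: str = "",
) -> CancerNetwork:
    """Fit the graphical regression on one lineage x pathway slice."""
    X, samples, proteins = _slice_matrix(study_slice)
    lineages = set(study_slice.annotations.loc[samples, "lineage"])
    if lineage is None:
        if len(lineages) != 1:
            raise ValidationError(f"slice spans multiple lineages: {sorted(lineages)}")
        lineage = next(iter(lineages))
    systems = set(study_slice.annotations.loc[samples, "system"])
    system = next(iter(systems)) if len(systems) == 1 else "patient"
    _standardize(X, proteins)  # surfaces zero-variance proteins by name
    est = BayesianGraphicalRegression(
        iterations=mcmc.iterations,
        burn_in=mcmc.burn_in,
        prior_inclusion=mcmc.prior_inclusion,
        tau2=mcmc.tau2,
        ig_a=mcmc.ig_a,
        ig_b=mcmc.ig_b,
        symmetrize=mcmc.symmetrize,
        random_state=mcmc.seed,
    ).fit(X)
    return CancerNetwork(
        lineage=lineage,
        pathway=pathway,
        proteins=proteins,
        ppi=est.ppi_,
        coef=est.coef_,
        sigma2=est.sigma2_,
        center=est.center_,
        scale=est.scale_,
        n_samples=len(samples),
        sampler_meta=mcmc,
        system=system,
    )


MAX_ORACLE_PROTEINS = 5


def exact_posterior_oracle(
    study_slice: ExpressionStudy, mcmc: MCMCSettings = MCMCSettings()
) -> np.ndarray:
    """Exact PPI matrix by predictor-subset enumeration (test oracle, <= 5 proteins).

    Enumerates all 2^(p-1) predictor subsets per node, weights each by its
    closed-form conjugate marginal likelihood times the Bernoulli prior, and
    returns exact posterior inclusion probabilities symmetrized with the same
    rule as the sampler.
    """
    X, _, proteins = _slice_matrix(study_slice)
    n, p = X.shape
    if p > MAX_ORACLE_PROTEINS:
        raise ValidationError(
            f"oracle limited to {MAX_ORACLE_PROTEINS} proteins, got {p}"
        )
    Z, _, _ = _standardize(X, proteins)
    pi = mcmc.prior_inclusion
    ppi_dir = np.zeros((p, p))
    for i in range(p):
        others = [j for j in range(p) if j != i]
        Xo, y = Z[:, others], Z[:, i]
        m = len(others)
        log_w = np.empty(2**m)
        masks = np.arange(2**m)
        for mask in masks:
            sel = np.array([(mask >> k) & 1 for k in range(m)], dtype=bool)
            lml = log_marginal_likelihood(Xo, y, sel, mcmc.tau2, mcmc.ig_a, mcmc.ig_b)
            log_w[mask] = lml + sel.sum() * np.log(pi) + (m - sel.sum()) * np.log(1 - pi)
        w = np.exp(log_w - log_w.max())
        w /= w.sum()
        for k in range(m):
            incl = (masks >> k) & 1
            ppi_dir[i, others[k]] = w[incl == 1].sum()
    return symmetrize_ppi(ppi_dir, mcmc.symmetrize)


def call_edges(network: CancerNetwork, threshold: float = 0.5) -> set[tuple[str, str]]:
    """Unordered protein pairs whose PPI strictly exceeds the threshold."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    prot = network.proteins
    p = len(prot)
    return {
        (prot[i], prot[j])
        for i in range(p)
        for j in range(i + 1, p)
        if network.ppi[i, j] > threshold
    }


def _score_matrix(network: CancerNetwork, study_slice: ExpressionStudy) -> np.ndarray:
    if study_slice.proteins != network.proteins:
        missing = [p for p in network.proteins if p not in study_slice.proteins]
        raise ValidationError(
            f"protein mismatch between network and study slice (missing: {missing})"
        )
    X = study_slice.values.to_numpy(float)
    est = BayesianGraphicalRegression()
    est.ppi_ = network.ppi
    est.coef_ = network.coef
    est.sigma2_ = network.sigma2
    est.center_ = network.center
    est.scale_ = network.scale
    est.n_features_in_ = len(network.proteins)
    return est.transform(X)


def score_samples(network: CancerNetwork, study_slice: ExpressionStudy) -> SampleScores:
    """Deconvolve the fitted network into per-sample protein status triples."""
    p = _score_matrix(network, study_slice)
    return SampleScores(
        samples=study_slice.samples,
        proteins=list(network.proteins),
        pathway=network.pathway,
        lineage=network.lineage,
        p=p,
    )


def score_cross_system(network: CancerNetwork, other_study: ExpressionStudy) -> SampleScores:
    """Score samples from the other model system against this fitted network.

    Identical math to :func:`score_samples`: the training slice's centering
    and scale are reused so scores are comparable across systems.
    """
    return score_samples(network, other_study)


def aggregate_pathway_scores(scores: SampleScores) -> PathwayScores:
    """Average protein triples into pathway triples (k+, k0, k-) per sample."""
    if scores.p.size == 0:
        raise ValidationError("cannot aggregate empty scores")
    k = scores.p.mean(axis=1)
    return PathwayScores(
        samples=list(scores.samples),
        pathway=scores.pathway,
        lineage=scores.lineage,
        k=k,
    )
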