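"""Synthetic multi-lineage proteomic studies with known ground truth.

Expression for each lineage x pathway block is drawn from a zero-mean Gaussian
whose precision matrix has Erdos-Renyi support with signed uniform weights and
an enforced diagonally-dominant (hence positive-definite) diagonal. Pathway
activity statuses are planted as mean shifts on member proteins; binary drug
response is driven by a weighted combination of true pathway aberrations.

Each lineage carries a ``baseline`` cohort (no planted statuses) alongside its
``case`` cohort: baseline samples calibrate the network fit, case samples are
the ones scored downstream. See docs/methods.md for why the split is needed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import DrugResponsePanel, ExpressionStudy, PathwayCatalog

__all__ = [
    "NetworkTruth",
    "GroundTruth",
    "LineagePlan",
    "SimulationConfig",
    "FixtureBundle",
    "simulate_network",
    "simulate_lineage",
    "simulate_drug_response",
    "make_fixture_study",
    "default_config",
]

STATUS_ORDER = ("activated", "neutral", "suppressed")


@dataclass
class NetworkTruth:
    """Ground-truth network for one lineage x pathway block."""

    adjacency: np.ndarray  # symmetric binary, zero diagonal
    precision: np.ndarray  # positive definite
    partial_correlations: np.ndarray

    @property
    def n_proteins(self) -> int:
        return self.adjacency.shape[0]

    @property
    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)

    def edges(self, proteins: list[str]) -> set[tuple[str, str]]:
        p = self.n_proteins
        return {
            (proteins[i], proteins[j])
            for i in range(p)
            for j in range(i + 1, p)
            if self.adjacency[i, j]
        }


@dataclass
class GroundTruth:
    """Full planted truth for a fixture bundle."""

    networks: dict[str, dict[str, NetworkTruth]]  # lineage -> pathway -> truth
    statuses: pd.DataFrame  # case samples x pathways, labels
    drug_weights: pd.DataFrame  # drugs x pathways
    avatar_pair: tuple[str, str]
    nonmatch_pair: tuple[str, str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "avatar_pair": list(self.avatar_pair),
            "nonmatch_pair": list(self.nonmatch_pair),
            "statuses": {
                s: dict(row) for s, row in self.statuses.iterrows()
            },
            "drug_weights": {
                d: dict(row) for d, row in self.drug_weights.iterrows()
            },
            "adjacency": {
                lin: {pw: t.adjacency.astype(int).tolist() for pw, t in pws.items()}
                for lin, pws in self.networks.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def simulate_network(
    n_proteins: int,
    density: float,
    seed: int | np.random.Generator,
    edge_low: float = 0.3,
    edge_high: float = 0.6,
) -> NetworkTruth:
    """Erdos-Renyi support, signed-uniform precision entries, dominant diagonal.

    Off-diagonal precision entries on the support are ``+/- u`` with
    ``u ~ Uniform(edge_low, edge_high)``; the diagonal is set to the absolute
    row sum plus a margin, guaranteeing positive definiteness. If the dominance
    repair shrinks more than 10% of requested edges below a detectable partial
    correlation (|rho| < 0.05) the requested density is considered infeasible.
    """
    if n_proteins < 3:
        raise ValueError("need at least 3 proteins")
    if not 0 <= density <= 1:
        raise ValueError("density must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = n_proteins
    adj = np.zeros((p, p), dtype=bool)
    iu = np.triu_indices(p, 1)
    adj[iu] = rng.random(len(iu[0])) < density
    adj |= adj.T

    omega = np.zeros((p, p))
    mags = rng.uniform(edge_low, edge_high, size=len(iu[0]))
    signs = rng.choice([-1.0, 1.0], size=len(iu[0]))
    omega[iu] = np.where(adj[iu], mags * signs, 0.0)
    omega += omega.T
    # strict diagonal dominance with a 0.5 margin: positive definite by
    # Gershgorin while keeping implied partial correlations detectable; the
    # floor of 1 gives isolated proteins unit variance
    np.fill_diagonal(omega, np.maximum(np.abs(omega).sum(axis=1) + 0.5, 1.0))

    d = np.sqrt(np.diag(omega))
    pcorr = -omega / np.outer(d, d)
    np.fill_diagonal(pcorr, 1.0)

    n_edges = int(adj[iu].sum())
    if n_edges:
        weak = int((np.abs(pcorr[iu][adj[iu]]) < 0.05).sum())
        if weak > 0.1 * n_edges:
            raise ValueError(
                "requested density is too high: positive-definiteness repair "
                "erases more than 10% of edges; lower the density"
            )
    return NetworkTruth(adjacency=adj.astype(int), precision=omega, partial_correlations=pcorr)


def draw_statuses(
    n_samples: int,
    status_fractions: tuple[float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    fa, fn, fs = status_fractions
    if abs(fa + fn + fs - 1.0) > 1e-9:
        raise ValueError("status fractions must sum to 1")
    return rng.choice(np.array(STATUS_ORDER), size=n_samples, p=[fa, fn, fs])


def simulate_lineage(
    network: NetworkTruth,
    n_samples: int,
    status_fractions: tuple[float, float, float] = (0.0, 1.0, 0.0),
    shift: float = 0.0,
    seed: int | np.random.Generator = 0,
    heavy_tail: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one lineage x pathway block plus its planted per-sample statuses.

    Samples come from the zero-mean Gaussian implied by the network's
    precision matrix; ``activated`` samples get ``+shift`` added to every
    pathway protein, ``suppressed`` get ``-shift``. With ``heavy_tail`` the
    Gaussian draw is replaced by a scaled Student-t (df=5) for robustness
    experiments.
    """
    if shift < 0:
        raise ValueError("shift must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = network.n_proteins
    cov = network.covariance
    L = np.linalg.cholesky(cov)
    Z = rng.standard_normal((n_samples, p))
    if heavy_tail:
        df = 5.0
        g = rng.chisquare(df, size=n_samples) / df
        Z = Z / np.sqrt(g)[:, None] * np.sqrt((df - 2) / df)
    X = Z @ L.T
    statuses = draw_statuses(n_samples, status_fractions, rng)
    X[statuses == "activated"] += shift
    X[statuses == "suppressed"] -= shift
    return X, statuses


def simulate_drug_response(
    aberration: pd.DataFrame,
    weights,
    noise_sd: float,
    seed: int | np.random.Generator,
    drug: str = "drug",
) -> DrugResponsePanel:
    """Binary sensitivity labels from a latent pathway-weighted score.

    latent = aberration @ weights + N(0, noise_sd); label 1 iff the latent
    strictly exceeds the cohort median of latents.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != aberration.shape[1]:
        raise ValueError(
            f"weights length {w.shape[0]} != number of pathways {aberration.shape[1]}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    latent = aberration.to_numpy(float) @ w + rng.normal(0.0, noise_sd, size=len(aberration))
    labels = (latent > np.median(latent)).astype(float)
    vals = pd.DataFrame({drug: labels}, index=aberration.index)
    return DrugResponsePanel(vals, binary=True)


# ---------------------------------------------------------------------------
# Full fixture bundles
# ---------------------------------------------------------------------------


@dataclass
class LineagePlan:
    """Per-lineage simulation settings.

    ``share_networks_with`` copies another lineage's ground-truth networks
    (the planted avatar mechanism); ``status_fractions`` maps pathway name to
    an (activated, neutral, suppressed) triple, defaulting to all-neutral.
    """

    name: str
    system: str
    n_cases: int = 60
    n_baseline: int = 100
    densities: dict[str, float] = field(default_factory=dict)
    status_fractions: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    share_networks_with: str | None = None


@dataclass
class SimulationConfig:
    """Study conditions for :func:`make_fixture_study`."""

    pathway_sizes: dict[str, int]
    lineages: list[LineagePlan]
    shift: float = 3.0
    default_density: float = 0.15
    edge_low: float = 0.3
    edge_high: float = 0.6
    drug_weights: dict[str, dict[str, float]] = field(default_factory=dict)
    drug_noise_sd: float = 0.5
    heavy_tail: bool = False
    avatar_pair: tuple[str, str] = ("", "")
    nonmatch_pair: tuple[str, str] = ("", "")

    def validate(self) -> None:
        for system in ("patient", "cell_line"):
            if sum(1 for l in self.lineages if l.system == system) < 1:
                raise ValueError(f"config needs at least one {system} lineage")
        if len(self.pathway_sizes) < 2:
            raise ValueError("config needs at least 2 pathways")
        names = [l.name for l in self.lineages]
        if len(set(names)) != len(names):
            raise ValueError("duplicate lineage names")


def default_config() -> SimulationConfig:
    """The package's reference study conditions.

    Six disjoint 8-protein pathways over four lineages (two per system). The
    planted avatar pair (PAT_A, cl_a) shares every network and status pattern:
    a dense pw1 (high cross-signaling) and coherent activation of pw2/pw3.
    The planted non-match (PAT_B, cl_b) is generated independently with
    structure-free (empty) networks; PAT_B carries its own suppression pattern
    and cl_b a mixed activation in pw2 that drives the example drug.
    """
    pathways = {f"pw{i}": 8 for i in range(1, 7)}
    act = (1.0, 0.0, 0.0)
    sup = (0.0, 0.0, 1.0)
    avatar_pattern = {"pw2": act, "pw3": act}
    lineages = [
        LineagePlan(
            name="PAT_A",
            system="patient",
            n_cases=60,
            densities={"pw1": 0.5, "pw2": 0.0, "pw3": 0.0},
            status_fractions=dict(avatar_pattern),
        ),
        LineagePlan(
            name="PAT_B",
            system="patient",
            n_cases=60,
            densities={pw: 0.0 for pw in pathways},
            status_fractions={"pw4": sup, "pw5": sup},
        ),
        LineagePlan(
            name="cl_a",
            system="cell_line",
            n_cases=45,
            densities={"pw1": 0.5, "pw2": 0.0, "pw3": 0.0},
            status_fractions=dict(avatar_pattern),
            share_networks_with="PAT_A",
        ),
        LineagePlan(
            name="cl_b",
            system="cell_line",
            n_cases=45,
            densities={pw: 0.0 for pw in pathways},
            status_fractions={"pw2": (0.5, 0.5, 0.0)},
        ),
    ]
    drugs = {
        "drug_pw2": {"pw2": 3.0},
        "drug_null": {},
    }
    return SimulationConfig(
        pathway_sizes=pathways,
        lineages=lineages,
        drug_weights=drugs,
        avatar_pair=("PAT_A", "cl_a"),
        nonmatch_pair=("PAT_B", "cl_b"),
    )


@dataclass
class FixtureBundle:
    study: ExpressionStudy
    catalog: PathwayCatalog
    panel: DrugResponsePanel
    truth: GroundTruth


def _true_aberration(statuses: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth aberration proxy: non-neutral samples are aberrant."""
    return (statuses != "neutral").astype(float) * 0.45 + 0.45


def make_fixture_study(
    config: SimulationConfig | None = None, seed: int = 0
) -> FixtureBundle:
    """Generate a complete study bundle with planted ground truth.

    Pure function of (config, seed): every random draw descends from one
    ``SeedSequence``. Sample IDs encode lineage and role; baseline samples
    carry no planted statuses and exist to calibrate the network fits.
    """
    if config is None:
        config = default_config()
    config.validate()
    root = np.random.SeedSequence([int(seed), 912837])
    rng = np.random.default_rng(root)

    pathway_names = list(config.pathway_sizes)
    proteins = {
        pw: [f"{pw}_P{i}" for i in range(config.pathway_sizes[pw])]
        for pw in pathway_names
    }
    catalog = PathwayCatalog({pw: list(ps) for pw, ps in proteins.items()})

    # ground-truth networks, honoring shared-network plans
    networks: dict[str, dict[str, NetworkTruth]] = {}
    for plan in config.lineages:
        if plan.share_networks_with:
            if plan.share_networks_with not in networks:
                raise ValueError(
                    f"{plan.name} shares networks with {plan.share_networks_with}, "
                    "which must be listed first"
                )
            networks[plan.name] = networks[plan.share_networks_with]
            continue
        networks[plan.name] = {
            pw: simulate_network(
                config.pathway_sizes[pw],
                plan.densities.get(pw, config.default_density),
                rng,
                config.edge_low,
                config.edge_high,
            )
            for pw in pathway_names
        }

    frames, ann_rows, status_rows = [], [], []
    for plan in config.lineages:
        min_n = 3 * max(config.pathway_sizes.values())
        if plan.n_cases < min_n:
            warnings.warn(
                f"lineage {plan.name}: {plan.n_cases} case samples is fewer than "
                f"3x the largest pathway ({min_n}); network identifiability may suffer"
            )
        blocks, case_status = {}, {}
        for pw in pathway_names:
            truth = networks[plan.name][pw]
            Xb, _ = simulate_lineage(
                truth, plan.n_baseline, (0.0, 1.0, 0.0), 0.0, rng, config.heavy_tail
            )
            fr = plan.status_fractions.get(pw, (0.0, 1.0, 0.0))
            Xc, st = simulate_lineage(
                truth, plan.n_cases, fr, config.shift, rng, config.heavy_tail
            )
            blocks[pw] = np.vstack([Xb, Xc])
            case_status[pw] = st
        sample_ids = [f"{plan.name}_ref{i:03d}" for i in range(plan.n_baseline)] + [
            f"{plan.name}_s{i:03d}" for i in range(plan.n_cases)
        ]
        roles = ["baseline"] * plan.n_baseline + ["case"] * plan.n_cases
        mat = np.hstack([blocks[pw] for pw in pathway_names])
        cols = [p for pw in pathway_names for p in proteins[pw]]
        frames.append(pd.DataFrame(mat, index=sample_ids, columns=cols))
        for sid, role in zip(sample_ids, roles):
            ann_rows.append(
                {"sample_id": sid, "system": plan.system, "lineage": plan.name, "role": role}
            )
        for i in range(plan.n_cases):
            row = {"sample_id": sample_ids[plan.n_baseline + i]}
            row.update({pw: case_status[pw][i] for pw in pathway_names})
            status_rows.append(row)

    values = pd.concat(frames, axis=0)
    annotations = pd.DataFrame(ann_rows).set_index("sample_id")
    study = ExpressionStudy(values, annotations.loc[values.index])
    statuses = pd.DataFrame(status_rows).set_index("sample_id")

    # binary drug panel over cell-line case samples, driven by true aberration
    cl_cases = annotations[
        (annotations["system"] == "cell_line") & (annotations["role"] == "case")
    ].index
    ab_true = _true_aberration(statuses.loc[statuses.index.intersection(cl_cases)])
    ab_true = ab_true.reindex(columns=pathway_names, fill_value=0.45)
    drug_cols = {}
    weights_rows = []
    for drug, wmap in config.drug_weights.items():
        w = np.array([wmap.get(pw, 0.0) for pw in pathway_names])
        panel1 = simulate_drug_response(ab_true, w, config.drug_noise_sd, rng, drug)
        drug_cols[drug] = panel1.values[drug]
        weights_rows.append({"drug": drug, **{pw: wi for pw, wi in zip(pathway_names, w)}})
    panel = DrugResponsePanel(pd.DataFrame(drug_cols, index=ab_true.index), binary=True)
    drug_weights = (
        pd.DataFrame(weights_rows).set_index("drug")
        if weights_rows
        else pd.DataFrame(columns=pathway_names)
    )

    truth = GroundTruth(
        networks=networks,
        statuses=statuses,
        drug_weights=drug_weights,
        avatar_pair=config.avatar_pair,
        nonmatch_pair=config.nonmatch_pair,
    )
    return FixtureBundle(study=study, catalog=catalog, panel=panel, truth=truth)
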