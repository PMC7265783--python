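"""Cross-lineage and cross-system network comparison.

Edge consistency counts how many lineages of each model system carry an edge
at a posterior inclusion probability strictly above the calling threshold.
The connectivity score (CS) of a fitted pathway network is the fraction of
possible undirected edges it holds; its significance is judged against a
permutation null (randomCS) obtained by refitting the network on random
same-size protein sets drawn from the pooled pathway catalog.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graphical_regression import CancerNetwork, MCMCSettings, call_edges
from .io import ExpressionStudy, ValidationError

__all__ = [
    "ConnectivityResult",
    "edge_consistency",
    "classify_conserved_edges",
    "connectivity_score",
    "random_cs_null",
    "link_lineages",
]


@dataclass
class ConnectivityResult:
    """Observed CS plus its permutation null for one lineage x pathway."""

    lineage: str
    pathway: str
    cs: float
    random_cs: np.ndarray
    n_reps: int
    seed: int

    @property
    def random_cs_proportion(self) -> float:
        """Fraction of null CS values >= the observed CS (ties against significance)."""
        return float((self.random_cs >= self.cs).mean())


def edge_consistency(
    networks: list[CancerNetwork], threshold: float = 0.5
) -> pd.DataFrame:
    """Per-pathway, per-edge lineage counts by model system.

    An edge counts for a lineage only when its PPI strictly exceeds the
    threshold. All networks of a pathway must share the protein set.
    """
    if not networks:
        raise ValidationError("empty network collection")
    rows: dict[tuple[str, str, str], dict] = {}
    by_pathway: dict[str, list[CancerNetwork]] = {}
    for net in networks:
        by_pathway.setdefault(net.pathway, []).append(net)
    for pathway, nets in by_pathway.items():
        prot = nets[0].proteins
        for net in nets:
            if net.proteins != prot:
                raise ValidationError(
                    f"inconsistent protein sets for pathway {pathway!r}"
                )
        p = len(prot)
        for i in range(p):
            for j in range(i + 1, p):
                key = (pathway, prot[i], prot[j])
                rows[key] = {"patient_count": 0, "cellline_count": 0}
        for net in nets:
            system = _network_system(net)
            col = "patient_count" if system == "patient" else "cellline_count"
            for a, b in call_edges(net, threshold):
                i, j = sorted((prot.index(a), prot.index(b)))
                rows[(pathway, prot[i], prot[j])][col] += 1
    out = pd.DataFrame(
        [
            {"pathway": pw, "protein_a": a, "protein_b": b, **counts}
            for (pw, a, b), counts in rows.items()
        ]
    )
    return out


def _network_system(net: CancerNetwork) -> str:
    return net.system


def classify_conserved_edges(
    table: pd.DataFrame, patient_cutoff: int, cellline_cutoff: int
) -> pd.DataFrame:
    """Conservation category per edge from the two per-system lineage counts."""
    if patient_cutoff < 1 or cellline_cutoff < 1:
        raise ValueError("cutoffs must be >= 1")
    out = table.copy()
    pat = out["patient_count"] >= patient_cutoff
    cl = out["cellline_count"] >= cellline_cutoff
    cat = np.where(
        pat & cl, "both", np.where(pat, "patients_only", np.where(cl, "celllines_only", "neither"))
    )
    out["category"] = cat
    return out


def connectivity_score(edges: set, n_proteins: int, proteins: list[str] | None = None) -> float:
    """Observed edges over all possible undirected edges in the pathway."""
    if n_proteins < 2:
        raise ValueError("need at least 2 proteins")
    if proteins is not None:
        valid = set(proteins)
        for a, b in edges:
            if a not in valid or b not in valid:
                raise ValidationError(f"edge ({a}, {b}) references unknown protein")
    total = n_proteins * (n_proteins - 1) // 2
    return len(edges) / total


def random_cs_null(
    study_slice: ExpressionStudy,
    pathway_size: int,
    protein_pool: list[str],
    observed_cs: float | None = None,
    n_reps: int = 1000,
    seed: int = 0,
    mcmc: MCMCSettings = MCMCSettings(iterations=2000, burn_in=500),
    threshold: float = 0.5,
    lineage: str | None = None,
    pathway: str = "",
) -> ConnectivityResult:
    """Null CS distribution from refitting on random same-size protein sets.

    Each replicate samples ``pathway_size`` proteins uniformly without
    replacement from the pooled catalog, refits the graphical regression on
    the same lineage slice, and records the resulting connectivity score.
    """
    if len(protein_pool) < pathway_size:
        raise ValueError("protein pool smaller than pathway size")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    from .graphical_regression import BayesianGraphicalRegression

    rng = np.random.default_rng(seed)
    missing = [p for p in protein_pool if p not in study_slice.values.columns]
    if missing:
        raise ValidationError(f"pool proteins absent from study slice: {missing[:5]}")
    pool_matrix = study_slice.values[list(protein_pool)].to_numpy(float)
    n_pool = pool_matrix.shape[1]
    iu = np.triu_indices(pathway_size, 1)
    total_pairs = pathway_size * (pathway_size - 1) // 2
    null = np.empty(n_reps)
    for rep in range(n_reps):
        cols = rng.choice(n_pool, size=pathway_size, replace=False)
        est = BayesianGraphicalRegression(
            iterations=mcmc.iterations,
            burn_in=mcmc.burn_in,
            prior_inclusion=mcmc.prior_inclusion,
            tau2=mcmc.tau2,
            ig_a=mcmc.ig_a,
            ig_b=mcmc.ig_b,
            symmetrize=mcmc.symmetrize,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(pool_matrix[:, cols])
        null[rep] = (est.ppi_[iu] > threshold).sum() / total_pairs
    return ConnectivityResult(
        lineage=lineage or "",
        pathway=pathway,
        cs=observed_cs if observed_cs is not None else np.nan,
        random_cs=null,
        n_reps=n_reps,
        seed=seed,
    )


def link_lineages(results: pd.DataFrame, cutoff: float = 0.9) -> pd.DataFrame:
    """Cell line-pathway-patient triplets where both lineages beat the null.

    ``results`` needs columns lineage, system, pathway, cs,
    random_cs_proportion. A lineage passes for a pathway when its observed CS
    strictly exceeds ``cutoff`` (as a fraction of n_reps) of the null values,
    i.e. ``1 - random_cs_proportion > cutoff``. Output ordering is
    deterministic and independent of input row order.
    """
    req = {"lineage", "system", "pathway", "cs", "random_cs_proportion"}
    missing = req - set(results.columns)
    if missing:
        raise ValueError(f"results table lacks columns: {sorted(missing)}")
    passing = results[(1.0 - results["random_cs_proportion"]) > cutoff]
    rows = []
    for pathway, grp in passing.groupby("pathway"):
        cls = sorted(grp.loc[grp["system"] == "cell_line", "lineage"])
        pats = sorted(grp.loc[grp["system"] == "patient", "lineage"])
        for c in cls:
            for p in pats:
                rows.append(
                    {"cellline_lineage": c, "pathway": pathway, "patient_lineage": p}
                )
    out = pd.DataFrame(rows, columns=["cellline_lineage", "pathway", "patient_lineage"])
    return out.sort_values(list(out.columns)).reset_index(drop=True)
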