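"""Pan-cancer stratification from network aberration scores.

The network aberration score of a sample in a pathway is ``k+ + k- = 1 - k0``:
the total probability mass away from neutral pathway activity. Patient and
cell-line samples are compared by the Pearson correlation of their aberration
vectors across pathways; lineage pairs where most sample pairs correlate
strongly are avatar candidates. All samples are stratified by complete-linkage
hierarchical clustering under correlation distance, with the number of
clusters chosen by the gap statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2_contingency
from sklearn.base import BaseEstimator, ClusterMixin

from .graphical_regression import PathwayScores
from .io import ValidationError

__all__ = [
    "aberration_scores",
    "pairwise_correlations",
    "avatar_links",
    "CorrelationCluster",
    "cluster_samples",
    "cluster_composition",
    "status_contrast",
]


def aberration_scores(
    scores: dict[str, PathwayScores] | list[PathwayScores],
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Samples x pathways matrix of aberration scores (k+ + k-).

    ``scores`` holds one :class:`PathwayScores` per (lineage, pathway); every
    sample must be scored on every pathway.
    """
    items = scores.values() if isinstance(scores, dict) else scores
    frames: dict[str, dict[str, float]] = {}
    for ps in items:
        ab = ps.aberration
        for sid, val in zip(ps.samples, ab):
            frames.setdefault(sid, {})[ps.pathway] = val
    mat = pd.DataFrame.from_dict(frames, orient="index").sort_index()
    if mat.isna().any().any():
        sid = mat.index[mat.isna().any(axis=1)][0]
        pw = mat.columns[mat.loc[sid].isna()][0]
        raise ValidationError(f"sample {sid!r} has no score for pathway {pw!r}")
    if annotations is not None:
        mat = mat.loc[mat.index.intersection(annotations.index)]
    return mat


def pairwise_correlations(
    patients: pd.DataFrame, celllines: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r over the pathway axis for every patient x cell-line sample pair.

    Pairs where either aberration vector is constant get NaN (flagged
    undefined; excluded from avatar percentages downstream).
    """
    if list(patients.columns) != list(celllines.columns):
        raise ValidationError("pathway sets/order differ between the two matrices")
    P = patients.to_numpy(float)
    C = celllines.to_numpy(float)
    Pc = P - P.mean(axis=1, keepdims=True)
    Cc = C - C.mean(axis=1, keepdims=True)
    Pn = np.linalg.norm(Pc, axis=1)
    Cn = np.linalg.norm(Cc, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Pc @ Cc.T) / np.outer(Pn, Cn)
    r[Pn == 0, :] = np.nan
    r[:, Cn == 0] = np.nan
    return pd.DataFrame(r, index=patients.index, columns=celllines.index)


def avatar_links(
    correlations: pd.DataFrame,
    patient_lineages: pd.Series,
    cellline_lineages: pd.Series,
    r_threshold: float = 0.9,
    pair_fraction: float = 0.75,
) -> pd.DataFrame:
    """Lineage pairs where most sample pairs correlate strongly.

    For each (patient lineage, cell-line lineage) the percentage of sample
    pairs with ``|r| >= r_threshold`` is computed over the defined pairs; a
    link is emitted iff that percentage strictly exceeds ``pair_fraction``
    (e.g. more than 75%). Undefined correlations are dropped from the
    denominator and counted separately.
    """
    if not (0 < r_threshold < 1 and 0 < pair_fraction < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    rows = []
    pat_groups = correlations.index.groupby(patient_lineages.loc[correlations.index])
    cl_groups = correlations.columns.groupby(cellline_lineages.loc[correlations.columns])
    for plin, pidx in sorted(pat_groups.items()):
        for clin, cidx in sorted(cl_groups.items()):
            block = correlations.loc[pidx, cidx].to_numpy(float)
            defined = ~np.isnan(block)
            n_def = int(defined.sum())
            n_undef = block.size - n_def
            if n_def == 0:
                pct = 0.0
            else:
                pct = float((np.abs(block[defined]) >= r_threshold).mean())
            rows.append(
                {
                    "patient_lineage": plin,
                    "cellline_lineage": clin,
                    "percent_pairs": 100.0 * pct,
                    "n_pairs": n_def,
                    "n_undefined": n_undef,
                    "linked": pct > pair_fraction,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ClusterResult:
    labels: pd.Series  # per-sample cluster ID (1..K)
    K: int
    gap_curve: pd.DataFrame  # columns: k, gap, se
    linkage_matrix: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if self.labels.nunique() != self.K:
            raise ValidationError("K must equal the number of distinct labels")


def _correlation_distance(X: np.ndarray, absolute: bool = False) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    r = (Xc @ Xc.T) / np.outer(norms, norms)
    r = np.clip(r, -1.0, 1.0)
    d = 1.0 - (np.abs(r) if absolute else r)
    np.fill_diagonal(d, 0.0)
    return d


def _within_dispersion(d: np.ndarray, labels: np.ndarray) -> float:
    """Tibshirani W_k: sum over clusters of (pairwise distances^2) / (2 n_r)."""
    w = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < 2:
            continue
        sub = d[np.ix_(idx, idx)]
        w += (sub**2).sum() / (2.0 * len(idx))
    return w


class CorrelationCluster(ClusterMixin, BaseEstimator):
    """Complete-linkage clustering under correlation distance with gap-statistic K.

    Distance between samples is ``1 - r`` of their aberration vectors
    (``1 - |r|`` with ``absolute=True``). The number of clusters is chosen by
    the gap statistic against ``gap_B`` uniform reference draws over the
    bounding box of the data, using the first-SE-max rule: the smallest k with
    ``gap(k) >= gap(k+1) - se(k+1)``.
    """

    def __init__(
        self,
        k_max: int = 10,
        gap_B: int = 50,
        absolute: bool = False,
        random_state: int = 0,
    ):
        self.k_max = k_max
        self.gap_B = gap_B
        self.absolute = absolute
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n < 3:
            raise ValidationError("need at least 3 samples to cluster")
        if self.k_max >= n:
            raise ValueError("k_max must be smaller than the number of samples")
        rng = np.random.default_rng(self.random_state)

        d = _correlation_distance(X, self.absolute)
        Z = linkage(squareform(d, checks=False), method="complete")
        ks = np.arange(1, self.k_max + 1)
        log_w = np.array(
            [np.log(max(_within_dispersion(d, fcluster(Z, k, "maxclust")), 1e-300)) for k in ks]
        )

        lo, hi = X.min(axis=0), X.max(axis=0)
        ref_log_w = np.empty((self.gap_B, len(ks)))
        for b in range(self.gap_B):
            R = rng.uniform(lo, hi, size=X.shape)
            dr = _correlation_distance(R, self.absolute)
            Zr = linkage(squareform(dr, checks=False), method="complete")
            for i, k in enumerate(ks):
                ref_log_w[b, i] = np.log(
                    max(_within_dispersion(dr, fcluster(Zr, k, "maxclust")), 1e-300)
                )
        gap = ref_log_w.mean(axis=0) - log_w
        se = ref_log_w.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / self.gap_B)

        K = int(ks[-1])
        for i in range(len(ks) - 1):
            if gap[i] >= gap[i + 1] - se[i + 1]:
                K = int(ks[i])
                break
        self.labels_ = fcluster(Z, K, "maxclust")
        self.n_clusters_ = K
        self.gap_curve_ = pd.DataFrame({"k": ks, "gap": gap, "se": se})
        self.linkage_ = Z
        return self


def cluster_samples(
    aberration: pd.DataFrame,
    k_max: int = 10,
    gap_B: int = 50,
    seed: int = 0,
    absolute: bool = False,
    on_correlations: bool = False,
) -> ClusterResult:
    """Cluster all samples (both systems) on their aberration vectors.

    Constant-vector samples cannot enter a correlation distance and are
    removed with a warning before clustering. Samples are processed in sorted
    ID order so the output is invariant to input row order. With
    ``on_correlations`` the rows of the sample x sample correlation matrix
    (rather than the aberration vectors themselves) become the feature
    vectors, the alternative reading of clustering "on the correlations".
    """
    ab = aberration.sort_index()
    const = ab.std(axis=1) == 0
    if const.any():
        import warnings

        warnings.warn(f"removing {int(const.sum())} constant-vector samples before clustering")
        ab = ab.loc[~const]
    X = ab.to_numpy(float)
    if on_correlations:
        X = np.corrcoef(X)
    est = CorrelationCluster(
        k_max=min(k_max, len(ab) - 1), gap_B=gap_B, absolute=absolute, random_state=seed
    ).fit(X)
    labels = pd.Series(est.labels_, index=ab.index, name="cluster")
    return ClusterResult(
        labels=labels,
        K=est.n_clusters_,
        gap_curve=est.gap_curve_,
        linkage_matrix=est.linkage_,
        seed=seed,
    )


def cluster_composition(result: ClusterResult, annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster counts and fractions by lineage and by system."""
    ann = annotations.loc[result.labels.index]
    df = pd.DataFrame(
        {"cluster": result.labels, "lineage": ann["lineage"], "system": ann["system"]}
    )
    rows = []
    lineage_sizes = df["lineage"].value_counts()
    for cluster, grp in df.groupby("cluster"):
        n = len(grp)
        sys_counts = grp["system"].value_counts()
        for lineage, cnt in grp["lineage"].value_counts().items():
            rows.append(
                {
                    "cluster": cluster,
                    "lineage": lineage,
                    "n": int(cnt),
                    "fraction_of_cluster": cnt / n,
                    "fraction_of_lineage": cnt / lineage_sizes[lineage],
                    "cluster_patient_fraction": sys_counts.get("patient", 0) / n,
                    "cluster_cellline_fraction": sys_counts.get("cell_line", 0) / n,
                }
            )
    return pd.DataFrame(rows)


def status_contrast(
    statuses: pd.Series, result: ClusterResult, clusters: tuple[int, int]
) -> dict:
    """3x2 contingency of pathway status across two clusters with a chi-square test.

    ``statuses`` maps sample ID to activated/neutral/suppressed for one
    pathway; ``clusters`` names the two cluster IDs to contrast.
    """
    a, b = clusters
    in_a = result.labels.index[result.labels == a]
    in_b = result.labels.index[result.labels == b]
    if len(in_a) == 0 or len(in_b) == 0:
        raise ValidationError("both clusters must be non-empty")
    order = ["activated", "neutral", "suppressed"]
    table = pd.DataFrame(
        {
            a: statuses.loc[statuses.index.intersection(in_a)].value_counts().reindex(order, fill_value=0),
            b: statuses.loc[statuses.index.intersection(in_b)].value_counts().reindex(order, fill_value=0),
        }
    )
    if (table.to_numpy().sum(axis=0) == 0).any():
        raise ValidationError("a contrasted cluster has no scored samples")
    # drop all-zero status rows so expected counts are positive
    nonzero = table.sum(axis=1) > 0
    reduced = table.loc[nonzero]
    if reduced.shape[0] < 2:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = chi2_contingency(reduced.to_numpy())
    percentages = 100.0 * table / table.sum(axis=0)
    return {"table": table, "percentages": percentages, "chi2": float(chi2), "p_value": float(p)}
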