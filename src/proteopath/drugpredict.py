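"""Drug-sensitivity models on pathway aberration scores.

For each lineage and drug with at least ``MIN_PROFILES`` response profiles, a
probit BART classifier is trained on the lineage's cell-line aberration
matrix (one predictor per pathway). Models are evaluated by pooled
out-of-fold AUC from stratified 5-fold cross-validation; pathway importance
is the posterior proportion of splitting rules using each pathway. Patient
response is predicted by applying the matched-lineage model to patient
aberration vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .bart import BartClassifier
from .io import DrugResponsePanel, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DrugModel",
    "binarize_response",
    "fit_drug_model",
    "cv_auc",
    "train_drug_models",
    "top_predictor_summary",
    "pathway_pair_synergy",
    "predict_patients",
]

MIN_PROFILES = 10


@dataclass
class DrugModel:
    lineage: str
    drug: str
    model: BartClassifier
    pathways: list[str]
    n_profiles: int
    cv_auc: float
    importance: pd.Series
    seed: int

    def __post_init__(self) -> None:
        if self.n_profiles < MIN_PROFILES:
            raise ValidationError(f"model trained on {self.n_profiles} < {MIN_PROFILES} profiles")
        if not np.isclose(self.importance.sum(), 1.0, atol=1e-8):
            raise ValidationError("importance must sum to 1")
        if (self.importance < 0).any():
            raise ValidationError("importance must be non-negative")


def binarize_response(panel: DrugResponsePanel) -> DrugResponsePanel:
    """Continuous potency to sensitive/resistant by per-drug median split.

    Sensitive (1) iff the potency value is strictly below the drug's median
    across available cell lines; ties at the median are resistant (0).
    Already-binary panels pass through unchanged; constant drugs are dropped.
    """
    if panel.binary:
        return panel
    out = {}
    for drug in panel.drugs:
        col = panel.values[drug]
        obs = col.dropna()
        if obs.nunique() < 2:
            logger.warning("drug %r has a constant response column; dropped", drug)
            continue
        med = obs.median()
        lab = (col < med).astype(float)
        lab[col.isna()] = np.nan
        out[drug] = lab
    return DrugResponsePanel(pd.DataFrame(out, index=panel.values.index), binary=True)


def _bart(trees: int, draws: int, burn: int, seed: int) -> BartClassifier:
    return BartClassifier(n_trees=trees, n_draws=draws, n_burn=burn, random_state=seed)


def cv_auc(
    aberration: pd.DataFrame,
    response: pd.Series,
    folds: int = 5,
    seed: int = 0,
    trees: int = 20,
    draws: int = 500,
    burn: int = 100,
) -> float:
    """Pooled out-of-fold AUC from stratified cross-validation.

    Out-of-fold predicted probabilities from every fold are pooled and the
    AUC computed once on the pooled vector. If a refold keeps producing
    single-class training splits after 10 attempts, NaN is returned (the
    drug is skipped upstream).
    """
    X = aberration.to_numpy(float)
    y = response.to_numpy(int)
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        try:
            splits = list(skf.split(X, y))
        except ValueError:
            return float("nan")
        if any(len(np.unique(y[tr])) < 2 for tr, _ in splits):
            continue
        pred = np.zeros(len(y))
        for tr, te in splits:
            m = _bart(trees, draws, burn, seed + attempt).fit(X[tr], y[tr])
            pred[te] = m.predict_proba(X[te])[:, 1]
        return float(roc_auc_score(y, pred))
    return float("nan")


def fit_drug_model(
    aberration: pd.DataFrame,
    response: pd.Series,
    lineage: str = "",
    drug: str = "",
    trees: int = 20,
    draws: int = 500,
    burn: int = 100,
    folds: int = 5,
    seed: int = 0,
) -> DrugModel | None:
    """Fit one lineage x drug BART model with CV evaluation.

    Returns None (with a logged reason) rather than raising when the drug is
    ineligible: fewer than 10 non-missing profiles, or a single-class
    response. This keeps batch training total.
    """
    obs = response.dropna()
    ab = aberration.loc[obs.index]
    if len(obs) < MIN_PROFILES:
        logger.info("skipping %s/%s: %d profiles < %d", lineage, drug, len(obs), MIN_PROFILES)
        return None
    if obs.nunique() < 2:
        logger.info("skipping %s/%s: single-class response", lineage, drug)
        return None
    auc = cv_auc(ab, obs, folds=folds, seed=seed, trees=trees, draws=draws, burn=burn)
    if np.isnan(auc):
        logger.info("skipping %s/%s: could not stratify folds", lineage, drug)
        return None
    model = _bart(trees, draws, burn, seed).fit(ab.to_numpy(float), obs.to_numpy(int))
    importance = pd.Series(model.importance_, index=list(ab.columns))
    return DrugModel(
        lineage=lineage,
        drug=drug,
        model=model,
        pathways=list(ab.columns),
        n_profiles=len(obs),
        cv_auc=auc,
        importance=importance,
        seed=seed,
    )


def train_drug_models(
    aberration: pd.DataFrame,
    panel: DrugResponsePanel,
    lineages: pd.Series,
    trees: int = 20,
    draws: int = 500,
    burn: int = 100,
    seed: int = 0,
) -> list[DrugModel]:
    """Batch-train one model per (lineage, eligible drug)."""
    if not panel.binary:
        panel = binarize_response(panel)
    models = []
    for li, (lineage, idx) in enumerate(sorted(aberration.index.groupby(lineages.loc[aberration.index]).items())):
        ab = aberration.loc[idx]
        for di, drug in enumerate(panel.drugs):
            common = ab.index.intersection(panel.values.index)
            resp = panel.values.loc[common, drug]
            m = fit_drug_model(
                ab.loc[common],
                resp,
                lineage=lineage,
                drug=drug,
                trees=trees,
                draws=draws,
                burn=burn,
                seed=(seed * 100_003 + li * 1_009 + di) % 2_147_483_647,
            )
            if m is not None:
                models.append(m)
    return models


def top_predictor_summary(
    models: list[DrugModel], auc_cutoff: float = 0.85, min_profiles: int = MIN_PROFILES
) -> pd.DataFrame:
    """Per-pathway share of qualifying drugs where it is the top predictor.

    Drugs qualify with >= min_profiles response profiles and CV AUC >=
    auc_cutoff. The reported transform is ln(1 + proportion), matching the
    scale conventionally used to display these shares.
    """
    qual = [m for m in models if m.n_profiles >= min_profiles and m.cv_auc >= auc_cutoff]
    if not qual:
        return pd.DataFrame(columns=["pathway", "proportion", "log1p_proportion", "n_drugs"])
    tops = pd.Series([m.importance.idxmax() for m in qual])
    counts = tops.value_counts()
    pathways = sorted({pw for m in qual for pw in m.pathways})
    rows = [
        {
            "pathway": pw,
            "proportion": counts.get(pw, 0) / len(qual),
            "log1p_proportion": float(np.log1p(counts.get(pw, 0) / len(qual))),
            "n_drugs": len(qual),
        }
        for pw in pathways
    ]
    return pd.DataFrame(rows)


def pathway_pair_synergy(
    models: list[DrugModel], auc_cutoff: float = 0.85, min_profiles: int = MIN_PROFILES
) -> pd.DataFrame:
    """Counts of unordered pathway pairs appearing as a model's top two predictors.

    Importance ties are broken by pathway name order (logged).
    """
    qual = [m for m in models if m.n_profiles >= min_profiles and m.cv_auc >= auc_cutoff]
    counts: dict[tuple[str, str], int] = {}
    for m in qual:
        imp = m.importance.sort_index()
        ranked = imp.sort_values(ascending=False, kind="stable")
        if len(ranked) >= 3 and ranked.iloc[1] == ranked.iloc[2]:
            logger.info("importance tie in %s/%s; pair chosen by name order", m.lineage, m.drug)
        pair = tuple(sorted(ranked.index[:2]))
        counts[pair] = counts.get(pair, 0) + 1
    rows = [
        {"pathway_a": a, "pathway_b": b, "count": c}
        for (a, b), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["pathway_a", "pathway_b", "count"])


def predict_patients(
    model: DrugModel,
    patient_aberration: pd.DataFrame,
    patient_lineages: pd.Series,
    lineage_map: dict[str, str],
    threshold: float = 0.5,
) -> tuple[pd.Series, float]:
    """Per-patient sensitivity probabilities plus the cohort response rate.

    Patients are restricted to the lineage mapped to the model's training
    lineage; a patient is called a responder when their posterior sensitivity
    probability strictly exceeds the threshold.
    """
    matched = [pl for pl, cl in lineage_map.items() if cl == model.lineage]
    if not matched:
        raise ValidationError(f"no patient lineage maps to cell-line lineage {model.lineage!r}")
    if list(patient_aberration.columns) != model.pathways:
        raise ValidationError("pathway mismatch between patient aberration matrix and model")
    keep = patient_lineages.loc[patient_aberration.index].isin(matched)
    sub = patient_aberration.loc[keep]
    if sub.empty:
        return pd.Series(dtype=float), float("nan")
    probs = model.model.predict_proba(sub.to_numpy(float))[:, 1]
    probs = pd.Series(probs, index=sub.index, name="sensitivity_probability")
    rate = float((probs > threshold).mean())
    return probs, rate
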