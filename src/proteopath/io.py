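"""Domain containers and plain-text readers/writers.

All on-disk formats are 2-D tab-separated UTF-8 tables with a header row
(expression matrices, annotations, drug panels) or GMT (pathway catalogs).
Floats are written with ``%.17g`` so a write/read round trip is the identity
and repeated writes are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.17g"

VALID_SYSTEMS = ("patient", "cell_line")


class LoadError(ValueError):
    """Raised when an external table fails validation on load."""


class ValidationError(ValueError):
    """Raised when an in-memory object violates a container invariant."""


# ---------------------------------------------------------------------------
# ExpressionStudy
# ---------------------------------------------------------------------------


@dataclass
class ExpressionStudy:
    """Annotated sample x protein expression matrix.

    Parameters
    ----------
    values : DataFrame
        Samples in rows, proteins in columns, continuous expression units
        (assumed approximately centered per protein after normalization).
    annotations : DataFrame
        Indexed by sample ID with columns ``system`` (``patient`` or
        ``cell_line``) and ``lineage`` (tissue-of-origin label).
    """

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        vals = self.values
        if vals.index.duplicated().any():
            dup = vals.index[vals.index.duplicated()][0]
            raise ValidationError(f"duplicate sample ID {dup}")
        if vals.columns.duplicated().any():
            dup = vals.columns[vals.columns.duplicated()][0]
            raise ValidationError(f"duplicate protein ID {dup}")
        missing_ann = vals.index.difference(self.annotations.index)
        if len(missing_ann):
            raise ValidationError(
                f"samples missing from annotations: {sorted(map(str, missing_ann))[:5]}"
            )
        for col in ("system", "lineage"):
            if col not in self.annotations.columns:
                raise ValidationError(f"annotations lack required column {col!r}")
        bad = set(self.annotations.loc[vals.index, "system"]) - set(VALID_SYSTEMS)
        if bad:
            raise ValidationError(f"unknown system labels: {sorted(bad)}")
        if not np.issubdtype(vals.to_numpy().dtype, np.floating):
            raise ValidationError("expression values must be floating point")

    # -- accessors ----------------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def proteins(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def lineages(self, system: str | None = None) -> list[str]:
        ann = self.annotations.loc[self.values.index]
        if system is not None:
            ann = ann[ann["system"] == system]
        return sorted(ann["lineage"].unique())

    def slice(
        self,
        lineage: str | None = None,
        system: str | None = None,
        proteins: Iterable[str] | None = None,
        role: str | None = None,
    ) -> "ExpressionStudy":
        """Restrict to one lineage/system/role and/or a protein subset (file order kept).

        ``role`` filters on the optional baseline/case annotation column; it is
        ignored when the study carries no role column.
        """
        ann = self.annotations.loc[self.values.index]
        keep = pd.Series(True, index=self.values.index)
        if lineage is not None:
            keep &= ann["lineage"] == lineage
        if system is not None:
            keep &= ann["system"] == system
        if role is not None and "role" in ann.columns:
            keep &= ann["role"] == role
        vals = self.values.loc[keep]
        if proteins is not None:
            proteins = list(proteins)
            unknown = [p for p in proteins if p not in self.values.columns]
            if unknown:
                raise ValidationError(f"unknown proteins requested: {unknown}")
            vals = vals[proteins]
        return ExpressionStudy(vals.copy(), self.annotations.loc[vals.index].copy())

    def fit_slice(self, lineage: str, proteins: Iterable[str] | None = None) -> "ExpressionStudy":
        """The samples a lineage's network is fitted on.

        Baseline-calibration samples when a ``role`` column is present,
        otherwise the whole lineage.
        """
        if "role" in self.annotations.columns:
            return self.slice(lineage=lineage, proteins=proteins, role="baseline")
        return self.slice(lineage=lineage, proteins=proteins)

    def case_slice(self, lineage: str | None = None, system: str | None = None,
                   proteins: Iterable[str] | None = None) -> "ExpressionStudy":
        """The samples scored and stratified downstream (non-baseline)."""
        if "role" in self.annotations.columns:
            return self.slice(lineage=lineage, system=system, proteins=proteins, role="case")
        return self.slice(lineage=lineage, system=system, proteins=proteins)


def read_expression_study(
    path: str | Path,
    annotation_path: str | Path,
    max_missing: float = 0.2,
) -> ExpressionStudy:
    """Load an expression matrix plus its per-sample annotation table.

    The matrix is tab-separated with the sample ID in the first column and
    protein IDs in the header. Blank cells are missing values; the missing
    policy (drop proteins with more than ``max_missing`` missing within any
    lineage, then impute the rest by the protein's lineage median) is applied
    so the returned study contains no NaN.
    """
    path, annotation_path = Path(path), Path(annotation_path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for col in header:
        if col in seen:
            raise LoadError(f"duplicate protein ID {col}")
        seen.add(col)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise LoadError(f"duplicate sample ID {dup}")
    vals = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            row = raw.index[bad][0]
            raise LoadError(f"non-numeric cell at row {row!r}, column {col!r}")
        vals[col] = converted

    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    if "sample_id" not in ann.columns:
        raise LoadError("annotation table must have a sample_id column")
    if ann["sample_id"].duplicated().any():
        dup = ann.loc[ann["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise LoadError(f"duplicate sample ID {dup} in annotations")
    ann = ann.set_index("sample_id")
    absent = vals.index.difference(ann.index)
    if len(absent):
        raise LoadError(
            f"samples present in matrix but absent from annotations: {sorted(map(str, absent))[:5]}"
        )
    ann = ann.loc[vals.index]

    vals = _apply_missing_policy(vals, ann["lineage"], max_missing)
    return ExpressionStudy(vals, ann)


def _apply_missing_policy(
    vals: pd.DataFrame, lineage: pd.Series, max_missing: float
) -> pd.DataFrame:
    """Drop proteins exceeding the per-lineage missing fraction; median-impute the rest.

    A protein is dropped globally as soon as it exceeds the threshold within
    any single lineage, which keeps the matrix rectangular.
    """
    if not vals.isna().any().any():
        return vals
    drop: set[str] = set()
    for lin, idx in vals.groupby(lineage).groups.items():
        frac = vals.loc[idx].isna().mean()
        drop |= set(frac.index[frac > max_missing])
    if drop:
        logger.warning("dropping %d proteins over the missing-value threshold", len(drop))
        vals = vals.drop(columns=sorted(drop))
    for lin, idx in vals.groupby(lineage).groups.items():
        block = vals.loc[idx]
        med = block.median()
        vals.loc[idx] = block.fillna(med)
    if vals.isna().any().any():
        # a lineage where every value of some protein is missing
        bad = vals.columns[vals.isna().any()].tolist()
        raise LoadError(f"proteins with no observable values in some lineage: {bad}")
    return vals


def write_expression_study(
    study: ExpressionStudy, path: str | Path, annotation_path: str | Path
) -> None:
    study.values.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="sample_id")
    cols = ["system", "lineage"] + (
        ["role"] if "role" in study.annotations.columns else []
    )
    ann = study.annotations.loc[study.values.index, cols]
    ann.to_csv(annotation_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# PathwayCatalog
# ---------------------------------------------------------------------------


@dataclass
class PathwayCatalog:
    """Map from pathway name to its ordered member protein list."""

    pathways: dict[str, list[str]]

    MIN_MEMBERS = 3

    def __post_init__(self) -> None:
        for name, members in self.pathways.items():
            if len(members) < self.MIN_MEMBERS:
                raise ValidationError(
                    f"pathway too small: {name!r} has {len(members)} proteins (need >= {self.MIN_MEMBERS})"
                )
            if len(set(members)) != len(members):
                raise ValidationError(f"pathway {name!r} lists a protein twice after dedup")

    @property
    def names(self) -> list[str]:
        return list(self.pathways)

    def proteins(self) -> list[str]:
        """Pooled protein list across all pathways, de-duplicated, order preserved."""
        seen: dict[str, None] = {}
        for members in self.pathways.values():
            for p in members:
                seen.setdefault(p, None)
        return list(seen)

    def unmatched(self, study: ExpressionStudy) -> dict[str, list[str]]:
        """Catalog proteins absent from the study, per pathway (exact string match)."""
        have = set(study.proteins)
        out = {
            name: [p for p in members if p not in have]
            for name, members in self.pathways.items()
        }
        return {k: v for k, v in out.items() if v}

    def validate_against(self, study: ExpressionStudy) -> None:
        missing = self.unmatched(study)
        if missing:
            raise ValidationError(f"catalog proteins missing from study: {missing}")

    def rename(self, mapping: dict[str, str]) -> "PathwayCatalog":
        """Exact-identifier remapping hook (e.g. antibody -> protein symbols).

        Matching stays exact, case-sensitive string equality; there is
        deliberately no fuzzy matching.
        """
        return PathwayCatalog(
            {name: [mapping.get(p, p) for p in members] for name, members in self.pathways.items()}
        )


def read_pathway_catalog(path: str | Path) -> PathwayCatalog:
    """Parse a GMT file: name, description, then tab-separated member proteins."""
    pathways: dict[str, list[str]] = {}
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise LoadError(f"empty pathway catalog: {path}")
    for ln in lines:
        parts = ln.split("\t")
        if len(parts) < 3:
            raise LoadError(f"malformed GMT line (need name, description, members): {ln!r}")
        name, members = parts[0], parts[2:]
        deduped: list[str] = []
        for m in members:
            if m in deduped:
                logger.warning("pathway %r lists protein %r twice; keeping one", name, m)
            elif m:
                deduped.append(m)
        if len(deduped) < PathwayCatalog.MIN_MEMBERS:
            raise LoadError(f"pathway too small: {name!r} ({len(deduped)} proteins)")
        pathways[name] = deduped
    return PathwayCatalog(pathways)


def write_pathway_catalog(catalog: PathwayCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in catalog.pathways.items():
            fh.write("\t".join([name, name] + list(members)) + "\n")


# ---------------------------------------------------------------------------
# DrugResponsePanel
# ---------------------------------------------------------------------------


@dataclass
class DrugResponsePanel:
    """Cell line x drug response table; continuous potency or binary labels.

    Missing entries are allowed (NaN) and counted per drug.
    """

    values: pd.DataFrame
    binary: bool = False

    def __post_init__(self) -> None:
        if self.binary:
            arr = self.values.to_numpy()
            ok = np.isnan(arr) | (arr == 0) | (arr == 1)
            if not ok.all():
                i, j = np.argwhere(~ok)[0]
                raise ValidationError(
                    f"binary panel contains non-binary value {arr[i, j]!r} "
                    f"at {self.values.index[i]!r} x {self.values.columns[j]!r}"
                )

    @property
    def cell_lines(self) -> list[str]:
        return list(self.values.index)

    @property
    def drugs(self) -> list[str]:
        return list(self.values.columns)

    def counts(self) -> pd.Series:
        """Per-drug non-missing profile counts."""
        return self.values.notna().sum()


def read_drug_panel(path: str | Path, mode: str = "continuous") -> DrugResponsePanel:
    if mode not in ("continuous", "binary"):
        raise ValueError(f"mode must be continuous or binary, got {mode!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise LoadError(f"duplicate cell line ID {dup}")
    vals = raw.astype(float)
    if mode == "binary":
        arr = vals.to_numpy()
        ok = np.isnan(arr) | (arr == 0) | (arr == 1)
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise LoadError(
                f"binary drug panel contains {arr[i, j]} at "
                f"{vals.index[i]!r} x {vals.columns[j]!r} (must be 0, 1 or blank)"
            )
    return DrugResponsePanel(vals, binary=(mode == "binary"))


def write_drug_panel(panel: DrugResponsePanel, path: str | Path) -> None:
    panel.values.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="cell_line")


# ---------------------------------------------------------------------------
# Network / score tables (written by the graphical-regression stage)
# ---------------------------------------------------------------------------


def write_network_edges(networks, path: str | Path) -> None:
    """Edge-list TSV: pathway, lineage, protein_a, protein_b, ppi, sign."""
    rows = []
    for net in networks:
        prot = net.proteins
        p = len(prot)
        for i in range(p):
            for j in range(i + 1, p):
                coef = net.coef[i, j] + net.coef[j, i]
                rows.append(
                    {
                        "pathway": net.pathway,
                        "lineage": net.lineage,
                        "protein_a": prot[i],
                        "protein_b": prot[j],
                        "ppi": net.ppi[i, j],
                        "sign": int(np.sign(coef)),
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_pathway_scores(scores, path: str | Path) -> None:
    """Long-format score TSV: sample_id, pathway, k_plus, k_zero, k_minus, aberration, status.

    ``scores`` is any iterable of PathwayScores (one per lineage x pathway).
    """
    rows = []
    for ps in scores:
        for idx, sample in enumerate(ps.samples):
            kp, k0, km = ps.k[idx]
            rows.append(
                {
                    "sample_id": sample,
                    "pathway": ps.pathway,
                    "k_plus": kp,
                    "k_zero": k0,
                    "k_minus": km,
                    "aberration": kp + km,
                    "status": ps.status[idx],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
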