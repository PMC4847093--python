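"""Priority indices, aggregation, quadrant classification, PCA, comparison.

The total priority index for one report is exposure score x toxicity
score; it ranks reports, it does not estimate risk.  Endpoint-specific
priority scores (e.g. the endocrine disruptor score) are exposure score x
endpoint certainty x endpoint potency.  This module also aggregates
scored records by chemical, chemical group or product segment, classifies
chemicals into concern quadrants about the median exposure and toxicity,
runs a correlation PCA over the per-chemical scoring variables, and
reports rank concordance against an external prioritization table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .domain import (
    ChemicalProfile,
    Endpoint,
    ProductReport,
    Route,
    ScoreRules,
    default_rules,
    normalize_label,
    profiles_by_id,
)
from .exposure import ExposureBreakdown, ScoringWarning, exposure_score
from .toxicity import ToxicityBreakdown, toxicity_score

__all__ = [
    "PriorityRecord",
    "ScoredDataset",
    "score_dataset",
    "records_to_frame",
    "aggregate",
    "aggregate_frame",
    "chemical_summary",
    "quadrant_classify",
    "pca_variable_table",
    "pca_analysis",
    "PCAResult",
    "compare_external",
    "ConcordanceReport",
]


@dataclass(frozen=True)
class PriorityRecord:
    """One fully scored report with its complete audit trail."""

    report: ProductReport
    chemical_group: str
    exposure: ExposureBreakdown
    toxicity: ToxicityBreakdown
    total_priority_index: float
    endpoint_scores: dict[Endpoint, float]

    @property
    def report_id(self) -> str:
        return self.report.report_id

    @property
    def chemical_id(self) -> str:
        return self.report.chemical_id


@dataclass
class ScoredDataset:
    records: list[PriorityRecord]
    rejections: list[dict] = field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return len(self.records)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


def _score_one(
    report: ProductReport, profile: ChemicalProfile, rules: ScoreRules
) -> PriorityRecord:
    exp = exposure_score(report, profile, rules)
    tox = toxicity_score(profile, rules)
    endpoint_scores = {
        e: exp.total * tox.endpoints[e].product for e in Endpoint
    }
    return PriorityRecord(
        report=report,
        chemical_group=profile.group,
        exposure=exp,
        toxicity=tox,
        total_priority_index=exp.total * tox.total,
        endpoint_scores=endpoint_scores,
    )


def score_dataset(
    reports: Iterable[ProductReport],
    profiles: Union[Iterable[ChemicalProfile], Mapping[str, ChemicalProfile]],
    rules: Optional[ScoreRules] = None,
) -> ScoredDataset:
    """Score every report; unresolvable chemicals go to the rejection list.

    A report whose ``chemical_id`` matches no profile (by id or
    normalized name) is recorded as a rejection, never silently dropped.
    """
    rules = rules or default_rules()
    index = dict(profiles) if isinstance(profiles, Mapping) else profiles_by_id(profiles)
    result = ScoredDataset(records=[])
    for report in reports:
        profile = index.get(report.chemical_id) or index.get(normalize_label(report.chemical_id))
        if profile is None:
            result.rejections.append(
                {
                    "report_id": report.report_id,
                    "chemical_id": report.chemical_id,
                    "reason": f"no profile for chemical {report.chemical_id!r}",
                }
            )
            continue
        result.records.append(_score_one(report, profile, rules))
    return result


def records_to_frame(records: Sequence[PriorityRecord]) -> pd.DataFrame:
    """Flatten scored records into one row per report with full breakdown."""
    rows = []
    for r in records:
        row: dict = {
            "report_id": r.report_id,
            "chemical_id": r.chemical_id,
            "chemical_group": r.chemical_group,
            "segment": r.report.segment,
            "brick": r.report.brick or "",
            "target_age": r.report.target_age.value,
            "concentration_bin": r.report.concentration_bin.value,
            "ls": r.exposure.ls,
            "ex": r.exposure.ex,
            "a": r.exposure.a,
            "con": r.exposure.con,
        }
        for route in Route:
            c = r.exposure.routes[route]
            row[f"{route.value}_mf"] = c.mf
            row[f"{route.value}_level"] = c.level
            row[f"{route.value}_component"] = c.component
        row["exposure_score"] = r.exposure.total
        for e in Endpoint:
            s = r.toxicity.endpoints[e]
            row[f"{e.value}_certainty"] = s.certainty
            row[f"{e.value}_potency"] = s.potency if s.potency is not None else ""
            row[f"{e.value}_product"] = s.product
            row[f"{e.value}_priority_score"] = r.endpoint_scores[e]
        row["toxicity_score"] = r.toxicity.total
        row["total_priority_index"] = r.total_priority_index
        rows.append(row)
    return pd.DataFrame(rows)


_AGG_KEYS = ("chemical", "group", "segment")


def _agg_key(record: PriorityRecord, key: str) -> str:
    if key == "chemical":
        return record.chemical_id
    if key == "group":
        # ungrouped chemicals aggregate under their own id so every record
        # lands in exactly one row (conservation)
        return record.chemical_group if record.chemical_group != "none" else record.chemical_id
    return record.report.segment


def aggregate(records: Sequence[PriorityRecord], key: str = "chemical") -> pd.DataFrame:
    """Pooled per-key statistics of exposure score and total priority index.

    Means and population standard deviations (divisor n) over all reports
    sharing the key; rows sorted by descending mean index, ties broken by
    key name ascending.
    """
    if key not in _AGG_KEYS:
        raise ValueError(f"key must be one of {_AGG_KEYS}, got {key!r}")
    if not records:
        raise ValueError("no records to aggregate")
    frame = pd.DataFrame(
        {
            "key": [_agg_key(r, key) for r in records],
            "exposure": [r.exposure.total for r in records],
            "index": [r.total_priority_index for r in records],
        }
    )
    out = (
        frame.groupby("key")
        .agg(
            n_reports=("exposure", "size"),
            exposure_mean=("exposure", "mean"),
            exposure_sd=("exposure", lambda s: float(np.std(s, ddof=0))),
            index_mean=("index", "mean"),
            index_sd=("index", lambda s: float(np.std(s, ddof=0))),
        )
        .reset_index()
    )
    return out.sort_values(
        ["index_mean", "key"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


_FRAME_KEY_COLUMNS = {"chemical": "chemical_id", "group": "chemical_group", "segment": "segment"}


def aggregate_frame(frame: pd.DataFrame, key: str = "chemical") -> pd.DataFrame:
    """:func:`aggregate` over a flattened scored-records table.

    Needs the ``exposure_score`` and ``total_priority_index`` columns plus
    the key column (``chemical_id`` / ``chemical_group`` / ``segment``);
    a missing column raises a ValueError naming it.
    """
    if key not in _FRAME_KEY_COLUMNS:
        raise ValueError(f"key must be one of {tuple(_FRAME_KEY_COLUMNS)}, got {key!r}")
    key_col = _FRAME_KEY_COLUMNS[key]
    for col in (key_col, "exposure_score", "total_priority_index"):
        if col not in frame.columns:
            raise ValueError(f"scored table is missing column {col!r}")
    if frame.empty:
        raise ValueError("no records to aggregate")
    work = frame.copy()
    if key == "group":
        ungrouped = work[key_col].isin(["none", ""]) | work[key_col].isna()
        work.loc[ungrouped, key_col] = work.loc[ungrouped, "chemical_id"]
    out = (
        work.rename(columns={key_col: "key"})
        .groupby("key")
        .agg(
            n_reports=("exposure_score", "size"),
            exposure_mean=("exposure_score", "mean"),
            exposure_sd=("exposure_score", lambda s: float(np.std(s, ddof=0))),
            index_mean=("total_priority_index", "mean"),
            index_sd=("total_priority_index", lambda s: float(np.std(s, ddof=0))),
        )
        .reset_index()
    )
    return out.sort_values(
        ["index_mean", "key"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def chemical_summary(records: Sequence[PriorityRecord]) -> pd.DataFrame:
    """Per-chemical mean exposure and (constant) toxicity score."""
    frame = pd.DataFrame(
        {
            "chemical_id": [r.chemical_id for r in records],
            "exposure": [r.exposure.total for r in records],
            "toxicity": [r.toxicity.total for r in records],
        }
    )
    return (
        frame.groupby("chemical_id")
        .agg(exposure_mean=("exposure", "mean"), toxicity=("toxicity", "first"))
        .reset_index()
    )


def quadrant_classify(
    summary: Union[pd.DataFrame, Mapping[str, tuple[float, float]]],
) -> pd.DataFrame:
    """Label each chemical by its position about the median exposure and
    median toxicity across chemicals.

    Input: a frame with ``chemical_id``/``exposure_mean``/``toxicity``
    columns (as from :func:`chemical_summary`) or a mapping
    chemical -> (mean exposure, toxicity).  Values exactly at a median
    fall on the high side.  Zero-toxicity chemicals additionally carry a
    ``no_toxicity_data`` flag: absence of toxicity data is not evidence
    of safety.
    """
    if isinstance(summary, Mapping):
        summary = pd.DataFrame(
            [
                {"chemical_id": k, "exposure_mean": v[0], "toxicity": v[1]}
                for k, v in summary.items()
            ]
        )
    if len(summary) < 2:
        raise ValueError("quadrant classification needs at least 2 chemicals")
    med_exp = float(np.median(summary["exposure_mean"]))
    med_tox = float(np.median(summary["toxicity"]))
    out = summary.copy()
    hi_exp = out["exposure_mean"] >= med_exp
    hi_tox = out["toxicity"] >= med_tox
    labels = np.where(
        hi_exp & hi_tox,
        "high-exposure/high-toxicity",
        np.where(
            hi_exp,
            "high-exposure/low-toxicity",
            np.where(hi_tox, "low-exposure/high-toxicity", "low-exposure/low-toxicity"),
        ),
    )
    out["quadrant"] = labels
    out["no_toxicity_data"] = out["toxicity"] == 0
    out.attrs["median_exposure"] = med_exp
    out.attrs["median_toxicity"] = med_tox
    return out


# -- principal component analysis ------------------------------------------

#: Variables entering the PCA, in column order: the four endpoint
#: certainty x potency products, the four additive exposure variables and
#: the three route components (report-level variables enter as per-chemical
#: means).
PCA_VARIABLES = (
    "ED", "RD", "Carc", "NT",
    "LS", "EX", "A", "Con",
    "oral_component", "dermal_component", "inhalation_component",
)


def pca_variable_table(records: Sequence[PriorityRecord]) -> pd.DataFrame:
    """Per-chemical variable table for the PCA (one row per chemical)."""
    rows = []
    for r in records:
        row = {
            "chemical_id": r.chemical_id,
            "ED": r.toxicity.product(Endpoint.ED),
            "RD": r.toxicity.product(Endpoint.RD),
            "Carc": r.toxicity.product(Endpoint.CARC),
            "NT": r.toxicity.product(Endpoint.NT),
            "LS": r.exposure.ls,
            "EX": r.exposure.ex,
            "A": r.exposure.a,
            "Con": r.exposure.con,
            "oral_component": r.exposure.routes[Route.ORAL].component,
            "dermal_component": r.exposure.routes[Route.DERMAL].component,
            "inhalation_component": r.exposure.routes[Route.INHALATION].component,
        }
        rows.append(row)
    return pd.DataFrame(rows).groupby("chemical_id").mean().loc[:, list(PCA_VARIABLES)]


@dataclass
class PCAResult:
    """Correlation-matrix PCA of the per-chemical scoring variables."""

    variables: list[str]
    dropped: list[str]
    scores: pd.DataFrame  # chemicals x components
    loadings: pd.DataFrame  # variables x components
    variance_fractions: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.variance_fractions)


def pca_analysis(table: pd.DataFrame) -> PCAResult:
    """PCA on the column-standardized table (correlation PCA).

    Columns are centered and scaled to unit variance; zero-variance
    columns are dropped with a warning.  Needs at least 3 rows.
    """
    from sklearn.decomposition import PCA

    if len(table) < 3:
        raise ValueError(f"PCA needs at least 3 chemicals, got {len(table)}")
    numeric = table.select_dtypes(include=[np.number])
    sd = numeric.std(ddof=0)
    dropped = list(sd.index[sd == 0])
    if dropped:
        warnings.warn(
            f"dropping zero-variance PCA columns: {dropped}", ScoringWarning, stacklevel=2
        )
    kept = numeric.drop(columns=dropped)
    z = (kept - kept.mean()) / kept.std(ddof=0)
    model = PCA()
    scores = model.fit_transform(z.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(model.n_components_)]
    return PCAResult(
        variables=list(kept.columns),
        dropped=dropped,
        scores=pd.DataFrame(scores, index=kept.index, columns=comp_names),
        loadings=pd.DataFrame(model.components_.T, index=kept.columns, columns=comp_names),
        variance_fractions=model.explained_variance_ratio_.copy(),
    )


# -- external comparison ----------------------------------------------------

@dataclass
class ConcordanceReport:
    """Rank concordance between this framework and an external scheme."""

    n_overlap: int
    spearman_rho: float
    spearman_p: float
    merged: pd.DataFrame  # chemical, internal, external, ranks
    discordant: list[str]
    only_internal: list[str]
    only_external: list[str]

    def to_text(self) -> str:
        lines = [
            f"chemicals compared: {self.n_overlap}",
            f"Spearman rank correlation: {self.spearman_rho:.3f} (p = {self.spearman_p:.3g})",
            "discordant (top tertile of one scheme, bottom tertile or absent in the other):",
        ]
        lines += [f"  - {c}" for c in self.discordant] or ["  (none)"]
        lines.append("not shared:")
        for c in self.only_internal:
            lines.append(f"  - {c} (internal only)")
        for c in self.only_external:
            lines.append(f"  - {c} (external only)")
        if not self.only_internal and not self.only_external:
            lines.append("  (none)")
        return "\n".join(lines)


def _tertile_labels(series: pd.Series) -> pd.Series:
    # rank-based tertiles, highest scores in the top tertile
    ranks = series.rank(method="average", ascending=False)
    n = len(series)
    top = ranks <= n / 3
    bottom = ranks > 2 * n / 3
    return pd.Series(np.where(top, "top", np.where(bottom, "bottom", "middle")), index=series.index)


def compare_external(
    internal: Union[Mapping[str, float], pd.Series],
    external: Union[Mapping[str, float], pd.Series],
) -> ConcordanceReport:
    """Rank concordance of per-chemical scores against an external table.

    Chemicals are joined on normalized name.  Requires at least 3
    overlapping chemicals.  A chemical is discordant when it sits in the
    top tertile of one scheme and in the bottom tertile of — or absent
    from — the other.
    """
    s_int = pd.Series(dict(internal), dtype=float)
    s_ext = pd.Series(dict(external), dtype=float)
    s_int.index = [normalize_label(i) for i in s_int.index]
    s_ext.index = [normalize_label(i) for i in s_ext.index]
    shared = sorted(set(s_int.index) & set(s_ext.index))
    if len(shared) < 3:
        raise ValueError(
            f"need at least 3 overlapping chemicals, got {len(shared)}: {shared}"
        )
    merged = pd.DataFrame(
        {"internal": s_int.loc[shared], "external": s_ext.loc[shared]}
    )
    rho, p = stats.spearmanr(merged["internal"], merged["external"])
    int_tert = _tertile_labels(merged["internal"])
    ext_tert = _tertile_labels(merged["external"])
    discordant = sorted(
        set(merged.index[(int_tert == "top") & (ext_tert == "bottom")])
        | set(merged.index[(ext_tert == "top") & (int_tert == "bottom")])
        | {c for c in s_int.index if c not in shared and _tertile_labels(s_int)[c] == "top"}
        | {c for c in s_ext.index if c not in shared and _tertile_labels(s_ext)[c] == "top"}
    )
    return ConcordanceReport(
        n_overlap=len(shared),
        spearman_rho=float(rho),
        spearman_p=float(p),
        merged=merged.assign(internal_tertile=int_tert, external_tertile=ext_tert),
        discordant=discordant,
        only_internal=sorted(set(s_int.index) - set(shared)),
        only_external=sorted(set(s_ext.index) - set(shared)),
    )
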