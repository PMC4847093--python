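"""File formats: report/profile tables, scored output, run manifests.

All tables are comma-delimited UTF-8 with a required header row.  ``NI``
and empty cells are read as missing, matching the no-information notation
of the published chemical table.  Output tables carry a provenance
header of ``#``-prefixed comment lines (rule-set hash, input names, seed)
and are read back with those lines skipped, so every output round-trips
through this module's own readers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Iterable, Optional, Sequence, Union

import pandas as pd
import yaml

from .domain import (
    ChemicalProfile,
    Endpoint,
    EndpointEvidence,
    ProductReport,
    ReportValidationError,
    Route,
    ScoreRules,
    parse_absorption,
    validate_report,
)

__all__ = [
    "read_reports_csv",
    "write_reports_csv",
    "read_profiles",
    "write_profiles_csv",
    "write_profiles_json",
    "rules_hash",
    "provenance_header",
    "write_table",
    "read_table",
    "RunManifest",
]

_MISSING_TOKENS = {"", "ni", "na", "nan", "none"}

_ENDPOINT_PREFIX = {
    Endpoint.ED: "ed",
    Endpoint.RD: "rd",
    Endpoint.CARC: "carc",
    Endpoint.NT: "nt",
}

_ROUTE_COLUMNS = {
    Route.ORAL: "oral",
    Route.DERMAL: "dermal",
    Route.INHALATION: "inhalation",
}

REPORT_COLUMNS = ("report_id", "chemical_id", "segment", "brick", "target_age", "concentration_bin", "function")


def _cell(value: Any) -> Optional[str]:
    if value is None:
        return None
    token = str(value).strip()
    return None if token.lower() in _MISSING_TOKENS else token


def read_reports_csv(path: Union[str, Path]) -> tuple[list[ProductReport], list[dict]]:
    """Read a report table; returns (accepted reports, rejection rows).

    Raises ValueError on a malformed header (required columns absent) and
    on an empty table.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    required = {"chemical_id", "segment", "target_age", "concentration_bin"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"malformed report header: missing columns {sorted(missing)}")
    if frame.empty:
        raise ValueError("empty report table")
    reports: list[ProductReport] = []
    rejections: list[dict] = []
    for i, row in frame.iterrows():
        record = {k: _cell(row.get(k)) for k in REPORT_COLUMNS if k in frame.columns}
        if not record.get("report_id"):
            record["report_id"] = f"row-{i}"
        try:
            reports.append(validate_report(record))
        except ReportValidationError as err:
            rejections.append(
                {"report_id": record.get("report_id"), "errors": "; ".join(err.errors)}
            )
    return reports, rejections


def write_reports_csv(reports: Iterable[ProductReport], path: Union[str, Path]) -> None:
    rows = [
        {
            "report_id": r.report_id,
            "chemical_id": r.chemical_id,
            "segment": r.segment,
            "brick": r.brick or "",
            "target_age": r.target_age.value,
            "concentration_bin": r.concentration_bin.value,
            "function": r.function or "",
        }
        for r in reports
    ]
    pd.DataFrame(rows, columns=list(REPORT_COLUMNS)).to_csv(path, index=False)


# -- chemical profiles ------------------------------------------------------

def _profile_to_row(p: ChemicalProfile) -> dict[str, Any]:
    row: dict[str, Any] = {
        "chemical_id": p.chemical_id,
        "name": p.name,
        "group": p.group,
        "water_solubility_mol_L": p.water_solubility,
        "solubility_score": p.solubility_score,
        "vapor_pressure_mmHg": p.vapor_pressure,
        "vp_score": p.vp_score,
        "log_kow": p.log_kow,
        "molecular_weight": p.molecular_weight,
        "kp_cm_h": p.kp,
        "kp_score": p.kp_score,
    }
    for route, col in _ROUTE_COLUMNS.items():
        row[f"abs_{col}"] = p.absorption.get(route)
        row[f"abs_{col}_score"] = p.absorption_scores.get(route)
    for endpoint, prefix in _ENDPOINT_PREFIX.items():
        ev = p.evidence(endpoint)
        row[f"{prefix}_certainty"] = ev.certainty
        row[f"{prefix}_potency_score"] = ev.potency_score
        row[f"{prefix}_noael"] = ev.noael
        row[f"{prefix}_loael"] = ev.loael
        row[f"{prefix}_rfd"] = ev.rfd
        row[f"{prefix}_uf_product"] = ev.uf_product
        row[f"{prefix}_td50_mouse"] = ev.td50_mouse
        row[f"{prefix}_td50_rat"] = ev.td50_rat
    return row


def _row_to_profile(row: dict[str, Any]) -> ChemicalProfile:
    def fnum(key: str) -> Optional[float]:
        token = _cell(row.get(key))
        return None if token is None else float(token)

    def inum(key: str) -> Optional[int]:
        token = _cell(row.get(key))
        return None if token is None else int(float(token))

    evidence = {}
    for endpoint, prefix in _ENDPOINT_PREFIX.items():
        evidence[endpoint] = EndpointEvidence(
            certainty=inum(f"{prefix}_certainty") or 0,
            potency_score=inum(f"{prefix}_potency_score"),
            noael=fnum(f"{prefix}_noael"),
            loael=fnum(f"{prefix}_loael"),
            rfd=fnum(f"{prefix}_rfd"),
            uf_product=fnum(f"{prefix}_uf_product"),
            td50_mouse=fnum(f"{prefix}_td50_mouse"),
            td50_rat=fnum(f"{prefix}_td50_rat"),
        )
    return ChemicalProfile(
        chemical_id=_cell(row.get("chemical_id")) or "",
        name=_cell(row.get("name")) or _cell(row.get("chemical_id")) or "",
        group=_cell(row.get("group")) or "none",
        water_solubility=fnum("water_solubility_mol_L"),
        solubility_score=inum("solubility_score"),
        vapor_pressure=fnum("vapor_pressure_mmHg"),
        vp_score=inum("vp_score"),
        log_kow=fnum("log_kow"),
        molecular_weight=fnum("molecular_weight"),
        kp=fnum("kp_cm_h"),
        kp_score=inum("kp_score"),
        absorption={
            route: parse_absorption(_cell(row.get(f"abs_{col}")))
            for route, col in _ROUTE_COLUMNS.items()
        },
        absorption_scores={
            route: inum(f"abs_{col}_score") for route, col in _ROUTE_COLUMNS.items()
        },
        endpoint_evidence=evidence,
    )


def read_profiles(path: Union[str, Path]) -> list[ChemicalProfile]:
    """Read chemical profiles from CSV or JSON (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "r", encoding="utf-8") as fh:
            rows = json.load(fh)
        if not isinstance(rows, list):
            raise ValueError("profile JSON must be a list of objects")
        return [_row_to_profile(row) for row in rows]
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    if "chemical_id" not in frame.columns:
        raise ValueError("malformed profile header: missing column 'chemical_id'")
    return [_row_to_profile(row.to_dict()) for _, row in frame.iterrows()]


def write_profiles_csv(profiles: Iterable[ChemicalProfile], path: Union[str, Path]) -> None:
    pd.DataFrame([_profile_to_row(p) for p in profiles]).to_csv(path, index=False)


def write_profiles_json(profiles: Iterable[ChemicalProfile], path: Union[str, Path]) -> None:
    rows = [_profile_to_row(p) for p in profiles]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(rows, fh, indent=1, default=str)


# -- provenance and manifests ----------------------------------------------

def rules_hash(rules: ScoreRules) -> str:
    """Stable short hash of a rule set (for output provenance)."""
    blob = yaml.safe_dump(rules.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(
    rules: Optional[ScoreRules] = None,
    inputs: Sequence[str] = (),
    seed: Optional[int] = None,
) -> str:
    lines = ["# produced by cspascore"]
    if rules is not None:
        lines.append(f"# rules_hash: {rules_hash(rules)}")
    if inputs:
        lines.append(f"# inputs: {', '.join(Path(p).name for p in inputs)}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    return "\n".join(lines) + "\n"


def write_table(
    frame: pd.DataFrame,
    path: Union[str, Path],
    rules: Optional[ScoreRules] = None,
    inputs: Sequence[str] = (),
    seed: Optional[int] = None,
) -> None:
    """Write a CSV with the provenance comment header."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(provenance_header(rules, inputs, seed))
        frame.to_csv(fh, index=False)


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", keep_default_na=False, na_values=[""])


@dataclass
class RunManifest:
    """Record of one CLI run; written on every run, including failed ones."""

    command: str
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    rules_hash: str = ""
    rule_overrides: dict[str, Any] = field(default_factory=dict)
    profile_source: str = ""
    seed: Optional[int] = None
    records_read: int = 0
    records_accepted: int = 0
    records_rejected: int = 0
    status: str = "ok"
    error: str = ""
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )

    def write(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)
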