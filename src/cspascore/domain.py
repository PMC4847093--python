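"""Domain types and the default scoring rule set.

The scoring engine consumes two kinds of records:

* :class:`ProductReport` — one manufacturer report of a chemical in a
  children's product (product segment, optional brick sub-category, target
  age group, concentration range bin).
* :class:`ChemicalProfile` — per-chemical physical properties, observed
  absorption by route, and toxicity-endpoint evidence (certainty of
  classification across curated hazard databases plus a potency input).

Every cutoff, bin edge and constant used by the scoring equations lives in
:class:`ScoreRules`, which serializes to/from a YAML mapping so individual
rules can be overridden in a config file without touching code.
"""

from __future__ import annotations

import dataclasses
import enum
import re
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Optional, Union

import yaml

__all__ = [
    "TargetAge",
    "ConcentrationBin",
    "Endpoint",
    "Route",
    "ABSORBED_UNKNOWN_RATE",
    "AbsorptionValue",
    "ProductReport",
    "EndpointEvidence",
    "ChemicalProfile",
    "ScoreRules",
    "ReportValidationError",
    "default_rules",
    "validate_report",
    "normalize_label",
    "KNOWN_SEGMENTS",
    "load_rules",
    "save_rules",
]


class TargetAge(str, enum.Enum):
    """Target age group a product is designed for, as reported."""

    UNDER_THREE = "under_three"
    THREE_TO_TWELVE = "three_to_twelve"


class ConcentrationBin(str, enum.Enum):
    """The six reportable concentration ranges, in ppm.

    Canonical tokens are used in all CSV output; :meth:`parse` also accepts
    the typographic range notations that appear in print (en dashes,
    thousands separators, ``10,000+``).
    """

    LT_100 = "lt100"
    FROM_100_500 = "100-500"
    FROM_500_1000 = "500-1000"
    FROM_1000_5000 = "1000-5000"
    FROM_5000_10000 = "5000-10000"
    GT_10000 = "gt10000"

    @classmethod
    def ordered(cls) -> list["ConcentrationBin"]:
        return [
            cls.LT_100,
            cls.FROM_100_500,
            cls.FROM_500_1000,
            cls.FROM_1000_5000,
            cls.FROM_5000_10000,
            cls.GT_10000,
        ]

    @property
    def rank(self) -> int:
        """Position of this bin in increasing concentration order (0-5)."""
        return ConcentrationBin.ordered().index(self)

    @classmethod
    def parse(cls, label: str) -> "ConcentrationBin":
        """Parse a bin label; raises ValueError for anything off-list."""
        token = str(label).strip().lower()
        token = token.replace(",", "").replace("–", "-").replace("—", "-")
        token = re.sub(r"\s+", "", token)
        token = token.replace("ppm", "")
        aliases = {
            "<100": cls.LT_100,
            "lt100": cls.LT_100,
            "100-500": cls.FROM_100_500,
            "500-1000": cls.FROM_500_1000,
            "1000-5000": cls.FROM_1000_5000,
            "5000-10000": cls.FROM_5000_10000,
            ">10000": cls.GT_10000,
            "10000+": cls.GT_10000,
            "gt10000": cls.GT_10000,
        }
        if token in aliases:
            return aliases[token]
        raise ValueError(f"unknown concentration bin label: {label!r}")


class Endpoint(str, enum.Enum):
    """The four systemic toxicity endpoints scored by the framework."""

    ED = "ED"  # endocrine disruption
    RD = "RD"  # reproductive and developmental toxicity
    CARC = "Carc"  # carcinogenicity
    NT = "NT"  # neurotoxicity


class Route(str, enum.Enum):
    ORAL = "oral"
    DERMAL = "dermal"
    INHALATION = "inhalation"


#: Sentinel for "absorbed in humans, but at an unknown rate".
ABSORBED_UNKNOWN_RATE = "unknown_rate"

#: An absorption observation: a percent in [0, 100], the unknown-rate
#: sentinel, or ``None`` for no information.
AbsorptionValue = Optional[Union[float, str]]

#: The 11 product segments in the reporting database, canonical names.
KNOWN_SEGMENTS: tuple[str, ...] = (
    "Clothing",
    "Footwear",
    "Toys/Games",
    "Beauty/Personal Care/Hygiene",
    "Baby Care",
    "Kitchen Merchandise",
    "Household/Office Furniture/Furnishings",
    "Personal Accessories",
    "Arts/Crafts/Needlework",
    "Stationery/Office Machinery/Occasion Supplies",
    "Camping",
)


def normalize_label(label: str) -> str:
    """Lowercase and collapse whitespace for case-insensitive matching."""
    return re.sub(r"\s+", " ", str(label).strip().lower())


_SEGMENT_LOOKUP = {normalize_label(s): s for s in KNOWN_SEGMENTS}


def canonical_segment(segment: str) -> Optional[str]:
    """Canonical segment name, or None if the segment is not recognized."""
    return _SEGMENT_LOOKUP.get(normalize_label(segment))


@dataclass(frozen=True)
class ProductReport:
    """One validated product report (chemical × product × age × bin)."""

    report_id: str
    chemical_id: str
    segment: str
    target_age: TargetAge
    concentration_bin: ConcentrationBin
    brick: Optional[str] = None
    function: Optional[str] = None

    @property
    def segment_known(self) -> bool:
        return canonical_segment(self.segment) is not None


class ReportValidationError(ValueError):
    """Raised when a raw record violates report invariants.

    ``errors`` names every violated field; nothing is silently coerced.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid product report: " + "; ".join(self.errors))


_FIELD_ALIASES = {
    "chemical_id": ("chemical_id", "chemical", "chem"),
    "segment": ("segment",),
    "brick": ("brick",),
    "target_age": ("target_age", "age"),
    "concentration_bin": ("concentration_bin", "concentration", "conc"),
    "report_id": ("report_id", "id"),
    "function": ("function",),
}


def _pick(record: Mapping[str, Any], key: str) -> Any:
    for alias in _FIELD_ALIASES[key]:
        if alias in record and record[alias] not in (None, ""):
            return record[alias]
    return None


def validate_report(record: Mapping[str, Any]) -> ProductReport:
    """Validate a raw field mapping into a :class:`ProductReport`.

    Raises :class:`ReportValidationError` listing every violated invariant;
    a record is never partially accepted.  Unknown segments are accepted
    here (they carry the original string and are flagged at scoring time),
    but age and concentration labels outside the enumerated values are
    rejections.
    """
    errors: list[str] = []

    chemical_id = _pick(record, "chemical_id")
    if not chemical_id:
        errors.append("chemical_id: missing")

    segment = _pick(record, "segment")
    if not segment:
        errors.append("segment: missing")

    age_raw = _pick(record, "target_age")
    age: Optional[TargetAge] = None
    if age_raw is None:
        errors.append("target_age: missing")
    else:
        try:
            age = TargetAge(normalize_label(age_raw).replace(" ", "_").replace("-", "_"))
        except ValueError:
            errors.append(f"target_age: unknown label {age_raw!r}")

    conc_raw = _pick(record, "concentration_bin")
    conc: Optional[ConcentrationBin] = None
    if conc_raw is None:
        errors.append("concentration_bin: missing")
    else:
        try:
            conc = ConcentrationBin.parse(conc_raw)
        except ValueError:
            errors.append(f"concentration_bin: not one of the six ranges: {conc_raw!r}")

    if errors:
        raise ReportValidationError(errors)

    return ProductReport(
        report_id=str(_pick(record, "report_id") or ""),
        chemical_id=str(chemical_id),
        segment=str(segment),
        target_age=age,  # type: ignore[arg-type]
        concentration_bin=conc,  # type: ignore[arg-type]
        brick=(str(_pick(record, "brick")) if _pick(record, "brick") else None),
        function=(str(_pick(record, "function")) if _pick(record, "function") else None),
    )


@dataclass(frozen=True)
class EndpointEvidence:
    """Evidence for one toxicity endpoint.

    ``certainty`` is the harmonized 0-3 classification strength (none /
    potential / suspected / known, taken as the maximum over the curated
    sources).  Potency may arrive pre-assigned (``potency_score``) or as a
    dose input to be binned: a NOAEL or LOAEL in mg/kg, an RfD in
    mg/kg/day with its uncertainty-factor product, or a TD50 pair
    (mouse, rat) in mg/kg/day for carcinogens.
    """

    certainty: int = 0
    potency_score: Optional[int] = None
    noael: Optional[float] = None
    loael: Optional[float] = None
    rfd: Optional[float] = None
    uf_product: Optional[float] = None
    td50_mouse: Optional[float] = None
    td50_rat: Optional[float] = None

    def __post_init__(self) -> None:
        if self.certainty not in (0, 1, 2, 3):
            raise ValueError(f"certainty must be 0-3, got {self.certainty}")
        if self.potency_score is not None and self.potency_score not in (1, 2, 3):
            raise ValueError(f"potency score must be 1-3, got {self.potency_score}")


def _check_score(name: str, value: Optional[int]) -> None:
    if value is not None and value not in (1, 2, 3):
        raise ValueError(f"{name} must be in {{1,2,3}}, got {value}")


@dataclass(frozen=True)
class ChemicalProfile:
    """Per-chemical properties, absorption observations and endpoint evidence.

    For each of the three route-matched properties (water solubility for
    oral, skin permeability Kp for dermal, vapor pressure for inhalation)
    either a pre-assigned 1-3 score or a raw value may be present; a
    pre-assigned score always wins over a raw value.  Absorption
    observations are percents, the unknown-rate sentinel, or missing.
    """

    chemical_id: str
    name: str
    group: str = "none"  # phthalates | parabens | ethylene_glycols | metals | none
    water_solubility: Optional[float] = None  # mol/L
    solubility_score: Optional[int] = None
    vapor_pressure: Optional[float] = None  # mmHg at 25 C
    vp_score: Optional[int] = None
    log_kow: Optional[float] = None
    molecular_weight: Optional[float] = None  # g/mol
    kp: Optional[float] = None  # cm/h
    kp_score: Optional[int] = None
    absorption: Mapping[Route, AbsorptionValue] = field(default_factory=dict)
    absorption_scores: Mapping[Route, Optional[int]] = field(default_factory=dict)
    endpoint_evidence: Mapping[Endpoint, EndpointEvidence] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_score("solubility_score", self.solubility_score)
        _check_score("vp_score", self.vp_score)
        _check_score("kp_score", self.kp_score)
        # normalize route mappings so every route key is present
        object.__setattr__(
            self, "absorption", {r: self.absorption.get(r) for r in Route}
        )
        object.__setattr__(
            self, "absorption_scores", {r: self.absorption_scores.get(r) for r in Route}
        )
        for route, score in self.absorption_scores.items():
            _check_score(f"absorption_scores[{route}]", score)
        object.__setattr__(
            self,
            "endpoint_evidence",
            {e: self.endpoint_evidence.get(e, EndpointEvidence()) for e in Endpoint},
        )
        for route, obs in self.absorption.items():
            if obs is None or obs == ABSORBED_UNKNOWN_RATE:
                continue
            if not (0 <= float(obs) <= 100):
                raise ValueError(f"absorption[{route}] out of [0,100]: {obs!r}")

    def evidence(self, endpoint: Endpoint) -> EndpointEvidence:
        return self.endpoint_evidence.get(endpoint, EndpointEvidence())


# --------------------------------------------------------------------------
# Rule set
# --------------------------------------------------------------------------

_LONG_TERM_SEGMENTS = (
    "Clothing",
    "Footwear",
    "Beauty/Personal Care/Hygiene",
    "Camping",
)

_APPLIED_TO_SKIN_SEGMENTS = ("Beauty/Personal Care/Hygiene",)

_DERMAL_PRIMARY_SEGMENTS = (
    "Clothing",
    "Beauty/Personal Care/Hygiene",
    "Footwear",
    "Arts/Crafts/Needlework",
    "Household/Office Furniture/Furnishings",
    "Camping",
    "Personal Accessories",
    "Toys/Games",
)

_ORAL_PRIMARY_SEGMENTS = ("Kitchen Merchandise",)


@dataclass
class ScoreRules:
    """Every cutoff, bin edge and constant used by the scoring equations.

    Defaults are the published rule set (see :func:`default_rules`); any
    field can be overridden through the YAML config.  Bin-edge sequences
    must be strictly increasing.
    """

    # -- product attributes (additive exposure block)
    lifestage_map: dict[str, float] = field(
        default_factory=lambda: {"under_three": 3.0, "three_to_twelve": 1.0}
    )
    concentration_map: dict[str, float] = field(
        default_factory=lambda: {
            "lt100": 0.5,
            "100-500": 1.0,
            "500-1000": 1.5,
            "1000-5000": 2.0,
            "5000-10000": 2.5,
            "gt10000": 3.0,
        }
    )
    long_term_segments: list[str] = field(default_factory=lambda: list(_LONG_TERM_SEGMENTS))
    duration_long_score: float = 3.0
    duration_short_score: float = 1.0
    applied_to_skin_segments: list[str] = field(
        default_factory=lambda: list(_APPLIED_TO_SKIN_SEGMENTS)
    )
    applied_yes_score: float = 3.0
    applied_no_score: float = 1.0

    # -- exposure routes
    mf_primary: int = 3
    mf_secondary: int = 2
    mf_tertiary: int = 1
    dermal_primary_segments: list[str] = field(
        default_factory=lambda: list(_DERMAL_PRIMARY_SEGMENTS)
    )
    oral_primary_segments: list[str] = field(default_factory=lambda: list(_ORAL_PRIMARY_SEGMENTS))

    # -- chemical properties
    solubility_cutoffs: list[float] = field(default_factory=lambda: [0.001, 0.01])  # mol/L
    vp_cutoffs: list[float] = field(default_factory=lambda: [0.075, 32.0])  # mmHg
    kp_cutoffs: list[float] = field(default_factory=lambda: [3.395e-3, 6.7e-3])  # cm/h

    # -- observed absorption (%)
    absorption_cutoffs: list[float] = field(default_factory=lambda: [5.0, 10.0])
    absorption_table1_variant: bool = False  # True: above 5% scores 3
    absorption_unknown_rate_score: int = 2

    # -- toxicity potency
    rd_noael_cutoffs: list[float] = field(default_factory=lambda: [200.0, 397.0])  # mg/kg
    ed_noael_cutoffs: list[float] = field(default_factory=lambda: [336.0, 667.0])  # mg/kg
    carc_td50_cutoffs: list[float] = field(default_factory=lambda: [233.0, 465.0])  # mg/kg/day
    nt_potency: int = 2
    suspected_potency: int = 1
    loael_uf: float = 10.0
    tertiles_from_data: bool = False  # recompute NOAEL tertiles from the dataset

    def __post_init__(self) -> None:
        for name in (
            "solubility_cutoffs",
            "vp_cutoffs",
            "kp_cutoffs",
            "absorption_cutoffs",
            "rd_noael_cutoffs",
            "ed_noael_cutoffs",
            "carc_td50_cutoffs",
        ):
            edges = getattr(self, name)
            if len(edges) != 2 or not edges[0] < edges[1]:
                raise ValueError(f"{name} must be two strictly increasing edges, got {edges}")
        if self.loael_uf <= 0:
            raise ValueError("loael_uf must be positive")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ScoreRules":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown rule keys: {sorted(unknown)}")
        return cls(**dict(data))

    def with_overrides(self, overrides: Mapping[str, Any]) -> "ScoreRules":
        """New rule set with the given fields replaced (others inherited)."""
        merged = self.to_dict()
        unknown = set(overrides) - set(merged)
        if unknown:
            raise ValueError(f"unknown rule keys: {sorted(unknown)}")
        merged.update(overrides)
        return ScoreRules.from_dict(merged)


def default_rules() -> ScoreRules:
    """The published rule set (all Table-1 cutoffs and constants)."""
    return ScoreRules()


def load_rules(path: str, base: Optional[ScoreRules] = None) -> ScoreRules:
    """Load a rules config; keys absent from the file inherit defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise ValueError(f"rules config must be a mapping, got {type(data).__name__}")
    return (base or default_rules()).with_overrides(data)


def save_rules(rules: ScoreRules, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(rules.to_dict(), fh, sort_keys=True)


def parse_absorption(value: Any) -> AbsorptionValue:
    """Parse an absorption cell: percent, unknown-rate marker, or missing.

    ``NI`` / empty / None mean no information, matching the notation used
    in the published chemical table.
    """
    if value is None:
        return None
    if isinstance(value, (int, float)):
        return float(value)
    token = normalize_label(value)
    if token in ("", "ni", "na", "none", "missing", "nan"):
        return None
    if token in ("unknown", "unknown_rate", "absorbed_unknown_rate", "absorbed at unknown rate"):
        return ABSORBED_UNKNOWN_RATE
    return float(token.rstrip("%"))


def profiles_by_id(profiles: Iterable[ChemicalProfile]) -> dict[str, ChemicalProfile]:
    """Index profiles by chemical_id and by normalized display name."""
    index: dict[str, ChemicalProfile] = {}
    for p in profiles:
        index[p.chemical_id] = p
        index.setdefault(normalize_label(p.name), p)
    return index
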