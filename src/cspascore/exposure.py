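"""Exposure scoring: route assignment and the additive exposure equation.

The exposure score for one product report is

    E = (LS + EX + A + Con)
        + O_MF * (S   + Abs_oral)/2
        + D_MF * (Kp  + Abs_dermal)/2
        + I_MF * (VP  + Abs_inhalation)/2

where the additive block scores the product (lifestage LS, exposure
duration EX, applied-to-skin A, concentration bin Con) and each route
component multiplies a primary/secondary/tertiary modifying factor (3/2/1)
by the route's toxicokinetic average: the mean of the route-matched
chemical property score (water solubility, skin permeability Kp, vapor
pressure) and the observed absorption score.  When a route has no observed
absorption, the property score is used alone; when the property itself is
missing (one bundled chemical lacks a Kp score) the observed absorption is
used alone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

from .domain import (
    ABSORBED_UNKNOWN_RATE,
    AbsorptionValue,
    ChemicalProfile,
    ConcentrationBin,
    ProductReport,
    Route,
    ScoreRules,
    TargetAge,
    canonical_segment,
    default_rules,
    normalize_label,
)

__all__ = [
    "ScoringWarning",
    "MissingPropertyError",
    "RouteAssignment",
    "RouteComponent",
    "ExposureBreakdown",
    "score_lifestage",
    "score_concentration",
    "score_duration",
    "score_applied_to_skin",
    "assign_exposure_routes",
    "score_solubility",
    "score_vapor_pressure",
    "compute_kp",
    "score_kp",
    "score_absorption",
    "route_component",
    "exposure_score",
]


class ScoringWarning(UserWarning):
    """A documented fallback fired while scoring (unknown segment, etc.)."""


class MissingPropertyError(ValueError):
    """A route has neither a property score/value nor an absorption datum."""


# -- additive product block -------------------------------------------------

def score_lifestage(target_age: TargetAge, rules: Optional[ScoreRules] = None) -> float:
    """Lifestage score: 3 for under-3 products, 1 for ages 3-12."""
    rules = rules or default_rules()
    return rules.lifestage_map[TargetAge(target_age).value]


def score_concentration(bin: ConcentrationBin, rules: Optional[ScoreRules] = None) -> float:
    """Concentration score on 0.5 increments from 0.5 (<100 ppm) to 3 (>10,000 ppm)."""
    rules = rules or default_rules()
    return rules.concentration_map[ConcentrationBin(bin).value]


def score_duration(segment: str, rules: Optional[ScoreRules] = None) -> float:
    """Exposure duration score by product segment (long-term 3, short-term 1).

    Unknown segments fall back to short-term with a :class:`ScoringWarning`.
    """
    rules = rules or default_rules()
    canon = canonical_segment(segment)
    if canon is None:
        warnings.warn(
            f"unknown product segment {segment!r}: duration defaults to short-term",
            ScoringWarning,
            stacklevel=2,
        )
        return rules.duration_short_score
    long_term = {normalize_label(s) for s in rules.long_term_segments}
    return rules.duration_long_score if normalize_label(canon) in long_term else rules.duration_short_score


def score_applied_to_skin(segment: str, rules: Optional[ScoreRules] = None) -> float:
    """Applied-directly-to-skin score: 3 for personal care/hygiene, else 1."""
    rules = rules or default_rules()
    applied = {normalize_label(s) for s in rules.applied_to_skin_segments}
    return rules.applied_yes_score if normalize_label(segment) in applied else rules.applied_no_score


# -- exposure route assignment ---------------------------------------------

_LEVEL_ORDER = {"tertiary": 1, "secondary": 2, "primary": 3}


@dataclass
class RouteAssignment:
    """Primary/secondary/tertiary level and modifying factor per route."""

    levels: dict[Route, str]
    rationale: dict[Route, str]
    rules: ScoreRules = field(default_factory=default_rules, repr=False)

    def mf(self, route: Route) -> int:
        return {
            "primary": self.rules.mf_primary,
            "secondary": self.rules.mf_secondary,
            "tertiary": self.rules.mf_tertiary,
        }[self.levels[route]]

    @property
    def oral_mf(self) -> int:
        return self.mf(Route.ORAL)

    @property
    def dermal_mf(self) -> int:
        return self.mf(Route.DERMAL)

    @property
    def inhalation_mf(self) -> int:
        return self.mf(Route.INHALATION)


_ORAL_BRICK_KEYWORDS = ("kitchen toy", "pacifier", "feeding", "food preparation")
_SPECIAL_BRICK_KEYWORDS = _ORAL_BRICK_KEYWORDS + ("paint", "party blower", "party horn", "fragrance")


def assign_exposure_routes(
    segment: str,
    brick: Optional[str] = None,
    target_age: TargetAge = TargetAge.THREE_TO_TWELVE,
    rules: Optional[ScoreRules] = None,
) -> RouteAssignment:
    """Assign oral/dermal/inhalation exposure levels for one product.

    Rule cascade (first match wins at each step):

    1. primary route(s) from the brick when it names a special product
       (paint, party blower, fragrance, kitchen toy, pacifier/feeding/food
       preparation), otherwise from the product segment;
    2. any primary-oral product gets secondary dermal (children hold what
       they mouth);
    3. under-3 products with non-primary oral get secondary oral
       (hand-to-mouth behavior);
    4. products with neither oral nor inhalation at primary/secondary keep
       both at tertiary (house-dust ingestion/inhalation);
    5. every unassigned route floors at tertiary.
    """
    rules = rules or default_rules()
    levels: dict[Route, Optional[str]] = {r: None for r in Route}
    rationale: dict[Route, str] = {}

    def put(route: Route, level: str, rule: str, force: bool = False) -> None:
        current = levels[route]
        if force or current is None or _LEVEL_ORDER[level] > _LEVEL_ORDER[current]:
            levels[route] = level
            rationale[route] = f"{level}:{rule}"

    # step 1 -- brick rules, then segment rules
    matched_brick = False
    if brick:
        b = normalize_label(brick)
        if "paint" in b:
            put(Route.INHALATION, "primary", "brick:paint")
            put(Route.DERMAL, "secondary", "brick:paint")
            put(Route.ORAL, "tertiary", "brick:paint")
            matched_brick = True
        elif "party blower" in b or "party horn" in b:
            put(Route.ORAL, "primary", "brick:party_blower")
            put(Route.INHALATION, "primary", "brick:party_blower")
            matched_brick = True
        elif "fragrance" in b:
            put(Route.DERMAL, "primary", "brick:fragrance")
            put(Route.INHALATION, "primary", "brick:fragrance")
            matched_brick = True
        elif any(k in b for k in _ORAL_BRICK_KEYWORDS):
            put(Route.ORAL, "primary", "brick:oral_contact")
            matched_brick = True
        else:
            warnings.warn(
                f"brick {brick!r} matches no brick rule; falling back to segment rules",
                ScoringWarning,
                stacklevel=2,
            )
    if not matched_brick:
        canon = canonical_segment(segment)
        oral_primary = {normalize_label(s) for s in rules.oral_primary_segments}
        dermal_primary = {normalize_label(s) for s in rules.dermal_primary_segments}
        if canon is None:
            warnings.warn(
                f"unknown product segment {segment!r}: no primary exposure route assigned",
                ScoringWarning,
                stacklevel=2,
            )
        elif normalize_label(canon) in oral_primary:
            put(Route.ORAL, "primary", "segment:oral")
        elif normalize_label(canon) in dermal_primary:
            put(Route.DERMAL, "primary", "segment:dermal")
        # known segments without a primary-route rule (e.g. stationery,
        # non-feeding baby care) fall through to the tertiary floor

    # step 2 -- primary oral implies secondary dermal
    if levels[Route.ORAL] == "primary":
        put(Route.DERMAL, "secondary", "secondary_dermal_for_oral")

    # step 3 -- under-3 products get at least secondary oral
    if TargetAge(target_age) is TargetAge.UNDER_THREE and levels[Route.ORAL] != "primary":
        put(Route.ORAL, "secondary", "under_three_oral", force=levels[Route.ORAL] == "tertiary")

    # step 4 -- house-dust floor for oral + inhalation
    if levels[Route.ORAL] not in ("primary", "secondary") and levels[Route.INHALATION] not in (
        "primary",
        "secondary",
    ):
        put(Route.ORAL, "tertiary", "house_dust")
        put(Route.INHALATION, "tertiary", "house_dust")

    # step 5 -- floor
    for route in Route:
        if levels[route] is None:
            put(route, "tertiary", "floor")

    return RouteAssignment(levels=dict(levels), rationale=rationale, rules=rules)  # type: ignore[arg-type]


# -- chemical property scores ----------------------------------------------

def score_solubility(solubility: float, rules: Optional[ScoreRules] = None) -> int:
    """Water solubility score (mol/L): insoluble 1, moderate 2, soluble 3."""
    rules = rules or default_rules()
    if solubility <= 0:
        raise ValueError(f"water solubility must be positive, got {solubility}")
    lo, hi = rules.solubility_cutoffs
    if solubility < lo:
        return 1
    if solubility < hi:
        return 2
    return 3


def score_vapor_pressure(vp: float, rules: Optional[ScoreRules] = None) -> int:
    """Vapor pressure score (mmHg, 25 C): nonvolatile 1, semi-volatile 2, volatile 3."""
    rules = rules or default_rules()
    if vp < 0:
        raise ValueError(f"vapor pressure must be non-negative, got {vp}")
    lo, hi = rules.vp_cutoffs
    if vp < lo:
        return 1
    if vp <= hi:
        return 2
    return 3


def compute_kp(log_kow: float, molecular_weight: float) -> float:
    """Skin permeability coefficient Kp (cm/h) from the Potts-Guy QSPR.

    log10(Kp) = -2.72 + 0.71 * log Kow - 0.0061 * MW
    """
    if molecular_weight < 0:
        raise ValueError(f"molecular weight must be non-negative, got {molecular_weight}")
    return 10.0 ** (-2.72 + 0.71 * log_kow - 0.0061 * molecular_weight)


def score_kp(kp: float, rules: Optional[ScoreRules] = None) -> int:
    """Kp score by tertile of the dataset's permeability distribution."""
    rules = rules or default_rules()
    if kp <= 0:
        raise ValueError(f"Kp must be positive, got {kp}")
    lo, hi = rules.kp_cutoffs
    if kp <= lo:
        return 1
    if kp <= hi:
        return 2
    return 3


def score_absorption(observation: AbsorptionValue, rules: Optional[ScoreRules] = None) -> Optional[int]:
    """Observed absorption score, or None when there is no observation.

    Default bins: <=5% scores 1, 5-10% or absorbed-at-unknown-rate scores
    2, above 10% scores 3.  The alternative binning in which anything
    above 5% scores 3 is selectable via ``rules.absorption_table1_variant``.
    """
    rules = rules or default_rules()
    if observation is None:
        return None
    if observation == ABSORBED_UNKNOWN_RATE:
        return rules.absorption_unknown_rate_score
    pct = float(observation)
    if not (0 <= pct <= 100):
        raise ValueError(f"absorption percent out of [0,100]: {pct}")
    lo, hi = rules.absorption_cutoffs
    if pct <= lo:
        return 1
    if rules.absorption_table1_variant:
        return 3
    if pct <= hi:
        return 2
    return 3


# -- equation assembly ------------------------------------------------------

def route_component(
    mf: int,
    property_score: Optional[int],
    absorption_score: Optional[int] = None,
    route: Optional[Route] = None,
) -> float:
    """One route term: MF x mean of the available toxicokinetic scores.

    With both scores present this is ``mf * (property + absorption) / 2``;
    with one missing, the other stands alone.  Both missing is an error
    naming the route's property.
    """
    if property_score is None and absorption_score is None:
        name = route.value if route is not None else "route"
        raise MissingPropertyError(
            f"no property score/value and no absorption observation for the {name} route"
        )
    if property_score is None:
        return mf * float(absorption_score)
    if absorption_score is None:
        return mf * float(property_score)
    return mf * (property_score + absorption_score) / 2.0


_PROPERTY_NAMES = {
    Route.ORAL: "water solubility",
    Route.DERMAL: "skin permeability (Kp)",
    Route.INHALATION: "vapor pressure",
}


def resolve_property_score(
    profile: ChemicalProfile, route: Route, rules: Optional[ScoreRules] = None
) -> Optional[int]:
    """Route-matched property score: pre-assigned score wins, else the raw
    value is binned; Kp may be predicted from log Kow and MW.  None when
    nothing is available."""
    rules = rules or default_rules()
    if route is Route.ORAL:
        if profile.solubility_score is not None:
            return profile.solubility_score
        if profile.water_solubility is not None:
            return score_solubility(profile.water_solubility, rules)
        return None
    if route is Route.INHALATION:
        if profile.vp_score is not None:
            return profile.vp_score
        if profile.vapor_pressure is not None:
            return score_vapor_pressure(profile.vapor_pressure, rules)
        return None
    if profile.kp_score is not None:
        return profile.kp_score
    if profile.kp is not None:
        return score_kp(profile.kp, rules)
    if profile.log_kow is not None and profile.molecular_weight is not None:
        return score_kp(compute_kp(profile.log_kow, profile.molecular_weight), rules)
    return None


def resolve_absorption_score(
    profile: ChemicalProfile, route: Route, rules: Optional[ScoreRules] = None
) -> Optional[int]:
    pre = profile.absorption_scores.get(route)
    if pre is not None:
        return pre
    return score_absorption(profile.absorption.get(route), rules)


@dataclass(frozen=True)
class RouteComponent:
    route: Route
    level: str
    mf: int
    property_score: Optional[int]
    absorption_score: Optional[int]
    component: float

    @property
    def toxicokinetic_average(self) -> float:
        return self.component / self.mf


@dataclass(frozen=True)
class ExposureBreakdown:
    """Full audit trail for one report's exposure score."""

    ls: float
    ex: float
    a: float
    con: float
    routes: dict[Route, RouteComponent]
    total: float

    @property
    def additive_total(self) -> float:
        return self.ls + self.ex + self.a + self.con


def exposure_score(
    report: ProductReport,
    profile: ChemicalProfile,
    rules: Optional[ScoreRules] = None,
) -> ExposureBreakdown:
    """Evaluate the exposure equation for one report, keeping all parts.

    Raises :class:`MissingPropertyError` if a route has neither a property
    score/raw value nor an absorption observation.
    """
    rules = rules or default_rules()
    ls = score_lifestage(report.target_age, rules)
    ex = score_duration(report.segment, rules)
    a = score_applied_to_skin(report.segment, rules)
    con = score_concentration(report.concentration_bin, rules)
    assignment = assign_exposure_routes(report.segment, report.brick, report.target_age, rules)

    components: dict[Route, RouteComponent] = {}
    for route in Route:
        prop = resolve_property_score(profile, route, rules)
        absorbed = resolve_absorption_score(profile, route, rules)
        if prop is None and absorbed is None:
            raise MissingPropertyError(
                f"profile {profile.chemical_id!r}: no {_PROPERTY_NAMES[route]} score or raw "
                f"value and no {route.value} absorption observation"
            )
        if prop is None:
            warnings.warn(
                f"profile {profile.chemical_id!r}: missing {_PROPERTY_NAMES[route]}; "
                f"using observed {route.value} absorption alone",
                ScoringWarning,
                stacklevel=2,
            )
        mf = assignment.mf(route)
        components[route] = RouteComponent(
            route=route,
            level=assignment.levels[route],
            mf=mf,
            property_score=prop,
            absorption_score=absorbed,
            component=route_component(mf, prop, absorbed, route),
        )

    total = ls + ex + a + con + sum(c.component for c in components.values())
    return ExposureBreakdown(ls=ls, ex=ex, a=a, con=con, routes=components, total=total)
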