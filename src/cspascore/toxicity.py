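"""Toxicity scoring: certainty harmonization, potency binning, Eq. total.

Toxicity Score = sum over endpoints {ED, RD, Carc, NT} of
certainty x potency, where certainty (0-3) is the strongest
classification across curated hazard databases and potency (1-3) is
binned from dose metrics: NOAEL-equivalents (mg/kg) for reproductive/
developmental toxicity and endocrine disruption, the lower of the mouse
and rat TD50 (mg/kg/day) for carcinogens, and a fixed factor for
neurotoxicants (no adequate dose source exists for that endpoint).
Potential or suspected toxicants carry a potency of 1 so their certainty
still counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

from .domain import ChemicalProfile, Endpoint, EndpointEvidence, ScoreRules, default_rules
from .exposure import ScoringWarning

__all__ = [
    "VERDICT_SCORES",
    "echa_ed_verdict",
    "harmonize_certainty",
    "loael_to_noael",
    "rfd_to_noael",
    "potency_from_noael",
    "potency_from_td50",
    "endpoint_potency",
    "data_tertile_rules",
    "toxicity_score",
    "ToxicityBreakdown",
    "EndpointScore",
]

#: Classification strength per verdict label.
VERDICT_SCORES: Mapping[str, int] = {
    "none": 0,
    "potential": 1,
    "suspected": 2,
    "known": 3,
}


def echa_ed_verdict(category: Optional[Union[int, str]]) -> str:
    """Map an ECHA endocrine-disruptor listing to a verdict label.

    Category 1 substances are known endocrine disruptors; categories 2
    and 3 are suspected; candidate-list substances without a category are
    potential; unlisted chemicals carry no evidence.
    """
    if category in (None, "", "unlisted"):
        return "none"
    if category in ("candidate", "candidate_unclassified"):
        return "potential"
    cat = int(category)
    if cat == 1:
        return "known"
    if cat in (2, 3):
        return "suspected"
    raise ValueError(f"unknown ECHA ED category: {category!r}")


def harmonize_certainty(verdicts: Union[Mapping[str, str], Iterable[str]]) -> int:
    """Certainty score: the maximum classification over all sources.

    ``verdicts`` maps source name to one of none/potential/suspected/known
    (or is a plain iterable of such labels).  No evidence scores 0.
    """
    labels = list(verdicts.values()) if isinstance(verdicts, Mapping) else list(verdicts)
    score = 0
    for label in labels:
        key = str(label).strip().lower()
        if key not in VERDICT_SCORES:
            raise ValueError(f"unknown verdict label: {label!r}")
        score = max(score, VERDICT_SCORES[key])
    return score


def loael_to_noael(loael: float, rules: Optional[ScoreRules] = None) -> float:
    """NOAEL-equivalent from a LOAEL via the uncertainty factor (default 10)."""
    rules = rules or default_rules()
    if loael <= 0:
        raise ValueError(f"LOAEL must be positive, got {loael}")
    return loael / rules.loael_uf


def rfd_to_noael(rfd: float, uf_product: float) -> float:
    """NOAEL-equivalent from a reference dose and its uncertainty-factor product."""
    if rfd <= 0 or uf_product <= 0:
        raise ValueError(f"RfD and UF product must be positive, got {rfd}, {uf_product}")
    return rfd * uf_product


def potency_from_noael(
    noael_equiv: float, endpoint: Endpoint, rules: Optional[ScoreRules] = None
) -> int:
    """Potency from a NOAEL-equivalent (mg/kg): lower doses are more potent.

    RD default tertile cutoffs 200/397 mg/kg; ED default 336/667 mg/kg.
    """
    rules = rules or default_rules()
    if noael_equiv <= 0:
        raise ValueError(f"NOAEL-equivalent must be positive, got {noael_equiv}")
    endpoint = Endpoint(endpoint)
    if endpoint is Endpoint.RD:
        lo, hi = rules.rd_noael_cutoffs
    elif endpoint is Endpoint.ED:
        lo, hi = rules.ed_noael_cutoffs
    else:
        raise ValueError(f"NOAEL potency applies to RD/ED, not {endpoint}")
    if noael_equiv > hi:
        return 1
    if noael_equiv >= lo:
        return 2
    return 3


def potency_from_td50(
    td50_mouse: Optional[float],
    td50_rat: Optional[float],
    rules: Optional[ScoreRules] = None,
) -> int:
    """Carcinogenic potency from the lower of the two species TD50s."""
    rules = rules or default_rules()
    values = [v for v in (td50_mouse, td50_rat) if v is not None]
    if not values:
        raise ValueError("at least one species TD50 is required")
    td50 = min(values)
    if td50 <= 0:
        raise ValueError(f"TD50 must be positive, got {td50}")
    lo, hi = rules.carc_td50_cutoffs
    if td50 < lo:
        return 3
    if td50 <= hi:
        return 2
    return 1


def data_tertile_rules(
    profiles: Iterable[ChemicalProfile], rules: Optional[ScoreRules] = None
) -> ScoreRules:
    """Rule set with RD/ED/TD50 cutoffs recomputed from a dataset.

    For novel chemical sets the potency tertiles can be taken from the
    range of NOAEL-equivalents (and TD50 minima) actually supplied,
    instead of the bundled fixed cutoffs.  Endpoints with fewer than two
    distinct dose values keep their existing cutoffs.
    """
    import numpy as np

    rules = rules or default_rules()
    overrides = {}
    pools: dict[str, list[float]] = {"rd": [], "ed": [], "carc": []}
    for p in profiles:
        for endpoint, key in ((Endpoint.RD, "rd"), (Endpoint.ED, "ed")):
            noael = _noael_equivalent(p.evidence(endpoint), rules)
            if noael is not None:
                pools[key].append(noael)
        ev = p.evidence(Endpoint.CARC)
        td50s = [v for v in (ev.td50_mouse, ev.td50_rat) if v is not None]
        if td50s:
            pools["carc"].append(min(td50s))
    for key, field_name in (
        ("rd", "rd_noael_cutoffs"),
        ("ed", "ed_noael_cutoffs"),
        ("carc", "carc_td50_cutoffs"),
    ):
        values = pools[key]
        if len(set(values)) >= 2:
            lo, hi = np.quantile(values, [1 / 3, 2 / 3])
            if lo < hi:
                overrides[field_name] = [float(lo), float(hi)]
    return rules.with_overrides(overrides)


def _noael_equivalent(ev: EndpointEvidence, rules: ScoreRules) -> Optional[float]:
    # NOAEL wins over LOAEL; LOAEL over RfD.
    if ev.noael is not None:
        return ev.noael
    if ev.loael is not None:
        return loael_to_noael(ev.loael, rules)
    if ev.rfd is not None and ev.uf_product is not None:
        return rfd_to_noael(ev.rfd, ev.uf_product)
    return None


def endpoint_potency(
    evidence: EndpointEvidence,
    endpoint: Endpoint,
    rules: Optional[ScoreRules] = None,
    chemical_id: str = "",
) -> Optional[int]:
    """Resolve one endpoint's potency score, or None when certainty is 0.

    Certainty 1-2 (potential/suspected) carries potency 1.  Known
    toxicants use a pre-assigned score when present, otherwise the dose
    input: NOAEL-equivalent tertiles for RD/ED, TD50 tertiles for
    carcinogens, and the fixed neurotoxicant factor.  A known toxicant
    with no potency input at all scores 1 with a warning.
    """
    rules = rules or default_rules()
    endpoint = Endpoint(endpoint)
    if evidence.certainty == 0:
        return None
    if evidence.certainty < 3:
        return rules.suspected_potency
    if evidence.potency_score is not None:
        return evidence.potency_score
    if endpoint is Endpoint.NT:
        return rules.nt_potency
    if endpoint is Endpoint.CARC:
        if evidence.td50_mouse is not None or evidence.td50_rat is not None:
            return potency_from_td50(evidence.td50_mouse, evidence.td50_rat, rules)
    else:
        noael = _noael_equivalent(evidence, rules)
        if noael is not None:
            return potency_from_noael(noael, endpoint, rules)
    warnings.warn(
        f"known {endpoint.value} toxicant {chemical_id or '<chemical>'} has no potency "
        "input; assigning potency 1",
        ScoringWarning,
        stacklevel=2,
    )
    return 1


@dataclass(frozen=True)
class EndpointScore:
    endpoint: Endpoint
    certainty: int
    potency: Optional[int]  # None when certainty is 0

    @property
    def product(self) -> int:
        return 0 if self.potency is None else self.certainty * self.potency


@dataclass(frozen=True)
class ToxicityBreakdown:
    """Per-endpoint certainty x potency products and their sum."""

    endpoints: dict[Endpoint, EndpointScore]
    total: int

    def product(self, endpoint: Endpoint) -> int:
        return self.endpoints[Endpoint(endpoint)].product


def toxicity_score(profile: ChemicalProfile, rules: Optional[ScoreRules] = None) -> ToxicityBreakdown:
    """Evaluate the toxicity equation for one chemical profile."""
    rules = rules or default_rules()
    endpoints: dict[Endpoint, EndpointScore] = {}
    for endpoint in Endpoint:
        ev = profile.evidence(endpoint)
        potency = endpoint_potency(ev, endpoint, rules, chemical_id=profile.chemical_id)
        endpoints[endpoint] = EndpointScore(endpoint=endpoint, certainty=ev.certainty, potency=potency)
    total = sum(s.product for s in endpoints.values())
    return ToxicityBreakdown(endpoints=endpoints, total=total)
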