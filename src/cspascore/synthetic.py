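"""Synthetic report databases with the reporting-database structure.

The real reporting database is not published, so downstream stages are
exercised on synthetic report sets drawn from configurable categorical
marginals: product segment (default weights proportional to the published
per-segment report counts; clothing dominates), target age (default 25%
under-3), concentration bin (default uniform over the six ranges) and
chemical (default weights proportional to the published per-chemical
report counts).  Records are independent draws — report-level correlation
structure is deliberately not modeled.  Sequences are deterministic for a
fixed seed (numpy PCG64 generator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .domain import (
    ChemicalProfile,
    ConcentrationBin,
    ProductReport,
    TargetAge,
    validate_report,
)
from .fixtures import CHEMICAL_SUMMARY, SEGMENT_SUMMARY, bundled_profiles

__all__ = ["GeneratorConfig", "generate_reports", "scenario_fixture"]

_SPECIAL_BRICKS = ("pacifier", "kitchen toy", "paint", "party blower", "fragrance")


def _default_segment_weights() -> dict[str, float]:
    counts = {seg: n for seg, (_, _, n) in SEGMENT_SUMMARY.items()}
    total = sum(counts.values())
    return {seg: n / total for seg, n in counts.items()}


def _default_chemical_weights() -> dict[str, float]:
    fixture_ids = {p.chemical_id for p in bundled_profiles()}
    counts = {c: n for c, (n, _, _) in CHEMICAL_SUMMARY.items() if c in fixture_ids}
    total = sum(counts.values())
    return {c: n / total for c, n in counts.items()}


def _default_concentration_weights() -> dict[str, float]:
    bins = ConcentrationBin.ordered()
    return {b.value: 1.0 / len(bins) for b in bins}


@dataclass
class GeneratorConfig:
    """Sampling distributions for one synthetic report database."""

    n_reports: int = 1000
    seed: int = 0
    segment_weights: Mapping[str, float] = field(default_factory=_default_segment_weights)
    under_three_fraction: float = 0.25
    concentration_weights: Mapping[str, float] = field(
        default_factory=_default_concentration_weights
    )
    chemical_weights: Mapping[str, float] = field(default_factory=_default_chemical_weights)
    #: probability that a report carries each special brick; the remainder
    #: get no brick.  Off by default.
    brick_injection_rates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_reports < 0:
            raise ValueError("n_reports must be >= 0")
        if not (0 <= self.under_three_fraction <= 1):
            raise ValueError("under_three_fraction must be in [0, 1]")
        for name in ("segment_weights", "concentration_weights", "chemical_weights"):
            weights = getattr(self, name)
            values = np.asarray(list(weights.values()), dtype=float)
            if len(values) == 0 or (values < 0).any() or not np.isclose(values.sum(), 1.0):
                raise ValueError(f"{name} must be non-negative and sum to 1")
        brick_total = sum(self.brick_injection_rates.values())
        if any(v < 0 for v in self.brick_injection_rates.values()) or brick_total > 1:
            raise ValueError("brick_injection_rates must be non-negative and sum to <= 1")


def _draw(rng: np.random.Generator, weights: Mapping[str, float], size: int) -> np.ndarray:
    keys = np.asarray(list(weights.keys()), dtype=object)
    p = np.asarray(list(weights.values()), dtype=float)
    return rng.choice(keys, size=size, p=p / p.sum())


def generate_reports(config: GeneratorConfig) -> list[ProductReport]:
    """Draw ``n_reports`` independent validated reports; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    segments = _draw(rng, config.segment_weights, n)
    chemicals = _draw(rng, config.chemical_weights, n)
    bins = _draw(rng, config.concentration_weights, n)
    under_three = rng.random(n) < config.under_three_fraction
    if config.brick_injection_rates:
        brick_weights = dict(config.brick_injection_rates)
        brick_weights[""] = 1.0 - sum(brick_weights.values())
        bricks = _draw(rng, brick_weights, n)
    else:
        bricks = np.full(n, "", dtype=object)

    reports = []
    for i in range(n):
        reports.append(
            validate_report(
                {
                    "report_id": f"syn-{config.seed}-{i:06d}",
                    "chemical_id": str(chemicals[i]),
                    "segment": str(segments[i]),
                    "brick": str(bricks[i]) or None,
                    "target_age": (
                        TargetAge.UNDER_THREE.value
                        if under_three[i]
                        else TargetAge.THREE_TO_TWELVE.value
                    ),
                    "concentration_bin": str(bins[i]),
                }
            )
        )
    return reports


def _edge_case_reports() -> list[ProductReport]:
    """Hand-built records exercising every routing rule and every bin."""
    bins = [b.value for b in ConcentrationBin.ordered()]
    specs: list[tuple[str, str, Optional[str], str]] = [
        # (chemical, segment, brick, age) — brick rules
        ("formaldehyde", "Household/Office Furniture/Furnishings", "paint", "three_to_twelve"),
        ("formaldehyde", "Stationery/Office Machinery/Occasion Supplies", "party blower", "three_to_twelve"),
        ("styrene", "Beauty/Personal Care/Hygiene", "fragrance", "three_to_twelve"),
        ("dibutyl_phthalate", "Baby Care", "pacifier", "under_three"),
        ("di2ethylhexyl_phthalate", "Toys/Games", "kitchen toy", "three_to_twelve"),
        # segment rules
        ("styrene", "Kitchen Merchandise", None, "three_to_twelve"),
        ("methyl_ethyl_ketone", "Clothing", None, "under_three"),  # under-3 non-oral
        ("ethylene_glycol", "Stationery/Office Machinery/Occasion Supplies", None, "three_to_twelve"),
        ("cobalt", "Baby Care", None, "three_to_twelve"),  # baby care without feeding brick
        ("molybdenum", "Arts/Crafts/Needlework", None, "three_to_twelve"),
        ("antimony", "Camping", None, "under_three"),  # missing-Kp fallback
        ("butyl_paraben", "Beauty/Personal Care/Hygiene", None, "three_to_twelve"),
        # unknown segment and unmatched brick fallbacks
        ("methyl_paraben", "Jewelry", None, "three_to_twelve"),
        ("propyl_paraben", "Toys/Games", "plush animal", "under_three"),
    ]
    reports = []
    for i, (chem, segment, brick, age) in enumerate(specs):
        reports.append(
            ProductReport(
                report_id=f"edge-{i:03d}",
                chemical_id=chem,
                segment=segment,
                brick=brick,
                target_age=TargetAge(age),
                concentration_bin=ConcentrationBin.ordered()[i % 6],
            )
        )
    # make sure every concentration bin occurs at least once
    for j, b in enumerate(bins):
        reports.append(
            ProductReport(
                report_id=f"edge-bin-{j}",
                chemical_id="styrene",
                segment="Toys/Games",
                target_age=TargetAge.THREE_TO_TWELVE,
                concentration_bin=ConcentrationBin(b),
            )
        )
    return reports


def scenario_fixture(
    name: str, n_reports: int = 1000, seed: int = 0
) -> tuple[list[ProductReport], list[ChemicalProfile]]:
    """Named test scenarios.

    ``paper_like``: the bundled 21 chemical profiles plus a synthetic
    report set drawn with the default (published-count) weights.
    ``edge_cases``: hand-built records hitting every routing rule, the
    missing-Kp fallback, the unknown-segment fallback and all six
    concentration bins.
    """
    profiles = bundled_profiles()
    if name == "paper_like":
        return generate_reports(GeneratorConfig(n_reports=n_reports, seed=seed)), profiles
    if name == "edge_cases":
        return _edge_case_reports(), profiles
    raise ValueError(f"unknown scenario {name!r}; expected 'paper_like' or 'edge_cases'")
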