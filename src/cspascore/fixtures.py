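"""Bundled chemical fixture: the 21 most-reported chemicals/groups.

Each row carries the pre-assigned 1-3 scores for observed absorption by
route (oral / dermal / inhalation), the three route-matched chemical
properties (water solubility S, skin permeability Kp, vapor pressure VP),
and certainty x potency evidence for the four toxicity endpoints
(reproductive/developmental RD, carcinogenicity Carc, neurotoxicity NT,
endocrine disruption ED).  ``None`` encodes a no-information cell; a
certainty of 0 has no applicable potency.

Antimony's Kp score cell is empty in the source table and is stored as
missing; its dermal toxicokinetics fall back to the observed dermal
absorption alone.

Also bundled: the published per-chemical summary statistics (report
counts, mean exposure score, mean total priority index) and the product
segment report counts, used as reference inputs by the comparison
utilities and as default sampling weights by the synthetic generator.
"""

from __future__ import annotations

from typing import Optional

from .domain import ChemicalProfile, Endpoint, EndpointEvidence, Route

__all__ = [
    "bundled_profiles",
    "profile",
    "CHEMICAL_SUMMARY",
    "GROUP_SUMMARY",
    "SEGMENT_SUMMARY",
    "GROUPS",
    "EGME_ALIAS_OF",
]

# chemical_id: (name, group,
#   abs_oral, abs_dermal, abs_inh, S, Kp, VP,
#   (RD_cert, RD_pot), (C_cert, C_pot), (NT_cert, NT_pot), (ED_cert, ED_pot))
_TABLE_ROWS: dict[str, tuple] = {
    "dibutyl_phthalate": (
        "Dibutyl phthalate", "phthalates",
        3, 2, 2, 1, 3, 1, (3, 3), (0, None), (3, 2), (3, 3)),
    "di2ethylhexyl_phthalate": (
        "Di-2-ethylhexyl phthalate", "phthalates",
        3, 2, 2, 1, 2, 1, (3, 3), (3, 1), (0, None), (3, 3)),
    "formaldehyde": (
        "Formaldehyde", "none",
        2, 3, 3, 3, 1, 3, (1, 1), (3, 3), (3, 2), (0, None)),
    "butyl_benzyl_phthalate": (
        "Butyl benzyl phthalate", "phthalates",
        3, 2, 3, 1, 3, 1, (3, 3), (0, None), (0, None), (3, 3)),
    "styrene": (
        "Styrene", "none",
        2, 2, 3, 1, 3, 2, (2, 1), (3, 3), (3, 2), (0, None)),
    "diisodecyl_phthalate": (
        "Diisodecyl phthalate", "phthalates",
        3, None, 3, 1, 2, 1, (3, 3), (0, None), (0, None), (2, 1)),
    "methyl_ethyl_ketone": (
        "Methyl ethyl ketone", "none",
        2, None, 3, 3, 2, 3, (3, 1), (0, None), (3, 2), (0, None)),
    "di_n_hexyl_phthalate": (
        "Di-n-hexyl phthalate", "phthalates",
        None, 3, None, 1, 2, 1, (3, 3), (0, None), (0, None), (2, 1)),
    "butyl_paraben": (
        "Butyl paraben", "parabens",
        None, None, None, 1, 3, 1, (0, None), (0, None), (0, None), (3, 3)),
    "ethylene_glycol": (
        "Ethylene glycol", "ethylene_glycols",
        2, 1, 3, 3, 1, 2, (2, 1), (0, None), (3, 2), (0, None)),
    "ethyl_paraben": (
        "Ethyl paraben", "parabens",
        None, None, None, 1, 3, 1, (0, None), (0, None), (0, None), (3, 1)),
    "cobalt": (
        "Cobalt and cobalt compounds", "metals",
        3, 1, 3, 1, 1, 1, (1, 1), (3, 3), (0, None), (0, None)),
    "diethyl_phthalate": (
        "Diethyl phthalate", "phthalates",
        2, 1, None, 1, 2, 1, (0, None), (1, 1), (0, None), (3, 3)),
    "antimony": (
        "Antimony and antimony compounds", "metals",
        2, 2, 2, 1, None, 1, (0, None), (3, 1), (0, None), (0, None)),
    "diisononyl_phthalate": (
        "Diisononyl phthalate", "phthalates",
        3, 1, 3, 1, 2, 1, (1, 1), (0, None), (0, None), (2, 1)),
    "di_n_octyl_phthalate": (
        "Di-n-octyl phthalate", "phthalates",
        2, None, None, 1, 2, 1, (1, 1), (0, None), (0, None), (1, 1)),
    "octamethylcyclotetrasiloxane": (
        "Octamethylcyclotetrasiloxane", "none",
        None, None, None, 1, 3, 3, (1, 1), (0, None), (0, None), (0, None)),
    "methyl_paraben": (
        "Methyl paraben", "parabens",
        None, None, None, 2, 2, 1, (0, None), (0, None), (0, None), (0, None)),
    "molybdenum": (
        "Molybdenum and molybdenum compounds", "metals",
        None, None, None, 1, 1, 1, (0, None), (0, None), (0, None), (0, None)),
    "phthalic_anhydride": (
        "Phthalic anhydride", "phthalates",
        None, None, None, 2, 1, 1, (0, None), (0, None), (0, None), (0, None)),
    "propyl_paraben": (
        "Propyl paraben", "parabens",
        None, None, None, 1, 3, 1, (0, None), (0, None), (0, None), (0, None)),
}

#: Fixed group membership lists used for group-level aggregation.
GROUPS: dict[str, tuple[str, ...]] = {
    "phthalates": (
        "dibutyl_phthalate", "di2ethylhexyl_phthalate", "butyl_benzyl_phthalate",
        "diisodecyl_phthalate", "di_n_hexyl_phthalate", "diethyl_phthalate",
        "diisononyl_phthalate", "di_n_octyl_phthalate", "phthalic_anhydride",
    ),
    "parabens": ("butyl_paraben", "ethyl_paraben", "methyl_paraben", "propyl_paraben"),
    "ethylene_glycols": ("ethylene_glycol", "ethylene_glycol_monoethyl_ester"),
    "metals": ("cobalt", "antimony", "molybdenum"),
}

#: Ethylene glycol monoethyl ester is reported separately but shares
#: ethylene glycol's toxicity profile; it is an alias, not a 22nd row.
EGME_ALIAS_OF = ("ethylene_glycol_monoethyl_ester", "ethylene_glycol")


def _evidence(pair: tuple[int, Optional[int]]) -> EndpointEvidence:
    certainty, potency = pair
    return EndpointEvidence(certainty=certainty, potency_score=potency)


def bundled_profiles() -> list[ChemicalProfile]:
    """The 21 bundled chemical profiles, in published priority order."""
    profiles = []
    for chem_id, row in _TABLE_ROWS.items():
        (name, group, a_o, a_d, a_i, s, kp, vp, rd, carc, nt, ed) = row
        profiles.append(
            ChemicalProfile(
                chemical_id=chem_id,
                name=name,
                group=group,
                solubility_score=s,
                kp_score=kp,
                vp_score=vp,
                absorption_scores={
                    Route.ORAL: a_o,
                    Route.DERMAL: a_d,
                    Route.INHALATION: a_i,
                },
                endpoint_evidence={
                    Endpoint.RD: _evidence(rd),
                    Endpoint.CARC: _evidence(carc),
                    Endpoint.NT: _evidence(nt),
                    Endpoint.ED: _evidence(ed),
                },
            )
        )
    return profiles


def profile(chemical: str) -> ChemicalProfile:
    """Look up a bundled profile by id or display name (case-insensitive).

    The ethylene glycol monoethyl ester alias resolves to the ethylene
    glycol profile.
    """
    from .domain import normalize_label, profiles_by_id

    index = profiles_by_id(bundled_profiles())
    alias_id, target = EGME_ALIAS_OF
    index[alias_id] = index[target]
    index[normalize_label("Ethylene glycol monoethyl ester")] = index[target]
    key = chemical if chemical in index else normalize_label(chemical)
    if key not in index:
        raise KeyError(f"no bundled profile for {chemical!r}")
    return index[key]


#: Published per-chemical summaries: chemical_id -> (n_reports,
#: mean exposure score, mean total priority index).
CHEMICAL_SUMMARY: dict[str, tuple[int, float, float]] = {
    "formaldehyde": (533, 14.2, 297.8),
    "dibutyl_phthalate": (778, 12.3, 294.7),
    "styrene": (2251, 13.6, 231.2),
    "butyl_benzyl_phthalate": (610, 12.5, 225.2),
    "di2ethylhexyl_phthalate": (909, 10.6, 223.2),
    "diisodecyl_phthalate": (235, 11.6, 127.9),
    "di_n_hexyl_phthalate": (178, 10.2, 112.0),
    "butyl_paraben": (83, 12.0, 108.0),
    "methyl_ethyl_ketone": (2378, 10.2, 91.5),
    "cobalt": (6927, 8.5, 84.5),
    "ethylene_glycol_monoethyl_ester": (31, 10.3, 82.1),
    "diethyl_phthalate": (380, 8.0, 80.0),
    "ethylene_glycol": (6042, 9.8, 78.5),
    "ethyl_paraben": (97, 12.0, 35.9),
    "antimony": (3378, 10.3, 31.0),
    "diisononyl_phthalate": (357, 10.3, 30.8),
    "di_n_octyl_phthalate": (279, 9.6, 19.3),
    "octamethylcyclotetrasiloxane": (2123, 13.9, 13.9),
    "methyl_paraben": (251, 10.2, 0.0),
    "molybdenum": (1617, 5.8, 0.0),
    "phthalic_anhydride": (137, 7.6, 0.0),
    "propyl_paraben": (207, 11.8, 0.0),
}

#: Published group summaries: group -> (n_reports, mean exposure, mean TPI).
GROUP_SUMMARY: dict[str, tuple[int, float, float]] = {
    "phthalates": (3863, 10.8, 172.5),
    "parabens": (638, 11.2, 19.5),
    "ethylene_glycols": (6073, 9.8, 78.5),
}

#: Published segment summaries: segment -> (mean TPI, mean exposure, n_reports).
SEGMENT_SUMMARY: dict[str, tuple[float, float, int]] = {
    "Kitchen Merchandise": (205.8, 12.2, 72),
    "Stationery/Office Machinery/Occasion Supplies": (158.6, 10.1, 365),
    "Toys/Games": (131.9, 13.0, 4910),
    "Arts/Crafts/Needlework": (105.3, 9.3, 631),
    "Household/Office Furniture/Furnishings": (105.1, 10.7, 1446),
    "Baby Care": (103.8, 10.7, 991),
    "Footwear": (90.5, 10.0, 4940),
    "Personal Accessories": (82.3, 9.0, 1229),
    "Clothing": (79.2, 9.3, 14551),
    "Camping": (71.1, 8.9, 87),
    "Beauty/Personal Care/Hygiene": (42.4, 10.2, 559),
}
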