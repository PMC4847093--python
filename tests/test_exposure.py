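"""Exposure scoring: unit rules, route cascade, equation and oracle check."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cspascore.domain import (
    ABSORBED_UNKNOWN_RATE,
    ChemicalProfile,
    ConcentrationBin,
    KNOWN_SEGMENTS,
    ProductReport,
    Route,
    TargetAge,
    default_rules,
)
from cspascore.exposure import (
    MissingPropertyError,
    ScoringWarning,
    assign_exposure_routes,
    compute_kp,
    exposure_score,
    route_component,
    score_absorption,
    score_applied_to_skin,
    score_concentration,
    score_duration,
    score_kp,
    score_lifestage,
    score_solubility,
    score_vapor_pressure,
)
from cspascore.fixtures import bundled_profiles

from eq1_oracle import oracle_exposure

AGES = [TargetAge.UNDER_THREE, TargetAge.THREE_TO_TWELVE]
BINS = ConcentrationBin.ordered()


class TestProductAttributeScores:
    @pytest.mark.parametrize(
        "age, expected",
        [(TargetAge.UNDER_THREE, 3), (TargetAge.THREE_TO_TWELVE, 1)],
    )
    def test_lifestage(self, age, expected):
        assert score_lifestage(age) == expected
        assert score_lifestage(age) == score_lifestage(age)  # pure

    @pytest.mark.parametrize(
        "token, expected",
        [
            ("lt100", 0.5),
            ("100-500", 1.0),
            ("500-1000", 1.5),
            ("1000-5000", 2.0),
            ("5000-10000", 2.5),
            ("gt10000", 3.0),
        ],
    )
    def test_concentration(self, token, expected):
        assert score_concentration(ConcentrationBin(token)) == expected

    @pytest.mark.parametrize(
        "segment, expected",
        [
            ("Clothing", 3),
            ("Footwear", 3),
            ("Beauty/Personal Care/Hygiene", 3),
            ("Camping", 3),
            ("Toys/Games", 1),
            ("Stationery/Office Machinery/Occasion Supplies", 1),
            ("Arts/Crafts/Needlework", 1),
        ],
    )
    def test_duration(self, segment, expected):
        assert score_duration(segment) == expected

    def test_duration_unknown_segment_warns_and_defaults_short(self):
        with pytest.warns(ScoringWarning, match="unknown product segment"):
            assert score_duration("Jewelry") == 1

    @pytest.mark.parametrize(
        "segment, expected",
        [
            ("Beauty/Personal Care/Hygiene", 3),
            ("Clothing", 1),
            ("Kitchen Merchandise", 1),
        ],
    )
    def test_applied_to_skin(self, segment, expected):
        assert score_applied_to_skin(segment) == expected


class TestChemicalPropertyScores:
    @pytest.mark.parametrize(
        "value, expected", [(0.0005, 1), (0.001, 2), (0.005, 2), (0.01, 3), (0.5, 3)]
    )
    def test_solubility(self, value, expected):
        assert score_solubility(value) == expected

    def test_solubility_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            score_solubility(0.0)

    @pytest.mark.parametrize(
        "value, expected", [(0.01, 1), (0.075, 2), (1.0, 2), (32.0, 2), (100.0, 3)]
    )
    def test_vapor_pressure(self, value, expected):
        assert score_vapor_pressure(value) == expected

    @pytest.mark.parametrize(
        "log_kow, mw, expected",
        [
            (0.0, 0.0, 10 ** -2.72),  # constant term only
            (2.0, 100.0, 10 ** -1.91),
            (0.0, 500.0, 10 ** -5.77),
        ],
    )
    def test_potts_guy_kp(self, log_kow, mw, expected):
        assert compute_kp(log_kow, mw) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("value, expected", [(1e-3, 1), (3.395e-3, 1), (5e-3, 2), (6.7e-3, 2), (1e-2, 3)])
    def test_kp_score(self, value, expected):
        assert score_kp(value) == expected

    @pytest.mark.parametrize(
        "obs, expected",
        [
            (None, None),
            (3.0, 1),
            (5.0, 1),
            (ABSORBED_UNKNOWN_RATE, 2),
            (7.0, 2),
            (10.0, 2),
            (50.0, 3),
        ],
    )
    def test_absorption_text_binning(self, obs, expected):
        assert score_absorption(obs) == expected

    def test_absorption_alternative_binning(self):
        rules = default_rules().with_overrides({"absorption_table1_variant": True})
        assert score_absorption(7.0, rules) == 3
        assert score_absorption(3.0, rules) == 1

    def test_absorption_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            score_absorption(150.0)


class TestRouteAssignment:
    def test_under_three_clothing(self):
        a = assign_exposure_routes("Clothing", None, TargetAge.UNDER_THREE)
        assert (a.dermal_mf, a.oral_mf, a.inhalation_mf) == (3, 2, 1)

    def test_paint_brick(self):
        a = assign_exposure_routes("Household/Office Furniture/Furnishings", "paint")
        assert (a.inhalation_mf, a.dermal_mf, a.oral_mf) == (3, 2, 1)

    def test_kitchen_merchandise_secondary_dermal(self):
        a = assign_exposure_routes("Kitchen Merchandise", None, TargetAge.THREE_TO_TWELVE)
        assert (a.oral_mf, a.dermal_mf, a.inhalation_mf) == (3, 2, 1)

    def test_party_blower_dual_primaries(self):
        a = assign_exposure_routes("Toys/Games", "party blower", TargetAge.THREE_TO_TWELVE)
        assert (a.oral_mf, a.inhalation_mf, a.dermal_mf) == (3, 3, 2)

    def test_fragrance_dual_primaries(self):
        a = assign_exposure_routes("Beauty/Personal Care/Hygiene", "fragrance")
        assert (a.dermal_mf, a.inhalation_mf, a.oral_mf) == (3, 3, 1)

    def test_pacifier_brick_is_oral(self):
        a = assign_exposure_routes("Baby Care", "pacifier", TargetAge.UNDER_THREE)
        assert (a.oral_mf, a.dermal_mf, a.inhalation_mf) == (3, 2, 1)

    def test_kitchen_toy_overrides_toys_dermal_default(self):
        a = assign_exposure_routes("Toys/Games", "kitchen toy")
        assert (a.oral_mf, a.dermal_mf) == (3, 2)

    def test_baby_care_without_special_brick_floors(self):
        a = assign_exposure_routes("Baby Care", None, TargetAge.THREE_TO_TWELVE)
        assert (a.oral_mf, a.dermal_mf, a.inhalation_mf) == (1, 1, 1)

    def test_unmatched_brick_falls_back_to_segment(self):
        with pytest.warns(ScoringWarning, match="matches no brick rule"):
            a = assign_exposure_routes("Toys/Games", "plush animal")
        assert a.dermal_mf == 3

    def test_unknown_segment_warns(self):
        with pytest.warns(ScoringWarning, match="unknown product segment"):
            a = assign_exposure_routes("Jewelry", None)
        assert (a.oral_mf, a.dermal_mf, a.inhalation_mf) == (1, 1, 1)

    @pytest.mark.parametrize("segment", KNOWN_SEGMENTS)
    @pytest.mark.parametrize("age", AGES)
    def test_invariants_hold_everywhere(self, segment, age):
        a = assign_exposure_routes(segment, None, age)
        factors = [a.mf(r) for r in Route]
        assert all(f in (1, 2, 3) for f in factors)
        assert sum(1 for r in Route if a.levels[r] == "primary") <= 2
        assert all(a.levels[r] in ("primary", "secondary", "tertiary") for r in Route)


class TestRouteComponent:
    @pytest.mark.parametrize(
        "mf, prop, absorbed, expected",
        [
            (3, 3, 2, 7.5),
            (2, 3, None, 6.0),
            (1, 1, 1, 1.0),
            (3, None, 2, 6.0),  # missing-property fallback
        ],
    )
    def test_values(self, mf, prop, absorbed, expected):
        assert route_component(mf, prop, absorbed) == expected

    def test_both_missing_is_an_error(self):
        with pytest.raises(MissingPropertyError):
            route_component(3, None, None, Route.DERMAL)


def _report(chem, segment, age, bin, brick=None, rid="r"):
    return ProductReport(
        report_id=rid,
        chemical_id=chem,
        segment=segment,
        target_age=age,
        concentration_bin=bin,
        brick=brick,
    )


class TestExposureEquation:
    def test_formaldehyde_in_under3_clothing(self, by_id):
        report = _report(
            "formaldehyde", "Clothing", TargetAge.UNDER_THREE, ConcentrationBin.FROM_100_500
        )
        b = exposure_score(report, by_id["formaldehyde"])
        assert (b.ls, b.ex, b.a, b.con) == (3, 3, 1, 1)
        assert b.routes[Route.ORAL].component == 5.0  # 2 x (3+2)/2
        assert b.routes[Route.DERMAL].component == 6.0  # 3 x (1+3)/2
        assert b.routes[Route.INHALATION].component == 3.0  # 1 x 3
        assert b.total == 22.0

    def test_all_minimum_chemical_in_short_term_arts_product(self):
        minimal = ChemicalProfile(
            chemical_id="min", name="min", solubility_score=1, kp_score=1, vp_score=1
        )
        report = _report(
            "min", "Arts/Crafts/Needlework", TargetAge.THREE_TO_TWELVE, ConcentrationBin.LT_100
        )
        b = exposure_score(report, minimal)
        assert b.additive_total == 3.5
        assert b.total == 8.5  # 3.5 + dermal 3x1 + oral 1x1 + inhalation 1x1

    def test_missing_kp_falls_back_to_dermal_absorption(self, by_id):
        report = _report("antimony", "Clothing", TargetAge.THREE_TO_TWELVE, ConcentrationBin.LT_100)
        with pytest.warns(ScoringWarning, match="skin permeability"):
            b = exposure_score(report, by_id["antimony"])
        assert b.routes[Route.DERMAL].component == 3 * 2  # MF x Abs_dermal alone

    def test_no_data_at_all_names_the_property(self):
        empty = ChemicalProfile(chemical_id="x", name="x", solubility_score=1, vp_score=1)
        report = _report("x", "Clothing", TargetAge.THREE_TO_TWELVE, ConcentrationBin.LT_100)
        with pytest.raises(MissingPropertyError, match="skin permeability"):
            exposure_score(report, empty)

    def test_raw_values_used_when_scores_absent(self):
        raw = ChemicalProfile(
            chemical_id="raw",
            name="raw",
            water_solubility=0.5,  # -> 3
            vapor_pressure=100.0,  # -> 3
            log_kow=2.0,
            molecular_weight=100.0,  # Kp ~ 1.23e-2 -> 3
        )
        report = _report("raw", "Clothing", TargetAge.THREE_TO_TWELVE, ConcentrationBin.LT_100)
        b = exposure_score(report, raw)
        assert all(c.property_score == 3 for c in b.routes.values())

    def test_preassigned_score_wins_over_raw_value(self):
        p = ChemicalProfile(
            chemical_id="p", name="p", solubility_score=1, water_solubility=0.5,
            kp_score=1, vp_score=1,
        )
        report = _report("p", "Clothing", TargetAge.THREE_TO_TWELVE, ConcentrationBin.LT_100)
        assert exposure_score(report, p).routes[Route.ORAL].property_score == 1


def _chem_dict(p):
    return {
        "s": p.solubility_score,
        "kp": p.kp_score,
        "vp": p.vp_score,
        "abs_oral": p.absorption_scores[Route.ORAL],
        "abs_dermal": p.absorption_scores[Route.DERMAL],
        "abs_inh": p.absorption_scores[Route.INHALATION],
    }


class TestGridProperties:
    """Whole-grid checks: 11 segments x 2 ages x 6 bins x 21 chemicals."""

    @pytest.fixture(scope="class")
    def grid(self):
        profiles = bundled_profiles()
        combos = []
        for segment, age, bin, p in itertools.product(KNOWN_SEGMENTS, AGES, BINS, profiles):
            report = _report(p.chemical_id, segment, age, bin)
            combos.append((report, p, exposure_score(report, p)))
        return combos

    def test_grid_size(self, grid):
        assert len(grid) == 11 * 2 * 6 * 21 == 2772

    def test_oracle_equivalence_everywhere(self, grid):
        for report, p, breakdown in grid:
            expected = oracle_exposure(
                report.segment,
                report.brick,
                report.target_age is TargetAge.UNDER_THREE,
                report.concentration_bin.value,
                _chem_dict(p),
            )
            assert breakdown.total == expected, (report.chemical_id, report.segment)

    def test_breakdown_total_equals_sum_of_parts(self, grid):
        for _, _, b in grid:
            recomputed = b.ls + b.ex + b.a + b.con + sum(c.component for c in b.routes.values())
            assert b.total == recomputed

    def test_bounds(self, grid):
        for _, _, b in grid:
            assert 6.5 <= b.total <= 36
            for c in b.routes.values():
                assert 1 <= c.toxicokinetic_average <= 3

    def test_monotone_in_concentration(self, by_id):
        for segment in KNOWN_SEGMENTS:
            totals = [
                exposure_score(
                    _report("styrene", segment, TargetAge.THREE_TO_TWELVE, bin),
                    by_id["styrene"],
                ).total
                for bin in BINS
            ]
            diffs = [b - a for a, b in zip(totals, totals[1:])]
            assert all(d == 0.5 for d in diffs)

    def test_under_three_never_decreases_score(self, by_id):
        for segment, p in itertools.product(KNOWN_SEGMENTS, by_id.values()):
            older = exposure_score(
                _report(p.chemical_id, segment, TargetAge.THREE_TO_TWELVE, BINS[0]), p
            ).total
            younger = exposure_score(
                _report(p.chemical_id, segment, TargetAge.UNDER_THREE, BINS[0]), p
            ).total
            assert younger >= older


@given(
    mf=st.sampled_from([1, 2, 3]),
    prop=st.sampled_from([1, 2, 3]),
    absorbed=st.sampled_from([None, 1, 2, 3]),
)
def test_route_component_matches_closed_form(mf, prop, absorbed):
    expected = mf * prop if absorbed is None else mf * (prop + absorbed) / 2
    assert route_component(mf, prop, absorbed) == expected
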