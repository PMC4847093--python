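# Methods

## The scoring model

`cspascore` implements a multi-attribute prioritization of
manufacturer-reported chemical/product records. Each record is scored on
a 0–3 points-of-concern scale per attribute, and the attributes combine
in three stages:

1. **Exposure score** — an additive product block (lifestage, exposure
   duration, applied-to-skin, concentration bin) plus three route terms,
   each the product of a route modifying factor (primary 3 / secondary 2
   / tertiary 1) and the route's toxicokinetic average. The
   toxicokinetic average is the mean of a route-matched chemical
   property score (water solubility for oral, skin permeability Kp for
   dermal, vapor pressure for inhalation) and the observed absorption
   score for that route.
2. **Toxicity score** — the sum over four endpoints (endocrine
   disruption ED, reproductive/developmental toxicity RD,
   carcinogenicity Carc, neurotoxicity NT) of certainty × potency.
   Certainty is the maximum classification strength across curated
   hazard databases; a certainty of 0 zeroes the endpoint regardless of
   potency.
3. **Total priority index** — exposure × toxicity, per report. The
   index ranks records; it is not a risk estimate, and ratios of indices
   are not ratios of risk.

The model assumes exposure occurs only by the oral, dermal and
inhalation routes; that every product eventually disintegrates into
house dust (so oral and inhalation never score below tertiary); and that
under-3 products always carry oral exposure potential (hand-to-mouth
behavior), which upgrades a non-primary oral route to secondary.

## Rule set and conventions

All cutoffs live in `ScoreRules` (YAML-overridable). Defaults, with the
conventions this implementation fixes where the published rules are
ambiguous at bin boundaries:

| rule | default | convention |
|---|---|---|
| lifestage | under-3 → 3, ages 3–12 → 1 | |
| concentration (ppm) | <100 → 0.5 … >10,000 → 3, half-point steps | bins lower-inclusive, upper-exclusive; top bin open |
| duration | clothing, footwear, personal care, camping → 3; others → 1 | unknown segment → 1 with warning |
| applied to skin | personal care/hygiene → 3, others → 1 | "no" scores 1, not 0 |
| water solubility (mol/L) | <0.001 → 1, 0.001–0.01 → 2, ≥0.01 → 3 | upper cutoff 0.01 (the alternative 0.1 leaves [0.01, 0.1) unmapped) |
| vapor pressure (mmHg, 25 °C) | <0.075 → 1, 0.075–32 → 2, >32 → 3 | middle band closed |
| Kp (cm/h) | ≤3.395e-3 → 1, ≤6.7e-3 → 2, else 3 | boundaries half-open upward; midpoint closes the 3.39/3.4e-3 printing gap |
| observed absorption | ≤5% → 1, 5–10% or unknown-rate → 2, >10% → 3 | <1% floors at 1; alternative "above 5% → 3" binning selectable via `absorption_table1_variant` |
| RD potency (NOAEL mg/kg) | >397 → 1, 200–397 → 2, <200 → 3 | middle band upper bound 397 (one printed occurrence reads 297; inconsistent with its own outer bound) |
| ED potency (NOAEL mg/kg) | >667 → 1, 336–667 → 2, <336 → 3 | the printed row is non-monotone; this is its unique monotone reading |
| Carc potency (TD50 mg/kg/day) | <233 → 3, 233–465 → 2, >465 → 1 | lower of mouse/rat TD50 |
| NT potency | 2 | the published rule table says 2 and the text says 3; 2 reproduces the derivable styrene (17) and methyl ethyl ketone (9) totals, so 2 is the default and 3 a config switch |
| LOAEL → NOAEL | divide by 10 | NOAEL wins when both present; RfD × UF product used only when neither dose is given |

Potency tertiles default to these fixed cutoffs. For novel chemical
sets, `toxicity.data_tertile_rules` recomputes the RD/ED/TD50 cutoffs
from the tertiles of the doses actually supplied.

Kp can be predicted from log Kow and molecular weight with the
Potts–Guy relation, log₁₀ Kp = −2.72 + 0.71·logKow − 0.0061·MW (Kp in
cm/h). Zero molecular weight is accepted (the relation degenerates to
its intercept); negative values are errors.

Pre-assigned scores always win over raw values, both for properties and
for absorption: the bundled fixture's printed scores are authoritative,
and raw values are binned only to fill gaps.

## Route assignment

A first-match cascade, brick rules before segment rules:

1. paint bricks → primary inhalation, secondary dermal, tertiary oral;
   party blowers → primary oral *and* inhalation; fragrances → primary
   dermal *and* inhalation; kitchen-toy, pacifier, feeding and
   food-preparation bricks → primary oral; otherwise kitchen merchandise
   → primary oral, and clothing / personal care / footwear / arts &
   crafts / household / camping / personal accessories / toys & games →
   primary dermal;
2. primary oral implies secondary dermal;
3. under-3 products with non-primary oral get secondary oral — this
   applies after step 1, so an under-3 paint brick upgrades its tertiary
   oral to secondary;
4. records with neither oral nor inhalation at primary/secondary keep
   both at tertiary (house dust);
5. every route floors at tertiary.

Segments with no assignment rule (stationery, baby care without a
feeding-type brick) receive no primary route and fall to the floors of
steps 3–5; unknown segments and unmatched bricks fall back the same way
with a logged warning. At most two routes can be primary. Under these
conventions the exposure score is bounded in [6.5, 36].

## Missing data

Missing observed absorption → the property score stands alone in the
toxicokinetic average. Missing property score (antimony's Kp cell is
empty in the source table) → the observed absorption stands alone,
symmetrically. Both missing is an error naming the route, never a
silent default. Chemicals absent from every hazard database score
toxicity 0 and index 0; they carry an explicit `no_toxicity_data` flag
in the quadrant output because missing evidence is not evidence of
safety.

## Known inconsistencies in the published results

Two published figures cannot be reconciled with the published scoring
inputs, and the implementation follows the inputs:

* **Formaldehyde's toxicity score**: the published per-chemical score
  table gives RD 1×1 + Carc 3×3 + NT 3×2 = 16, but the results text
  prints 21 and the published summary ratios imply ≈21. The package
  computes 16 and the tests assert the discrepancy explicitly.
* **Report-level extremes** (maximum 20.5, minimum 5) and the
  database-wide averages are not reproducible under any single
  consistent reading of the route-assignment rules, and depend on the
  unpublished ~33,000-record database; the same applies to the published
  PCA variance percentages (33.6%/23.1%), whose input matrix is
  under-specified. These are replaced by structural checks: exact
  equivalence with an independent brute-force evaluation of the exposure
  equation over all 2,772 segment × age × bin × chemical combinations,
  bound and monotonicity properties, and the exposure × toxicity
  identity on every scored record.

For the remaining 17 chemicals with nonzero published indices, published
mean index ÷ published mean exposure recovers the fixture-computed
toxicity score to within ±0.1 — including ethylene glycol monoethyl
ester, which is not a row of the bundled score table and shares ethylene
glycol's toxicity profile (its published ratio ≈ 8 confirms this
treatment).

## Synthetic report generator

The generator emulates the *structure* of the reporting database —
categorical marginals over segment, chemical, age and concentration bin
— not its unpublished joint distribution. Defaults:

* segment weights proportional to the published per-segment report
  counts (clothing ≈ 49% of the covered segments, consistent with the
  reported "almost half");
* chemical weights proportional to the published per-chemical report
  counts over the 21 fixture chemicals;
* under-3 fraction 0.25 — the age split is unpublished; a quarter is a
  realistic figure for a children's-product reporting stream and is
  fixed here once;
* concentration bins uniform (joint distribution unpublished);
* special-brick injection (paint, party blower, fragrance, pacifier,
  kitchen toy) off by default, exercised by the `edge_cases` scenario.

Records are independent draws from a seeded numpy PCG64 generator;
determinism is per-seed within this implementation, and statistical
properties rather than bit-identity are the portable contract. Because
records are independent, passing tests on synthetic data demonstrate
correctness of the scoring arithmetic and pipeline plumbing — not
fidelity to real-world report correlations (one product reported for
several chemicals, segment-specific concentration patterns), which the
generator does not model.

## Numerical and design choices

* Aggregation uses the population standard deviation (divisor *n*); the
  published tables do not state their convention and no reproduction
  check depends on it. Rows sort by descending mean index with
  alphabetical tie-break (stable).
* Group aggregation pools report-level records (the published group
  dispersions are much larger than their members', consistent with
  pooling); chemicals without a named group aggregate under their own
  id so that row counts always conserve the number of accepted records.
* Quadrant classification splits at the median per-chemical mean
  exposure and median toxicity; values exactly at a median fall on the
  high side.
* PCA is a correlation PCA (columns standardized to unit variance;
  zero-variance columns dropped with a warning) over 11 variables: the
  four endpoint certainty × potency products, the four additive
  exposure variables and the three route components, report-level
  variables entering as per-chemical means. The variable list is
  declared in the output header so deviations are attributable.
* External comparison reports rank statistics only (Spearman ρ, tertile
  discordance); no attempt is made to place mg/kg/day exposure
  predictions and unitless exposure scores on a common scale.
* Test and acceptance problem sizes: the exposure oracle runs the full
  2,772-combination grid; pipeline checks use 400–600 synthetic
  reports; distributional checks use 10,000; the acceptance script
  scores 5,000. All complete in seconds.

## Limitations

* Metal groups are scored as groups (only total elemental mass is
  reported); compound-specific toxicokinetics are out of reach.
* Bioaccumulation is not modeled; no persistent organic pollutants are
  among the bundled chemicals.
* The four-endpoint toxicity score ignores endpoints outside ED/RD/
  Carc/NT, and databases not encoded in the profiles.
* The index weights all attributes equally within the published rule
  structure; it is a screening rank, not a dose-response model.
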