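# cspascore

Toxicological prioritization of chemicals reported in children's
consumer products.

Under Washington State's Children's Safe Product Act (CSPA),
manufacturers report which of 66 chemicals of high concern occur in
children's products, in which product category, at which concentration
range, and for which target age group. `cspascore` implements a scoring
framework that turns those reports — together with per-chemical
physicochemical properties, absorption data and curated hazard-database
evidence — into rankable priority indices, so that regulators and
researchers can triage tens of thousands of reports by combined exposure
potential and toxicity.

## The scoring model

Each report receives an **exposure score**

```
E = (LS + EX + A + Con)
    + O_MF (S  + Abs_oral)/2
    + D_MF (Kp + Abs_dermal)/2
    + I_MF (VP + Abs_inhalation)/2
```

where the additive block scores the product — lifestage `LS` (3 for
under-3 products, 1 otherwise), exposure duration `EX` (long-term
segments such as clothing score 3), applied-to-skin `A`, and the
concentration bin `Con` (0.5 to 3 in half-point steps over the six
reportable ranges) — and each route term multiplies a modifying factor
`MF` (3/2/1 for primary/secondary/tertiary routes, assigned from the
product segment, brick and target age) by the mean of the route-matched
chemical property score (water solubility `S`, Potts–Guy skin
permeability `Kp`, vapor pressure `VP`) and the observed absorption
score for that route.

Each chemical receives a **toxicity score**

```
T = Σ_e  certainty_e × potency_e ,   e ∈ {ED, RD, Carc, NT}
```

over four endpoints — endocrine disruption, reproductive/developmental
toxicity, carcinogenicity, neurotoxicity. Certainty (0–3) is the
strongest classification across curated databases (ECHA, GHS, IARC,
IRIS, Proposition 65, …); potency (1–3) is binned from NOAEL-equivalents
(LOAEL/10, RfD × uncertainty factors) for ED/RD, from the lower
mouse/rat TD50 for carcinogens, and is a fixed factor of 2 for known
neurotoxicants.

Their product is the **total priority index** `TPI = E × T` — a rank,
not a risk estimate — and per-endpoint indices such as the endocrine
disruptor score `E × ED_certainty × ED_potency` support comparison with
other prioritization schemes (ToxPi, ExpoCast).

The package bundles the published 21-chemical score table as a fixture,
every scoring cutoff as an overridable rule set, a synthetic report
generator emulating the structure of the reporting database, and tools
for aggregation, median-split quadrant classification, correlation PCA
and Spearman rank concordance against external score tables.

## Worked example

```python
from cspascore import exposure_score, toxicity_score, validate_report
from cspascore.fixtures import profile

report = validate_report({
    "report_id": "example-1",
    "chemical_id": "formaldehyde",
    "segment": "Clothing",
    "target_age": "under_three",
    "concentration_bin": "100-500",
})
chem = profile("formaldehyde")
exp = exposure_score(report, chem)
tox = toxicity_score(chem)

print(f"additive block  LS={exp.ls} EX={exp.ex} A={exp.a} Con={exp.con}")
for route, c in exp.routes.items():
    print(f"{route.value:<10} level={c.level:<9} MF={c.mf} "
          f"property={c.property_score} absorption={c.absorption_score} -> {c.component}")
print(f"exposure score      = {exp.total}")
print(f"toxicity score      = {tox.total}")
print(f"total priority index = {exp.total * tox.total}")
```

prints

```
additive block  LS=3.0 EX=3.0 A=1.0 Con=1.0
oral       level=secondary MF=2 property=3 absorption=2 -> 5.0
dermal     level=primary   MF=3 property=1 absorption=3 -> 6.0
inhalation level=tertiary  MF=1 property=3 absorption=3 -> 3.0
exposure score      = 22.0
toxicity score      = 16
total priority index = 352.0
```

Clothing makes dermal the primary route (MF 3); an under-3 product adds
secondary oral (MF 2); inhalation floors at tertiary. Formaldehyde's
high water solubility and absorption push the oral and inhalation
toxicokinetics up, and the additive block contributes 8 points, giving
an exposure score of 22. Its toxicity score of 16 (known carcinogen 3×3,
known neurotoxicant 3×2, potential reproductive toxicant 1×1) multiplies
to a total priority index of 352 for this report.

## Command line

```sh
cspascore simulate --seed 1 --n 1000 --out-dir run/
cspascore score run/reports.csv --out-dir run/
cspascore aggregate run/scored.csv --key chemical --out-dir run/
cspascore quadrants run/scored.csv --out-dir run/
cspascore pca run/scored.csv --out-dir run/
cspascore compare run/aggregate_chemical.csv external_scores.csv --out-dir run/
```

Every run writes a JSON manifest (inputs, rule-set hash, overrides, seed,
record counts). Rules can be overridden globally with `--config
rules.yaml` or `--rules-override KEY=VALUE`.

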