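"""Independent brute-force evaluation of the exposure equation.

Written flat from the scoring rules, sharing no code with the package:
used to cross-check the implementation over the full
segment x age x bin x chemical grid.
"""

LONG_TERM = {"Clothing", "Footwear", "Beauty/Personal Care/Hygiene", "Camping"}
DERMAL_PRIMARY = {
    "Clothing",
    "Beauty/Personal Care/Hygiene",
    "Footwear",
    "Arts/Crafts/Needlework",
    "Household/Office Furniture/Furnishings",
    "Camping",
    "Personal Accessories",
    "Toys/Games",
}
CON_SCORES = {
    "lt100": 0.5,
    "100-500": 1.0,
    "500-1000": 1.5,
    "1000-5000": 2.0,
    "5000-10000": 2.5,
    "gt10000": 3.0,
}
MF = {"P": 3, "S": 2, "T": 1}


def oracle_routes(segment, brick, under_three):
    oral, dermal, inh = "T", "T", "T"
    b = (brick or "").lower()
    if "paint" in b:
        inh, dermal, oral = "P", "S", "T"
    elif "party blower" in b or "party horn" in b:
        oral, inh = "P", "P"
    elif "fragrance" in b:
        dermal, inh = "P", "P"
    elif any(k in b for k in ("pacifier", "kitchen toy", "feeding", "food preparation")):
        oral = "P"
    elif segment == "Kitchen Merchandise":
        oral = "P"
    elif segment in DERMAL_PRIMARY:
        dermal = "P"
    if oral == "P" and dermal == "T":
        dermal = "S"
    if under_three and oral == "T":
        oral = "S"
    return oral, dermal, inh


def oracle_component(level, prop, absorbed):
    if prop is None and absorbed is None:
        raise ValueError("no toxicokinetic data")
    if prop is None:
        tk = absorbed
    elif absorbed is None:
        tk = prop
    else:
        tk = (prop + absorbed) / 2.0
    return MF[level] * tk


def oracle_exposure(segment, brick, under_three, conc_token, chem):
    """chem: dict with s, kp, vp property scores and abs_oral/abs_dermal/
    abs_inh observed-absorption scores (None for no information)."""
    ls = 3.0 if under_three else 1.0
    ex = 3.0 if segment in LONG_TERM else 1.0
    a = 3.0 if segment == "Beauty/Personal Care/Hygiene" else 1.0
    con = CON_SCORES[conc_token]
    oral, dermal, inh = oracle_routes(segment, brick, under_three)
    return (
        ls
        + ex
        + a
        + con
        + oracle_component(oral, chem["s"], chem["abs_oral"])
        + oracle_component(dermal, chem["kp"], chem["abs_dermal"])
        + oracle_component(inh, chem["vp"], chem["abs_inh"])
    )
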