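"""Independent straight-line reference costing, used as the oracle.

Implements the attribution rules directly from their statement, one visit at
a time, accumulating exact Decimal euros box by box; never imports the
engine.  The only shared convention is the documented one: the statutory
reimbursement is rounded half-up to the cent once per drug line.
"""

from decimal import Decimal, ROUND_HALF_UP

CENT = Decimal("0.01")


def reference_breakdown(visit: dict, lines: list[dict], tariff: dict) -> dict:
    """visit/lines/tariff are plain dicts; returns euro Decimals per cell."""
    zero = Decimal("0.00")

    # consultation
    if visit["sector"] == "NUA":
        cons_ss = cons_rem = cons_total = zero
        costed = False
    else:
        costed = True
        cons_total = Decimal(tariff["s2"]) if visit["sector"] == "S2" else Decimal(tariff["s1"])
        share = Decimal("1") if visit["has_dld"] else Decimal(tariff["ss_share"])
        cons_ss = (Decimal(tariff["base"]) * share).quantize(CENT, ROUND_HALF_UP)
        if visit["age"] > int(tariff["adult_age"]):
            cons_ss -= Decimal(tariff["lump_sum"])
        if cons_ss < 0:
            cons_ss = zero
        if cons_ss > cons_total:
            cons_ss = cons_total
        cons_rem = cons_total - cons_ss

    # prescription, box by box
    rx_ss = rx_total = zero
    for line in lines:
        price = Decimal(line["unit_price"])
        rate = Decimal("1") if line["dld_related"] else Decimal(str(line["tier"]))
        reimbursed = franchise = line_total = zero
        for _ in range(int(line["n_boxes"])):
            line_total += price
            reimbursed += rate * price
            franchise += Decimal(tariff["franchise"])
        if rate == 0:
            line_ss = zero
        else:
            line_ss = reimbursed.quantize(CENT, ROUND_HALF_UP) - franchise
            if line_ss < 0:
                line_ss = zero
        rx_ss += line_ss
        rx_total += line_total
    rx_rem = rx_total - rx_ss

    c = 1 if costed else 0
    return {
        "consultation_ss": cons_ss, "consultation_remaining": cons_rem,
        "consultation_total": cons_total,
        "prescription_ss": rx_ss, "prescription_remaining": rx_rem,
        "prescription_total": rx_total,
        "total_ss": c * cons_ss + rx_ss,
        "total_remaining": c * cons_rem + rx_rem,
        "health_expenditure": c * cons_total + rx_total,
        "consultation_costed": costed,
    }


DEFAULT_TARIFF = {
    "s1": "22.00", "s2": "32.00", "base": "22.00", "ss_share": "0.70",
    "lump_sum": "1.00", "adult_age": 18, "franchise": "0.25",
}
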