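"""Tight vs loose identifiers on a charge-discrepant compound pair.

The same C-C(=O)-O skeleton is stored neutral in one database and with a
deprotonated oxygen (formal charge -1) in the other.  Tight coloring keeps
charge in the atom strings, so the identifiers differ; loose coloring keeps
only atom and bond type and absorbs the discrepancy.
"""

from molcolor import ColoringConfig, color_compound, compound_identifier, make_named_fixture

neutral = make_named_fixture("charge_pairA").graph
anion = make_named_fixture("charge_pairB").graph

for label, cfg in (("tight", ColoringConfig.tight()), ("loose", ColoringConfig.loose())):
    ids = [
        compound_identifier(color_compound(g, cfg), label).text
        for g in (neutral, anion)
    ]
    verdict = "MATCH" if ids[0] == ids[1] else "differ"
    print(f"{label}: {verdict}")
    for which, text in zip(("neutral", "anion  "), ids):
        print(f"  {which} {text}")

# tight: differ (the charged oxygen has its own color); loose: MATCH —
# which is why harmonization runs tight first, then falls back to loose.
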