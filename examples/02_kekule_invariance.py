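"""Two Kekulé drawings of the same aromatic compound get one identifier.

Databases draw aromatic rings with alternating single/double bonds placed
arbitrarily.  For a fused ring system the placements can be genuinely
different graphs — one drawing of naphthalene puts a double bond on the ring
fusion bond, the other does not — so coloring the raw drawings yields two
different identifiers for the same compound.  Normalizing detected aromatic
substructures to the aromatic bond order first makes every drawing render
the same graph.
"""

from molcolor import (
    color_compound,
    compound_identifier,
    make_named_fixture,
    normalize_compound,
)

ids = {}
for name in ("naphthalene", "naphthalene_kekuleB"):
    raw = make_named_fixture(name).graph
    raw_id = compound_identifier(color_compound(raw), "loose").text
    normalized = normalize_compound(raw)
    norm_id = compound_identifier(color_compound(normalized), "loose").text
    ids[name] = (raw_id, norm_id)
    print(f"{name}:")
    print(f"  raw identifier has {len(raw_id)} characters")
    print(f"  normalized identifier: {norm_id}")

raw_same = ids["naphthalene"][0] == ids["naphthalene_kekuleB"][0]
norm_same = ids["naphthalene"][1] == ids["naphthalene_kekuleB"][1]
print(f"\nraw identifiers equal: {raw_same}; normalized equal: {norm_same}")

# raw: False — the two drawings would never match across databases;
# normalized: True — the shared string is the cross-database matching key.
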