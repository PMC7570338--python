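"""Color the atoms of a small molecule and inspect its symmetry classes.

Glycerol's heavy-atom skeleton (C-C-C with one hydroxyl oxygen per carbon)
has a mirror symmetry: the two terminal carbons are equivalent, as are their
oxygens, while the central carbon and oxygen are unique.  The coloring
assigns equal identifiers exactly to the symmetric atoms.
"""

from molcolor import ColoringConfig, color_compound, make_named_fixture

g = make_named_fixture("glycerol").graph
colors = color_compound(g, ColoringConfig.loose())

print("per-atom identifiers (atom index: identifier):")
for idx in sorted(colors.full):
    atom = g.atom(idx)
    print(f"  {idx} ({atom.element}): {colors.full[idx]}")

print("\nsymmetry classes (atoms sharing an identifier):")
for group in colors.classes():
    print(" ", sorted(group))

# Expected: classes {0,2}, {1}, {3,5}, {4} — the mirror pairs share a color,
# the unique central atoms do not.
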