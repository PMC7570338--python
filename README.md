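# molcolor

Neighborhood-specific graph coloring identifiers for atoms and compounds,
with cross-database compound harmonization.

## The problem

Atom-resolved metabolic networks need a name for *every atom* of every
metabolite that satisfies two rules: different atoms get different
identifiers, and symmetric atoms — atoms exchanged by an automorphism of the
molecular graph — get the **same** identifier, so that symmetry-induced
alternative atom mappings through reactions are found automatically.
Canonical line notations (SMILES, InChI) do not name atoms this way, and
InChI cannot represent R-group entries at all.  The same machinery solves a
second problem: metabolic databases draw the same compound differently
(Kekulé bond placement, formal charges, stereo annotation), and compounds
must be recognized as identical across databases before networks can be
integrated.

## The method

Every atom gets a **0_layer** string from its own chemistry (element, and —
configurably — charge, stereo parity, isotope).  Breadth-first rounds then
append, per round, a sorted layer of `(bond token)(neighbor 0_layer)` pairs
from the atom's current BFS frontier.  After a minimum of three rounds,
extension continues only for atoms whose identifier is still shared.  A
validation pass re-compares the BFS shells of atoms left sharing an
identifier and a recoloring pass separates flagged *pseudosymmetric* atoms
(asymmetric atoms merged by an under-informative coloring), so the final
classes equal the automorphism orbits of the colored graph.

Atoms are then grouped by identifier and the compound identifier is the
sorted concatenation

```
(n1)[a1](n2)[a2]...(nk)[ak]
```

with `n_k` the number of atoms colored `a_k`.  Equal strings across two
databases propose a correspondence.  **Tight** coloring (all chemical
layers) is matched first; **loose** coloring (atom + bond type only)
absorbs cross-database representation noise.  Candidate pairs are confirmed
by shared cross-references and validated by Enzyme Commission numbers of
the reactions each compound participates in (3-level and 4-level
agreement).  Aromatic substructures are normalized to a single bond order
beforehand, so every Kekulé drawing of a ring system yields one identifier.

## A worked example

```python
from molcolor import ColoringConfig, color_compound, make_named_fixture

g = make_named_fixture("glycerol").graph   # heavy atoms: C-C-C, one O each
colors = color_compound(g, ColoringConfig.loose())
for group in colors.classes():
    print(sorted(group))
```

prints

```
[0, 2]
[1]
[3, 5]
[4]
```

— the two terminal carbons (indices 0, 2) share an identifier, as do their
oxygens (3, 5), while the central carbon (1) and oxygen (4) are unique:
exactly the mirror symmetry of the molecule.  The identifiers themselves
are readable strings; the central carbon's is

```
C(-C,-C,-O)(-O,-O)
```

(its own element, then a layer of two single-bonded carbons and one oxygen,
then the next BFS shell).  Further narrative scripts live in `examples/`:
per-atom coloring, Kekulé invariance of naphthalene identifiers, tight vs
loose matching of charge-discrepant twins, and a full toy-database
harmonization with planted ground truth.

A thin CLI wraps the same functions:

```
molcolor identify compound.mol --mode loose
molcolor harmonize --left dbA/ --right dbB/ -o pairs.tsv
molcolor simdb --seed 1 --n 50 -o toydb/
```

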