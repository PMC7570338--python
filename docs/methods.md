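# Methods

## The problem

Constructing an atom-resolved metabolic network requires naming every atom
of every compound such that (1) different atoms get different identifiers
and (2) symmetric atoms — atoms in the same orbit of the molecular graph's
automorphism group — get the *same* identifier, because either member of a
symmetric pair can carry the same mapping through a reaction.  Canonical
line notations do not provide this: InChI cannot name individual atoms
consistently with symmetry and cannot represent R-group entries at all.
A second, compound-level need follows: two databases drawing the same
metabolite differently (Kekulé placement, formal charges, stereo annotation)
should still be recognized as the same compound.  `molcolor` addresses both
with one mechanism, neighborhood-specific atom coloring.

## Atom coloring

Each atom starts from a **0_layer** string built from its own chemistry in
the fixed field order element | charge | atom stereo | isotope, with
disabled or zero-valued fields omitted (`O`, `O-1`, `C@1`, `N*+2`...).
The field markers (`+ - @ *`) cannot occur in element symbols, so the
encoding is injective over the enabled layers.

The identifier is then extended by breadth-first rounds.  For the atom's
current BFS frontier, each frontier atom contributes its 0_layer string
prefixed by a bond descriptor (`-`, `=`, `#` for orders 1–3, `:` for
aromatic, optionally suffixed `/c` or `/t` for cis/trans when bond stereo is
enabled); the contributions are sorted lexicographically and appended as one
parenthesized layer, after which the frontier advances to unvisited
neighbors-of-frontier.  Three rounds are applied to every atom
(`min_rounds = 3`); extension then continues only for atoms whose identifier
is still shared, until every identifier is unique or the frontier is
exhausted.  Because every step is a canonical function of the graph —
within-layer sorting removes any dependence on atom numbering — symmetric
atoms necessarily finish with equal identifiers, and the whole computation
is deterministic.

Two details are deliberate choices the format does not dictate:

* When a frontier atom is reachable from the visited region through several
  bonds (rings), its bond descriptor is the lexicographically smallest of
  those bond tokens — any fixed rule works as long as it is
  relabeling-invariant.
* Hydrogens are excluded from coloring and from frontier expansion by
  default (`include_hydrogen = False`), because databases disagree about how
  many explicit hydrogens a molfile carries.

**Tight vs loose.**  `ColoringConfig.tight()` enables charge, atom stereo,
bond stereo and isotope; `ColoringConfig.loose()` keeps only atom type and
bond type.  Loose coloring deliberately under-specifies the chemistry so
that cross-database annotation discrepancies (a deprotonated oxygen, a
dropped stereo flag) do not block a match; tight coloring is the stronger
claim and is tried first during harmonization.

## Validation and recoloring of pseudosymmetric atoms

Extending names with 0_layer information only can merge atoms that are not
symmetric ("pseudosymmetric" atoms): in a tricyclic system whose lower two
rings are mirror images, the mirror-related atoms see identical element/bond
shells at every BFS distance even though no automorphism relates them.  Two
repair passes follow the initial coloring:

* **Validation.**  For every group of atoms sharing an identifier, BFS
  shells are expanded simultaneously from each member and compared layer by
  layer until the whole component is consumed.  The comparison uses each
  shell atom's **full identifier** (with its connecting-bond descriptor),
  not its 0_layer string: full identifiers are automorphism-invariant, so
  genuinely symmetric groups always pass, while shells of bare element
  symbols can coincide for asymmetric atoms and would miss exactly the cases
  validation exists to catch (the bundled `pseudosym_triring` fixture
  demonstrates such a false pass).
* **Recoloring.**  Members of a flagged group are re-extended by the same
  BFS scheme but with full identifiers in the layer strings, stopping as
  soon as the members' accumulated strings diverge.  Atoms outside flagged
  groups keep their identifiers.

`color_compound` iterates validate → recolor until validation is clean; a
later pass reads the identifiers refined by an earlier one, which resolves
groups whose first recoloring could not separate them because *other*
atoms' identifiers were still merged.  On every bundled fixture and on
seeded random molecules the final classes equal the exact automorphism
orbits computed by an independent backtracking oracle
(`symmetry_orbits_oracle`), under both tight and loose configurations.

## Compound identifiers

Atoms are grouped by final identifier; each group renders as
`(count)[color]`, substrings are sorted lexicographically as whole strings
(so the count participates in ordering) and concatenated.  Because atom
colors themselves contain `()[]`, those characters are backslash-escaped
inside `[...]`, making the grammar unambiguous; `parse_identifier` is the
exact inverse on canonical strings.  Identifiers are unbounded strings;
equality is always defined on the full text, with a truncated sha256 digest
available for display and indexing only.

## Aromatic perception and normalization

Aromaticity is *not* perceived by electron counting (Hückel rules mislabel
quinoids and depend on ring-size limits); it comes from two pragmatic
sources that mirror how curated databases annotate aromaticity:

1. **Reference matching.**  A library of reference aromatic fragments is
   matched into each compound by VF2 induced subgraph isomorphism with exact
   element compatibility and bond orders compared under the {1, 2, aromatic}
   equivalence, so any Kekulé placement matches a stored fragment.  To keep
   saturated rings from matching, every carbon of an embedding must carry at
   least one double or aromatic bond somewhere in the host — true of all
   Kekulé and quinoid drawings, false for cyclohexane.  Overlapping and
   bonded matches are merged; fragments are the connected components after
   removing bonds that lie on no ring, so fused systems are single fragments
   while biphenyl-type rings stay separate.  The bundled library (benzene,
   pyridine, pyrrole, furan, thiophene, imidazole, naphthalene) is a small
   working set standing in for a database-derived curated collection; users
   point `--library` at their own fragment directory.  Entries are
   deduplicated by loose compound identifier.
2. **O/S ring heuristic.**  Curated atom-type annotations often lack
   aromatic oxygen/sulfur types.  For each ring of size ≤ 8 (minimum cycle
   basis) containing O or S in which every other member is an
   aromatic-labelled C or N, the O/S atoms are added to the aromatic set.
   A ring whose carbons carry no aromatic label (a 1,4-dioxin bridging two
   aromatic rings) is left alone, reproducing the known limitation that
   such cases need inspection.

All bonds interior to a detected fragment are rewritten to order 4 and the
atoms flagged aromatic.  The operation is idempotent and Kekulé-invariant:
every drawing of an aromatic system yields one normalized graph, hence one
compound identifier.

## Double-bond cis/trans

For acyclic order-2 bonds whose ends each carry a heavy substituent besides
the partner, a reference substituent is chosen per end (lowest loose 0_layer
string, ties to lowest index) and the sign of the 2-D cross product of the
substituent vector with the bond axis is compared between the ends: equal
signs → cis, opposite → trans, nearly collinear geometry (|cross| < 1e-6
after unit normalization) → no label.  This is a simplified geometric rule
operating on the 2-D depictions databases actually ship; it feeds coloring
only when bond stereo is enabled (tight mode).  Ring-internal double bonds
and terminal alkenes are never labelled.

## Implicit hydrogens

Molfiles omit hydrogens; `add_implicit_hydrogens` fills each heavy atom to a
default valence (H 1, B 3, C 4, N 3, O 2, F 1, Si 4, P 3, S 2, Cl 1, Br 1,
I 1) adjusted for formal charge: lone-pair elements (N, O, S, P, halogens)
gain a bond per positive and lose one per negative charge, carbon loses a
bond for either sign, boron behaves oppositely to nitrogen.  Aromatic bonds
count 1.5 toward the bond-order sum, floored per atom, which yields one
hydrogen per aromatic CH carbon without Kekulé information.  R-group tokens
are skipped (they are placeholders, not atoms with valence); unknown real
elements raise.  The operation is idempotent and never renumbers existing
atoms.  The valence table is a package decision — the chemical table format
itself does not carry one.

## Harmonization and EC validation

Each database directory (`<id>.mol` files + optional `reactions.tsv` /
`crossrefs.tsv`) is normalized, colored and indexed by identifier text;
compounds sharing a key across databases form candidate pairs (full
Cartesian product within a key — one-to-many mappings are reported, never
auto-resolved).  Tight matching runs first; loose matching is a superset by
construction, and a pair found by both is reported once as tight.  Pairs are
then classified independently two ways:

* `id_confirmed`: the two compounds share a (namespace, foreign id)
  cross-reference, or one side's foreign id in the partner's namespace
  equals the partner's own id.
* `reaction_status`: `no_reactions` if either side participates in no
  reaction, else `in_reactions`, upgraded to `ec3_verified` when some EC
  number from each side agrees on the first three levels (both specified to
  depth ≥ 3 — wildcard suffixes like `2.3.1.-` cap a number at its depth),
  and to `ec4_verified` on full four-level agreement.

## Synthetic data

The `fixtures` module generates every input the tests and the acceptance
script consume; nothing is downloaded.

* **Named fixtures** cover each phenomenon the method must handle: Kekulé
  pairs (benzene, toluene, naphthalene — the naphthalene pair differs on the
  fusion bond, so the raw drawings are genuinely non-isomorphic), molecules
  with hand-checkable symmetry (glycerol, n-propanol, biphenyl), the
  pseudosymmetric tricyclic trap (no symmetric atoms, but mirror pairs that
  collide under a weakened coloring with `min_rounds = 1, max_rounds = 1` —
  the full default coloring avoids the trap, so the cap exists to exercise
  the repair path), charge-discrepant twins, cis/trans butene with explicit
  geometry, and negative controls for aromatic perception.  Declared orbit
  partitions ship with the fixtures.
* **Random molecules** are valence-respecting connected heavy-atom graphs
  over {C, N, O, S, P} (C-weighted), grown as random trees with occasional
  double bonds and closed into rings; sizes 5–25 atoms, deterministic per
  seed.
* **Database pairs** plant a correspondence table: every base compound
  (deduplicated by normalized loose identifier at generation time) appears
  on both sides, right-hand copies perturbed by the requested noise classes;
  each pair's expected match mode (tight unless charge/stereo noise applies),
  cross-reference confirmation (every second pair) and EC outcome (the four
  statuses in rotation) are recorded as planted truth.  Unmatched extras are
  added to each side where requested.

What passing these tests shows — and does not.  The generators emulate
*representation* noise between databases (Kekulé placement, atom order,
charge and stereo annotation); they do not emulate curation errors, R-group
entries at scale, linear/circular or resonance representation changes, or
realistic metabolite size distributions.  Exact planted-truth recovery
therefore demonstrates the method's invariances, not an error rate on real
databases.

## Problem sizes and numerics

Default test and acceptance sizes: 200 random molecules (≤ 25 atoms) for
orbit checks against the exhaustive oracle (bounded at 30 colorable atoms),
20 permutations per fixture for invariance, a 50-compound database pair for
harmonization, and a 1,000-molecule coloring sweep — sizes chosen so the
exhaustive oracle stays exact while exercising every code path; the whole
suite runs in seconds on one CPU.  There is no floating-point numerics in
coloring (pure string/set operations); the only tolerances are the 1e-6
collinearity threshold in stereo perception and 4-decimal molfile
coordinate columns.

## Known limitations

* Geometric symmetry of the 3-D embedding (rotations/reflections beyond
  graph automorphism) is out of scope; identifiers are graph-theoretic.
* Aromatic coverage equals library coverage plus the O/S heuristic; a ring
  system absent from the library and not caught by the heuristic stays in
  its Kekulé form (consistently so, which preserves within-run matching but
  not matching against a database that drew it aromatic).
* Tautomers, resonance forms and linear/circular sugar representations
  yield different graphs and different identifiers by design.
* The cis/trans rule needs meaningful 2-D coordinates and labels only
  acyclic double bonds with heavy substituents on both ends.
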