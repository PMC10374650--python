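# Methods

This note documents the conventions, design choices and limitations behind
the package. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## The data scheme

A transferable force field is modeled as seven relational sections:

1. **intermolecular** — one record per site type (a single tag), holding
   the nonbonded form ID and parameters (charge first).
2. **bond** — tag pair + bond order.
3. **angle** — tag triple; *tag2 is the central site*; order1 connects
   tag1–tag2, order2 connects tag2–tag3.
4. **torsion** — tag quadruple along an unbranched path; tag2/tag3 are the
   central sites.
5. **improper** — central tag0 plus three neighbors; bond orders run from
   tag0 to each neighbor; tag0/tag1/tag2 span the reference plane.
6. **1,n** — scaling factors for intramolecular pairs n−1 bonds apart,
   van der Waals and electrostatic channels separately. An empty table
   means the defaults apply (0 for n ≤ 4, 1 for n > 4), not that 1,n
   interactions are absent.
7. **special** — tag pair at an exact bond-count distance, for
   interactions outside sections 1–6 (e.g. the polyol O···H r⁻¹² guard).

Two documented source ambiguities are worth noting. The prose description
of the tag's running example reads parts 3/4 with swapped roles relative
to the normative field table; the field table (part 3 = bond count,
part 4 = highest order) is implemented, which is the reading consistent
with the bundled data (`A-C-2-1` is the 2-bond CH₂ site). Likewise the
column table labels the angle section's *tag1* "central" while the data
and the running text put the central site in the middle column; tag2 is
central here.

One further convention: part 3 counts bonds to *interaction sites*. Fused
(implicit) hydrogens are not sites and never count; explicitly modeled
polar hydrogens are sites and do count — which is what makes the alcohol
oxygen `Ak-O-2-1` (bonded to one carbon site and one explicit H site) and
the hydroxyl hydrogen `Ak-H-1-1`.

## Units

Evaluators are unit-agnostic: energies come out in whatever unit the
parameters are expressed in; lengths are Å and angles degrees throughout
(harmonic angle/torsion constants are therefore per deg²). Only the
point-charge term needs a physical constant, supplied by a `UnitProfile`
as e²/(4πε₀) in (energy·Å)/e²:

* `eV-Å-e` — 14.3996 eV·Å (the format's declared energy unit; default),
* `K-Å-e` — 167 101 K·Å, for datasets whose dispersion energies are ε/k_B
  in Kelvin, which is how the bundled united-atom alkane/alcohol values
  are printed.

No silent conversion between profiles is ever performed; a dataset carries
its profile marker and the component force field inherits it. The
dielectric ε_l of intermolecular form 4 defaults to 1 (vacuum).

## Resolution semantics

The wildcard `X` matches any value of a tag field or bond order. For a
concrete term, candidate records match in forward or reversed orientation
(impropers: central tag fixed, neighbors as a multiset). The winner is the
unique candidate with maximal specificity = number of non-wildcard tag
fields (0–4 per tag) + 1 per exact bond order. Ties are an error, not a
silent first-match — the scheme defines no precedence between equally
specific records, and ambiguity in a construction plan should be surfaced.

Unresolvable bonds, bends and torsions abort the build: the molecule is
outside the force field's coverage. Two kinds of candidates are instead
dropped silently by design:

* *special* pairs are only candidates by distance; a pair whose tags match
  no special record simply has no special term;
* *improper* candidates (every 3-neighbor combination around a branched
  center) with no matching record are dropped and noted on the component —
  many force fields, including the bundled one, define no impropers, and a
  branched alkane must still build.

1,n pairs whose scaling is (0, 0) are recorded as exclusions rather than
terms, which is the form downstream simulation engines need. A pair can be
both a 1,n pair and a special pair (the diol O···H pairs are); both
contributions apply.

## Atom typing

United-atom fusion folds each hydrogen into its unique heavy neighbor
except in polar contexts (hydroxyl, thiol, amine, amide) where the
hydrogen stays an explicit site; `ALL_HYDROGENS` keeps everything for
all-atom work.

Functional-group assignment matches structural motifs in a fixed priority
order (ring labels first, then carbonyl-rich motifs, then
ether/alcohol/amine, then sulfur groups); each site keeps the first label
it receives, unlabeled carbons default to the alkane group `A` (which by
convention also covers alkene/alkyne carbons), and explicit hydrogens
inherit their heavy neighbor's group. A group's label extends exactly over
the sites in its motif formula — for an alcohol the O, the hydroxyl H and
the α-carbon — and no further; carbons beyond the α-position revert to
`A`. This α-carbon convention is inferred from how the bundled data
parameterizes charged α-carbon types (`Ak-C-x-1`) separately from neutral
alkane carbons, and it is exactly what makes the fixture alcohols build
with zero net charge. How far a group label *should* extend along a carbon
skeleton is not defined by the scheme itself; chemistries beyond the
bundled alkane/alcohol coverage are typed best-effort through the
extensible motif registry.

Aromatic input must be kekulized (bond type 4 is rejected); a six-ring
with alternating single/double bonds types as benzene `B`, saturated
carbon rings as `CA5`/`CA6`/`CA` by size.

## Geometry conventions

Torsions use the signed IUPAC dihedral, trans = 180°. The improper angle Ψ
is measured between the tag0→tag3 bond and the plane through tag0, tag1,
tag2 (the scheme fixes that plane but not the angle convention; this
choice is documented rather than canonical). Rigid constraints are checked,
not evaluated: a deviation of the actual geometry from the constrained
value beyond 10⁻⁶ Å (or deg; configurable) produces a warning record,
never an exception, and the term contributes zero energy.

## Fixtures and what they show

The fixture generator produces small molecules (methane through n-pentane,
isobutane, methanol, ethanol, 1,2-ethanediol, dimethyl ether,
3-methyl-1-butene) with explicit hydrogens and, where the bundled dataset
defines every term, reference coordinates at idealized geometry (bonds
1.54/1.43/0.945 Å, angles 114/112/109.47/108.5°, torsions trans). At these
geometries all flexible bonded terms sit at their reference values, so
bonded energies vanish up to the constant c₀ offsets of torsion series
that are nonzero at trans — a sharp, closed-form check of the whole
pipeline. These molecules exercise every record of the bundled dataset but
are deliberately desk-scale (≤ 8 sites); passing them demonstrates the
correctness of storage, typing, resolution and evaluation, not the
thermodynamic accuracy of any force field, and says nothing about large,
cyclic or polyfunctional chemistry beyond the motifs tested.

Problem sizes throughout the suite and the acceptance script are these
fixture molecules, 200-point r-grids for potential identities, and 20
random atom permutations for determinism checks — the quantities probed
(exact parameter retrieval, algebraic identities, enumeration counts) do
not change with scale.

## Numerical choices

* Exact equality is asserted for parameter retrieval and round trips
  (values pass through SQLite REAL / XLSX doubles unchanged); identities
  checked in floating point use 10⁻¹² relative tolerance.
* The Mie prefactor C_n = n/(n−6)·(n/6)^{6/(n−6)} requires n > 6 and
  reduces to 4 at n = 12; this identity is tested to machine precision.
* Workbook reading coerces numeric cells stored as text ("62500" →
  62500.0); interior gaps in a record's parameter columns are format
  errors, trailing empties are the unused columns of the fixed-width
  layout (widths 4/4/9/12/2/2 = the maximum arity per section).
* Duplicate detection normalizes tuple orientation (bond pair sorted,
  angle/torsion reversed when the reversed tag-text tuple is smaller,
  improper neighbors sorted), since a reversed tuple describes the same
  chemistry.
* Dataset writers refuse invalid datasets; the validator itself never
  throws and reports ERRORs (syntax, arity, duplicates, ranges) separately
  from WARNINGs (non-DOI refs, unknown groups).

## Known limitations

* Coarse-grain, reactive and machine-learned force fields are outside the
  scheme; cis/trans-dependent torsion specifications are not supported.
* No conformer generation, minimization, cutoffs, long-range
  electrostatics, tail corrections, or analytic forces; energies are plain
  sums over terms.
* Workbook I/O is XLSX-only (no legacy binary .xls).
* 1,n separations count bonds through all sites including explicit polar
  hydrogens; this matches the bundled special records' distance
  bookkeeping but is a convention, not a rule the scheme states.
* Typing is guaranteed for the bundled alkane/alcohol chemistry;
  other functional groups are handled best-effort and intended to be
  refined through the extensible registries.
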