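# ffdat

A Python implementation of a tag-based data scheme for **transferable
classical force fields** — the generalized chemical construction plans
(TraPPE-UA, OPLS-AA, Potoff, …) from which component-specific molecular
models are derived for molecular dynamics and Monte Carlo simulation.

The package is aimed at force-field developers, database maintainers and
simulators who need transferable force fields in a machine-readable,
lossless, interoperable form, and who need to turn such a construction plan
plus a molecule's connectivity into an evaluable component model.

## What it implements

**Tags.** Every interaction-site type is named by a four-part identifier
`group-site-nbonds-maxorder`, e.g. `A-C-2-1`: an alkane-group (`A`) carbon
site (`C`, with fused hydrogens implied) forming 2 bonds to other
interaction sites, highest incident bond order 1. Any field may be the
wildcard `X`, so `A-C-X-X` names *all* alkane carbon sites. Twenty-one
functional groups (alkane, alcohol `Ak`, ether `E`, ester `Es`, benzene
`B`, …) are built in and the registry is user-extensible.

**Seven-section datasets.** A transferable force field is stored as seven
relational sections — `intermolecular`, `bond`, `angle`, `torsion`,
`improper`, `1n_potential`, `special` — each row holding a tag tuple, bond
orders, a potential-function ID, its parameters, and a DOI reference.
A function ID of `none` marks a rigid constraint whose single parameter is
the fixed length/angle. Datasets round-trip losslessly between a
single-file SQLite database and an XLSX workbook (one sheet per section).

**Potentials.** The registry covers the standard forms: 12-6
Lennard-Jones and n-6 Mie with point charges and Lorentz–Berthelot-style
combination rules

&nbsp;&nbsp;&nbsp;&nbsp;ε<sub>ij</sub> = √(ε<sub>ii</sub> ε<sub>jj</sub>),&nbsp;
σ<sub>ij</sub> = (σ<sub>ii</sub> + σ<sub>jj</sub>)/2,&nbsp;
q<sub>ij</sub> = q<sub>ii</sub> q<sub>jj</sub>,&nbsp;
n<sub>ij</sub> = (n<sub>ii</sub> + n<sub>jj</sub>)/2,

harmonic/quartic bonds, three bend forms, six torsion forms (cosine series
U(Φ) = c₀ + c₁(1+cos Φ) + c₂(1−cos 2Φ) + c₃(1+cos 3Φ) and friends),
harmonic impropers, the repulsive k₁₂/r¹² special form, and scaled
intermolecular 1,n interactions (default scaling 0 for n ≤ 4, 1 for n > 4,
van der Waals and electrostatics scaled independently).

**Atom typing and assembly.** A MOL/SDF V2000 file (or programmatic graph)
is fused to united-atom sites (polar hydrogens stay explicit), each site
gets a functional group by priority-ordered motif matching and then a
concrete tag; the assembler enumerates all bonds / bends / torsions /
impropers / 1,n and special pairs, resolves each against the dataset by
wildcard matching with a most-specific-wins rule, and emits a
`ComponentForceField` (JSON-serializable) whose energy breakdown can be
evaluated on coordinates.

A transcription of the TraPPE-UA alkane/alcohol subset ships as the
bundled example dataset (`load_bundled("trappe-ua-alkane-alcohol")`).

## Worked example

```python
import ffdat as F

ds = F.load_bundled("trappe-ua-alkane-alcohol")

sg = F.type_molecule(F.make_fixture("ethanol"))
print([str(t) for t in sg.tags()])
# ['A-C-1-1', 'Ak-C-2-1', 'Ak-O-2-1', 'Ak-H-1-1']

ff = F.build_component_ff(ds, F.make_fixture("ethanol"))
print(len(ff.bonds), len(ff.angles), len(ff.torsions), F.net_charge(ff))
# 3 2 1 5.551115123125783e-17

e = F.molecule_energy(ff, F.fixture_coordinates("ethanol"))
print(e.bonded_total)
# 0.0
```

The typed ethanol has four united-atom sites; its CH₃ resolves to the
uncharged alkane type while the α-CH₂, O and hydroxyl H carry the
alcohol-group charges (+0.265, −0.700, +0.435 e), summing to zero at
floating-point precision. All three bonds are rigid constraints, and at the
reference geometry (bonds 1.54/1.43/0.945 Å, angles 109.47/108.5°, trans
torsion) every bonded energy channel is zero.

The same machinery is scriptable from the shell:

```sh
ffdat query --bundled trappe-ua-alkane-alcohol --bond A-C-1-1 1 A-C-2-1
# BondRecord(... id2=None, params=(1.54,), ...)      <- rigid C-C bond
ffdat energy --fixture n-butane --bundled trappe-ua-alkane-alcohol
# bond: 0.000000 K ... total: 0.000000 K
ffdat convert trappe.xlsx trappe.sqlite
```

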