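"""Record types for the seven-section force-field dataset and its validator.

A transferable force field is stored as seven relational sections:
intermolecular, bond, angle, torsion, improper, 1,n scaling, and special
pair interactions.  Records reference site types through tags (possibly
wildcard patterns) plus integer bond orders, carry a potential-function ID
and its parameters, and cite the source publication by DOI.

A function ID of ``None`` marks a *rigid* entry ("none" in the file
formats): the single parameter is then the constrained bond length / angle
/ torsion value itself rather than a potential parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

from . import potentials
from .potentials import OneNRule, Section
from .tags import Tag, WILDCARD, format_tag, known_group, GroupRegistry

Order = Union[int, type(WILDCARD)]

#: Fixed parameter-column widths per section (max arity over the registry).
PARAM_WIDTHS = {
    Section.INTERMOLECULAR: 4,
    Section.BOND: 4,
    Section.ANGLE: 9,
    Section.TORSION: 12,
    Section.IMPROPER: 2,
    Section.SPECIAL: 2,
}


def _order_key(o) -> str:
    return "X" if o is WILDCARD else str(o)


@dataclass(frozen=True)
class InterRecord:
    tag: Tag
    id1: int
    params: tuple
    ref: str = ""

    def key(self):
        return (format_tag(self.tag),)


@dataclass(frozen=True)
class BondRecord:
    tag1: Tag
    order: Order
    tag2: Tag
    id2: Optional[int]  # None = rigid; params[0] is the fixed bond length
    params: tuple
    ref: str = ""

    @property
    def rigid(self) -> bool:
        return self.id2 is None

    def key(self):
        a = (format_tag(self.tag1), _order_key(self.order), format_tag(self.tag2))
        b = (a[2], a[1], a[0])
        return min(a, b)


@dataclass(frozen=True)
class AngleRecord:
    """Angle entry; ``tag2`` names the central site of the bend."""

    tag1: Tag
    order1: Order
    tag2: Tag
    order2: Order
    tag3: Tag
    id3: Optional[int]
    params: tuple
    ref: str = ""

    @property
    def rigid(self) -> bool:
        return self.id3 is None

    def key(self):
        a = (format_tag(self.tag1), _order_key(self.order1), format_tag(self.tag2),
             _order_key(self.order2), format_tag(self.tag3))
        b = (a[4], a[3], a[2], a[1], a[0])
        return min(a, b)


@dataclass(frozen=True)
class TorsionRecord:
    tag1: Tag
    order1: Order
    tag2: Tag
    order2: Order
    tag3: Tag
    order3: Order
    tag4: Tag
    id4: Optional[int]
    params: tuple
    ref: str = ""

    @property
    def rigid(self) -> bool:
        return self.id4 is None

    def key(self):
        a = (format_tag(self.tag1), _order_key(self.order1), format_tag(self.tag2),
             _order_key(self.order2), format_tag(self.tag3), _order_key(self.order3),
             format_tag(self.tag4))
        b = tuple(reversed(a))
        return min(a, b)


@dataclass(frozen=True)
class ImproperRecord:
    """Improper entry; ``tag0`` is the central site, orders run from it to
    each neighbor; tag0/tag1/tag2 span the reference plane."""

    tag0: Tag
    order1: Order
    tag1: Tag
    order2: Order
    tag2: Tag
    order3: Order
    tag3: Tag
    id5: Optional[int]
    params: tuple
    ref: str = ""

    @property
    def rigid(self) -> bool:
        return self.id5 is None

    def key(self):
        neighbors = sorted(
            ((format_tag(t), _order_key(o)) for t, o in
             ((self.tag1, self.order1), (self.tag2, self.order2), (self.tag3, self.order3)))
        )
        return (format_tag(self.tag0),) + tuple(x for pair in neighbors for x in pair)


@dataclass(frozen=True)
class OneNRecord:
    n: int
    scaling1: float  # van der Waals channel
    scaling2: float  # electrostatic channel
    ref: str = ""

    def key(self):
        return (self.n,)

    def to_rule(self) -> OneNRule:
        return OneNRule(self.n, self.scaling1, self.scaling2, self.ref)


@dataclass(frozen=True)
class SpecialRecord:
    tag1: Tag
    dist: int  # bond-count separation of the pair
    tag2: Tag
    id7: Optional[int]
    params: tuple
    ref: str = ""

    def key(self):
        a, b = format_tag(self.tag1), format_tag(self.tag2)
        return (min(a, b), self.dist, max(a, b))


@dataclass
class ForceFieldDataset:
    """A transferable force field: the seven record lists plus metadata."""

    name: str = ""
    intermolecular: list = field(default_factory=list)
    bond: list = field(default_factory=list)
    angle: list = field(default_factory=list)
    torsion: list = field(default_factory=list)
    improper: list = field(default_factory=list)
    one_n: list = field(default_factory=list)
    special: list = field(default_factory=list)
    unit_profile: str = "eV-Å-e"

    def sections(self):
        return {
            Section.INTERMOLECULAR: self.intermolecular,
            Section.BOND: self.bond,
            Section.ANGLE: self.angle,
            Section.TORSION: self.torsion,
            Section.IMPROPER: self.improper,
            Section.ONE_N: self.one_n,
            Section.SPECIAL: self.special,
        }

    def one_n_rules(self):
        return [r.to_rule() for r in self.one_n]

    def sorted(self) -> "ForceFieldDataset":
        """Copy with each section in deterministic (key-sorted) row order."""
        return ForceFieldDataset(
            name=self.name,
            intermolecular=sorted(self.intermolecular, key=lambda r: r.key()),
            bond=sorted(self.bond, key=lambda r: r.key()),
            angle=sorted(self.angle, key=lambda r: r.key()),
            torsion=sorted(self.torsion, key=lambda r: r.key()),
            improper=sorted(self.improper, key=lambda r: r.key()),
            one_n=sorted(self.one_n, key=lambda r: r.key()),
            special=sorted(self.special, key=lambda r: r.key()),
            unit_profile=self.unit_profile,
        )


@dataclass(frozen=True)
class Issue:
    severity: str  # "ERROR" | "WARNING"
    section: str
    row: Optional[int]
    message: str

    def __str__(self):
        where = f"{self.section}[{self.row}]" if self.row is not None else self.section
        return f"{self.severity} {where}: {self.message}"


_SECTION_ID_SLOT = {
    Section.INTERMOLECULAR: "id1",
    Section.BOND: "id2",
    Section.ANGLE: "id3",
    Section.TORSION: "id4",
    Section.IMPROPER: "id5",
    Section.SPECIAL: "id7",
}


def _record_tags(rec):
    return [v for name, v in vars(rec).items() if isinstance(v, Tag)]


def _record_orders(rec):
    return [
        v for name, v in vars(rec).items()
        if name.startswith("order") and not isinstance(v, Tag)
    ]


def validate_dataset(
    dataset: ForceFieldDataset, registry: GroupRegistry | None = None
) -> list:
    """Check a dataset against the schema constraints; never raises.

    ERRORs: unknown function ID, parameter count != function arity,
    duplicate key after symmetry normalization, out-of-range order / dist /
    n, rigid entries without exactly one parameter.  WARNINGs: refs that are
    not DOI-formatted, unknown group abbreviations.
    """
    issues: list = []

    def err(section, row, msg):
        issues.append(Issue("ERROR", section.value, row, msg))

    def warn(section, row, msg):
        issues.append(Issue("WARNING", section.value, row, msg))

    for section, records in dataset.sections().items():
        seen = {}
        for i, rec in enumerate(records):
            # duplicates under symmetry normalization
            k = rec.key()
            if k in seen:
                err(section, i, f"duplicate key {k} (first at row {seen[k]})")
            else:
                seen[k] = i

            if section is Section.ONE_N:
                if rec.n <= 1:
                    err(section, i, f"1,n rank must exceed 1, got {rec.n}")
                for s, label in ((rec.scaling1, "scaling1"), (rec.scaling2, "scaling2")):
                    if not (0.0 <= s <= 1.0):
                        err(section, i, f"{label}={s} outside [0, 1]")
                _check_ref(rec.ref, section, i, warn)
                continue

            # tags: group abbreviation known?
            for tag in _record_tags(rec):
                if tag.group is not WILDCARD and not known_group(tag.group, registry):
                    warn(section, i, f"unknown group abbreviation {tag.group!r} in {tag}")

            # orders / dist ranges
            for o in _record_orders(rec):
                if o is not WILDCARD and (not isinstance(o, int) or o < 1):
                    err(section, i, f"bond order must be >= 1 or wildcard, got {o!r}")
            if section is Section.SPECIAL and rec.dist < 2:
                err(section, i, f"special pair distance must be >= 2, got {rec.dist}")

            # function ID and arity
            fid = getattr(rec, _SECTION_ID_SLOT[section])
            if fid is None:
                if section is Section.INTERMOLECULAR:
                    err(section, i, "intermolecular entries cannot be rigid")
                elif len(rec.params) != 1:
                    err(section, i,
                        f"rigid entry must carry exactly 1 parameter, got {len(rec.params)}")
            else:
                try:
                    fn = potentials.get_function(section, fid)
                except potentials.RegistryError:
                    err(section, i, f"unknown function ID {fid} for section {section.value}")
                else:
                    if len(rec.params) != fn.arity:
                        err(section, i,
                            f"ID {fid} expects {fn.arity} parameters "
                            f"({', '.join(fn.param_names)}), got {len(rec.params)}")
            _check_ref(rec.ref, section, i, warn)

    return issues


def _check_ref(ref, section, i, warn):
    if not isinstance(ref, str) or not ref.startswith("10."):
        warn(section, i, f"ref {ref!r} is not a DOI (expected '10.' prefix)")


def errors_only(issues: Sequence[Issue]) -> list:
    return [i for i in issues if i.severity == "ERROR"]
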