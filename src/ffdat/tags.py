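"""Four-part tag identifiers for interaction-site types.

A tag names a site type in a transferable force field as
``group-site-nbonds-maxorder``, e.g. ``A-C-2-1`` for the CH2 united-atom
site of an alkane chain: alkane group, carbon, two bonds to other
interaction sites, highest incident bond order 1.  Any of the four fields
may be the wildcard ``X``, turning the tag into a pattern that matches a
family of concrete site types (``A-C-X-X`` is "any alkane carbon site").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Union

from .errors import TagError


class _Wildcard:
    """Singleton sentinel for a wildcard tag field (printed ``X``)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "X"

    def __reduce__(self):  # pickle back to the singleton
        return (_Wildcard, ())


#: The wildcard field value; compares equal only to itself.
WILDCARD = _Wildcard()

StrField = Union[str, _Wildcard]
IntField = Union[int, _Wildcard]


@dataclass(frozen=True)
class Tag:
    """One interaction-site type identifier.

    Parameters
    ----------
    group:
        Functional-group abbreviation (see :class:`GroupRegistry`) or
        :data:`WILDCARD`.
    site:
        Element symbol of the (possibly hydrogen-fused) site, ``"C"`` for
        fused carbon groups, or :data:`WILDCARD`.
    n_bonds:
        Number of bonds the site forms with other interaction sites
        (fused hydrogens are not sites), or :data:`WILDCARD`.
    max_order:
        Highest bond order the site enters into, or :data:`WILDCARD`.
    """

    group: StrField
    site: StrField
    n_bonds: IntField
    max_order: IntField

    def __post_init__(self):
        for name in ("group", "site"):
            v = getattr(self, name)
            if v is WILDCARD:
                continue
            if not isinstance(v, str) or not v or "-" in v or v == "X":
                raise TagError(f"invalid tag field {name!r}: {v!r}")
        for name in ("n_bonds", "max_order"):
            v = getattr(self, name)
            if v is WILDCARD:
                continue
            if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                raise TagError(f"tag field {name!r} must be an integer >= 0, got {v!r}")

    @property
    def fields(self) -> tuple:
        return (self.group, self.site, self.n_bonds, self.max_order)

    @property
    def is_concrete(self) -> bool:
        """True when no field is a wildcard."""
        return not any(f is WILDCARD for f in self.fields)

    def __str__(self) -> str:
        return format_tag(self)

    # ordering is on canonical text (wildcards print as "X")
    def __lt__(self, other):
        if not isinstance(other, Tag):
            return NotImplemented
        return format_tag(self) < format_tag(other)


def parse_tag(text: str) -> Tag:
    """Parse ``part1-part2-part3-part4`` text into a :class:`Tag`.

    ``X`` in any part yields a wildcard; parts 3 and 4 are otherwise
    non-negative integers.  Raises :class:`~ffdat.errors.TagError` naming
    the offending part on malformed input.
    """
    if not isinstance(text, str) or not text.strip():
        raise TagError(f"empty tag text: {text!r}")
    parts = text.strip().split("-")
    if len(parts) != 4:
        raise TagError(f"tag {text!r} must have exactly 4 '-'-separated parts, got {len(parts)}")
    out = []
    for idx, part in enumerate(parts, start=1):
        if part == "":
            raise TagError(f"tag {text!r}: part {idx} is empty")
        if part == "X":
            out.append(WILDCARD)
        elif idx <= 2:
            out.append(part)
        else:
            try:
                value = int(part)
            except ValueError:
                raise TagError(
                    f"tag {text!r}: part {idx} must be an integer or 'X', got {part!r}"
                ) from None
            if value < 0:
                raise TagError(f"tag {text!r}: part {idx} must be >= 0, got {value}")
            out.append(value)
    return Tag(*out)


def format_tag(tag: Tag) -> str:
    """Canonical ``part1-part2-part3-part4`` text; inverse of :func:`parse_tag`."""
    return "-".join("X" if f is WILDCARD else str(f) for f in tag.fields)


def matches(pattern: Tag, concrete: Tag) -> bool:
    """True iff every non-wildcard field of ``pattern`` equals ``concrete``'s.

    ``concrete`` must be fully concrete (wildcards there are a usage error).
    """
    if isinstance(pattern, str):
        pattern = parse_tag(pattern)
    if isinstance(concrete, str):
        concrete = parse_tag(concrete)
    if not concrete.is_concrete:
        raise TagError(f"matches() requires a concrete tag, got pattern {concrete}")
    return all(p is WILDCARD or p == c for p, c in zip(pattern.fields, concrete.fields))


def specificity(pattern: Tag) -> int:
    """Number of non-wildcard fields, 0..4 (4 = fully concrete)."""
    if isinstance(pattern, str):
        pattern = parse_tag(pattern)
    return sum(1 for f in pattern.fields if f is not WILDCARD)


@dataclass
class GroupRegistry:
    """Functional-group abbreviations usable in a tag's first part.

    Data-driven and extensible at runtime: new groups can be registered
    alongside the built-in list.
    """

    entries: dict = field(default_factory=dict)

    def register(self, abbrev: str, name: str, motif: str) -> None:
        if abbrev in self.entries:
            raise TagError(f"group {abbrev!r} already registered")
        if not abbrev or "-" in abbrev or abbrev == "X":
            raise TagError(f"invalid group abbreviation {abbrev!r}")
        self.entries[abbrev] = (name, motif)

    def __contains__(self, abbrev: str) -> bool:
        return abbrev in self.entries

    def __iter__(self) -> Iterable[str]:
        return iter(self.entries)

    def name(self, abbrev: str) -> str:
        return self.entries[abbrev][0]

    def motif(self, abbrev: str) -> str:
        return self.entries[abbrev][1]


#: (abbreviation, functional group name, structural motif) built-ins.
#: Alkenes (sp2) and alkynes (sp1) share the alkane abbreviation "A";
#: groups inside saturated rings / aromatic rings use the CA* / B labels.
_BUILTIN_GROUPS = [
    ("A", "alkane", "CHx-CHx, CHx=CHx, CHx#CHx"),
    ("Ac", "acrylate", "CHx-O-C(=O)-CH=CH2"),
    ("Ace", "acetal", "CHx-O-C(-X)2-O-CHx"),
    ("Ad", "amide", "CHx-C(=O)-N-X2"),
    ("Ak", "alcohol", "CHx-O-H"),
    ("Al", "aldehyde", "X-C(-H)=O"),
    ("Am", "amine", "CHx-N-X2"),
    ("B", "benzene", "CH-CH (aromatic)"),
    ("CA", "cycloalkane with 6 < ring size < 18", "CH2-CH2 (cyclic)"),
    ("CA5", "cycloalkane with ring size 5", "CH2-CH2 (cyclic)"),
    ("CA6", "cycloalkane with ring size 6", "CH2-CH2 (cyclic)"),
    ("Cac", "carboxylic acid", "CHx-C(=O)-O-H"),
    ("DS", "disulfide", "CHx-S-S-CHx"),
    ("E", "ether", "CHx-O-CHx"),
    ("Es", "ester", "CHx-C(=O)-O-CHx"),
    ("K", "ketone", "CHx-C(=O)-CHx"),
    ("mAc", "methacrylate", "CHx-O-C(=O)-C(-CH3)=CHx"),
    ("Nl", "nitrile", "CHx-C#N"),
    ("No", "nitro", "CHx-N-O2"),
    ("Sd", "sulfide", "CHx-S-CHx"),
    ("Tl", "thiol", "CHx-S-H"),
]


def default_registry() -> GroupRegistry:
    """Fresh registry seeded with the built-in functional groups."""
    reg = GroupRegistry()
    for abbrev, name, motif in _BUILTIN_GROUPS:
        reg.register(abbrev, name, motif)
    return reg


_DEFAULT = default_registry()


def known_group(abbrev: str, registry: GroupRegistry | None = None) -> bool:
    """True iff ``abbrev`` is a registered functional-group abbreviation."""
    return abbrev in (registry if registry is not None else _DEFAULT)
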