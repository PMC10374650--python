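"""Atom typing: united-atom fusion, functional-group assignment, tags.

The data scheme presumes that every interaction site of a molecule carries
a concrete four-part tag.  This module derives those tags from plain
connectivity in three steps:

1. :func:`unite_atoms` — fuse hydrogens into their heavy neighbor to form
   united-atom interaction sites, keeping polar hydrogens (hydroxyl, thiol,
   amine, amide) as explicit sites, which is how united-atom force fields
   model them;
2. :func:`assign_groups` — label each site with a functional-group
   abbreviation by matching small structural motifs in priority order
   (most specific first: ester before ether and ketone, acid before
   alcohol, acetal before ether); plain carbon defaults to the alkane
   group, which also covers alkene/alkyne carbons;
3. :func:`assign_tags` — read off each site's tag: group, site symbol
   (fused carbon groups are written "C"), number of bonds to other
   interaction sites, and highest incident bond order.

A functional group's label extends to the sites inside its motif formula:
for an alcohol that is the oxygen, the hydroxyl hydrogen, and the
alpha-carbon bonded to the oxygen; carbons beyond the alpha position revert
to the alkane group.  That convention is what lets e.g. ethanol resolve its
CH3 to the uncharged alkane type while the charged alpha-CH2/O/H sites get
alcohol-group parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import networkx as nx

from .errors import StructureError, TypingError
from .molgraph import MolecularGraph
from .tags import GroupRegistry, Tag, default_registry

#: Hydrogen contexts kept as explicit sites by default (polar hydrogens).
DEFAULT_KEEP_H = frozenset({"hydroxyl", "thiol", "amine-H", "amide-H"})
#: Pass as keep_h_on to retain every hydrogen (all-atom modeling level).
ALL_HYDROGENS = frozenset({"all"})


@dataclass
class Site:
    """One interaction site: a heavy atom (plus fused hydrogens) or an
    explicit hydrogen."""

    element: str
    fused_h: int = 0
    group: Optional[str] = None
    tag: Optional[Tag] = None
    atom_index: int = -1  # index of the retained atom in the source graph


@dataclass
class SiteGraph:
    sites: list
    bonds: list  # (i, j, order) between site indices
    name: str = ""
    source_atom_count: int = 0

    def neighbors(self, i: int) -> list:
        out = []
        for a, b, order in self.bonds:
            if a == i:
                out.append((b, order))
            elif b == i:
                out.append((a, order))
        return out

    def degree(self, i: int) -> int:
        return len(self.neighbors(i))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(name=self.name)
        g.add_nodes_from(range(len(self.sites)))
        g.add_edges_from((i, j, {"order": o}) for i, j, o in self.bonds)
        return g

    def tags(self) -> list:
        return [s.tag for s in self.sites]


def _hydrogen_context(graph: MolecularGraph, h: int) -> str:
    """Chemical context of a hydrogen atom, used to decide explicit modeling."""
    nbrs = graph.neighbors(h)
    if len(nbrs) != 1:
        raise StructureError(
            f"hydrogen atom {h} has {len(nbrs)} neighbors; exactly 1 required"
        )
    heavy, _ = nbrs[0]
    elem = graph.atoms[heavy]
    if elem == "O":
        return "hydroxyl"
    if elem == "S":
        return "thiol"
    if elem == "N":
        # amide when the nitrogen sits next to a carbonyl carbon
        for c, order in graph.neighbors(heavy):
            if graph.atoms[c] == "C" and any(
                graph.atoms[k] == "O" and o2 == 2 for k, o2 in graph.neighbors(c)
            ):
                return "amide-H"
        return "amine-H"
    return "alkyl"


def unite_atoms(
    graph: MolecularGraph, keep_h_on: Iterable[str] = DEFAULT_KEEP_H
) -> SiteGraph:
    """Fuse hydrogens into their heavy neighbors, producing interaction sites.

    A hydrogen whose context (hydroxyl, thiol, amine-H, amide-H, alkyl) is
    in ``keep_h_on`` stays an explicit site; pass :data:`ALL_HYDROGENS` for
    an all-atom site graph.  Heavy-atom connectivity is unchanged.
    """
    keep = frozenset(keep_h_on)
    keep_all = "all" in keep

    fuse_into = {}  # H atom index -> heavy atom index
    for i, elem in enumerate(graph.atoms):
        if elem != "H":
            continue
        context = _hydrogen_context(graph, i)  # also validates valence
        if keep_all or context in keep:
            continue
        heavy, order = graph.neighbors(i)[0]
        if graph.atoms[heavy] == "H":
            raise StructureError(f"hydrogen atom {i} is bonded to another hydrogen")
        fuse_into[i] = heavy

    site_of = {}
    sites = []
    for i, elem in enumerate(graph.atoms):
        if i in fuse_into:
            continue
        site_of[i] = len(sites)
        sites.append(Site(element=elem, atom_index=i))
    for h, heavy in fuse_into.items():
        sites[site_of[heavy]].fused_h += 1

    bonds = [
        (site_of[a], site_of[b], order)
        for a, b, order in graph.bonds
        if a not in fuse_into and b not in fuse_into
    ]
    return SiteGraph(sites, bonds, name=graph.name, source_atom_count=len(graph.atoms))


# ---------------------------------------------------------------------------
# functional-group motifs

def _has_hydrogen(sg: SiteGraph, i: int) -> bool:
    return sg.sites[i].fused_h > 0 or any(
        sg.sites[j].element == "H" for j, _ in sg.neighbors(i)
    )


def _explicit_h(sg: SiteGraph, i: int) -> list:
    return [j for j, _ in sg.neighbors(i) if sg.sites[j].element == "H"]


def _nbr_elems(sg: SiteGraph, i: int, element: str, order: int | None = None) -> list:
    return [
        j for j, o in sg.neighbors(i)
        if sg.sites[j].element == element and (order is None or o == order)
    ]


def _carbonyl_carbons(sg: SiteGraph) -> list:
    """(carbon, doubly-bonded oxygen) pairs."""
    out = []
    for i, s in enumerate(sg.sites):
        if s.element == "C":
            for j in _nbr_elems(sg, i, "O", order=2):
                out.append((i, j))
    return out


def _ring_motifs(sg: SiteGraph):
    """Benzene / cycloalkane ring labels for ring-member carbons."""
    g = sg.to_networkx()
    motifs = []
    for ring in nx.minimum_cycle_basis(g):
        if not all(sg.sites[i].element == "C" for i in ring):
            continue
        ring_set = set(ring)
        edge_orders = [
            o for a, b, o in sg.bonds if a in ring_set and b in ring_set
        ]
        size = len(ring)
        if size == 6 and sorted(edge_orders) == [1, 1, 1, 2, 2, 2]:
            motifs.append(("B", ring_set))
        elif all(o == 1 for o in edge_orders):
            if size == 5:
                motifs.append(("CA5", ring_set))
            elif size == 6:
                motifs.append(("CA6", ring_set))
            elif 6 < size < 18:
                motifs.append(("CA", ring_set))
    return motifs


def _ester_like(sg: SiteGraph):
    """(carbonyl C, =O, -O-, alkoxy partner or None, acid H or None) tuples."""
    out = []
    for c, o_dbl in _carbonyl_carbons(sg):
        for o_single in _nbr_elems(sg, c, "O", order=1):
            partners = [j for j, _ in sg.neighbors(o_single) if j != c]
            alkoxy_c = next(
                (j for j in partners if sg.sites[j].element == "C"), None
            )
            acid_h = next(
                (j for j in partners if sg.sites[j].element == "H"), None
            )
            acid = acid_h is not None or (alkoxy_c is None and sg.sites[o_single].fused_h > 0)
            out.append((c, o_dbl, o_single, alkoxy_c, acid_h, acid))
    return out


def _motifs(sg: SiteGraph):
    """Yield (group, member set) motif instances in priority order."""
    motifs = list(_ring_motifs(sg))

    ester_like = _ester_like(sg)

    # acetal: C(-O-C)(-O-C) without a carbonyl
    carbonyl_cs = {c for c, _ in _carbonyl_carbons(sg)}
    for i, s in enumerate(sg.sites):
        if s.element != "C" or i in carbonyl_cs:
            continue
        single_os = [
            o for o in _nbr_elems(sg, i, "O", order=1)
            if any(sg.sites[j].element == "C" and j != i for j, _ in sg.neighbors(o))
        ]
        if len(single_os) == 2:
            members = {i, *single_os}
            for o in single_os:
                members.update(
                    j for j, _ in sg.neighbors(o) if sg.sites[j].element == "C"
                )
            motifs.append(("Ace", members))

    # carboxylic acid before ester before alcohol/ether
    for c, o_dbl, o_single, alkoxy_c, acid_h, acid in ester_like:
        alpha = [j for j in _nbr_elems(sg, c, "C")]
        if acid:
            members = {c, o_dbl, o_single, *alpha}
            if acid_h is not None:
                members.add(acid_h)
            motifs.append(("Cac", members))
        elif alkoxy_c is not None:
            members = {c, o_dbl, o_single, alkoxy_c, *alpha}
            # acrylate / methacrylate: vinyl carbon on the carbonyl side
            vinyl = None
            for a in alpha:
                partners = _nbr_elems(sg, a, "C", order=2)
                if partners:
                    vinyl = (a, partners[0])
                    break
            if vinyl is not None:
                a, v = vinyl
                members |= {a, v}
                methyls = [
                    j for j in _nbr_elems(sg, a, "C")
                    if j != v and j != c and sg.degree(j) == 1
                ]
                motifs.append(("mAc" if methyls else "Ac", members))
            else:
                motifs.append(("Es", members))

    # amide: carbonyl C bonded to N
    for c, o_dbl in _carbonyl_carbons(sg):
        for n in _nbr_elems(sg, c, "N"):
            members = {c, o_dbl, n, *_explicit_h(sg, n), *_nbr_elems(sg, c, "C")}
            motifs.append(("Ad", members))

    # aldehyde / ketone
    ester_cs = {c for c, *_ in ester_like}
    amide_cs = {
        c for c, _ in _carbonyl_carbons(sg) if _nbr_elems(sg, c, "N")
    }
    for c, o_dbl in _carbonyl_carbons(sg):
        if c in ester_cs or c in amide_cs:
            continue
        alpha = _nbr_elems(sg, c, "C")
        if len(alpha) == 2:
            motifs.append(("K", {c, o_dbl, *alpha}))
        elif len(alpha) <= 1 and _has_hydrogen(sg, c):
            motifs.append(("Al", {c, o_dbl, *_explicit_h(sg, c)}))

    # nitro / nitrile / amine
    for i, s in enumerate(sg.sites):
        if s.element == "N":
            oxygens = _nbr_elems(sg, i, "O")
            if len(oxygens) >= 2:
                motifs.append(("No", {i, *oxygens, *_nbr_elems(sg, i, "C")}))
    for i, s in enumerate(sg.sites):
        if s.element == "C":
            triple_n = _nbr_elems(sg, i, "N", order=3)
            if triple_n:
                motifs.append(("Nl", {i, *triple_n, *_nbr_elems(sg, i, "C")}))
    for i, s in enumerate(sg.sites):
        if s.element != "N":
            continue
        nbr_elems = {sg.sites[j].element for j, _ in sg.neighbors(i)}
        if nbr_elems <= {"C", "H"} and not any(
            j in {c for c, _ in _carbonyl_carbons(sg)} for j in _nbr_elems(sg, i, "C")
        ):
            motifs.append(("Am", {i, *_explicit_h(sg, i), *_nbr_elems(sg, i, "C")}))

    # ethers and alcohols (esters/acetals already claimed their oxygens)
    for i, s in enumerate(sg.sites):
        if s.element != "O":
            continue
        carbons = _nbr_elems(sg, i, "C", order=1)
        has_h = s.fused_h > 0 or _explicit_h(sg, i)
        if len(carbons) == 2 and not has_h:
            motifs.append(("E", {i, *carbons}))
        elif len(carbons) == 1 and has_h:
            motifs.append(("Ak", {i, *carbons, *_explicit_h(sg, i)}))

    # sulfur groups
    for i, s in enumerate(sg.sites):
        if s.element != "S":
            continue
        s_nbrs = _nbr_elems(sg, i, "S")
        carbons = _nbr_elems(sg, i, "C")
        has_h = s.fused_h > 0 or _explicit_h(sg, i)
        if s_nbrs:
            j = s_nbrs[0]
            motifs.append(
                ("DS", {i, j, *carbons, *_nbr_elems(sg, j, "C")})
            )
        elif has_h and carbons:
            motifs.append(("Tl", {i, *carbons, *_explicit_h(sg, i)}))
        elif len(carbons) == 2:
            motifs.append(("Sd", {i, *carbons}))

    return motifs


#: Priority of group labels, most specific motif first.  A site keeps the
#: first label it receives.
GROUP_PRIORITY = [
    "B", "CA5", "CA6", "CA",          # ring membership wins
    "Ace", "Cac", "mAc", "Ac", "Es",  # oxygen-rich carbonyl motifs
    "Ad", "No", "Nl", "Al", "K",
    "Am", "E", "Ak",
    "DS", "Tl", "Sd",
]


def assign_groups(
    sg: SiteGraph, registry: GroupRegistry | None = None
) -> SiteGraph:
    """Label every site with a functional-group abbreviation (in place).

    Motifs are applied most-specific-first; carbon sites in no motif
    default to the alkane group "A" (this includes alkene/alkyne carbons);
    explicit hydrogens in no motif inherit their heavy neighbor's group.
    Unassignable sites raise :class:`~ffdat.errors.TypingError`.
    """
    if registry is None:
        registry = default_registry()
    rank = {g: k for k, g in enumerate(GROUP_PRIORITY)}
    assigned = {}
    for group, members in sorted(
        _motifs(sg), key=lambda m: rank.get(m[0], len(rank))
    ):
        if group not in registry:
            continue
        for i in members:
            assigned.setdefault(i, group)

    for i, site in enumerate(sg.sites):
        if i in assigned:
            continue
        if site.element == "C":
            assigned[i] = "A"

    # explicit hydrogens inherit the group of their heavy neighbor
    for i, site in enumerate(sg.sites):
        if i in assigned or site.element != "H":
            continue
        heavy = [j for j, _ in sg.neighbors(i)]
        if heavy and heavy[0] in assigned:
            assigned[i] = assigned[heavy[0]]

    missing = [i for i in range(len(sg.sites)) if i not in assigned]
    if missing:
        desc = ", ".join(
            f"site {i} ({sg.sites[i].element})" for i in missing
        )
        raise TypingError(f"no functional group assignable to: {desc}")

    for i, site in enumerate(sg.sites):
        site.group = assigned[i]
    return sg


def assign_tags(sg: SiteGraph) -> SiteGraph:
    """Derive each site's concrete tag from its group and bonding (in place).

    Part 2 is "C" for any carbon site (fused hydrogens are not written),
    the element symbol otherwise.  Part 3 counts bonds to other interaction
    sites (an isolated united site like methane has 0), part 4 is the
    highest incident bond order (0 when unbonded).
    """
    for i, site in enumerate(sg.sites):
        if site.group is None:
            raise TypingError(f"site {i} has no group; run assign_groups first")
        orders = [o for _, o in sg.neighbors(i)]
        site.tag = Tag(
            group=site.group,
            site=site.element,
            n_bonds=len(orders),
            max_order=max(orders, default=0),
        )
    return sg


def type_molecule(
    graph: MolecularGraph,
    registry: GroupRegistry | None = None,
    keep_h_on: Iterable[str] = DEFAULT_KEEP_H,
) -> SiteGraph:
    """Full pipeline: fuse hydrogens, assign groups, derive tags."""
    sg = unite_atoms(graph, keep_h_on=keep_h_on)
    assign_groups(sg, registry)
    return assign_tags(sg)


def site_report(sg: SiteGraph) -> str:
    """Tab-delimited typed-site table: index, element, fused H, group, tag."""
    lines = ["site\telement\tfused_h\tgroup\ttag"]
    for i, s in enumerate(sg.sites):
        lines.append(f"{i}\t{s.element}\t{s.fused_h}\t{s.group or '-'}\t{s.tag or '-'}")
    return "\n".join(lines) + "\n"
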