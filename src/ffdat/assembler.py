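"""Build component-specific force fields from a typed molecule and a dataset.

Given a typed :class:`~ffdat.atomtyping.SiteGraph` and a
:class:`~ffdat.records.ForceFieldDataset`, this module enumerates every
interaction term the molecular topology implies (bonds, bends, proper and
improper torsions, 1,n pairs, special pairs), resolves each against the
dataset's records under wildcard/specificity semantics, and produces a
self-contained :class:`ComponentForceField` whose energies can be evaluated
on 3D coordinates.

Resolution semantics: a record is a candidate when its tag tuple and bond
orders match the term's concrete tags in forward or reversed orientation
(impropers match their three neighbors as a multiset around the fixed
central tag).  The winner is the unique candidate of maximal specificity,
where specificity sums the non-wildcard tag fields (0-4 per tag) plus 1 per
exact bond order; ties raise instead of resolving silently.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from . import potentials
from .atomtyping import DEFAULT_KEEP_H, SiteGraph, type_molecule
from .errors import (
    AmbiguousResolutionError,
    FFDatError,
    UnparameterizedTermError,
)
from .molgraph import MolecularGraph
from .potentials import Section, UnitProfile, get_profile
from .records import ForceFieldDataset
from .tags import Tag, WILDCARD, format_tag, matches, specificity


# ---------------------------------------------------------------------------
# term enumeration

@dataclass(frozen=True)
class Term:
    """One interaction term of a molecule's topology.

    ``sites`` are site indices in canonical orientation (lexicographically
    smallest of the tuple and its reverse; improper neighbors sorted).
    ``separation`` is the neighbor rank n for 1,n pairs and the bond-count
    distance for special pairs.
    """

    kind: str  # bond | angle | torsion | improper | one_n | special
    sites: tuple
    orders: tuple = ()
    separation: Optional[int] = None


def _canonical(seq, orders):
    rev = tuple(reversed(seq)), tuple(reversed(orders))
    fwd = tuple(seq), tuple(orders)
    return min(fwd, rev)


def enumerate_terms(sg: SiteGraph, special_dists: Sequence[int] = ()) -> list:
    """All topology terms of a connected site graph.

    Bonds are the edges; angles all length-2 paths; torsions all simple
    length-3 paths; impropers one candidate per 3-combination of neighbors
    around any site of degree >= 3; 1,n pairs all site pairs at shortest
    bond distance d >= 3 (labeled n = d+1); special pairs all site pairs at
    a bond distance listed in ``special_dists``.
    """
    order_of = {}
    adj = {i: [] for i in range(len(sg.sites))}
    for a, b, o in sg.bonds:
        adj[a].append(b)
        adj[b].append(a)
        order_of[(a, b)] = order_of[(b, a)] = o
    for nbrs in adj.values():
        nbrs.sort()

    terms = []
    for a, b, o in sorted((min(i, j), max(i, j), o) for i, j, o in sg.bonds):
        terms.append(Term("bond", (a, b), (o,)))

    for j in range(len(sg.sites)):
        for i, k in itertools.combinations(adj[j], 2):
            sites, orders = _canonical((i, j, k), (order_of[(i, j)], order_of[(j, k)]))
            terms.append(Term("angle", sites, orders))

    seen = set()
    for j, k, _ in sg.bonds:
        for jj, kk in ((j, k), (k, j)):
            for i in adj[jj]:
                if i == kk:
                    continue
                for l in adj[kk]:
                    if l == jj or l == i:
                        continue
                    sites, orders = _canonical(
                        (i, jj, kk, l),
                        (order_of[(i, jj)], order_of[(jj, kk)], order_of[(kk, l)]),
                    )
                    if sites not in seen:
                        seen.add(sites)
                        terms.append(Term("torsion", sites, orders))

    for c in range(len(sg.sites)):
        if len(adj[c]) < 3:
            continue
        for trio in itertools.combinations(adj[c], 3):
            orders = tuple(order_of[(c, t)] for t in trio)
            terms.append(Term("improper", (c, *trio), orders))

    dists = dict(nx.all_pairs_shortest_path_length(sg.to_networkx()))
    special_dists = set(special_dists)
    n_sites = len(sg.sites)
    for i in range(n_sites):
        for j in range(i + 1, n_sites):
            d = dists.get(i, {}).get(j)
            if d is None:
                continue
            if d >= 3:
                terms.append(Term("one_n", (i, j), separation=d + 1))
            if d in special_dists:
                terms.append(Term("special", (i, j), separation=d))
    return terms


# ---------------------------------------------------------------------------
# resolution

def _order_matches(pattern_order, concrete_order) -> bool:
    return pattern_order is WILDCARD or pattern_order == concrete_order


def _order_score(pattern_order) -> int:
    return 0 if pattern_order is WILDCARD else 1


def _match_linear(rec_tags, rec_orders, tags, orders):
    """Best specificity of a forward/reversed linear tuple match, or None."""
    best = None
    for rt, ro, tt, to in (
        (rec_tags, rec_orders, tags, orders),
        (rec_tags, rec_orders, tuple(reversed(tags)), tuple(reversed(orders))),
    ):
        if all(matches(p, c) for p, c in zip(rt, tt)) and all(
            _order_matches(p, c) for p, c in zip(ro, to)
        ):
            score = sum(specificity(p) for p in rt) + sum(_order_score(p) for p in ro)
            best = score if best is None else max(best, score)
    return best


def _match_improper(rec, tags, orders):
    """Central tag fixed; neighbors matched as a multiset (best permutation)."""
    if not matches(rec.tag0, tags[0]):
        return None
    rec_nbrs = ((rec.tag1, rec.order1), (rec.tag2, rec.order2), (rec.tag3, rec.order3))
    best = None
    for perm in itertools.permutations(range(3)):
        ok = all(
            matches(rec_nbrs[k][0], tags[1 + perm[k]])
            and _order_matches(rec_nbrs[k][1], orders[perm[k]])
            for k in range(3)
        )
        if ok:
            score = (
                specificity(rec.tag0)
                + sum(specificity(t) for t, _ in rec_nbrs)
                + sum(_order_score(o) for _, o in rec_nbrs)
            )
            best = score if best is None else max(best, score)
    return best


def _term_signature(term, site_tags):
    tags = ", ".join(str(site_tags[i]) for i in term.sites)
    extra = f", dist={term.separation}" if term.separation is not None else ""
    return f"{term.kind}({tags}{extra})"


def resolve(dataset: ForceFieldDataset, term: Term, site_tags: Sequence[Tag]):
    """Resolve a term against the dataset; returns the unique winning record.

    Raises :class:`UnparameterizedTermError` when nothing matches and
    :class:`AmbiguousResolutionError` when two records tie at maximal
    specificity.
    """
    tags = tuple(site_tags[i] for i in term.sites)
    for t in tags:
        if not t.is_concrete:
            raise FFDatError(f"term resolution requires concrete tags, got {t}")
    candidates = []  # (score, record)

    if term.kind == "bond":
        for rec in dataset.bond:
            s = _match_linear((rec.tag1, rec.tag2), (rec.order,), tags, term.orders)
            if s is not None:
                candidates.append((s, rec))
    elif term.kind == "angle":
        for rec in dataset.angle:
            s = _match_linear(
                (rec.tag1, rec.tag2, rec.tag3), (rec.order1, rec.order2), tags, term.orders
            )
            if s is not None:
                candidates.append((s, rec))
    elif term.kind == "torsion":
        for rec in dataset.torsion:
            s = _match_linear(
                (rec.tag1, rec.tag2, rec.tag3, rec.tag4),
                (rec.order1, rec.order2, rec.order3),
                tags,
                term.orders,
            )
            if s is not None:
                candidates.append((s, rec))
    elif term.kind == "improper":
        for rec in dataset.improper:
            s = _match_improper(rec, tags, term.orders)
            if s is not None:
                candidates.append((s, rec))
    elif term.kind == "special":
        for rec in dataset.special:
            if rec.dist != term.separation:
                continue
            fwd = matches(rec.tag1, tags[0]) and matches(rec.tag2, tags[1])
            rev = matches(rec.tag1, tags[1]) and matches(rec.tag2, tags[0])
            if fwd or rev:
                candidates.append((specificity(rec.tag1) + specificity(rec.tag2), rec))
    else:
        raise FFDatError(f"cannot resolve term kind {term.kind!r}")

    if not candidates:
        raise UnparameterizedTermError(
            f"no record matches {_term_signature(term, site_tags)}"
        )
    best = max(s for s, _ in candidates)
    winners = [rec for s, rec in candidates if s == best]
    if len(winners) > 1:
        listing = "; ".join(repr(w) for w in winners)
        raise AmbiguousResolutionError(
            f"{len(winners)} records tie at specificity {best} for "
            f"{_term_signature(term, site_tags)}: {listing}"
        )
    return winners[0]


def resolve_site(dataset: ForceFieldDataset, tag: Tag):
    """Intermolecular record for one concrete site tag (specificity rule)."""
    candidates = [
        (specificity(rec.tag), rec)
        for rec in dataset.intermolecular
        if matches(rec.tag, tag)
    ]
    if not candidates:
        raise UnparameterizedTermError(f"no intermolecular record matches {tag}")
    best = max(s for s, _ in candidates)
    winners = [rec for s, rec in candidates if s == best]
    if len(winners) > 1:
        raise AmbiguousResolutionError(
            f"{len(winners)} intermolecular records tie for {tag}"
        )
    return winners[0]


# ---------------------------------------------------------------------------
# the component force field

@dataclass(frozen=True)
class SiteParams:
    index: int
    tag: Tag
    id1: int
    params: tuple  # intermolecular parameters; params[0] is the charge q / e
    ref: str

    @property
    def charge(self) -> float:
        return self.params[0]


@dataclass(frozen=True)
class ResolvedTerm:
    kind: str
    sites: tuple
    orders: tuple
    function_id: Optional[int]  # None = rigid constraint
    params: tuple
    ref: str
    separation: Optional[int] = None
    scaling: Optional[tuple] = None  # (vdW, elec) for 1,n terms

    @property
    def rigid(self) -> bool:
        return self.function_id is None


@dataclass
class ComponentForceField:
    """A molecule-specific model built from a transferable dataset."""

    name: str
    unit_profile: str
    sites: list  # SiteParams per site
    bonds: list
    angles: list
    torsions: list
    impropers: list
    one_n: list
    specials: list
    exclusions: list  # (i, j, n) pairs whose 1,n scaling is (0, 0)
    notes: list = field(default_factory=list)

    @property
    def profile(self) -> UnitProfile:
        return get_profile(self.unit_profile)

    def bonded_terms(self):
        return [*self.bonds, *self.angles, *self.torsions, *self.impropers]


def build_component_ff(
    dataset: ForceFieldDataset,
    molecule,
    registry=None,
    keep_h_on=DEFAULT_KEEP_H,
) -> ComponentForceField:
    """Type a molecule (if needed) and resolve its full term list.

    ``molecule`` may be a :class:`MolecularGraph` or an already-typed
    :class:`SiteGraph`.  Improper candidates with no matching record are
    dropped (improper potentials are optional refinements; a force field
    without them simply leaves branched centers unrestrained out of plane)
    and noted on the result; every other unresolved term is an error.
    """
    if isinstance(molecule, MolecularGraph):
        sg = type_molecule(molecule, registry=registry, keep_h_on=keep_h_on)
    elif isinstance(molecule, SiteGraph):
        sg = molecule
        if any(s.tag is None for s in sg.sites):
            raise FFDatError("SiteGraph must be fully tagged; run type_molecule")
    else:
        raise TypeError(f"expected MolecularGraph or SiteGraph, got {type(molecule)!r}")

    tags = sg.tags()
    try:
        sites = [
            SiteParams(i, tag, rec.id1, rec.params, rec.ref)
            for i, (tag, rec) in enumerate(
                (t, resolve_site(dataset, t)) for t in tags
            )
        ]
    except FFDatError as exc:
        raise type(exc)(f"{sg.name or 'molecule'}: {exc}") from None

    special_dists = sorted({rec.dist for rec in dataset.special})
    rules = dataset.one_n_rules()
    ff = ComponentForceField(
        name=sg.name, unit_profile=dataset.unit_profile, sites=sites,
        bonds=[], angles=[], torsions=[], impropers=[], one_n=[], specials=[],
        exclusions=[],
    )
    bucket = {"bond": ff.bonds, "angle": ff.angles, "torsion": ff.torsions,
              "improper": ff.impropers, "special": ff.specials}

    for term in enumerate_terms(sg, special_dists=special_dists):
        if term.kind == "one_n":
            vdw, elec = potentials.scale_1n(rules, term.separation)
            if vdw == 0.0 and elec == 0.0:
                ff.exclusions.append((*term.sites, term.separation))
            else:
                ff.one_n.append(ResolvedTerm(
                    "one_n", term.sites, (), None, (), "",
                    separation=term.separation, scaling=(vdw, elec),
                ))
            continue
        try:
            rec = resolve(dataset, term, tags)
        except UnparameterizedTermError as exc:
            if term.kind == "improper":
                ff.notes.append(f"improper candidate left unparameterized: {exc}")
                continue
            if term.kind == "special":
                # candidates are selected by distance alone; a pair whose
                # tags match no special record simply has no special term
                continue
            raise UnparameterizedTermError(f"{sg.name or 'molecule'}: {exc}") from None
        except AmbiguousResolutionError as exc:
            raise AmbiguousResolutionError(f"{sg.name or 'molecule'}: {exc}") from None
        if term.kind == "bond":
            fid = rec.id2
        elif term.kind == "angle":
            fid = rec.id3
        elif term.kind == "torsion":
            fid = rec.id4
        elif term.kind == "improper":
            fid = rec.id5
        elif term.kind == "special":
            fid = rec.id7
        bucket[term.kind].append(ResolvedTerm(
            term.kind, term.sites, term.orders, fid, rec.params, rec.ref,
            separation=term.separation,
        ))

    for lst in bucket.values():
        lst.sort(key=lambda t: t.sites)
    ff.one_n.sort(key=lambda t: t.sites)
    ff.exclusions.sort()
    return ff


def net_charge(ff: ComponentForceField) -> float:
    """Total charge of the component in e."""
    return sum(site.charge for site in ff.sites)


# ---------------------------------------------------------------------------
# geometry

def _distance(a, b) -> float:
    return float(np.linalg.norm(np.asarray(b, float) - np.asarray(a, float)))


def _angle_deg(a, b, c) -> float:
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _dihedral_deg(a, b, c, d) -> float:
    """Signed IUPAC dihedral in degrees; anti (trans) = 180."""
    p = [np.asarray(x, float) for x in (a, b, c, d)]
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x, y = np.dot(n1, n2), np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def _out_of_plane_deg(center, p1, p2, p3) -> float:
    """Angle between the center->p3 bond and the (center, p1, p2) plane."""
    c = np.asarray(center, float)
    normal = np.cross(np.asarray(p1, float) - c, np.asarray(p2, float) - c)
    nn = np.linalg.norm(normal)
    v = np.asarray(p3, float) - c
    sin_psi = np.dot(normal, v) / (nn * np.linalg.norm(v))
    return float(np.degrees(np.arcsin(np.clip(sin_psi, -1.0, 1.0))))


def _wrap_deg(delta: float) -> float:
    return (delta + 180.0) % 360.0 - 180.0


# ---------------------------------------------------------------------------
# energies

@dataclass
class EnergyBreakdown:
    """Per-channel energies in the force field's unit profile.

    Rigid ("none") terms contribute no energy; their geometric deviation
    from the constrained value is reported in ``residuals`` and, above
    ``rigid_tol``, echoed in ``warnings``.
    """

    bond: float = 0.0
    angle: float = 0.0
    torsion: float = 0.0
    improper: float = 0.0
    one_n_vdw: float = 0.0
    one_n_elec: float = 0.0
    special: float = 0.0
    residuals: list = field(default_factory=list)  # (kind, sites, deviation)
    warnings: list = field(default_factory=list)

    @property
    def bonded_total(self) -> float:
        return self.bond + self.angle + self.torsion + self.improper

    @property
    def total(self) -> float:
        return self.bonded_total + self.one_n_vdw + self.one_n_elec + self.special


def molecule_energy(
    ff: ComponentForceField, coords, rigid_tol: float = 1e-6
) -> EnergyBreakdown:
    """Intramolecular energy breakdown at the given site coordinates (Å)."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(ff.sites), 3):
        raise ValueError(
            f"expected {len(ff.sites)} site coordinates, got shape {coords.shape}"
        )
    profile = ff.profile
    out = EnergyBreakdown()

    def note_rigid(kind, term, actual):
        dev = actual - term.params[0]
        if kind in ("torsion", "improper"):
            dev = _wrap_deg(dev)
        out.residuals.append((kind, term.sites, dev))
        if abs(dev) > rigid_tol:
            out.warnings.append(
                f"rigid {kind} {term.sites} deviates by {dev:.3g} from {term.params[0]}"
            )

    for term in ff.bonds:
        r = _distance(coords[term.sites[0]], coords[term.sites[1]])
        if term.rigid:
            note_rigid("bond", term, r)
        else:
            out.bond += potentials.eval_bond(term.function_id, term.params, r)

    for term in ff.angles:
        i, j, k = term.sites
        theta = _angle_deg(coords[i], coords[j], coords[k])
        if term.rigid:
            note_rigid("angle", term, theta)
        else:
            out.angle += potentials.eval_angle(
                term.function_id, term.params, theta,
                r_ij=_distance(coords[i], coords[j]),
                r_jk=_distance(coords[j], coords[k]),
            )

    for term in ff.torsions:
        phi = _dihedral_deg(*(coords[i] for i in term.sites))
        if term.rigid:
            note_rigid("torsion", term, phi)
        else:
            out.torsion += potentials.eval_torsion(term.function_id, term.params, phi)

    for term in ff.impropers:
        psi = _out_of_plane_deg(*(coords[i] for i in term.sites))
        if term.rigid:
            note_rigid("improper", term, psi)
        else:
            out.improper += potentials.eval_improper(term.function_id, term.params, psi)

    for term in ff.one_n:
        i, j = term.sites
        si, sj = ff.sites[i], ff.sites[j]
        if si.id1 != sj.id1:
            raise FFDatError(f"sites {i}, {j} use different intermolecular forms")
        cross = potentials.combine(si.id1, si.params, sj.params)
        vdw, elec = potentials.eval_intermolecular_split(
            si.id1, cross, _distance(coords[i], coords[j]), profile
        )
        out.one_n_vdw += term.scaling[0] * vdw
        out.one_n_elec += term.scaling[1] * elec

    for term in ff.specials:
        r = _distance(coords[term.sites[0]], coords[term.sites[1]])
        out.special += potentials.eval_special(term.function_id, term.params, r)

    return out


def pair_interaction_energy(
    ff_a: ComponentForceField,
    ff_b: ComponentForceField,
    coords_a,
    coords_b,
) -> float:
    """Intermolecular energy between two built components (same form/profile)."""
    if ff_a.unit_profile != ff_b.unit_profile:
        raise FFDatError(
            f"unit profiles differ: {ff_a.unit_profile} vs {ff_b.unit_profile}"
        )
    ids = {s.id1 for s in ff_a.sites} | {s.id1 for s in ff_b.sites}
    if len(ids) != 1:
        raise FFDatError(f"intermolecular form IDs differ across sites: {sorted(ids)}")
    (id1,) = ids
    coords_a = np.asarray(coords_a, float)
    coords_b = np.asarray(coords_b, float)
    profile = ff_a.profile
    total = 0.0
    for sa, ra in zip(ff_a.sites, coords_a):
        for sb, rb in zip(ff_b.sites, coords_b):
            cross = potentials.combine(id1, sa.params, sb.params)
            total += potentials.eval_intermolecular(
                id1, cross, _distance(ra, rb), profile
            )
    return total


# ---------------------------------------------------------------------------
# JSON serialization

def to_json_dict(ff: ComponentForceField) -> dict:
    def term_dict(t: ResolvedTerm) -> dict:
        d = {
            "kind": t.kind,
            "sites": list(t.sites),
            "orders": list(t.orders),
            "function_id": t.function_id,
            "params": list(t.params),
            "ref": t.ref,
        }
        if t.separation is not None:
            d["separation"] = t.separation
        if t.scaling is not None:
            d["scaling_vdw"], d["scaling_elec"] = t.scaling
        return d

    return {
        "format": "ffdat-component-ff",
        "version": 1,
        "name": ff.name,
        "unit_profile": ff.unit_profile,
        "sites": [
            {
                "index": s.index,
                "tag": format_tag(s.tag),
                "id1": s.id1,
                "params": list(s.params),
                "charge": s.charge,
                "ref": s.ref,
            }
            for s in ff.sites
        ],
        "terms": {
            "bond": [term_dict(t) for t in ff.bonds],
            "angle": [term_dict(t) for t in ff.angles],
            "torsion": [term_dict(t) for t in ff.torsions],
            "improper": [term_dict(t) for t in ff.impropers],
            "one_n": [term_dict(t) for t in ff.one_n],
            "special": [term_dict(t) for t in ff.specials],
        },
        "exclusions": [list(e) for e in ff.exclusions],
        "notes": list(ff.notes),
    }


def to_json(ff: ComponentForceField) -> str:
    """Deterministic JSON text (sorted keys, full float precision)."""
    return json.dumps(to_json_dict(ff), sort_keys=True, indent=2)
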