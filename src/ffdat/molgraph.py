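"""Molecular connectivity: a simple atoms+bonds graph and MOL/SDF ingestion."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .errors import FormatError, StructureError


@dataclass
class MolecularGraph:
    """Atoms (element symbols) and integer-order bonds of one molecule."""

    atoms: list  # element symbols, e.g. ["C", "H", ...]
    bonds: list  # (i, j, order) with order >= 1
    name: str = ""

    def __post_init__(self):
        n = len(self.atoms)
        seen = set()
        norm = []
        for i, j, order in self.bonds:
            if i == j:
                raise StructureError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise StructureError(f"bond ({i}, {j}) references a missing atom")
            if not isinstance(order, int) or order < 1:
                raise StructureError(f"bond ({i}, {j}) has invalid order {order!r}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise StructureError(f"duplicate bond between atoms {i} and {j}")
            seen.add(key)
            norm.append((i, j, order))
        self.bonds = norm

    def neighbors(self, i: int) -> list:
        """(neighbor index, bond order) pairs of atom ``i``."""
        out = []
        for a, b, order in self.bonds:
            if a == i:
                out.append((b, order))
            elif b == i:
                out.append((a, order))
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(name=self.name)
        g.add_nodes_from((i, {"element": e}) for i, e in enumerate(self.atoms))
        g.add_edges_from((i, j, {"order": o}) for i, j, o in self.bonds)
        return g

    def is_connected(self) -> bool:
        if len(self.atoms) <= 1:
            return True
        return nx.is_connected(self.to_networkx())


def read_molfile(path) -> MolecularGraph:
    """Read a MOL/SDF V2000 connection table into a :class:`MolecularGraph`.

    Hydrogens may be explicit or left implicit (they are then added from
    valence).  Aromatic bond type 4 is rejected: kekulized input with
    integer bond orders is required.
    """
    path = Path(path)
    text = path.read_text()
    return parse_molblock(text, name=path.stem)


def parse_molblock(text: str, name: str = "") -> MolecularGraph:
    """Parse V2000 molblock text; see :func:`read_molfile`."""
    from rdkit import Chem

    if "V3000" in text:
        raise FormatError("V3000 connection tables are not supported; supply V2000")
    mol = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
    if mol is None:
        raise FormatError("malformed MOL/SDF V2000 block (unreadable counts line or body)")
    for bond in mol.GetBonds():
        t = bond.GetBondType()
        if t == Chem.BondType.AROMATIC:
            raise FormatError(
                "aromatic bond type 4 encountered: kekulized input required"
            )
        if t not in (Chem.BondType.SINGLE, Chem.BondType.DOUBLE, Chem.BondType.TRIPLE):
            raise FormatError(f"unsupported bond type {t} (integer orders 1-3 required)")
    mol.UpdatePropertyCache(strict=False)
    mol = Chem.AddHs(mol)  # materialize valence-implied hydrogens
    atoms = [a.GetSymbol() for a in mol.GetAtoms()]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), int(b.GetBondTypeAsDouble()))
        for b in mol.GetBonds()
    ]
    title = (text.splitlines() or [""])[0].strip()
    return MolecularGraph(atoms, bonds, name=name or title)


def to_molblock(graph: MolecularGraph, coords=None) -> str:
    """Write a minimal V2000 molblock (zero coordinates unless given)."""
    n, m = len(graph.atoms), len(graph.bonds)
    if n > 999 or m > 999:
        raise FormatError("V2000 connection tables hold at most 999 atoms/bonds")
    lines = [graph.name or "molecule", "  ffdat", ""]
    lines.append(f"{n:3d}{m:3d}  0  0  0  0  0  0  0  0999 V2000")
    for i, elem in enumerate(graph.atoms):
        x, y, z = (coords[i] if coords is not None else (0.0, 0.0, 0.0))
        lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {elem:<3} 0  0  0  0  0  0  0  0  0  0  0  0")
    for i, j, order in graph.bonds:
        lines.append(f"{i + 1:3d}{j + 1:3d}{order:3d}  0")
    lines.append("M  END")
    return "\n".join(lines) + "\n"


def read_xyz(path):
    """Read an XYZ file -> (element list, list of (x, y, z) in Å)."""
    import numpy as np

    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError("empty XYZ file")
    try:
        count = int(lines[0].strip())
    except ValueError:
        raise FormatError(f"XYZ first line must be the atom count, got {lines[0]!r}") from None
    body = lines[2 : 2 + count]
    if len(body) < count:
        raise FormatError(f"XYZ declares {count} atoms but has {len(body)} coordinate lines")
    elements, coords = [], []
    for ln in body:
        parts = ln.split()
        if len(parts) < 4:
            raise FormatError(f"bad XYZ coordinate line: {ln!r}")
        elements.append(parts[0])
        coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
    return elements, np.asarray(coords, dtype=float)


def write_xyz(path, elements, coords, comment: str = "") -> None:
    lines = [str(len(elements)), comment]
    for e, (x, y, z) in zip(elements, coords):
        lines.append(f"{e} {x:.10f} {y:.10f} {z:.10f}")
    Path(path).write_text("\n".join(lines) + "\n")
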