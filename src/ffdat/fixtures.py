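"""Deterministic fixture molecules (explicit hydrogens) and reference
coordinates at idealized united-atom geometry.

Reference geometries place every flexible or rigid term of the bundled
alkane/alcohol dataset at its reference value (bonds 1.54 / 1.43 / 0.945 Å,
angles 114 / 112 / 109.47 / 108.5 deg, torsions trans), so bonded energies
evaluate to zero and rigid residuals vanish.  Coordinates are per
interaction site of the default united-atom fusion, in the site order that
fusion produces.  Molecules whose united-atom terms the bundled dataset
does not parameterize (the ether, the alkene) ship without coordinates.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import RegistryError
from .molgraph import MolecularGraph

_VALENCE = {"C": 4, "O": 2, "H": 1}


def _fill_hydrogens(elements, bonds):
    """Append H atoms (and bonds) to satisfy standard valences."""
    elements = list(elements)
    bonds = list(bonds)
    used = [0] * len(elements)
    for i, j, o in bonds:
        used[i] += o
        used[j] += o
    for i, elem in list(enumerate(elements)):
        for _ in range(_VALENCE[elem] - used[i]):
            h = len(elements)
            elements.append("H")
            bonds.append((i, h, 1))
    return elements, bonds


def _chain_alkane(n, name):
    elements = ["C"] * n
    bonds = [(i, i + 1, 1) for i in range(n - 1)]
    elements, bonds = _fill_hydrogens(elements, bonds)
    return MolecularGraph(elements, bonds, name=name)


def _with_explicit_order(heavy, heavy_bonds, hydroxyl_h_on=(), name=""):
    """Heavy atoms first, then hydroxyl hydrogens, then remaining hydrogens."""
    elements = list(heavy)
    bonds = list(heavy_bonds)
    for o_index in hydroxyl_h_on:
        h = len(elements)
        elements.append("H")
        bonds.append((o_index, h, 1))
    elements, bonds = _fill_hydrogens(elements, bonds)
    return MolecularGraph(elements, bonds, name=name)


def _build(name):
    if name == "methane":
        return _chain_alkane(1, name)
    if name == "ethane":
        return _chain_alkane(2, name)
    if name == "propane":
        return _chain_alkane(3, name)
    if name == "n-butane":
        return _chain_alkane(4, name)
    if name == "n-pentane":
        return _chain_alkane(5, name)
    if name == "isobutane":
        return _with_explicit_order(
            ["C", "C", "C", "C"], [(0, 1, 1), (0, 2, 1), (0, 3, 1)], name=name
        )
    if name == "methanol":
        return _with_explicit_order(
            ["C", "O"], [(0, 1, 1)], hydroxyl_h_on=(1,), name=name
        )
    if name == "ethanol":
        return _with_explicit_order(
            ["C", "C", "O"], [(0, 1, 1), (1, 2, 1)], hydroxyl_h_on=(2,), name=name
        )
    if name == "1,2-ethanediol":
        return _with_explicit_order(
            ["C", "C", "O", "O"],
            [(0, 1, 1), (0, 2, 1), (1, 3, 1)],
            hydroxyl_h_on=(2, 3),
            name=name,
        )
    if name == "dimethyl-ether":
        return _with_explicit_order(
            ["C", "O", "C"], [(0, 1, 1), (1, 2, 1)], name=name
        )
    if name == "3-methyl-1-butene":
        return _with_explicit_order(
            ["C", "C", "C", "C", "C"],
            [(0, 1, 2), (1, 2, 1), (2, 3, 1), (2, 4, 1)],
            name=name,
        )
    raise RegistryError(
        f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
    )


FIXTURE_NAMES = [
    "methane", "ethane", "propane", "n-butane", "n-pentane", "isobutane",
    "methanol", "ethanol", "1,2-ethanediol", "dimethyl-ether",
    "3-methyl-1-butene",
]


def make_fixture(name: str) -> MolecularGraph:
    """Fixture molecular graph with explicit hydrogens."""
    return _build(name)


# ---------------------------------------------------------------------------
# reference coordinates

def _place(a, b, c, length, angle_deg, dihedral_deg):
    """Place a point at distance/angle/dihedral from sites c/b/a."""
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    d2 = np.array([
        -length * math.cos(ang),
        length * math.sin(ang) * math.cos(dih),
        length * math.sin(ang) * math.sin(dih),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _chain_coords(lengths, angles, dihedrals):
    pts = [np.zeros(3), np.array([lengths[0], 0.0, 0.0])]
    if len(lengths) > 1:
        ang = math.radians(angles[0])
        pts.append(pts[1] + lengths[1] * np.array(
            [-math.cos(ang), math.sin(ang), 0.0]
        ))
    for k in range(2, len(lengths)):
        pts.append(_place(
            pts[k - 2], pts[k - 1], pts[k],
            lengths[k], angles[k - 1], dihedrals[k - 2],
        ))
    return np.array(pts)


_CC, _CO, _OH = 1.54, 1.43, 0.945
_A_CH2, _A_CH, _A_CCO, _A_COH = 114.0, 112.0, 109.47, 108.5


def _star_coords(length, angle_deg):
    """Central site at origin with three neighbors at pairwise ``angle_deg``."""
    cos_t = math.cos(math.radians(angle_deg))
    cos_a = math.sqrt((cos_t + 0.5) / 1.5)
    sin_a = math.sqrt(1.0 - cos_a**2)
    pts = [np.zeros(3)]
    for phi in (0.0, 120.0, 240.0):
        r = math.radians(phi)
        pts.append(length * np.array(
            [sin_a * math.cos(r), sin_a * math.sin(r), cos_a]
        ))
    return np.array(pts)


def fixture_coordinates(name: str, jitter: float = 0.0, rng=None):
    """Per-site reference coordinates (Å) for the default united-atom model,
    or None when the bundled dataset does not define the geometry.

    ``jitter`` adds uniform displacement noise in [-jitter, jitter] Å per
    component (deterministic under a seeded ``rng``), for perturbation tests.
    """
    coords = _reference_coords(name)
    if coords is None:
        return None
    if jitter:
        gen = rng if rng is not None else np.random.default_rng(0)
        coords = coords + gen.uniform(-jitter, jitter, size=coords.shape)
    return coords


def _reference_coords(name):
    if name == "methane":
        return np.zeros((1, 3))
    if name == "ethane":
        return np.array([[0.0, 0.0, 0.0], [_CC, 0.0, 0.0]])
    if name == "propane":
        return _chain_coords([_CC, _CC], [_A_CH2], [])
    if name == "n-butane":
        return _chain_coords([_CC] * 3, [_A_CH2] * 2, [180.0])
    if name == "n-pentane":
        return _chain_coords([_CC] * 4, [_A_CH2] * 3, [180.0, 180.0])
    if name == "isobutane":
        return _star_coords(_CC, _A_CH)
    if name == "methanol":
        # sites: C, O, H
        return _chain_coords([_CO, _OH], [_A_COH], [])
    if name == "ethanol":
        # sites: CH3, CH2, O, H
        return _chain_coords([_CC, _CO, _OH], [_A_CCO, _A_COH], [180.0])
    if name == "1,2-ethanediol":
        # chain H-O-C-C-O-H all-trans, then reordered to site order
        chain = _chain_coords(
            [_OH, _CO, _CC, _CO, _OH],
            [_A_COH, _A_CCO, _A_CCO, _A_COH],
            [180.0, 180.0, 180.0],
        )
        # sites: C0, C1, O0, O1, H0, H1  <- chain indices 2, 3, 1, 4, 0, 5
        return chain[[2, 3, 1, 4, 0, 5]]
    return None
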