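"""Bundled example dataset: the TraPPE-UA alkane/alcohol subset.

TraPPE-UA is a semi-flexible united-atom transferable force field: CHx
groups are fused single sites, all bonds are rigid ("none" entries), bends
and torsions are flexible, and hydroxyl hydrogens are modeled explicitly.
Dispersion energies are given on the epsilon/kB scale (Kelvin), hence the
Kelvin unit-profile marker.  The improper section is empty (the force field
has no improper torsions) and the 1,n section is empty (the default 0 for
n <= 4 / 1 for n > 4 scaling applies); the two special records are the
repulsive r^-12 guards between a hydroxyl oxygen and hydrogens 4 and 5
bonds away, used in polyols.
"""

from __future__ import annotations

from .errors import RegistryError
from .records import (
    AngleRecord,
    BondRecord,
    ForceFieldDataset,
    InterRecord,
    SpecialRecord,
    TorsionRecord,
)
from .tags import parse_tag as T

# source publications, by DOI
_ALKANES = "10.1021/jp972543+"          # n-alkanes
_BRANCHED = "10.1021/jp984742e"         # branched alkanes
_ALCOHOLS = "10.1021/jp003882x"         # alcohols
_ETHERS_GLYCOLS = "10.1021/jp049459w"   # ethers / glycols

TRAPPE_UA_NAME = "trappe-ua-alkane-alcohol"

# intermolecular: tag, ID1=1 (12-6 LJ + point charge), (q/e, eps/K, sigma/Å)
_INTERMOLECULAR = [
    ("A-C-0-0", (0.0, 148.0, 3.73), _ALKANES),   # CH4
    ("A-C-1-1", (0.0, 98.0, 3.75), _ALKANES),    # CH3
    ("A-C-2-1", (0.0, 46.0, 3.95), _ALKANES),    # CH2
    ("A-C-3-1", (0.0, 10.0, 4.68), _BRANCHED),   # CH
    ("A-C-4-1", (0.0, 0.5, 6.4), _BRANCHED),     # C
    ("Ak-O-2-1", (-0.7, 93.0, 3.02), _ALCOHOLS),
    ("Ak-H-1-1", (0.435, 0.0, 0.0), _ALCOHOLS),
    ("Ak-C-1-1", (0.265, 98.0, 3.75), _ALCOHOLS),   # alpha-CH3 (methanol)
    ("Ak-C-2-1", (0.265, 46.0, 3.95), _ALCOHOLS),   # alpha-CH2
    ("Ak-C-3-1", (0.265, 10.0, 4.33), _ALCOHOLS),   # alpha-CH
    ("Ak-C-4-1", (0.265, 0.5, 5.8), _ALCOHOLS),     # alpha-C
]

# bond: tag1, order, tag2, rigid length / Å
_BONDS = [
    ("X-C-X-1", 1, "X-C-X-1", 1.54, _ALKANES),
    ("Ak-C-X-X", 1, "Ak-O-2-1", 1.43, _ALCOHOLS),
    ("Ak-H-1-1", 1, "Ak-O-2-1", 0.945, _ALCOHOLS),
]

# angle: tag1, o1, tag2 (central), o2, tag3, ID3=1 harmonic, (l2 / K deg^-2 *2, theta0 / deg)
_ANGLES = [
    ("X-C-X-X", 1, "X-C-2-1", 1, "X-C-X-X", (62500.0, 114.0), _ALKANES),
    ("X-C-X-X", 1, "X-C-3-1", 1, "X-C-X-X", (62500.0, 112.0), _BRANCHED),
    ("X-C-X-X", 1, "X-C-4-1", 1, "X-C-X-X", (62500.0, 109.47), _BRANCHED),
    ("X-C-X-X", 1, "Ak-C-X-1", 1, "Ak-O-2-1", (50400.0, 109.47), _ALCOHOLS),
    ("Ak-C-X-1", 1, "Ak-O-2-1", 1, "Ak-H-1-1", (55400.0, 108.5), _ALCOHOLS),
]

# torsion: tag1..tag4, orders, ID4=1 cosine series, (c0..c3 / K)
_TORSIONS = [
    ("X-C-X-X", 1, "X-C-2-1", 1, "X-C-2-1", 1, "X-C-X-X",
     (0.0, 355.03, -68.19, 791.32), _ALKANES),
    ("X-C-X-X", 1, "X-C-2-1", 1, "X-C-3-1", 1, "X-C-X-X",
     (-251.06, 428.73, -111.85, 441.27), _BRANCHED),
    ("X-C-X-X", 1, "X-C-2-1", 1, "X-C-4-1", 1, "X-C-X-X",
     (0.0, 0.0, 0.0, 461.29), _BRANCHED),
    ("X-C-X-X", 1, "X-C-3-1", 1, "X-C-3-1", 1, "X-C-X-X",
     (-251.06, 428.73, -111.85, 441.27), _BRANCHED),
    ("X-C-X-X", 1, "X-C-2-1", 1, "X-C-3-2", 1, "X-C-X-X",
     (0.0, 0.0, 0.0, 461.29), _BRANCHED),
    ("X-C-X-X", 1, "Ak-C-2-1", 1, "Ak-O-2-1", 1, "Ak-H-1-1",
     (0.0, 209.82, -29.17, 187.93), _ALCOHOLS),
    ("X-C-X-X", 1, "Ak-C-3-1", 1, "Ak-O-2-1", 1, "Ak-H-1-1",
     (215.96, 197.33, 31.46, -173.92), _ALCOHOLS),
    ("X-C-X-X", 1, "Ak-C-4-1", 1, "Ak-O-2-1", 1, "Ak-H-1-1",
     (0.0, 0.0, 0.0, 163.56), _ALCOHOLS),
    ("X-C-X-X", 1, "X-C-2-X", 1, "X-C-2-1", 1, "X-O-2-1",
     (0.0, 176.62, -53.34, 769.93), _ALCOHOLS),
    ("X-C-X-X", 1, "X-C-X-1", 1, "X-O-2-1", 1, "X-C-X-1",
     (0.0, 725.35, -163.75, 558.2), _ETHERS_GLYCOLS),
    ("X-O-2-1", 1, "X-C-2-1", 1, "X-C-2-1", 1, "X-O-2-1",
     (503.24, 0.0, -251.62, 1006.47), _ETHERS_GLYCOLS),
]

# special: tag1, dist, tag2, ID7=1 (k12/r^12), k12 / K Å^12
_SPECIAL = [
    ("Ak-O-X-X", 4, "X-H-1-1", 75000000.0, _ETHERS_GLYCOLS),
    ("Ak-O-X-X", 5, "X-H-1-1", 75000000.0, _ETHERS_GLYCOLS),
]


def _build_trappe() -> ForceFieldDataset:
    return ForceFieldDataset(
        name=TRAPPE_UA_NAME,
        intermolecular=[InterRecord(T(t), 1, p, ref) for t, p, ref in _INTERMOLECULAR],
        bond=[BondRecord(T(a), o, T(b), None, (length,), ref)
              for a, o, b, length, ref in _BONDS],
        angle=[AngleRecord(T(a), o1, T(b), o2, T(c), 1, p, ref)
               for a, o1, b, o2, c, p, ref in _ANGLES],
        torsion=[TorsionRecord(T(a), o1, T(b), o2, T(c), o3, T(d), 1, p, ref)
                 for a, o1, b, o2, c, o3, d, p, ref in _TORSIONS],
        improper=[],
        one_n=[],
        special=[SpecialRecord(T(a), d, T(b), 1, (k,), ref)
                 for a, d, b, k, ref in _SPECIAL],
        unit_profile="K-Å-e",
    )


_BUNDLED = {TRAPPE_UA_NAME: _build_trappe}


def bundled_names() -> list:
    return sorted(_BUNDLED)


def load_bundled(name: str = TRAPPE_UA_NAME) -> ForceFieldDataset:
    """Return a fresh copy of a bundled dataset by name."""
    try:
        return _BUNDLED[name]()
    except KeyError:
        raise RegistryError(
            f"unknown bundled dataset {name!r}; available: {', '.join(bundled_names())}"
        ) from None
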