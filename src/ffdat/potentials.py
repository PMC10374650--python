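"""Interaction-potential registry and evaluators.

Each of the data scheme's sections has its own numbered list of parametric
energy functions (the section's ``ID``).  The registry below binds
``(section, id)`` to an energy form, its parameter names, and arity; new
entries can be registered at runtime.

All evaluators are unit-agnostic: they combine parameters and geometry
arithmetically exactly as written, so the energy comes out in whatever
energy unit the parameters are expressed in.  Lengths are Å, angles are
degrees throughout.  Only the point-charge term needs a physical constant,
which a :class:`UnitProfile` supplies (``e^2/(4 pi eps0)`` expressed in the
profile's energy unit times Å per e^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

from .errors import RegistryError


class Section(str, Enum):
    """The seven sections of the data scheme (improper ID is section 5, the
    1,n section carries scalings rather than a function list)."""

    INTERMOLECULAR = "intermolecular"
    BOND = "bond"
    ANGLE = "angle"
    TORSION = "torsion"
    IMPROPER = "improper"
    ONE_N = "1n_potential"
    SPECIAL = "special"


@dataclass(frozen=True)
class PotentialFunction:
    """Registry entry binding a (section, id) to a parametric energy form."""

    section: Section
    id: int
    arity: int
    param_names: tuple
    description: str


@dataclass(frozen=True)
class UnitProfile:
    """Energy-unit convention for charge terms.

    ``coulomb_constant`` is e^2/(4 pi eps0) in (energy unit)·Å/e^2, so the
    electrostatic term of the intermolecular forms is simply
    ``coulomb_constant * q_ij / r_ij`` with q in e and r in Å.
    """

    name: str
    energy_unit: str
    coulomb_constant: float


#: e^2/(4 pi eps0) in eV·Å (CODATA).
_COULOMB_EV_A = 14.399645478425668
#: Boltzmann constant in eV/K (exact, SI 2019).
_KB_EV_PER_K = 8.617333262e-5

#: Default profile: energies in eV (the format's declared energy unit).
EV_PROFILE = UnitProfile("eV-Å-e", "eV", _COULOMB_EV_A)
#: Alternative profile for datasets whose energies are eps/kB in Kelvin
#: (the convention of the bundled united-atom alkane/alcohol data).
KELVIN_PROFILE = UnitProfile("K-Å-e", "K", _COULOMB_EV_A / _KB_EV_PER_K)

PROFILES = {p.name: p for p in (EV_PROFILE, KELVIN_PROFILE)}


def get_profile(name: str) -> UnitProfile:
    try:
        return PROFILES[name]
    except KeyError:
        raise RegistryError(f"unknown unit profile {name!r}") from None


# ---------------------------------------------------------------------------
# registry

_REGISTRY: dict = {}


def register_function(fn: PotentialFunction) -> None:
    """Add a potential function; (section, id) must be new."""
    key = (fn.section, fn.id)
    if key in _REGISTRY:
        raise RegistryError(f"potential {key} already registered")
    _REGISTRY[key] = fn


def get_function(section: Section, fid: int) -> PotentialFunction:
    try:
        return _REGISTRY[(Section(section), fid)]
    except KeyError:
        raise RegistryError(f"no potential function registered for ({section}, {fid})") from None


def registered_ids(section: Section) -> list:
    return sorted(fid for (sec, fid) in _REGISTRY if sec == Section(section))


def _reg(section, fid, names, desc):
    register_function(PotentialFunction(section, fid, len(names), tuple(names), desc))


_reg(Section.INTERMOLECULAR, 1, ("q", "epsilon", "sigma"),
     "12-6 Lennard-Jones + point charge; geometric-mean epsilon, arithmetic-mean sigma")
_reg(Section.INTERMOLECULAR, 2, ("q", "epsilon", "sigma", "n"),
     "n-6 Mie + point charge; arithmetic-mean repulsive exponent")
_reg(Section.INTERMOLECULAR, 3, ("q", "epsilon", "sigma"),
     "12-6 Lennard-Jones + e^2 q/r point charge")
_reg(Section.INTERMOLECULAR, 4, ("q", "epsilon", "r_min"),
     "12-6 in r_min form + q/(eps_l r) point charge")
_reg(Section.BOND, 1, ("k2", "r0"), "harmonic bond (k2/2)(r-r0)^2")
_reg(Section.BOND, 2, ("k2", "k3", "k4", "r0"), "quartic bond polynomial in (r-r0)")
_reg(Section.BOND, 3, ("k4", "r0"), "(k4/4)(r^2-r0^2)^2")
_reg(Section.ANGLE, 1, ("l2", "theta0"), "harmonic angle (l2/2)(theta-theta0)^2")
_reg(Section.ANGLE, 2, ("l2", "l3", "l4", "theta0", "k2", "r1", "r2", "N1", "N2"),
     "quartic angle polynomial with bond-bond and bond-angle coupling")
_reg(Section.ANGLE, 3, ("theta0", "c"), "cosine-harmonic c(cos theta - cos theta0)^2/2")
_reg(Section.TORSION, 1, ("c0", "c1", "c2", "c3"),
     "c0 + c1(1+cos) + c2(1-cos2) + c3(1+cos3)")
_reg(Section.TORSION, 2, ("c", "phi0"), "harmonic torsion c(phi-phi0)^2/2")
_reg(Section.TORSION, 3, tuple(f"c{i}" for i in range(7)), "cosine series sum ci cos(i phi)")
_reg(Section.TORSION, 4, ("c0", "phi0"), "c0[1 - cos(2 phi + phi0)]")
_reg(Section.TORSION, 5, tuple(f"c{i}" for i in range(8)), "power series sum ci cos^i(phi)")
_reg(Section.TORSION, 6,
     ("c1", "n1", "phi1", "c2", "n2", "phi2", "c3", "n3", "phi3", "c4", "n4", "phi4"),
     "sum ci[1 + cos(ni phi - phii)]")
_reg(Section.IMPROPER, 1, ("l2", "psi0"), "harmonic out-of-plane (l2/2)(psi-psi0)^2")
_reg(Section.SPECIAL, 1, ("k12",), "purely repulsive k12/r^12")


# ---------------------------------------------------------------------------
# combination rules (intermolecular cross parameters)

def combine(id1: int, params_i: Sequence[float], params_j: Sequence[float]) -> tuple:
    """Cross parameters between unlike sites for intermolecular form ``id1``.

    Charges multiply (q_ij = q_ii q_jj), dispersion energies combine by
    geometric mean, size parameters (sigma or r_min) and the Mie exponent by
    arithmetic mean.
    """
    fn = get_function(Section.INTERMOLECULAR, id1)
    pi, pj = list(params_i), list(params_j)
    if len(pi) != fn.arity or len(pj) != fn.arity:
        raise ValueError(
            f"id1={id1} expects {fn.arity} parameters, got {len(pi)} and {len(pj)}"
        )
    q = pi[0] * pj[0]
    eps = math.sqrt(pi[1] * pj[1])
    size = (pi[2] + pj[2]) / 2.0
    if id1 == 2:
        return (q, eps, size, (pi[3] + pj[3]) / 2.0)
    if id1 in (1, 3, 4):
        return (q, eps, size)
    raise RegistryError(f"no combination rule for id1={id1}")


def mie_prefactor(n_ij: float) -> float:
    """C_n = n/(n-6) * (n/6)^(6/(n-6)); equals 4 for n = 12 (Lennard-Jones)."""
    if n_ij <= 6:
        raise ValueError(f"Mie exponent must exceed 6, got {n_ij}")
    return (n_ij / (n_ij - 6.0)) * (n_ij / 6.0) ** (6.0 / (n_ij - 6.0))


# ---------------------------------------------------------------------------
# evaluators

def eval_intermolecular_split(
    id1: int,
    cross: Sequence[float],
    r: float,
    profile: UnitProfile = EV_PROFILE,
    dielectric: float = 1.0,
) -> tuple:
    """(van der Waals, electrostatic) energy channels at separation ``r`` Å.

    ``cross`` holds already-combined pair parameters (see :func:`combine`);
    for a like pair pass ``combine(id1, p, p)``.
    """
    if r <= 0:
        raise ValueError(f"separation must be positive, got {r}")
    fn = get_function(Section.INTERMOLECULAR, id1)
    if len(cross) != fn.arity:
        raise ValueError(f"id1={id1} expects {fn.arity} cross parameters, got {len(cross)}")
    q = cross[0]
    eps = cross[1]
    if id1 in (1, 3):
        sr6 = (cross[2] / r) ** 6
        vdw = 4.0 * eps * (sr6 * sr6 - sr6)
        elec = profile.coulomb_constant * q / r
    elif id1 == 2:
        n = cross[3]
        cn = mie_prefactor(n)
        sr = cross[2] / r
        vdw = cn * eps * (sr**n - sr**6)
        elec = profile.coulomb_constant * q / r
    elif id1 == 4:
        sr6 = (cross[2] / r) ** 6
        vdw = eps * (sr6 * sr6 - sr6)
        elec = profile.coulomb_constant * q / (dielectric * r)
    else:
        raise RegistryError(f"no intermolecular evaluator for id1={id1}")
    return vdw, elec


def eval_intermolecular(id1, cross, r, profile=EV_PROFILE, dielectric=1.0) -> float:
    vdw, elec = eval_intermolecular_split(id1, cross, r, profile, dielectric)
    return vdw + elec


def _check_arity(section, fid, p):
    fn = get_function(section, fid)
    if len(p) != fn.arity:
        raise ValueError(
            f"{section.value} id {fid} expects {fn.arity} parameters "
            f"({', '.join(fn.param_names)}), got {len(p)}"
        )


def eval_bond(id2: int, p: Sequence[float], r: float) -> float:
    """Bond-stretch energy at length ``r`` Å."""
    _check_arity(Section.BOND, id2, p)
    if id2 == 1:
        k2, r0 = p
        return 0.5 * k2 * (r - r0) ** 2
    if id2 == 2:
        k2, k3, k4, r0 = p
        d = r - r0
        return k2 * d**2 + k3 * d**3 + k4 * d**4
    if id2 == 3:
        k4, r0 = p
        return 0.25 * k4 * (r**2 - r0**2) ** 2
    raise RegistryError(f"no bond evaluator for id2={id2}")


def eval_angle(
    id3: int,
    p: Sequence[float],
    theta: float,
    r_ij: float | None = None,
    r_jk: float | None = None,
) -> float:
    """Angle-bend energy; ``theta`` in degrees.

    Form 2 couples the bend to the two flanking bond lengths and therefore
    requires ``r_ij`` and ``r_jk``; forms 1 and 3 ignore them.
    """
    _check_arity(Section.ANGLE, id3, p)
    if id3 == 1:
        l2, theta0 = p
        return 0.5 * l2 * (theta - theta0) ** 2
    if id3 == 2:
        if r_ij is None or r_jk is None:
            raise ValueError("angle form 2 requires r_ij and r_jk distances")
        l2, l3, l4, theta0, k2, r1, r2, n1, n2 = p
        dt = theta - theta0
        return (
            l2 * dt**2 + l3 * dt**3 + l4 * dt**4
            + k2 * (r_ij - r1) * (r_jk - r2)
            + n1 * (r_ij - r1) * dt
            + n2 * (r_jk - r2) * dt
        )
    if id3 == 3:
        theta0, c = p
        return 0.5 * c * (math.cos(math.radians(theta)) - math.cos(math.radians(theta0))) ** 2
    raise RegistryError(f"no angle evaluator for id3={id3}")


def eval_torsion(id4: int, p: Sequence[float], phi: float) -> float:
    """Torsion (dihedral) energy; ``phi`` in degrees, trans = 180°."""
    _check_arity(Section.TORSION, id4, p)
    rad = math.radians(phi)
    if id4 == 1:
        c0, c1, c2, c3 = p
        return (
            c0
            + c1 * (1 + math.cos(rad))
            + c2 * (1 - math.cos(2 * rad))
            + c3 * (1 + math.cos(3 * rad))
        )
    if id4 == 2:
        c, phi0 = p
        return 0.5 * c * (phi - phi0) ** 2
    if id4 == 3:
        return sum(ci * math.cos(i * rad) for i, ci in enumerate(p))
    if id4 == 4:
        c0, phi0 = p
        return c0 * (1 - math.cos(2 * rad + math.radians(phi0)))
    if id4 == 5:
        return sum(ci * math.cos(rad) ** i for i, ci in enumerate(p))
    if id4 == 6:
        total = 0.0
        for k in range(4):
            ck, nk, phik = p[3 * k : 3 * k + 3]
            total += ck * (1 + math.cos(nk * rad - math.radians(phik)))
        return total
    raise RegistryError(f"no torsion evaluator for id4={id4}")


def eval_improper(id5: int, p: Sequence[float], psi: float) -> float:
    """Out-of-plane (improper torsion) energy; ``psi`` in degrees."""
    _check_arity(Section.IMPROPER, id5, p)
    if id5 == 1:
        l2, psi0 = p
        return 0.5 * l2 * (psi - psi0) ** 2
    raise RegistryError(f"no improper evaluator for id5={id5}")


def eval_special(id7: int, p: Sequence[float], r: float) -> float:
    """Special-case pair energy at separation ``r`` Å."""
    _check_arity(Section.SPECIAL, id7, p)
    if r <= 0:
        raise ValueError(f"separation must be positive, got {r}")
    if id7 == 1:
        (k12,) = p
        return k12 / r**12
    raise RegistryError(f"no special evaluator for id7={id7}")


# ---------------------------------------------------------------------------
# 1,n scaling

@dataclass(frozen=True)
class OneNRule:
    """Scaling of the intermolecular form for intramolecular 1,n pairs.

    ``n`` is the neighbor rank: the pair sits n-1 bonds apart.  The van der
    Waals and electrostatic channels scale independently.
    """

    n: int
    scaling_vdw: float
    scaling_elec: float
    ref: str = ""

    def __post_init__(self):
        if self.n <= 1:
            raise ValueError(f"1,n rule requires n > 1, got {self.n}")


def scale_1n(rule_table: Sequence[OneNRule], n: int) -> tuple:
    """(vdW, electrostatic) scaling for a 1,n pair.

    An explicit rule for ``n`` wins; otherwise the convention is full
    exclusion up to 1,4 and full strength beyond: 0 for n <= 4, 1 for n > 4.
    """
    if n <= 1:
        raise ValueError(f"1,n scaling requires n > 1, got {n}")
    for rule in rule_table:
        if rule.n == n:
            return (rule.scaling_vdw, rule.scaling_elec)
    default = 0.0 if n <= 4 else 1.0
    return (default, default)
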