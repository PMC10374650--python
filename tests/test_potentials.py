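import math

import numpy as np
import pytest

from ffdat import (
    EV_PROFILE,
    KELVIN_PROFILE,
    OneNRule,
    Section,
    combine,
    eval_angle,
    eval_bond,
    eval_improper,
    eval_intermolecular,
    eval_special,
    eval_torsion,
    get_function,
    mie_prefactor,
    scale_1n,
)
from ffdat.errors import RegistryError
from ffdat.potentials import eval_intermolecular_split, register_function, PotentialFunction


class TestCombinationRules:
    def test_arithmetic_mean_sigma(self):
        # CH4 (3.73) with CH3 (3.75)
        q, eps, sigma = combine(1, (0.0, 148.0, 3.73), (0.0, 98.0, 3.75))
        assert sigma == pytest.approx(3.74, abs=1e-12)

    def test_geometric_mean_epsilon_equal_values(self):
        assert combine(1, (0.0, 148.0, 3.73), (0.0, 148.0, 3.73))[1] == pytest.approx(148.0)

    def test_geometric_mean_epsilon(self):
        assert combine(1, (0.0, 148.0, 3.73), (0.0, 98.0, 3.75))[1] == pytest.approx(
            math.sqrt(148.0 * 98.0)
        )

    def test_charges_multiply(self):
        assert combine(1, (-0.7, 93.0, 3.02), (0.435, 0.0, 0.0))[0] == pytest.approx(-0.3045)

    def test_mie_exponent_mean(self):
        cross = combine(2, (0.0, 100.0, 3.0, 12.0), (0.0, 100.0, 3.0, 16.0))
        assert cross[3] == pytest.approx(14.0)

    def test_unknown_form(self):
        with pytest.raises(RegistryError):
            combine(9, (0.0, 1.0, 1.0), (0.0, 1.0, 1.0))

    def test_arity_mismatch(self):
        with pytest.raises(ValueError):
            combine(1, (0.0, 1.0), (0.0, 1.0, 1.0))


class TestMiePrefactor:
    def test_lennard_jones_limit(self):
        assert mie_prefactor(12.0) == pytest.approx(4.0, rel=1e-14)

    def test_n16(self):
        # frozen from an exact symbolic evaluation of (n/(n-6))(n/6)^(6/(n-6))
        assert mie_prefactor(16.0) == pytest.approx(2.8820480821773086, rel=1e-13)

    @pytest.mark.parametrize("bad", [6.0, 5.0, 0.0])
    def test_domain(self, bad):
        with pytest.raises(ValueError):
            mie_prefactor(bad)


class TestIntermolecular:
    CH4 = (0.0, 148.0, 3.73)

    def test_lj_zero_at_sigma(self):
        cross = combine(1, self.CH4, self.CH4)
        assert eval_intermolecular(1, cross, 3.73, KELVIN_PROFILE) == pytest.approx(0.0, abs=1e-12)

    def test_lj_minimum_is_minus_epsilon(self):
        cross = combine(1, self.CH4, self.CH4)
        r_min = 2 ** (1 / 6) * 3.73
        assert eval_intermolecular(1, cross, r_min, KELVIN_PROFILE) == pytest.approx(-148.0)

    def test_mie12_equals_lj_on_grid(self):
        lj = combine(1, self.CH4, self.CH4)
        mie = combine(2, (*self.CH4, 12.0), (*self.CH4, 12.0))
        for r in np.linspace(3.0, 12.0, 50):
            a = eval_intermolecular(1, lj, r, KELVIN_PROFILE)
            b = eval_intermolecular(2, mie, r, KELVIN_PROFILE)
            assert b == pytest.approx(a, rel=1e-12, abs=1e-12)

    def test_charge_term_uses_profile_constant(self):
        cross = ((-0.7) * 0.435, 0.0, 0.0)
        r = 2.5
        vdw, elec = eval_intermolecular_split(1, cross, r, KELVIN_PROFILE)
        assert vdw == 0.0
        assert elec == pytest.approx(KELVIN_PROFILE.coulomb_constant * -0.3045 / r)
        # the Kelvin and eV profiles differ exactly by Boltzmann's constant
        _, elec_ev = eval_intermolecular_split(1, cross, r, EV_PROFILE)
        assert elec / elec_ev == pytest.approx(
            KELVIN_PROFILE.coulomb_constant / EV_PROFILE.coulomb_constant
        )

    def test_nonpositive_separation(self):
        with pytest.raises(ValueError):
            eval_intermolecular(1, combine(1, self.CH4, self.CH4), 0.0)


class TestBondedForms:
    def test_harmonic_bond(self):
        assert eval_bond(1, (62500.0, 1.54), 1.54) == 0.0
        assert eval_bond(1, (2.0, 1.0), 2.0) == pytest.approx(1.0)

    def test_quartic_bond_vanishes_at_reference(self):
        assert eval_bond(2, (10.0, -3.0, 7.0, 1.2), 1.2) == 0.0

    def test_squared_difference_bond(self):
        assert eval_bond(3, (4.0, 1.0), 0.0) == pytest.approx(1.0)
        assert eval_bond(3, (4.0, 1.0), 1.0) == 0.0

    def test_unknown_bond_id(self):
        with pytest.raises(RegistryError):
            eval_bond(9, (1.0, 1.0), 1.0)

    def test_harmonic_angle(self):
        assert eval_angle(1, (62500.0, 114.0), 114.0) == 0.0
        assert eval_angle(1, (62500.0, 114.0), 115.0) == pytest.approx(31250.0)

    def test_cosine_harmonic_angle(self):
        assert eval_angle(3, (114.0, 500.0), 114.0) == pytest.approx(0.0, abs=1e-12)
        expected = 0.5 * 500.0 * (math.cos(math.radians(100)) - math.cos(math.radians(114))) ** 2
        assert eval_angle(3, (114.0, 500.0), 100.0) == pytest.approx(expected)

    def test_coupled_angle_requires_distances(self):
        p = (1.0, 0.0, 0.0, 100.0, 2.0, 1.5, 1.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            eval_angle(2, p, 101.0)
        # hand-expanded: 1*1^2 + 2*(0.1)(-0.1) + 0.5*(0.1)(1) + 0.5*(-0.1)(1)
        assert eval_angle(2, p, 101.0, r_ij=1.6, r_jk=1.4) == pytest.approx(0.98)

    def test_harmonic_improper(self):
        assert eval_improper(1, (2.0, 0.0), 3.0) == pytest.approx(9.0)
        assert eval_improper(1, (2.0, 5.0), 5.0) == 0.0
        assert eval_improper(1, (0.0, 0.0), 37.0) == 0.0

    @pytest.mark.parametrize(
        "id_, params",
        [
            (1, (100.0, 1.5)),
            (3, (50.0, 1.2)),
        ],
    )
    def test_harmonic_forms_nonnegative(self, id_, params):
        for r in np.linspace(0.5, 3.0, 25):
            assert eval_bond(id_, params, r) >= 0.0


class TestTorsion:
    ALKANE = (0.0, 355.03, -68.19, 791.32)
    ETHANOL = (0.0, 209.82, -29.17, 187.93)

    def test_cosine_series_zero_at_trans(self):
        assert eval_torsion(1, self.ALKANE, 180.0) == pytest.approx(0.0, abs=1e-10)
        assert eval_torsion(1, self.ETHANOL, 180.0) == pytest.approx(0.0, abs=1e-10)

    def test_cis_barrier_is_twice_c1_plus_c3(self):
        assert eval_torsion(1, self.ALKANE, 0.0) == pytest.approx(2292.70)
        assert eval_torsion(1, self.ETHANOL, 0.0) == pytest.approx(795.50)

    def test_periodicity(self):
        for phi in np.linspace(-360.0, 360.0, 37):
            assert eval_torsion(1, self.ALKANE, phi) == pytest.approx(
                eval_torsion(1, self.ALKANE, phi + 360.0), abs=1e-10
            )

    def test_harmonic_torsion_vanishes_at_reference(self):
        assert eval_torsion(2, (123.0, 60.0), 60.0) == 0.0

    def test_cosine_and_power_series(self):
        c = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0)
        assert eval_torsion(3, c, 0.0) == pytest.approx(sum(c))
        c8 = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)
        assert eval_torsion(5, c8, 0.0) == pytest.approx(sum(c8))
        assert eval_torsion(5, c8, 90.0) == pytest.approx(c8[0])

    def test_shifted_double_well(self):
        assert eval_torsion(4, (10.0, 0.0), 90.0) == pytest.approx(20.0)
        assert eval_torsion(4, (10.0, 0.0), 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_multi_harmonic_series(self):
        p = (1.0, 2.0, 0.0) + (0.0,) * 9
        assert eval_torsion(6, p, 90.0) == pytest.approx(1 + math.cos(math.pi))

    def test_unknown_id(self):
        with pytest.raises(RegistryError):
            eval_torsion(7, (1.0,), 0.0)


def test_symbolic_cross_check_of_torsion_forms():
    """Dual route: evaluate each torsion form from an independently written
    symbolic expression and compare on a random grid."""
    import sympy as sp

    phi = sp.Symbol("phi")
    rad = sp.pi * phi / 180
    rng = np.random.default_rng(7)
    forms = {
        1: (list(sp.symbols("c0:4")),
            lambda c: c[0] + c[1] * (1 + sp.cos(rad)) + c[2] * (1 - sp.cos(2 * rad))
            + c[3] * (1 + sp.cos(3 * rad))),
        3: (list(sp.symbols("c0:7")),
            lambda c: sum(c[i] * sp.cos(i * rad) for i in range(7))),
        5: (list(sp.symbols("c0:8")),
            lambda c: sum(c[i] * sp.cos(rad) ** i for i in range(8))),
    }
    for fid, (syms, build) in forms.items():
        expr = build(syms)
        fn = sp.lambdify([phi, *syms], expr, "numpy")
        params = tuple(rng.uniform(-500, 500, size=len(syms)))
        for p in rng.uniform(-180, 180, size=8):
            assert eval_torsion(fid, params, p) == pytest.approx(
                float(fn(p, *params)), rel=1e-10, abs=1e-8
            )


class TestSpecial:
    def test_inverse_twelfth_power(self):
        assert eval_special(1, (75000000.0,), 10.0) == pytest.approx(75000000.0 / 10.0**12)
        assert eval_special(1, (0.0,), 3.0) == 0.0

    def test_monotonically_decaying(self):
        values = [eval_special(1, (75000000.0,), r) for r in np.linspace(2.0, 12.0, 30)]
        assert all(a > b > 0 for a, b in zip(values, values[1:]))

    def test_domain(self):
        with pytest.raises(ValueError):
            eval_special(1, (1.0,), 0.0)


class TestOneNScaling:
    def test_defaults(self):
        for n in (2, 3, 4):
            assert scale_1n([], n) == (0.0, 0.0)
        for n in (5, 6, 12):
            assert scale_1n([], n) == (1.0, 1.0)

    def test_explicit_rule_overrides_default(self):
        table = [OneNRule(4, 0.5, 0.833)]
        assert scale_1n(table, 4) == (0.5, 0.833)
        assert scale_1n(table, 5) == (1.0, 1.0)

    def test_invalid_rank(self):
        with pytest.raises(ValueError):
            scale_1n([], 1)
        with pytest.raises(ValueError):
            OneNRule(1, 0.0, 0.0)


def test_registry_is_open_and_unique():
    fn = get_function(Section.TORSION, 1)
    assert fn.arity == 4 and fn.param_names == ("c0", "c1", "c2", "c3")
    with pytest.raises(RegistryError):
        register_function(PotentialFunction(Section.TORSION, 1, 4, ("a", "b", "c", "d"), "dup"))
    with pytest.raises(RegistryError):
        get_function(Section.BOND, 42)


def test_evaluators_are_smooth_at_generic_points():
    """Central differences at two step sizes agree (no kinks/branches)."""
    probes = [
        (lambda x: eval_bond(1, (62500.0, 1.54), x), 1.7),
        (lambda x: eval_bond(3, (4.0, 1.0), x), 1.3),
        (lambda x: eval_angle(1, (62500.0, 114.0), x), 120.0),
        (lambda x: eval_torsion(1, (0.0, 355.03, -68.19, 791.32), x), 47.0),
        (lambda x: eval_special(1, (75000000.0,), x), 3.1),
        (lambda x: eval_intermolecular(
            1, (0.0, 148.0, 3.73), x, KELVIN_PROFILE), 4.1),
    ]
    for f, x0 in probes:
        h = 1e-4 * max(1.0, abs(x0))
        d1 = (f(x0 + h) - f(x0 - h)) / (2 * h)
        d2 = (f(x0 + h / 2) - f(x0 - h / 2)) / h
        assert d2 == pytest.approx(d1, rel=1e-5, abs=1e-8)
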