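import dataclasses
import json
from pathlib import Path

import numpy as np
import pytest

import ffdat as F
from ffdat import assembler, potentials
from ffdat.assembler import Term, enumerate_terms, resolve
from ffdat.errors import (
    AmbiguousResolutionError,
    FFDatError,
    UnparameterizedTermError,
)
from ffdat.fixtures import _chain_coords
from ffdat.records import BondRecord, ForceFieldDataset
from ffdat.tags import parse_tag as T

from conftest import BUILDABLE
import oracles


def _kind_sets(terms):
    out = {}
    for t in terms:
        out.setdefault(t.kind, set()).add(t.sites)
    return out


class TestEnumeration:
    @pytest.mark.parametrize("name", F.FIXTURE_NAMES)
    def test_matches_brute_force_oracle(self, name, typed):
        sg = typed[name]
        got = _kind_sets(enumerate_terms(sg))
        expected = oracles.brute_force_terms(sg)
        for kind in ("bond", "angle", "torsion", "improper"):
            assert got.get(kind, set()) == expected[kind], (name, kind)

    @pytest.mark.parametrize("name", F.FIXTURE_NAMES)
    def test_one_n_separations_match_shortest_path_oracle(self, name, typed):
        sg = typed[name]
        got = {
            t.sites: t.separation for t in enumerate_terms(sg) if t.kind == "one_n"
        }
        expected = {
            pair: d + 1
            for pair, d in oracles.shortest_separations(sg).items()
            if d >= 3
        }
        assert got == expected

    def test_butane_term_counts(self, typed):
        kinds = _kind_sets(enumerate_terms(typed["n-butane"]))
        assert len(kinds["bond"]) == 3
        assert len(kinds["angle"]) == 2
        assert len(kinds["torsion"]) == 1
        assert len(kinds.get("improper", ())) == 0
        one_n = [t for t in enumerate_terms(typed["n-butane"]) if t.kind == "one_n"]
        assert [(t.sites, t.separation) for t in one_n] == [((0, 3), 4)]

    def test_pentane_term_counts(self, typed):
        terms = enumerate_terms(typed["n-pentane"])
        kinds = _kind_sets(terms)
        assert (len(kinds["bond"]), len(kinds["angle"]), len(kinds["torsion"])) == (4, 3, 2)
        ranks = sorted(t.separation for t in terms if t.kind == "one_n")
        assert ranks == [4, 4, 5]

    def test_isobutane_branching(self, typed):
        kinds = _kind_sets(enumerate_terms(typed["isobutane"]))
        assert len(kinds["angle"]) == 3
        assert kinds["improper"] == {(0, 1, 2, 3)}

    def test_special_candidates_follow_dataset_distances(self, typed):
        sg = typed["1,2-ethanediol"]
        terms = enumerate_terms(sg, special_dists=(4, 5))
        specials = {(t.sites, t.separation) for t in terms if t.kind == "special"}
        seps = oracles.shortest_separations(sg)
        assert specials == {
            (pair, d) for pair, d in seps.items() if d in (4, 5)
        }


class TestResolution:
    def test_alkane_bond_resolves_to_rigid_wildcard_row(self, trappe):
        term = Term("bond", (0, 1), (1,))
        rec = resolve(trappe, term, [T("A-C-1-1"), T("A-C-2-1")])
        assert rec.rigid and rec.params == (1.54,)
        assert str(rec.tag1) == "X-C-X-1"

    def test_propane_angle(self, trappe):
        term = Term("angle", (0, 1, 2), (1, 1))
        rec = resolve(trappe, term, [T("A-C-1-1"), T("A-C-2-1"), T("A-C-1-1")])
        assert rec.params == (62500.0, 114.0)

    def test_ethanol_hydroxyl_torsion(self, trappe):
        term = Term("torsion", (0, 1, 2, 3), (1, 1, 1))
        tags = [T("A-C-1-1"), T("Ak-C-2-1"), T("Ak-O-2-1"), T("Ak-H-1-1")]
        rec = resolve(trappe, term, tags)
        assert rec.params == (0.0, 209.82, -29.17, 187.93)

    @pytest.mark.parametrize("name", BUILDABLE)
    def test_orientation_invariance(self, name, typed, trappe):
        sg = typed[name]
        tags = sg.tags()
        for term in enumerate_terms(sg):
            if term.kind not in ("bond", "angle", "torsion"):
                continue
            fwd = resolve(trappe, term, tags)
            rev = resolve(
                trappe,
                Term(term.kind, tuple(reversed(term.sites)),
                     tuple(reversed(term.orders))),
                tags,
            )
            assert fwd is rev

    def test_specificity_monotonicity(self, trappe):
        term = Term("bond", (0, 1), (1,))
        tags = [T("A-C-1-1"), T("A-C-2-1")]
        generic = resolve(trappe, term, tags)
        specific = BondRecord(T("A-C-1-1"), 1, T("A-C-2-1"), None, (1.55,), "10.0/test")
        amended = dataclasses.replace(trappe, bond=[*trappe.bond, specific])
        assert resolve(amended, term, tags) is specific
        restored = dataclasses.replace(amended, bond=list(trappe.bond))
        assert resolve(restored, term, tags) is generic

    def test_tied_specificity_is_an_error(self, trappe):
        a = BondRecord(T("A-C-1-1"), 1, T("X-C-X-X"), None, (1.6,), "10.0/a")
        b = BondRecord(T("X-C-X-X"), 1, T("A-C-2-1"), None, (1.7,), "10.0/b")
        ds = ForceFieldDataset(bond=[a, b])
        with pytest.raises(AmbiguousResolutionError):
            resolve(ds, Term("bond", (0, 1), (1,)), [T("A-C-1-1"), T("A-C-2-1")])

    def test_unparameterized_term_names_tags(self):
        ds = ForceFieldDataset()
        with pytest.raises(UnparameterizedTermError, match="A-C-1-1"):
            resolve(ds, Term("bond", (0, 1), (1,)), [T("A-C-1-1"), T("A-C-1-1")])

    def test_wildcard_in_concrete_tags_rejected(self, trappe):
        with pytest.raises(FFDatError):
            resolve(trappe, Term("bond", (0, 1), (1,)), [T("A-C-X-1"), T("A-C-1-1")])

    def test_intermolecular_site_resolution(self, trappe):
        rec = assembler.resolve_site(trappe, T("Ak-C-3-1"))
        assert rec.params == (0.265, 10.0, 4.33)
        with pytest.raises(UnparameterizedTermError):
            assembler.resolve_site(trappe, T("E-O-2-1"))


class TestComponentBuild:
    def test_ethanol_component(self, trappe):
        ff = F.build_component_ff(trappe, F.make_fixture("ethanol"))
        assert len(ff.sites) == 4
        assert len(ff.bonds) == 3 and all(t.rigid for t in ff.bonds)
        assert len(ff.angles) == 2 and len(ff.torsions) == 1
        assert len(ff.impropers) == 0 and len(ff.specials) == 0
        assert ff.exclusions == [(0, 3, 4)]  # CH3..H pair, 1,4-excluded
        assert ff.unit_profile == "K-Å-e"

    def test_methane_has_no_bonded_terms(self, trappe):
        ff = F.build_component_ff(trappe, F.make_fixture("methane"))
        assert len(ff.sites) == 1
        assert ff.bonded_terms() == [] and ff.one_n == [] and ff.specials == []

    def test_diol_special_pairs(self, trappe):
        ff = F.build_component_ff(trappe, F.make_fixture("1,2-ethanediol"))
        # each hydroxyl H sees the opposite O four bonds away
        assert [(t.sites, t.separation) for t in ff.specials] == [
            ((2, 5), 4), ((3, 4), 4)
        ]
        assert all(t.function_id == 1 and t.params == (75000000.0,)
                   for t in ff.specials)

    def test_isobutane_improper_candidate_is_dropped_with_note(self, trappe):
        ff = F.build_component_ff(trappe, F.make_fixture("isobutane"))
        assert ff.impropers == []
        assert any("improper" in n for n in ff.notes)

    def test_unbuildable_molecule_raises_with_context(self, trappe):
        with pytest.raises(UnparameterizedTermError, match="dimethyl-ether"):
            F.build_component_ff(trappe, F.make_fixture("dimethyl-ether"))

    @pytest.mark.parametrize("name", BUILDABLE)
    def test_net_charge_neutrality(self, name, trappe):
        ff = F.build_component_ff(trappe, F.make_fixture(name))
        assert abs(F.net_charge(ff)) < 1e-12

    def test_site_charges_from_table(self, trappe):
        ff = F.build_component_ff(trappe, F.make_fixture("ethanol"))
        assert [s.charge for s in ff.sites] == [0.0, 0.265, -0.7, 0.435]

    def test_deterministic_output_order(self, trappe):
        a = F.build_component_ff(trappe, F.make_fixture("n-pentane"))
        b = F.build_component_ff(trappe, F.make_fixture("n-pentane"))
        assert assembler.to_json(a) == assembler.to_json(b)


class TestEnergies:
    @pytest.mark.parametrize("name", BUILDABLE)
    def test_reference_geometry_has_zero_bonded_energy(self, name, trappe):
        ff = F.build_component_ff(trappe, F.make_fixture(name))
        coords = F.fixture_coordinates(name)
        e = F.molecule_energy(ff, coords)
        # flexible channels vanish up to the c0 offsets of torsion rows
        # whose series is not zero at trans (the O-C-C-O diol torsion)
        offset = sum(
            t.params[0] for t in ff.torsions if not t.rigid
        )
        assert e.bond == 0.0 and e.improper == 0.0
        assert e.angle == pytest.approx(0.0, abs=1e-8)
        assert e.torsion == pytest.approx(offset, abs=1e-8)
        assert e.warnings == []
        assert all(abs(dev) < 1e-6 for _, _, dev in e.residuals)

    def test_butane_cis_torsion_barrier(self, trappe):
        ff = F.build_component_ff(trappe, F.make_fixture("n-butane"))
        cis = _chain_coords([1.54] * 3, [114.0] * 2, [0.0])
        e = F.molecule_energy(ff, cis)
        assert e.torsion == pytest.approx(2292.70)
        assert e.bond == 0.0 and e.angle == pytest.approx(0.0, abs=1e-8)

    def test_pentane_one_n_channels_against_direct_formula(self, trappe):
        ff = F.build_component_ff(trappe, F.make_fixture("n-pentane"))
        coords = F.fixture_coordinates("n-pentane")
        e = F.molecule_energy(ff, coords)
        (term,) = [t for t in ff.one_n if t.separation == 5]
        i, j = term.sites
        r = float(np.linalg.norm(coords[i] - coords[j]))
        eps = 98.0  # CH3-CH3 pair
        sigma = 3.75
        expected = 4 * eps * ((sigma / r) ** 12 - (sigma / r) ** 6)
        assert e.one_n_vdw == pytest.approx(expected, rel=1e-12)
        assert e.one_n_elec == 0.0

    def test_diol_special_energy_against_direct_formula(self, trappe):
        ff = F.build_component_ff(trappe, F.make_fixture("1,2-ethanediol"))
        coords = F.fixture_coordinates("1,2-ethanediol")
        e = F.molecule_energy(ff, coords)
        expected = sum(
            75000000.0 / float(np.linalg.norm(coords[i] - coords[j])) ** 12
            for (i, j) in (t.sites for t in ff.specials)
        )
        assert e.special == pytest.approx(expected, rel=1e-12)

    def test_rigid_residual_warning_on_distorted_geometry(self, trappe):
        ff = F.build_component_ff(trappe, F.make_fixture("ethanol"))
        coords = F.fixture_coordinates("ethanol", jitter=0.05,
                                       rng=np.random.default_rng(3))
        e = F.molecule_energy(ff, coords)
        assert e.warnings  # distorted rigid bonds are reported, not raised

    def test_coordinate_count_mismatch(self, trappe):
        ff = F.build_component_ff(trappe, F.make_fixture("ethanol"))
        with pytest.raises(ValueError):
            F.molecule_energy(ff, np.zeros((3, 3)))


class TestPairInteraction:
    def test_two_methanes_at_sigma_and_minimum(self, trappe):
        ff = F.build_component_ff(trappe, F.make_fixture("methane"))
        assert F.pair_interaction_energy(
            ff, ff, [[0, 0, 0]], [[3.73, 0, 0]]
        ) == pytest.approx(0.0, abs=1e-10)
        assert F.pair_interaction_energy(
            ff, ff, [[0, 0, 0]], [[2 ** (1 / 6) * 3.73, 0, 0]]
        ) == pytest.approx(-148.0)

    def test_methane_ethane_against_double_loop_oracle(self, trappe):
        ff_a = F.build_component_ff(trappe, F.make_fixture("methane"))
        ff_b = F.build_component_ff(trappe, F.make_fixture("ethane"))
        ca = np.array([[0.0, 0.0, 0.0]])
        cb = np.array([[5.0, 0.0, 0.0], [5.0 + 1.54, 0.0, 0.0]])
        expected = 0.0
        for sa, ra in zip(ff_a.sites, ca):
            for sb, rb in zip(ff_b.sites, cb):
                cross = potentials.combine(1, sa.params, sb.params)
                r = float(np.linalg.norm(ra - rb))
                sr6 = (cross[2] / r) ** 6
                expected += 4 * cross[1] * (sr6**2 - sr6)
        got = F.pair_interaction_energy(ff_a, ff_b, ca, cb)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_combined_sigma_gives_zero_crossing(self, trappe):
        # methane (3.73) against a CH3 site (3.75): sigma_ij = 3.74
        methane = F.build_component_ff(trappe, F.make_fixture("methane"))
        ethane = F.build_component_ff(trappe, F.make_fixture("ethane"))
        far = 1e6  # park the second ethane site far away
        e = F.pair_interaction_energy(
            methane, ethane, [[0, 0, 0]], [[3.74, 0, 0], [far, 0, 0]]
        )
        assert e == pytest.approx(0.0, abs=1e-10)

    def test_profile_mismatch(self, trappe):
        ff = F.build_component_ff(trappe, F.make_fixture("methane"))
        other = dataclasses.replace(ff, unit_profile="eV-Å-e")
        with pytest.raises(FFDatError):
            F.pair_interaction_energy(ff, other, [[0, 0, 0]], [[5, 0, 0]])


class TestSerialization:
    def test_json_document_structure(self, trappe):
        ff = F.build_component_ff(trappe, F.make_fixture("ethanol"))
        doc = json.loads(assembler.to_json(ff))
        schema = json.loads(
            (Path(F.__file__).parent / "schemas" / "component_ff.schema.json").read_text()
        )
        for key in schema["required"]:
            assert key in doc
        assert doc["format"] == "ffdat-component-ff"
        assert [s["tag"] for s in doc["sites"]] == [
            "A-C-1-1", "Ak-C-2-1", "Ak-O-2-1", "Ak-H-1-1"
        ]
        assert all(t["function_id"] is None for t in doc["terms"]["bond"])
        assert doc["terms"]["torsion"][0]["params"] == [0.0, 209.82, -29.17, 187.93]
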