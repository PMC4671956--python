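"""Halogen-bond, hydrogen-bond, and structural-water detection."""

import numpy as np
import pytest

from pocketstates import (
    Ensemble,
    HalogenProbeSpec,
    PocketFixtureConfig,
    WaterSpec,
    detect_halogen_bonds,
    detect_hbonds,
    gen_pocket_fixture,
    read_pdb,
    water_b_stats,
    water_network,
    write_pdb,
)
from pocketstates.interactions import BONDI_RADII, TopologyError
from pocketstates.structio import Atom, EmptyInputError, LookupFailure, Residue, StructureModel


def _probe_model(distance, angle, element="Br"):
    return gen_pocket_fixture(PocketFixtureConfig(
        halogen_probe=HalogenProbeSpec(element, distance, angle)))


class TestHalogenBonds:
    def test_commanded_geometry_recovered(self):
        """Near-ideal Br geometry: commanded (3.0 A, 174 deg) reported exactly."""
        records = detect_halogen_bonds(_probe_model(3.0, 174.0))
        assert len(records) == 1
        rec = records[0]
        assert rec.distance == pytest.approx(3.0, abs=1e-6)
        assert rec.angle == pytest.approx(174.0, abs=1e-6)
        assert rec.acceptor_atom == ("A", 145, "LEU", "O")
        assert rec.donor_atom[3] == "BR"

    def test_no_halogens_empty(self, pocket_model):
        model = gen_pocket_fixture(PocketFixtureConfig())
        assert detect_halogen_bonds(model) == []

    def test_angle_filter(self):
        assert detect_halogen_bonds(_probe_model(3.0, 90.0)) == []

    def test_vdw_sum_cutoff(self):
        # Br...O vdW sum = 1.85 + 1.52 = 3.37: a 3.5 A contact fails vdw_sum
        assert detect_halogen_bonds(_probe_model(3.5, 174.0)) == []
        assert BONDI_RADII["Br"] + BONDI_RADII["O"] == pytest.approx(3.37)
        # ... but passes a 3.6 A fixed cutoff
        found = detect_halogen_bonds(_probe_model(3.5, 174.0),
                                     max_dist_mode="fixed", fixed_max_dist=3.6)
        assert len(found) == 1

    @pytest.mark.parametrize("tighten", ["angle", "distance"])
    def test_monotonicity(self, tighten):
        """Tightening a threshold never adds records."""
        model = _probe_model(3.1, 160.0)
        if tighten == "angle":
            loose = detect_halogen_bonds(model, min_sigma_hole_angle=140.0)
            tight = detect_halogen_bonds(model, min_sigma_hole_angle=165.0)
        else:
            loose = detect_halogen_bonds(model, max_dist_mode="fixed", fixed_max_dist=3.2)
            tight = detect_halogen_bonds(model, max_dist_mode="fixed", fixed_max_dist=3.0)
        keys = lambda recs: {(r.donor_atom, r.acceptor_atom) for r in recs}
        assert keys(tight) <= keys(loose)

    def test_halogen_without_carbon_is_topology_error(self):
        model = StructureModel(model_no=1)
        res = Residue(chain_id="A", res_seq=900, res_name="LIG")
        res.atoms.append(Atom(1, "BR", "Br", "", np.zeros(3), 1.0, 20.0, is_hetero=True))
        model.add_residue(res)
        acc = Residue(chain_id="A", res_seq=145, res_name="LEU")
        acc.atoms.append(Atom(2, "O", "O", "", np.array([3.0, 0, 0]), 1.0, 20.0))
        model.add_residue(acc)
        with pytest.raises(TopologyError):
            detect_halogen_bonds(model)


def _pair_model(distances):
    """Backbone O at origin-ish plus waters at given distances along x."""
    model = StructureModel(model_no=1)
    res = Residue(chain_id="A", res_seq=10, res_name="GLY")
    res.atoms.append(Atom(1, "O", "O", "", np.zeros(3), 1.0, 15.0))
    model.add_residue(res)
    for i, d in enumerate(distances):
        w = Residue(chain_id="A", res_seq=500 + i, res_name="HOH")
        w.atoms.append(Atom(10 + i, "O", "O", "", np.array([d, 0.0, 0.0]),
                            1.0, 20.0, is_hetero=True))
        model.add_residue(w)
    return model


class TestHBonds:
    def test_constructed_pair(self):
        records = detect_hbonds(_pair_model([2.8]))
        assert len(records) == 1
        assert records[0].distance == pytest.approx(2.8, abs=1e-9)
        assert records[0].water_mediated

    def test_cutoff_excludes(self):
        assert detect_hbonds(_pair_model([3.6])) == []

    def test_three_partner_water_sorted(self):
        records = detect_hbonds(_pair_model([2.7, 2.9, 3.1]))
        protein = [r for r in records if 10 in (r.donor_atom[1], r.acceptor_atom[1])]
        assert [round(r.distance, 1) for r in protein] == [2.7, 2.9, 3.1]

    def test_covalent_exclusion(self):
        assert detect_hbonds(_pair_model([1.5])) == []

    def test_symmetric_in_role_swap(self, pocket_model):
        sel = [(res, a) for res, a in pocket_model.iter_atoms() if a.element in "NOS"]
        fwd = detect_hbonds(pocket_model, donors=sel, acceptors=sel)
        pairs = {frozenset((r.donor_atom, r.acceptor_atom)) for r in fwd}
        assert len(pairs) == len(fwd)  # each unordered pair reported once


class TestWaterNetwork:
    def test_w1_and_w2_tagged(self, pocket_model):
        sites = {rec.water_id: rec for rec in water_network(pocket_model, "A")}
        assert sites[("A", 501)].bridge_label == "W1"
        assert sites[("A", 502)].bridge_label == "W2"
        assert sites[("A", 503)].bridge_label is None

    def test_w1_partners_within_cutoff(self, pocket_model):
        rec = next(r for r in water_network(pocket_model, "A") if r.bridge_label == "W1")
        partner_keys = {(p[1], p[3]) for p in rec.partners}
        assert {(147, "O"), (228, "O")} <= partner_keys

    def test_no_bridge_water_no_tag(self):
        model = gen_pocket_fixture(PocketFixtureConfig(waters=(WaterSpec("free", 3.0, 30.0),)))
        labels = [r.bridge_label for r in water_network(model, "A")]
        assert labels == [None]

    def test_tie_goes_to_lower_res_seq(self):
        model = gen_pocket_fixture(PocketFixtureConfig(
            waters=(WaterSpec("W1", 2.8, 12.0), WaterSpec("W1", 2.8, 13.0))))
        tagged = [r for r in water_network(model, "A") if r.bridge_label == "W1"]
        assert len(tagged) == 1 and tagged[0].water_id == ("A", 501)

    def test_stable_under_water_reordering(self, pocket_model):
        text = write_pdb(Ensemble(models=[pocket_model]))
        lines = text.splitlines(keepends=True)
        waters = [l for l in lines if " HOH " in l]
        others = [l for l in lines if " HOH " not in l and not l.startswith("END")]
        reordered = read_pdb("".join(others + waters[::-1]) + "END\n").models[0]
        tags = {r.water_id: r.bridge_label for r in water_network(reordered, "A")}
        baseline = {r.water_id: r.bridge_label for r in water_network(pocket_model, "A")}
        assert tags == baseline

    def test_missing_partner_atoms_listed(self):
        model = gen_pocket_fixture(PocketFixtureConfig())
        del model.residues[("A", 147, "")]
        with pytest.raises(LookupFailure, match="147"):
            water_network(model, "A")


class TestWaterBStats:
    def test_direct_arithmetic(self):
        model = _pair_model([5.0, 6.0, 7.0])
        for i, b in enumerate([10.0, 20.0, 30.0]):
            model.residues[("A", 500 + i, "")].atoms[0].b_factor = b
        stats = water_b_stats(model, "A")
        assert (stats["min_b"], stats["max_b"], stats["mean_b"]) == (10.0, 30.0, 20.0)
        assert (stats["min_b_int"], stats["max_b_int"]) == (10, 30)

    def test_singleton(self):
        model = _pair_model([5.0])
        model.residues[("A", 500, "")].atoms[0].b_factor = 15.3
        stats = water_b_stats(model, "A")
        assert stats["min_b"] == stats["max_b"] == stats["mean_b"] == 15.3
        assert stats["n"] == 1

    def test_no_waters(self):
        with pytest.raises(EmptyInputError):
            water_b_stats(_pair_model([]), "A")
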