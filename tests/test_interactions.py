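"""Interaction detectors: planted geometries, oracle equality, invariances."""

import numpy as np
import pytest

from helpers import random_rotation, transform_model
from oracles import ORACLES
from thermogal import interactions as ia
from thermogal import synthetic_data as syn
from thermogal.structure_io import AtomRecord, Residue, StructureModel


def _two_residue_model(res_a, res_b):
    model = StructureModel(structure_id="pair")
    model.chains["A"] = [res_a, res_b]
    return model


def _residue(name, seq, atom_specs):
    return Residue(
        chain_id="A", seq_number=seq, insertion_code="", res_name=name,
        atoms=[AtomRecord(name=n, element=e, coord=np.asarray(c, float)) for n, e, c in atom_specs],
    )


class TestSaltBridges:
    def test_below_cutoff_detected(self):
        lys = _residue("LYS", 1, [("NZ", "N", (0, 0, 0))])
        glu = _residue("GLU", 5, [("OE1", "O", (3.9, 0, 0))])
        records = ia.detect_salt_bridges(_two_residue_model(lys, glu))
        assert len(records) == 1
        assert records[0].distance == pytest.approx(3.9)
        assert {records[0].atom_a, records[0].atom_b} == {"NZ", "OE1"}

    def test_above_cutoff_empty(self):
        lys = _residue("LYS", 1, [("NZ", "N", (0, 0, 0))])
        glu = _residue("GLU", 5, [("OE1", "O", (4.05, 0, 0))])
        assert ia.detect_salt_bridges(_two_residue_model(lys, glu)) == []

    def test_minimum_over_atom_pairs(self):
        lys = _residue("LYS", 1, [("NZ", "N", (0, 0, 0))])
        glu = _residue("GLU", 5, [("OE1", "O", (3.9, 0, 0)), ("OE2", "O", (3.2, 0.5, 0))])
        (rec,) = ia.detect_salt_bridges(_two_residue_model(lys, glu))
        assert rec.distance == pytest.approx(np.hypot(3.2, 0.5))


class TestHydrogenBonds:
    def test_backbone_pair_detected_and_cutoff(self):
        a = _residue("ALA", 1, [("O", "O", (0, 0, 0))])
        b = _residue("ALA", 5, [("N", "N", (2.9, 0, 0))])
        assert len(ia.detect_hydrogen_bonds(_two_residue_model(a, b))) == 1
        far = _residue("ALA", 5, [("N", "N", (3.6, 0, 0))])
        assert ia.detect_hydrogen_bonds(_two_residue_model(a, far)) == []

    def test_sequence_neighbours_backbone_excluded(self):
        a = _residue("ALA", 1, [("O", "O", (0, 0, 0))])
        b = _residue("ALA", 2, [("N", "N", (2.9, 0, 0))])
        assert ia.detect_hydrogen_bonds(_two_residue_model(a, b)) == []
        # side-chain donors of a neighbour still count
        c = _residue("SER", 2, [("OG", "O", (2.9, 0, 0)), ("N", "N", (2.8, 1, 0))])
        records = ia.detect_hydrogen_bonds(_two_residue_model(a, c))
        assert len(records) == 1


class TestRingDescriptors:
    def test_phe_centroid_is_ring_mean_and_normal_z(self):
        phe = _residue(
            "PHE", 1,
            [(n, "C", c) for n, _, c in
             [t for t in syn._TEMPLATES["PHE"] if t[0] in
              ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")]],
        )
        (desc,) = ia.compute_ring_descriptors(phe)
        ring = phe.coords(desc.ring_atom_names)
        np.testing.assert_allclose(desc.centroid, ring.mean(axis=0), atol=1e-12)
        assert abs(desc.normal[2]) == pytest.approx(1.0, abs=1e-9)
        assert np.linalg.norm(desc.normal) == pytest.approx(1.0, abs=1e-9)

    def test_trp_yields_two_rings(self):
        trp = _residue("TRP", 1, syn._TEMPLATES["TRP"])
        descriptors = ia.compute_ring_descriptors(trp)
        assert sorted(d.ring_label for d in descriptors) == ["TRP5", "TRP6"]

    def test_incomplete_ring_warns_and_skips(self):
        phe = _residue("PHE", 1, [("CG", "C", (0, 0, 0)), ("CD1", "C", (1.4, 0, 0))])
        with pytest.warns(UserWarning, match="incomplete"):
            assert ia.compute_ring_descriptors(phe) == []


class TestPiPiAndCationPi:
    def _phe_at(self, seq, offset):
        off = np.asarray(offset, float)
        return _residue("PHE", seq, [(n, e, np.asarray(c) + off) for n, e, c in syn._TEMPLATES["PHE"]])

    def test_centroid_distance_window(self):
        m = _two_residue_model(self._phe_at(1, (0, 0, 0)), self._phe_at(5, (0, 0, 7.1)))
        (rec,) = ia.detect_pi_pi(m)
        assert rec.distance == pytest.approx(7.1)
        far = _two_residue_model(self._phe_at(1, (0, 0, 0)), self._phe_at(5, (0, 0, 7.3)))
        assert ia.detect_pi_pi(far) == []

    def test_sequence_adjacent_aromatics_excluded(self):
        m = _two_residue_model(self._phe_at(1, (0, 0, 0)), self._phe_at(2, (0, 0, 5.0)))
        assert ia.detect_pi_pi(m) == []

    def test_cation_on_ring_normal_detected_at_angle_zero(self):
        phe = self._phe_at(1, (0, 0, 0))
        lys = _residue("LYS", 5, [("NZ", "N", (0, 0, 4.0))])
        (rec,) = ia.detect_cation_pi(_two_residue_model(phe, lys))
        assert rec.distance == pytest.approx(4.0)
        assert rec.angle == pytest.approx(0.0, abs=1e-6)

    def test_cation_in_ring_plane_rejected_by_angle(self):
        phe = self._phe_at(1, (0, 0, 0))
        lys = _residue("LYS", 5, [("NZ", "N", (5.0, 0, 0))])
        assert ia.detect_cation_pi(_two_residue_model(phe, lys)) == []


class TestDisulfides:
    @pytest.mark.parametrize("d, n_expected", [(2.05, 1), (3.5, 0)])
    def test_sg_sg_cutoff(self, d, n_expected):
        a = _residue("CYS", 1, [("SG", "S", (0, 0, 0))])
        b = _residue("CYS", 9, [("SG", "S", (d, 0, 0))])
        assert len(ia.detect_disulfides(_two_residue_model(a, b))) == n_expected


class TestMetalCoordination:
    def test_synthetic_bidentate_site_count(self):
        model, expected = syn.generate_calcium_site(
            n_waters=3, n_backbone_o=2, bidentate_glu=True, n_outside=1, seed=2
        )
        (site,) = ia.metal_coordination(model)
        assert site.coordination_number == expected == 7
        glu_atoms = {name for _, res_name, name, _ in site.ligands if res_name == "GLU"}
        assert glu_atoms == {"OE1", "OE2"}

    def test_cutoff_construction(self):
        model, expected = syn.generate_calcium_site(
            n_waters=4, n_backbone_o=0, bidentate_glu=False, n_outside=1, seed=3
        )
        (site,) = ia.metal_coordination(model)
        assert site.coordination_number == expected

    def test_no_metal_returns_empty(self):
        a = _residue("ALA", 1, [("CA", "C", (0, 0, 0))])
        model = StructureModel(structure_id="m")
        model.chains["A"] = [a]
        assert ia.metal_coordination(model) == []


@pytest.mark.parametrize("seed", range(12))
def test_detectors_match_bruteforce_oracle_and_manifest(seed):
    """Fuzzed planted structures: detector == exhaustive scan == plan."""
    model, truth = syn.generate_planted_structure(syn.random_plant_spec(seed))
    planted = {}
    for g in truth:
        planted.setdefault(g.kind, {})[frozenset((g.residue_a, g.residue_b))] = g.distance
    detectors = {
        "salt_bridge": ia.detect_salt_bridges,
        "hbond": ia.detect_hydrogen_bonds,
        "pi_pi": ia.detect_pi_pi,
        "cation_pi": ia.detect_cation_pi,
        "disulfide": ia.detect_disulfides,
    }
    for kind, detect in detectors.items():
        records = {r.pair: r.distance for r in detect(model)}
        oracle = ORACLES[kind](model)
        assert records.keys() == oracle.keys(), kind
        for pair, d in records.items():
            assert d == pytest.approx(oracle[pair], abs=1e-9)
        expected = planted.get(kind, {})
        assert records.keys() == expected.keys(), kind
        for pair, d in records.items():
            assert d == pytest.approx(expected[pair], abs=1e-6)


def test_detectors_invariant_under_rigid_motion():
    model, _ = syn.generate_planted_structure(syn.random_plant_spec(5))
    rng = np.random.default_rng(11)
    moved = transform_model(model, random_rotation(rng), rng.uniform(-30, 30, 3))
    for detect in (ia.detect_salt_bridges, ia.detect_hydrogen_bonds, ia.detect_pi_pi,
                   ia.detect_cation_pi, ia.detect_disulfides):
        orig = sorted((r.pair, r.distance) for r in detect(model))
        new = sorted((r.pair, r.distance) for r in detect(moved))
        assert [p for p, _ in orig] == [p for p, _ in new]
        np.testing.assert_allclose(
            [d for _, d in orig], [d for _, d in new], atol=1e-6
        )


def test_records_are_order_normalized_and_deduplicated():
    model, _ = syn.generate_planted_structure(syn.random_plant_spec(8))
    for detect in (ia.detect_salt_bridges, ia.detect_hydrogen_bonds, ia.detect_pi_pi,
                   ia.detect_cation_pi, ia.detect_disulfides):
        records = detect(model)
        pairs = [r.pair for r in records]
        assert len(pairs) == len(set(pairs))
        assert all(r.residue_a <= r.residue_b for r in records)


def test_tsv_export_columns():
    model, _ = syn.generate_planted_structure(syn.random_plant_spec(1))
    frame = ia.records_to_frame(ia.detect_salt_bridges(model), structure_id="x")
    assert list(frame.columns) == [
        "structure_id", "kind", "res_a", "res_b", "atom_a", "atom_b",
        "distance_A", "angle_deg",
    ]
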