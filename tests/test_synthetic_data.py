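"""Generators: determinism, digest-simulator physics, kinetics closed forms."""

import itertools
from collections import Counter

import numpy as np
import pytest

from thermogal import degradation as dg
from thermogal import synthetic_data as syn
from thermogal.structure_io import write_structure


class TestDeterminism:
    def test_planted_structure_regeneration_is_identical(self):
        spec = syn.random_plant_spec(17)
        a, truth_a = syn.generate_planted_structure(spec)
        b, truth_b = syn.generate_planted_structure(syn.random_plant_spec(17))
        assert truth_a == truth_b
        assert write_structure(a) == write_structure(b)

    def test_digest_and_trajectory_and_kinetics_deterministic(self):
        spec = syn.DigestSpec(n_chains=20, chain_length=10, seed=3)
        a = syn.simulate_endo_hydrolysis(spec)
        b = syn.simulate_endo_hydrolysis(syn.DigestSpec(n_chains=20, chain_length=10, seed=3))
        assert [tp.census for tp in a] == [tp.census for tp in b]
        ta = syn.generate_trajectory(5, 10, 0.3, seed=4)
        tb = syn.generate_trajectory(5, 10, 0.3, seed=4)
        np.testing.assert_array_equal(ta.coords, tb.coords)
        ka = syn.generate_kinetics(0.5, 30, 1e-3, 45000, [0.1, 1, 2], noise_cv=0.1, seed=5)
        kb = syn.generate_kinetics(0.5, 30, 1e-3, 45000, [0.1, 1, 2], noise_cv=0.1, seed=5)
        np.testing.assert_array_equal(ka[1], kb[1])


class TestPlantSpecValidation:
    def test_distance_outside_safe_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            syn.PlantSpec(planted=[("salt_bridge", 4.5, "")]).validate()
        with pytest.raises(ValueError, match="window"):
            syn.PlantSpec(decoys=[("pi_pi", 7.25)]).validate()


def _enumerate_l4_outcomes(n_minus, n_plus, inert):
    """Exhaustive terminal censuses reachable from a single 4-chain."""

    def expand(census):
        census = Counter(census)
        cuttable = [length for length in census if length > inert]
        if not cuttable:
            yield frozenset(census.items())
            return
        for length in cuttable:
            for k in range(1, length):
                nxt = Counter(census)
                nxt[length] -= 1
                if nxt[length] == 0:
                    del nxt[length]
                nxt[k] += 1
                nxt[length - k] += 1
                yield from expand(nxt)

    return set(expand(Counter({4: 1})))


class TestDigestSimulator:
    def test_fungal_archetype_terminates_in_mono_and_di(self):
        spec = syn.DigestSpec(n_chains=40, chain_length=12, archetype="fungal", seed=1)
        series = syn.simulate_endo_hydrolysis(spec)
        final = series[-1].census
        assert set(final) <= {1, 2}

    def test_iagal_like_l4_outcomes_match_exhaustive_enumeration(self):
        allowed = _enumerate_l4_outcomes(3, 2, 3)
        # L=4 with inert 3 can only split into (1,3) or (2,2)
        assert allowed == {frozenset({(1, 1), (3, 1)}), frozenset({(2, 2)})}
        spec = syn.DigestSpec(n_chains=50, chain_length=4, archetype="iagal_like", seed=2)
        final = syn.simulate_endo_hydrolysis(spec)[-1].census
        assert max(final) < 4
        # composition: every cut produced either a (1,3) or a (2,2) pair
        assert final.get(1, 0) == final.get(3, 0)
        assert final.get(2, 0) % 2 == 0

    def test_monomer_conservation_exact_at_every_sampled_time(self):
        spec = syn.DigestSpec(
            n_chains=30, chain_length=("geometric", 15.0),
            archetype="blgal_like", sampling_times=[0.001, 0.01, 0.1, 1.0, 10.0], seed=4,
        )
        series = syn.simulate_endo_hydrolysis(spec)
        units = {tp.monomer_units() for tp in series}
        assert len(units) == 1

    def test_chain_count_and_doh_monotone(self):
        spec = syn.DigestSpec(
            n_chains=25, chain_length=18, archetype="fungal",
            sampling_times=list(np.geomspace(1e-4, 10.0, 12)), seed=5,
        )
        series = syn.simulate_endo_hydrolysis(spec)
        chains = [sum(tp.census.values()) for tp in series]
        assert chains == sorted(chains)
        doh = [dg.compute_doh(tp.sample) for tp in series]
        assert doh == sorted(doh)

    def test_bond_rate_weights_follow_subsite_occupancy(self):
        w = syn._bond_weights(8, 3, 2)
        expected = [min(k, 3) * min(8 - k, 2) for k in range(1, 8)]
        assert list(w) == expected

    def test_unknown_archetype_rejected(self):
        with pytest.raises(ValueError, match="archetype"):
            syn.DigestSpec(archetype="nope").subsites


class TestKineticsGenerator:
    def test_noise_free_curve_is_exact(self):
        s, v = syn.generate_kinetics(0.5, 20.0, 1e-3, 50000.0, [0.1, 0.5, 1.0, 5.0])
        vmax = 20.0 * (1e-3 / 50000.0) * 1e3
        np.testing.assert_allclose(v, vmax * s / (0.5 + s), rtol=1e-12)

    def test_rate_at_ten_km_is_ten_elevenths_vmax(self):
        km = 0.47
        s, v = syn.generate_kinetics(km, 34.0, 1e-3, 45000.0, [10 * km])
        vmax = 34.0 * (1e-3 / 45000.0) * 1e3
        assert v[0] / vmax == pytest.approx(10 / 11, abs=1e-12)


class TestTrajectoryGenerator:
    def test_zero_sigma_is_static(self):
        traj = syn.generate_trajectory(8, 12, 0.0, seed=0)
        assert np.all(traj.coords == traj.coords[0])

    def test_flip_validation(self):
        with pytest.raises(ValueError, match="switch_frame"):
            syn.generate_trajectory(5, 10, 0.1, flip=(2, 1.0, 0), seed=0)
        with pytest.raises(ValueError, match="CB"):
            syn.generate_trajectory(5, 10, 0.1, flip=(99, 1.0, 5), seed=0)


def test_planted_structures_survive_io_round_trip_and_detection():
    """Generator -> PDB text -> parse -> detectors still match the manifest."""
    from thermogal.structure_io import parse_structure
    from thermogal import interactions as ia

    model, truth = syn.generate_planted_structure(syn.random_plant_spec(23))
    reparsed = parse_structure(write_structure(model))
    detected = {
        "salt_bridge": ia.detect_salt_bridges(reparsed),
        "hbond": ia.detect_hydrogen_bonds(reparsed),
        "pi_pi": ia.detect_pi_pi(reparsed),
        "cation_pi": ia.detect_cation_pi(reparsed),
        "disulfide": ia.detect_disulfides(reparsed),
    }
    expected = Counter(g.kind for g in truth)
    got = Counter({k: len(v) for k, v in detected.items()})
    assert {k: v for k, v in got.items() if v} == dict(expected)
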