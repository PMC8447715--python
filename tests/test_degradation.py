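"""Degradation-profile arithmetic and Michaelis-Menten fitting."""

import numpy as np
import pytest

from thermogal import degradation as dg
from thermogal import synthetic_data as syn


def _sample(load=2.0, analytes=None, re_mM=1.0):
    return dg.DigestSample(
        sample_id="s", enzyme_id="e", substrate_load=load,
        analytes=analytes or {}, reducing_ends=re_mM,
    )


class TestTheoreticalMax:
    @pytest.mark.parametrize(
        "load, expected",
        [(2.0, 12.335), (0.16214, 1.000), (1.0, 6.167)],
    )
    def test_anhydro_unit_arithmetic(self, load, expected):
        assert dg.theoretical_max_reducing_ends(load) == pytest.approx(expected, abs=1e-3)

    def test_nonpositive_load_raises(self):
        with pytest.raises(ValueError):
            dg.theoretical_max_reducing_ends(0.0)


class TestDoH:
    def test_ten_percent_example(self):
        assert dg.compute_doh(_sample(load=2.0, re_mM=1.2335)) == pytest.approx(10.0, abs=1e-3)

    def test_bounds(self):
        assert dg.compute_doh(_sample(re_mM=0.0)) == 0.0
        full = dg.theoretical_max_reducing_ends(2.0)
        assert dg.compute_doh(_sample(re_mM=full)) == pytest.approx(100.0)

    def test_slack_clips_with_warning_but_excess_raises(self):
        full = dg.theoretical_max_reducing_ends(2.0)
        with pytest.warns(UserWarning, match="clipped"):
            assert dg.compute_doh(_sample(re_mM=full * 1.04)) == 100.0
        with pytest.raises(ValueError, match="exceed"):
            dg.compute_doh(_sample(re_mM=full * 1.10))


class TestGGt5:
    def test_subtraction_and_clipping(self):
        s = _sample(analytes={"G1": 1.0, "G2": 1.0, "G3": 2.0}, re_mM=5.0)
        assert dg.estimate_g_gt5(s) == pytest.approx(1.0)
        with pytest.warns(UserWarning, match="clipped"):
            assert dg.estimate_g_gt5(
                _sample(analytes={"G1": 4.2}, re_mM=4.0)
            ) == 0.0

    def test_consistency_identity_without_clipping(self):
        s = _sample(analytes={"G1": 0.7, "G4": 1.3}, re_mM=3.1)
        assert dg.estimate_g_gt5(s) + s.analyte_sum() == pytest.approx(s.reducing_ends)

    def test_matches_simulator_chain_census(self):
        """G>5 from mass balance equals the true count of long chains."""
        spec = syn.DigestSpec(
            n_chains=60, chain_length=20, archetype="iagal_like",
            sampling_times=[0.001, 0.01, 0.05], seed=12,
        )
        for tp in syn.simulate_endo_hydrolysis(spec):
            sample, scale = syn.census_to_sample(
                tp.census, spec.substrate_load, "e", "s"
            )
            truth = tp.g_gt5_true_mM(scale)
            assert dg.estimate_g_gt5(sample) == pytest.approx(truth, abs=1e-9)


class TestEndpointRatio:
    @pytest.mark.parametrize(
        "analytes, species, expected",
        [
            ({"G1": 1.5, "G2": 1.0, "G3": 3.0}, ("G1", "G2", "G3"), "3:2:6"),
            ({"G1": 2.0, "G2": 1.0}, ("G1", "G2"), "2:1"),
            ({"G1": 1.48, "G2": 1.02, "G3": 2.97}, ("G1", "G2", "G3"), "3:2:6"),
        ],
    )
    def test_integer_ratio_recovery(self, analytes, species, expected):
        samples = [_sample(analytes=analytes, re_mM=sum(analytes.values()))]
        assert dg.endpoint_ratio(samples, species=species) == expected

    def test_all_zero_and_single_species_raise(self):
        with pytest.raises(ValueError):
            dg.endpoint_ratio([_sample(analytes={"G1": 0.0, "G2": 0.0})])
        with pytest.raises(ValueError, match="two nonzero"):
            dg.endpoint_ratio([_sample(analytes={"G1": 1.0, "G2": 0.0})])


class TestMichaelisMenten:
    S_LEVELS = np.geomspace(0.05, 5.0, 10)

    def test_noise_free_recovery_to_four_significant_figures(self):
        s, v = syn.generate_kinetics(0.47, 34.0, 1e-3, 45000.0, self.S_LEVELS)
        fit = dg.fit_michaelis_menten(s, v, 1e-3, 45000.0)
        assert fit.km == pytest.approx(0.47, rel=1e-4)
        assert fit.kcat == pytest.approx(34.0, rel=1e-4)
        assert fit.efficiency == pytest.approx(fit.kcat / fit.km, abs=1e-9)

    def test_ci_coverage_with_five_percent_noise(self):
        hits = 0
        for seed in range(100):
            s, v = syn.generate_kinetics(
                0.47, 34.0, 1e-3, 45000.0, self.S_LEVELS, noise_cv=0.05, seed=seed
            )
            fit = dg.fit_michaelis_menten(s, v, 1e-3, 45000.0)
            lo, hi = fit.km_ci95
            hits += lo <= 0.47 <= hi
        assert hits >= 90

    def test_profile_ci_close_to_linearized(self):
        s, v = syn.generate_kinetics(
            0.47, 34.0, 1e-3, 45000.0, self.S_LEVELS, noise_cv=0.05, seed=5
        )
        lin = dg.fit_michaelis_menten(s, v, 1e-3, 45000.0)
        prof = dg.fit_michaelis_menten(s, v, 1e-3, 45000.0, ci_method="profile")
        lin_hw = (lin.km_ci95[1] - lin.km_ci95[0]) / 2
        prof_hw = (prof.km_ci95[1] - prof.km_ci95[0]) / 2
        assert prof_hw == pytest.approx(lin_hw, rel=0.5)

    def test_saturated_rates_are_unidentifiable(self):
        s = np.geomspace(0.05, 5.0, 8)
        v = np.full_like(s, 0.5)  # zero-order regime only
        with pytest.raises(RuntimeError):
            dg.fit_michaelis_menten(s, v, 1e-3, 45000.0)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="5 substrate"):
            dg.fit_michaelis_menten(
                np.array([0.1, 1, 2]), np.array([1.0, 2, 3]), 1e-3, 45000.0
            )


def test_degradation_profile_pipeline():
    load = 2.0
    samples = [
        _sample(load=load, analytes={"G1": 0.1, "G2": 0.1, "G3": 0.2}, re_mM=1.0),
        _sample(load=load, analytes={"G1": 1.5, "G2": 1.0, "G3": 3.0}, re_mM=5.5),
    ]
    profile = dg.degradation_profile(samples)
    assert profile.endpoint_ratio == "3:2:6"
    assert profile.doh_percent[0] < profile.doh_percent[1]
    assert profile.g_gt5_mM[0] == pytest.approx(0.6)
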