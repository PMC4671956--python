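"""Synthetic generators: commanded-value round-trips, Markov statistics,
seed determinism."""

import numpy as np
import pytest

from pocketstates import (
    Ensemble,
    HalogenProbeSpec,
    PocketFixtureConfig,
    TrajectoryConfig,
    WaterSpec,
    chi1_of,
    classify_rotamer,
    detect_halogen_bonds,
    gen_chi1_trajectory,
    gen_cys_fragment,
    gen_pocket_fixture,
    gen_structure_set,
    pocket_width,
    proline_gate,
    read_pdb,
    write_pdb,
)
from pocketstates.conformation import RotamerState, Subsite3State, subsite3_state
from pocketstates.structio import EmptyInputError
from pocketstates.synthdata import ConstructionError, WELL_CENTERS


class TestCysFragment:
    @pytest.mark.parametrize("chi1", [-60.0, 180.0, 60.0, -179.0, 0.5])
    def test_roundtrip(self, chi1):
        assert chi1_of(gen_cys_fragment(chi1), "A", 220) == pytest.approx(chi1, abs=1e-6)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            gen_cys_fragment(-180.0)

    def test_serialization_roundtrip_precision(self):
        """Commanded chi1 survives write -> read at PDB coordinate precision."""
        model = gen_cys_fragment(-60.0)
        reread = read_pdb(write_pdb(Ensemble(models=[model]))).models[0]
        assert chi1_of(reread, "A", 220) == pytest.approx(-60.0, abs=1e-1)


class TestPocketFixture:
    def test_all_commanded_scalars(self):
        config = PocketFixtureConfig(width=7.5, gate=5.0, chi1=-60.0)
        model = gen_pocket_fixture(config)
        assert pocket_width(model, "A") == pytest.approx(7.5, abs=1e-6)
        assert proline_gate(model, "A") == pytest.approx(5.0, abs=1e-6)
        chi1 = chi1_of(model, "A", 220)
        assert chi1 == pytest.approx(-60.0, abs=1e-6)
        rot = classify_rotamer(chi1)
        assert rot is RotamerState.G_MINUS
        assert subsite3_state(rot) is Subsite3State.OPEN

    def test_probe_detected_exactly_once(self):
        model = gen_pocket_fixture(PocketFixtureConfig(
            halogen_probe=HalogenProbeSpec("Br", 3.0, 174.0)))
        records = detect_halogen_bonds(model)
        assert len(records) == 1
        assert records[0].distance == pytest.approx(3.0, abs=1e-6)
        assert records[0].angle == pytest.approx(174.0, abs=1e-6)

    def test_infeasible_water_constraint(self):
        # Val147 O and Asp228 O anchors are 2.8 A apart; a 1.0 A bridge is impossible
        with pytest.raises(ConstructionError):
            gen_pocket_fixture(PocketFixtureConfig(waters=(WaterSpec("W1", 1.0, 10.0),)))

    def test_commanded_values_survive_serialization(self):
        config = PocketFixtureConfig(width=8.123, gate=4.567, chi1=77.7)
        model = gen_pocket_fixture(config)
        reread = read_pdb(write_pdb(Ensemble(models=[model]))).models[0]
        assert pocket_width(reread, "A") == pytest.approx(8.123, abs=1e-3)
        assert proline_gate(reread, "A") == pytest.approx(4.567, abs=1e-3)


class TestChi1Trajectory:
    def test_transition_matrix_stationarity_identity(self):
        """pi . T = pi exactly for the mixture transition rule, any stay prob."""
        for s in (0.0, 0.5, 0.99):
            config = TrajectoryConfig(n_frames=10, stay_prob=s)
            T = config.transition_matrix
            pi = np.asarray(config.stationary)
            assert np.allclose(pi @ T, pi, atol=1e-15)
            assert np.allclose(T.sum(axis=1), 1.0, atol=1e-15)

    def test_degenerate_distribution(self):
        config = TrajectoryConfig(n_frames=500, stationary=(1.0, 0.0, 0.0), seed=3)
        result = gen_chi1_trajectory(config, build_frames=False)
        states = [classify_rotamer(x) for x in result.chi1]
        assert all(s is RotamerState.G_MINUS for s in states)
        assert all(subsite3_state(s) is Subsite3State.OPEN for s in states)

    def test_seed_determinism_byte_identical(self):
        config = TrajectoryConfig(n_frames=25, seed=42, stay_prob=0.3)
        r1 = gen_chi1_trajectory(config)
        r2 = gen_chi1_trajectory(config)
        assert np.array_equal(r1.chi1, r2.chi1)
        assert write_pdb(r1.ensemble) == write_pdb(r2.ensemble)

    def test_frames_match_series(self):
        config = TrajectoryConfig(n_frames=20, seed=7, stay_prob=0.5)
        result = gen_chi1_trajectory(config)
        assert result.ensemble is not None and len(result.ensemble) == 20
        for i, model in enumerate(result.ensemble.models):
            assert chi1_of(model, "A", 220) == pytest.approx(result.chi1[i], abs=1e-6)

    def test_stay_prob_dwell_oracle(self):
        """Same stationary frequencies, longer dwells at high stay probability.

        Independent dwell-count oracle: mean dwell in state i for
        T = s I + (1-s) pi' is 1 / ((1-s)(1 - pi_i)).
        """
        n = 60_000

        def mean_dwells(states):
            runs = {0: [], 1: [], 2: []}
            count, prev = 0, states[0]
            for s in states[1:]:
                if s == prev:
                    count += 1
                else:
                    runs[prev].append(count + 1)
                    count, prev = 0, s
            runs[prev].append(count + 1)
            return {k: np.mean(v) for k, v in runs.items() if v}

        pi = (0.38, 0.48, 0.14)
        fast = gen_chi1_trajectory(TrajectoryConfig(n, pi, 0.0, 15.0, 11),
                                   build_frames=False)
        slow = gen_chi1_trajectory(TrajectoryConfig(n, pi, 0.9, 15.0, 11),
                                   build_frames=False)
        for i, p in enumerate(pi):
            for result, s in ((fast, 0.0), (slow, 0.9)):
                expected = 1.0 / ((1.0 - s) * (1.0 - p))
                observed = mean_dwells(result.states)[i]
                assert observed == pytest.approx(expected, rel=0.08)
        # long-run frequencies agree between the two chains
        f_fast = np.bincount(fast.states, minlength=3) / n
        f_slow = np.bincount(slow.states, minlength=3) / n
        assert np.allclose(f_fast, f_slow, atol=0.03)

    def test_noise_stays_within_bin_guard(self):
        """At sd <= 15 deg, samples within 4 sd of a well center keep its bin."""
        config = TrajectoryConfig(n_frames=30_000, seed=5, noise_sd=15.0)
        result = gen_chi1_trajectory(config, build_frames=False)
        centers = np.asarray(WELL_CENTERS)[result.states]
        delta = np.abs((result.chi1 - centers + 180.0) % 360.0 - 180.0)
        within = delta <= 4 * 15.0
        expected = np.array([classify_rotamer(float(c)) for c in centers[within]])
        observed = np.array([classify_rotamer(float(x)) for x in result.chi1[within]])
        assert np.all(expected == observed)

    @pytest.mark.parametrize("bad", [
        dict(stationary=(0.5, 0.5, 0.5)),
        dict(stationary=(-0.1, 0.6, 0.5)),
        dict(noise_sd=60.0),
        dict(stay_prob=1.0),
        dict(n_frames=0),
    ])
    def test_invalid_config(self, bad):
        kwargs = dict(n_frames=10)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            TrajectoryConfig(**kwargs)


class TestStructureSet:
    def test_range_endpoints(self):
        from pocketstates.pocketmetrics import POCKET_WIDTH
        from pocketstates import ensemble_metric_summary
        summ = ensemble_metric_summary(gen_structure_set([7.1, 8.8]), POCKET_WIDTH)
        assert summ.min == pytest.approx(7.1, abs=1e-9)
        assert summ.max == pytest.approx(8.8, abs=1e-9)

    def test_singleton(self):
        ens = gen_structure_set([7.5])
        assert len(ens) == 1

    def test_empty_list(self):
        with pytest.raises(EmptyInputError):
            gen_structure_set([])
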