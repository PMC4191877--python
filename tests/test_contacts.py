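"""Contact counting, the three contact-fraction statistics, block averaging."""

import numpy as np
import pytest

import memphase as mp
from memphase.contacts import UndefinedStatisticError, block_average_error, tail_window
from memphase.core import CompositionSpec, Trajectory
from memphase.synthetic import SyntheticSpec, generate_striped_membrane

from conftest import EQUAL_THICKNESS, po4_frame
from _oracles import brute_count_contacts, random_bead_frame


class TestCountContacts:
    def test_single_pair_inside_and_outside_cutoff(self):
        frame = po4_frame([[1, 1, 1], [1.5, 1, 1]], ["DLiPC", "DPPC"])
        a, b = [0], [1]
        assert mp.count_contacts(frame, a, b, 1.1) == 1
        assert mp.count_contacts(frame, a, b, 0.4) == 0

    def test_cutoff_is_inclusive(self):
        frame = po4_frame([[0, 1, 1], [1.1, 1, 1]], ["DLiPC", "DPPC"])
        assert mp.count_contacts(frame, [0], [1], 1.1) == 1

    def test_same_molecule_pairs_excluded(self):
        frame = po4_frame([[1, 1, 1], [1.2, 1, 1]], ["DLiPC", "DLiPC"])
        frame.molecule_index[:] = 0
        assert mp.count_contacts(frame, [0, 1], [0, 1], 1.1, "bead_pairs") == 0

    @pytest.mark.parametrize("counting", ["bead_pairs", "unordered_pairs",
                                          "ordered_from_a"])
    def test_matches_brute_force_oracle(self, counting):
        rng = np.random.default_rng(99)
        for _ in range(10):
            frame = random_bead_frame(rng, int(rng.integers(20, 120)))
            n = frame.n_beads
            sel_a = rng.choice(n, size=n // 2, replace=False)
            sel_b = rng.choice(n, size=n // 2, replace=False)
            cutoff = float(rng.uniform(0.3, 1.5))
            assert mp.count_contacts(frame, sel_a, sel_b, cutoff, counting) == \
                brute_count_contacts(frame, sel_a, sel_b, cutoff, counting)


class TestLipidMixingFraction:
    def test_hand_enumerated_ordered_convention(self):
        # one DLiPC with one DPPC and one DLiPC neighbour; the second DLiPC
        # has no other neighbour -> c_cross = 1, c_same(ordered) = 2, f = 1/3
        frame = po4_frame([[1, 1, 1], [1.9, 1, 1], [1, 2, 1]],
                          ["DLiPC", "DPPC", "DLiPC"])
        res = mp.dlipc_dppc_contact_fraction(frame)
        assert res.counts == {"DLiPC-DPPC": 1, "DLiPC-DLiPC": 2}
        assert res.value == pytest.approx(1 / 3)

    def test_zero_at_complete_phase_separation(self, separated_frame):
        frame, _ = separated_frame
        assert mp.dlipc_dppc_contact_fraction(frame).value == 0.0

    def test_ideal_mixing_limit(self):
        # randomly mixed membrane: expectation is the DPPC phospholipid
        # molar fraction 828/1368 ~ 0.605
        vals = [
            mp.dlipc_dppc_contact_fraction(generate_striped_membrane(
                SyntheticSpec(seed=s, mixing_lambda=1.0,
                              phase_thickness=EQUAL_THICKNESS))[0]).value
            for s in range(12)
        ]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(828 / 1368, abs=3.5 * se)

    def test_undefined_without_any_contacts(self):
        frame = po4_frame([[1, 1, 1], [8, 8, 8]], ["DLiPC", "DPPC"])
        with pytest.raises(UndefinedStatisticError):
            mp.dlipc_dppc_contact_fraction(frame)

    def test_invariant_under_rigid_translation(self, striped_frame):
        frame, _ = striped_frame
        ref = mp.dlipc_dppc_contact_fraction(frame).value
        shifted = frame.copy()
        shifted.positions += np.array([3.7, -1.3, 0.4])
        shifted.positions = shifted.box.wrap(shifted.positions)
        assert mp.dlipc_dppc_contact_fraction(shifted).value == pytest.approx(ref)


class TestPartitioningFractions:
    def test_ld_dissolved_solute_contacts_only_dlipc(self):
        spec = SyntheticSpec(seed=1, composition=CompositionSpec(n_solute=64),
                             solute_mode="ld_partition", interphase_buffer=1.2)
        frame, _ = generate_striped_membrane(spec)
        res = mp.solute_dlipc_contact_fraction(frame, "OCT")
        assert res.value == pytest.approx(1.0)

    def test_solute_fraction_matches_oracle_on_toy_frame(self):
        rng = np.random.default_rng(5)
        frame = random_bead_frame(rng, 60)
        for sp_sel, cutoff in ((("OCT",), 0.8),):
            sol = mp.select_beads(frame, "OCT")
            dlipc = mp.select_beads(frame, "DLiPC")
            dppc = mp.select_beads(frame, "DPPC")
            c1 = brute_count_contacts(frame, sol, dlipc, cutoff, "bead_pairs")
            c2 = brute_count_contacts(frame, sol, dppc, cutoff, "bead_pairs")
            res = mp.solute_dlipc_contact_fraction(frame, "OCT", cutoff)
            assert res.value == pytest.approx(c1 / (c1 + c2))

    def test_chol_fraction_zero_when_chol_confined_to_lo(self):
        spec = SyntheticSpec(seed=1, chol_ld_fraction=0.0, interphase_buffer=1.2)
        frame, _ = generate_striped_membrane(spec)
        assert mp.chol_dlipc_contact_fraction(frame).value == 0.0

    def test_chol_fraction_near_molar_fraction_when_mixed(self):
        vals = [
            mp.chol_dlipc_contact_fraction(generate_striped_membrane(
                SyntheticSpec(seed=s, mixing_lambda=1.0,
                              phase_thickness=EQUAL_THICKNESS))[0]).value
            for s in range(8)
        ]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(540 / 1368, abs=max(4 * se, 0.02))


class TestSeries:
    def test_constant_trajectory_gives_constant_series(self, striped_frame):
        frame, _ = striped_frame
        frames = [frame.copy() for _ in range(3)]
        for i, fr in enumerate(frames):
            fr.time = float(i)
        traj = Trajectory(frames)
        times, vals = mp.contact_fraction_series(traj, "dlipc_dppc")
        assert len(vals) == 3
        assert np.ptp(vals) == 0.0

    def test_single_frame_series_has_length_one(self, striped_frame):
        frame, _ = striped_frame
        traj = Trajectory([frame])
        _, vals = mp.contact_fraction_series(traj, "solute_dlipc", solute="OCT")
        assert len(vals) == 1

    def test_unknown_statistic_rejected(self, striped_traj):
        traj, _ = striped_traj
        with pytest.raises(ValueError, match="unknown statistic"):
            mp.contact_fraction_series(traj, "voronoi")


class TestBlockAveraging:
    def test_constant_series_has_zero_error(self):
        mean, err = block_average_error(np.full(64, 0.25), tail_fraction=1.0)
        assert mean == 0.25
        assert err == 0.0

    def test_iid_noise_matches_closed_form(self):
        rng = np.random.default_rng(0)
        n = 4096
        _, err = block_average_error(rng.normal(0, 1, n), tail_fraction=1.0)
        assert 1 / 1.5 <= err * np.sqrt(n) <= 1.5

    def test_ar1_noise_matches_effective_sample_size(self):
        rng = np.random.default_rng(1)
        phi, n = 0.9, 65536
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(0, np.sqrt(1 - phi**2), n)  # unit marginal variance
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        _, err = block_average_error(x, tail_fraction=1.0)
        target = np.sqrt((1 + phi) / (1 - phi)) / np.sqrt(n)
        assert 1 / 1.5 <= err / target <= 1.5

    def test_short_series_rejected_with_minimum(self):
        with pytest.raises(ValueError, match=">= 4"):
            block_average_error([1.0, 2.0, 3.0], tail_fraction=1.0)

    def test_tail_window_prefers_duration_when_long_enough(self):
        times = np.arange(0.0, 10000.0, 100.0)
        idx = tail_window(times, duration=5000.0, fraction=0.5)
        assert times[idx[0]] == pytest.approx(times[-1] - 5000.0)
        short = tail_window(times[:10], duration=5000.0, fraction=0.5)
        assert len(short) == 5
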