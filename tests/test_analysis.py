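import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import picmelt as pm
from picmelt.analysis import (StateTrace, assign_state, bubble_size,
                              calibrate_break_threshold, contact_fraction,
                              estimate_gate_open_distance, gate_distance,
                              kabsch_rmsd, moving_average)
from picmelt.contacts import ContactRecord
from picmelt.params import AnalysisParams


class TestBubble:
    def test_ideal_duplex_has_zero_bubble(self, bdna20):
        topo, x = bdna20
        assert bubble_size(x, topo) == 0

    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_displaced_pairs_counted_exactly(self, bdna20, k):
        topo, x0 = bdna20
        x = x0.copy()
        for p in topo.wc_pairs[:k]:
            axis = x[p.base_j] - x[p.base_i]
            x[p.base_j] += 10.0 * axis / np.linalg.norm(axis)
        assert bubble_size(x, topo) == k

    def test_monotone_under_distance_increase(self, bdna20):
        topo, x0 = bdna20
        x = x0.copy()
        before = bubble_size(x, topo)
        for p in topo.wc_pairs:
            axis = x[p.base_j] - x[p.base_i]
            x[p.base_j] += 3.0 * axis / np.linalg.norm(axis)
        assert bubble_size(x, topo) >= before

    def test_window_restriction(self, bdna20):
        topo, x0 = bdna20
        x = x0.copy()
        p = topo.wc_pairs[0]
        axis = x[p.base_j] - x[p.base_i]
        x[p.base_j] += 10 * axis / np.linalg.norm(axis)
        assert bubble_size(x, topo, window=[0]) == 1
        assert bubble_size(x, topo, window=list(range(5, 15))) == 0


class TestBreakThresholdCalibration:
    def test_target_100_percent_returns_grid_minimum(self, bdna20):
        topo, x = bdna20
        thr = calibrate_break_threshold(np.array([x]), topo,
                                        target_false_rate=1.0,
                                        grid=[4.0, 6.0, 8.0])
        assert thr == 4.0

    def test_matches_quantile_of_known_distribution(self, bdna20):
        """Synthetic frames with pair distances drawn from a known
        distribution: the calibrated threshold is that distribution's
        (1 - target) quantile on the grid."""
        topo, x0 = bdna20
        rng = np.random.default_rng(0)
        frames = []
        for _ in range(300):
            x = x0.copy()
            for p in topo.wc_pairs:
                axis = x[p.base_j] - x[p.base_i]
                axis /= np.linalg.norm(axis)
                d_target = rng.uniform(4.0, 8.0)  # uniform pair distances
                mid = 0.5 * (x[p.base_i] + x[p.base_j])
                x[p.base_i] = mid - 0.5 * d_target * axis
                x[p.base_j] = mid + 0.5 * d_target * axis
            frames.append(x)
        frames = np.asarray(frames)
        target = 0.10
        grid = np.arange(4.0, 8.5, 0.1)
        thr = calibrate_break_threshold(frames, topo, target, grid)
        # uniform(4, 8): exceed-rate <= 0.10 first at ~7.6
        assert thr == pytest.approx(7.6, abs=0.15)
        # feeding the threshold back reproduces the target rate
        from picmelt.analysis import bubble_trace
        rate = bubble_trace(frames, topo, thr).break_rate
        assert rate <= target
        assert rate > target - 0.03

    def test_unattainable_target_raises(self, bdna20):
        topo, x0 = bdna20
        x = x0.copy()
        for p in topo.wc_pairs:
            axis = x[p.base_j] - x[p.base_i]
            x[p.base_j] += 100.0 * axis / np.linalg.norm(axis)
        with pytest.raises(ValueError, match="unattainable"):
            calibrate_break_threshold(np.array([x]), topo, 0.001,
                                      grid=[5.0, 6.0])


class TestContactFraction:
    def _records(self):
        return [ContactRecord(0, 1, 5.0, 1.2, {"CC"}),
                ContactRecord(0, 2, 5.0, 1.2, {"CC"})]

    def test_all_at_r0_gives_one(self):
        x = np.array([[0, 0, 0], [5, 0, 0], [0, 5, 0]], dtype=float)
        assert contact_fraction(x, self._records()) == 1.0

    def test_all_far_gives_zero(self):
        x = np.array([[0, 0, 0], [500, 0, 0], [0, 500, 0]], dtype=float)
        assert contact_fraction(x, self._records()) == 0.0

    def test_half_formed(self):
        x = np.array([[0, 0, 0], [5, 0, 0], [0, 15, 0]], dtype=float)
        assert contact_fraction(x, self._records()) == 0.5

    def test_empty_subset_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            contact_fraction(np.zeros((3, 3)), [])


class TestAssignState:
    def _trace(self, fcc, foc, fitc, ew=None, gate=None):
        n = len(fcc)
        tr = StateTrace(f_cc=np.asarray(fcc, float),
                        f_oc=np.asarray(foc, float),
                        f_itc=np.asarray(fitc, float))
        if ew is not None:
            tr.ewing_formed = np.asarray(ew, bool)
        if gate is not None:
            tr.gate_open = np.asarray(gate, bool)
        return tr

    def test_all_zero_fractions_unassigned(self):
        labels = assign_state(self._trace([0.0], [0.0], [0.0]))
        assert labels == ["unassigned"]

    def test_canonical_states(self):
        tr = self._trace(
            [0.9, 0.1, 0.05, 0.0], [0.1, 0.4, 0.9, 0.86],
            [0.0, 0.05, 0.1, 0.95])
        assert assign_state(tr) == ["CC", "pre-OC", "OC", "ITC"]

    def test_intermediates_split_by_ewing_and_gate(self):
        tr = self._trace([0.0, 0.0], [0.5, 0.5], [0.4, 0.4],
                         ew=[True, False], gate=[False, False])
        assert assign_state(tr) == ["I1", "I2"]

    def test_perturbed_reference_frames_recover_labels(self, toy_pic):
        cs = toy_pic.contact_sets
        for state, expected in (("CC", "CC"), ("OC", "OC"), ("ITC", "ITC")):
            frame = pm.perturb_to_state(
                toy_pic.reference_set.coords[state],
                cs.records(cs.subset_for_state(state)), noise=0.3, seed=4)
            from picmelt.analysis import state_fractions
            tr = state_fractions(np.array([frame]), cs)
            assert assign_state(tr) == [expected]


class TestGateDistance:
    def test_identical_groups_zero(self):
        x = np.random.default_rng(0).normal(size=(6, 3))
        assert gate_distance(x, ([0, 1, 2], [0, 1, 2])) == 0.0

    def test_two_single_beads(self):
        x = np.array([[0, 0, 0], [3, 4, 0]], dtype=float)
        assert gate_distance(x, ([0], [1])) == pytest.approx(5.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            gate_distance(np.zeros((3, 3)), ([], [0]))

    def test_open_cutoff_from_first_decile(self):
        series = np.concatenate([np.full(20, 10.0), np.full(180, 30.0)])
        cut = estimate_gate_open_distance(series)
        assert cut == pytest.approx(10.0, abs=0.01)


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        s = np.full(40, 3.3)
        assert np.allclose(moving_average(s, 11), s)

    def test_window_one_is_identity(self):
        s = np.arange(20, dtype=float)
        assert np.allclose(moving_average(s, 1), s)

    def test_ramp_interior_unchanged(self):
        s = np.arange(11, dtype=float)
        out = moving_average(s, 3)
        assert np.allclose(out[1:-1], s[1:-1])
        # truncated edges are means of the partial windows
        assert out[0] == pytest.approx(0.5)
        assert out[-1] == pytest.approx(9.5)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average(np.arange(10.0), 4)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 3))
    def test_preserves_mean_of_symmetric_series(self, half):
        s = np.concatenate([np.arange(10.0), np.arange(10.0)[::-1]])
        out = moving_average(s, 2 * half + 1)
        assert out.shape == s.shape


class TestKabschRMSD:
    def test_identical_zero(self):
        x = np.random.default_rng(1).normal(size=(30, 3))
        assert kabsch_rmsd(x, x) == pytest.approx(0.0, abs=1e-9)

    def test_rotated_copy_zero(self):
        from scipy.spatial.transform import Rotation
        x = np.random.default_rng(2).normal(size=(30, 3)) * 5
        y = Rotation.from_euler("zyx", [1.0, 0.5, -0.7]).apply(x) + 4.0
        assert kabsch_rmsd(x, y) == pytest.approx(0.0, abs=1e-8)

    def test_single_displaced_bead_scales_as_d_over_sqrt_n(self):
        n, d = 400, 2.0
        x = np.random.default_rng(3).normal(size=(n, 3)) * 20
        y = x.copy()
        y[0] += np.array([d, 0.0, 0.0])
        # for large n the optimal superposition barely moves, so
        # RMSD ~ d / sqrt(n)
        assert kabsch_rmsd(x, y) == pytest.approx(d / np.sqrt(n), rel=0.05)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((5, 3)), np.zeros((6, 3)))
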