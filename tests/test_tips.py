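import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from tipscoder import (
    DecisionConfig,
    TIWindow,
    apply_tips,
    calibrate_criterion,
    decision_statistic,
    integrator_output,
    make_sequence,
    window_value,
)
from conftest import brute_force_decisions


@pytest.fixture
def grid_window():
    """Window sampled at a 1.1 ms grid (the worked-example spacing)."""
    return TIWindow(dt=1.1e-3)


def _seq(single_channel_map, pulses):
    return make_sequence([(t, 10, m) for t, m in pulses], single_channel_map)


class TestWindow:
    def test_center_is_one_from_both_branches(self):
        w = TIWindow()
        assert window_value(0.0, w) == 1.0
        assert window_value(-1e-12, w) == pytest.approx(1.0, abs=1e-9)

    def test_backward_side_time_constant(self):
        w = TIWindow()
        assert window_value(w.tau_a, w) == pytest.approx(np.exp(-1), abs=1e-12)

    def test_forward_side_double_exponential(self):
        w = TIWindow()
        expected = 0.83 * np.exp(-1.0) + 0.17 * np.exp(-4.6 / 16.6)
        assert window_value(-4.6e-3, w) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.4342, abs=1e-4)

    def test_monotone_decay_on_both_sides_and_zero_outside_support(self):
        w = TIWindow()
        t_pos = np.linspace(0, w.half_support, 2000)
        t_neg = np.linspace(-w.half_support, 0, 2000)
        assert np.all(np.diff(window_value(t_pos, w)) < 0)
        assert np.all(np.diff(window_value(t_neg, w)) > 0)
        assert window_value(w.half_support + 1e-6, w) == 0.0
        assert window_value(-w.half_support - 1e-6, w) == 0.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            TIWindow(tau_a=-1.0)
        with pytest.raises(ValueError):
            TIWindow(r=1.5)


class TestIntegratorOutput:
    def test_zero_train_gives_zero_output(self, grid_window):
        out = integrator_output(np.zeros(50), grid_window)
        assert np.all(out == 0)

    def test_single_unit_pulse_reproduces_window_shape(self, grid_window):
        train = np.zeros(201)
        train[100] = 1.0
        out = integrator_output(train, grid_window, domain="magnitude")
        # O(m) = W((100 - m) * dt): forward-masking tail after the pulse
        m = np.arange(201)
        expected = window_value((100 - m) * grid_window.dt, grid_window)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_superposition_exact(self, grid_window):
        t1, t2 = np.zeros(120), np.zeros(120)
        t1[30], t2[75] = 0.7, 0.4
        both = integrator_output(t1 + t2, grid_window, domain="magnitude")
        sep = integrator_output(t1, grid_window, domain="magnitude") + \
            integrator_output(t2, grid_window, domain="magnitude")
        np.testing.assert_array_equal(both, sep)

    def test_negative_train_rejected(self, grid_window):
        with pytest.raises(ValueError):
            integrator_output(np.array([-0.1]), grid_window)


class TestDecisionStatistic:
    def test_isolated_pulse_gets_infinite_statistic(
        self, single_channel_map, grid_window
    ):
        seq = _seq(single_channel_map, [(0.5, 0.8)])
        stat = decision_statistic(seq, 0, grid_window, DecisionConfig())
        assert np.isinf(stat)

    def test_small_pulse_after_strong_masker(self, single_channel_map, grid_window):
        # O_without at the target's time = 1^2 * W(-1.1 ms) ~= 0.8126;
        # adding the 0.1-magnitude pulse raises it by 0.01 -> ~0.053 dB
        seq = _seq(single_channel_map, [(0.0, 1.0), (1.1e-3, 0.1)])
        stat = decision_statistic(seq, 1, grid_window, DecisionConfig())
        assert stat == pytest.approx(0.053, abs=0.002)
        assert stat < 1.3  # removed at the reference criterion

    def test_equal_pulse_after_equal_masker(self, single_channel_map, grid_window):
        seq = _seq(single_channel_map, [(0.0, 1.0), (1.1e-3, 1.0)])
        stat = decision_statistic(seq, 1, grid_window, DecisionConfig())
        assert stat == pytest.approx(3.48, abs=0.01)
        assert stat > 1.3  # kept at the reference criterion

    def test_statistic_matches_brute_force_oracle(
        self, single_channel_map, grid_window
    ):
        pulses = [(0.0, 0.9), (1.1e-3, 0.2), (3.3e-3, 0.6), (8.8e-3, 0.4)]
        seq = _seq(single_channel_map, pulses)
        cfg = DecisionConfig()
        _, oracle_stats = brute_force_decisions(seq, grid_window, cfg)
        for k in range(len(seq)):
            got = decision_statistic(seq, k, grid_window, cfg)
            if np.isinf(oracle_stats[k]):
                assert np.isinf(got)
            else:
                assert got == pytest.approx(oracle_stats[k], abs=1e-9)

    def test_out_of_range_index_rejected(self, single_channel_map, grid_window):
        seq = _seq(single_channel_map, [(0.0, 0.5)])
        with pytest.raises(IndexError):
            decision_statistic(seq, 5, grid_window, DecisionConfig())


class TestApplyTips:
    def test_criterion_minus_inf_removes_nothing(self, single_channel_map, grid_window):
        seq = _seq(single_channel_map, [(k * 1.1e-3, 0.5) for k in range(20)])
        pruned, rep = apply_tips(
            seq, grid_window, DecisionConfig(criterion_db=-np.inf)
        )
        assert len(pruned) == len(seq)
        assert rep.removal_fraction == 0.0

    def test_criterion_plus_inf_keeps_only_isolated(self, single_channel_map, grid_window):
        # two clusters far beyond the window support, one isolated pulse
        seq = _seq(
            single_channel_map,
            [(0.0, 0.9), (1.1e-3, 0.9), (0.5, 0.7)],
        )
        pruned, rep = apply_tips(
            seq, grid_window, DecisionConfig(criterion_db=np.inf)
        )
        assert list(pruned.times) == [0.5]
        assert rep.n_isolated == 1

    def test_pruning_never_moves_or_rescales(self, single_channel_map, grid_window):
        rng = np.random.default_rng(11)
        pulses = [(k * 1.1e-3, float(m)) for k, m in
                  enumerate(rng.uniform(0.1, 1.0, 60))]
        seq = _seq(single_channel_map, pulses)
        pruned, _ = apply_tips(seq, grid_window, DecisionConfig(criterion_db=1.3))
        original = {(round(t, 9), m) for t, m in zip(seq.times, seq.magnitudes)}
        for t, m in zip(pruned.times, pruned.magnitudes):
            assert (round(t, 9), m) in original

    @settings(
        max_examples=30, deadline=None,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(st.integers(0, 2**31 - 1))
    def test_batch_matches_brute_force_on_small_sequences(
        self, single_channel_map, seed
    ):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 11))
        w = TIWindow(dt=1 / 900)
        frames = np.sort(rng.choice(60, size=n, replace=False))
        pulses = [(k / 900, float(m)) for k, m in
                  zip(frames, rng.uniform(0.05, 1.0, n))]
        seq = _seq(single_channel_map, pulses)
        cfg = DecisionConfig(criterion_db=float(rng.uniform(0.0, 4.0)))
        pruned, _ = apply_tips(seq, w, cfg)
        oracle_keep, _ = brute_force_decisions(seq, w, cfg)
        np.testing.assert_array_equal(
            np.isin(np.round(seq.times * 1e9), np.round(pruned.times * 1e9)),
            oracle_keep,
        )

    def test_batch_is_permutation_invariant(self, single_channel_map):
        # identical pattern, two different construction orders
        w = TIWindow(dt=1 / 900)
        rng = np.random.default_rng(5)
        pulses = [(k / 900, float(m)) for k, m in
                  enumerate(rng.uniform(0.1, 1.0, 40))]
        seq_fwd = _seq(single_channel_map, pulses)
        seq_rev = _seq(single_channel_map, pulses[::-1])
        cfg = DecisionConfig(criterion_db=1.0)
        p1, _ = apply_tips(seq_fwd, w, cfg)
        p2, _ = apply_tips(seq_rev, w, cfg)
        np.testing.assert_allclose(p1.times, p2.times)

    def test_channel_independence(self, cis_map):
        w = TIWindow(dt=1 / 900)
        rng = np.random.default_rng(9)
        base = [(k / 900, 10, float(m)) for k, m in
                enumerate(rng.uniform(0.1, 1.0, 50))]
        other = [(k / 900 + 3 * cis_map.slot_us * 1e-6, 12, float(m))
                 for k, m in enumerate(rng.uniform(0.1, 1.0, 50))]
        cfg = DecisionConfig(criterion_db=1.0)
        seq_a = make_sequence(base, cis_map)
        seq_b = make_sequence(base + other, cis_map)
        pa, _ = apply_tips(seq_a, w, cfg)
        pb, _ = apply_tips(seq_b, w, cfg)
        kept_b_ch10 = pb.times[pb.channels == 10]
        np.testing.assert_allclose(pa.times, kept_b_ch10)

    def test_ratio_invariance_under_channel_rescaling(
        self, single_channel_map, grid_window
    ):
        rng = np.random.default_rng(21)
        pulses = [(k * 1.1e-3, float(m)) for k, m in
                  enumerate(rng.uniform(0.1, 1.0, 30))]
        seq1 = _seq(single_channel_map, pulses)
        seq2 = _seq(single_channel_map, [(t, m * 0.37) for t, m in pulses])
        cfg = DecisionConfig()
        for k in range(len(seq1)):
            s1 = decision_statistic(seq1, k, grid_window, cfg)
            s2 = decision_statistic(seq2, k, grid_window, cfg)
            if np.isinf(s1):
                assert np.isinf(s2)
            else:
                assert s1 == pytest.approx(s2, abs=1e-9)

    def test_sequential_mode_prunes_against_evolving_pattern(
        self, single_channel_map, grid_window
    ):
        # masker, weak pulse, then a pulse masked by the weak one only:
        # batch removes both followers; sequential keeps the third because
        # the second was already deleted from the pattern
        pulses = [(0.0, 1.0), (1.1e-3, 0.12), (2.2e-3, 0.14)]
        seq = _seq(single_channel_map, pulses)
        crit = 1.0
        batch, _ = apply_tips(
            seq, grid_window, DecisionConfig(criterion_db=crit)
        )
        seqm, _ = apply_tips(
            seq, grid_window,
            DecisionConfig(criterion_db=crit, scan_mode="sequential"),
        )
        assert len(seqm) >= len(batch)


class TestCalibration:
    def _speech_like_seq(self, single_channel_map, n=400, seed=2):
        rng = np.random.default_rng(seed)
        # slow log-normal level contour -> realistic masking variety
        level = np.exp(0.6 * np.cumsum(rng.standard_normal(n)) / np.sqrt(n))
        level = 0.05 + 0.9 * (level - level.min()) / np.ptp(level)
        return _seq(single_channel_map, [(k / 900, float(m))
                                         for k, m in enumerate(level)])

    def test_target_zero_removes_nothing(self, single_channel_map):
        seq = self._speech_like_seq(single_channel_map)
        w = TIWindow(dt=1 / 900)
        crit = calibrate_criterion(seq, 0.0, w, DecisionConfig())
        _, rep = apply_tips(seq, w, DecisionConfig(criterion_db=crit))
        assert rep.n_removed == 0

    @pytest.mark.parametrize("target", [0.25, 1 / 3, 0.5])
    def test_quantile_calibration_hits_target(self, single_channel_map, target):
        seq = self._speech_like_seq(single_channel_map)
        w = TIWindow(dt=1 / 900)
        crit = calibrate_criterion(seq, target, w, DecisionConfig())
        _, rep = apply_tips(seq, w, DecisionConfig(criterion_db=crit))
        assert abs(rep.removal_fraction - target) <= 1.0 / len(seq) + 1e-12

    def test_criterion_monotone_in_target(self, single_channel_map):
        seq = self._speech_like_seq(single_channel_map)
        w = TIWindow(dt=1 / 900)
        cfg = DecisionConfig()
        assert calibrate_criterion(seq, 0.33, w, cfg) <= calibrate_criterion(
            seq, 0.5, w, cfg
        )

    def test_removal_fraction_monotone_in_criterion(self, single_channel_map):
        seq = self._speech_like_seq(single_channel_map, n=200, seed=4)
        w = TIWindow(dt=1 / 900)
        fracs = []
        for crit in np.linspace(-1.0, 6.0, 15):
            _, rep = apply_tips(seq, w, DecisionConfig(criterion_db=float(crit)))
            fracs.append(rep.removal_fraction)
        assert all(a <= b + 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_unreachable_target_rejected(self, single_channel_map):
        # two isolated pulses: nothing can ever be removed
        seq = _seq(single_channel_map, [(0.0, 0.5), (0.5, 0.5)])
        w = TIWindow(dt=1 / 900)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="isolated"):
                calibrate_criterion(seq, 0.5, w, DecisionConfig())

    def test_sequential_calibration_converges(self, single_channel_map):
        seq = self._speech_like_seq(single_channel_map, n=300, seed=8)
        w = TIWindow(dt=1 / 900)
        cfg = DecisionConfig(scan_mode="sequential")
        crit = calibrate_criterion(seq, 0.4, w, cfg)
        _, rep = apply_tips(
            seq, w, DecisionConfig(criterion_db=crit, scan_mode="sequential")
        )
        assert abs(rep.removal_fraction - 0.4) <= 0.01
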