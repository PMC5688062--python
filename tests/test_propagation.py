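"""Burst matching, propagation probabilities, DPI and the surrogate test."""

import math

import numpy as np
import pytest

import meaflow as mf
from meaflow.fixtures import build_session, div20_reference_session
from meaflow.model import Burst, Chamber, PropagationConfig
from meaflow.propagation import match_bursts_bruteforce


def random_burst_log(rng, n, chamber, rate=0.5, dur_range=(0.05, 0.3)):
    """Sorted non-overlapping bursts from exponential gaps."""
    bursts = []
    t = 0.0
    for _ in range(n):
        t += rng.exponential(1.0 / rate)
        dur = rng.uniform(*dur_range)
        bursts.append(Burst(onset=t, offset=t + dur, chamber=chamber))
        t += dur
    return bursts


class TestMatchBursts:
    def test_forward_pair_with_overlap(self):
        s = [Burst(onset=1.00, offset=1.20, chamber=Chamber.SOURCE)]
        t = [Burst(onset=1.15, offset=1.35, chamber=Chamber.TARGET)]
        (pair,) = mf.match_bursts(s, t)
        assert pair.delay_ms == pytest.approx(150.0)
        assert pair.direction == "S_to_T"

    def test_gap_without_spiking_blocks_match(self):
        s = [Burst(onset=1.00, offset=1.20, chamber=Chamber.SOURCE)]
        t = [Burst(onset=1.30, offset=1.50, chamber=Chamber.TARGET)]
        assert mf.match_bursts(s, t) == []

    def test_lag_window_blocks_distant_match(self):
        s = [Burst(onset=1.00, offset=2.00, chamber=Chamber.SOURCE)]
        t = [Burst(onset=1.60, offset=2.20, chamber=Chamber.TARGET)]
        assert mf.match_bursts(s, t, max_lag=0.5) == []

    def test_backward_pair_from_negative_delay(self):
        s = [Burst(onset=1.13, offset=1.33, chamber=Chamber.SOURCE)]
        t = [Burst(onset=1.00, offset=1.20, chamber=Chamber.TARGET)]
        (pair,) = mf.match_bursts(s, t)
        assert pair.direction == "T_to_S"
        assert pair.delay_ms == pytest.approx(-130.0)

    def test_nearest_initiator_wins(self):
        s = [Burst(onset=0.90, offset=1.30, chamber=Chamber.SOURCE),
             Burst(onset=1.40, offset=1.60, chamber=Chamber.SOURCE)]
        t = [Burst(onset=1.45, offset=1.70, chamber=Chamber.TARGET)]
        (pair,) = mf.match_bursts(s, t)
        assert pair.source_index == 1  # |50 ms| beats |550 ms|

    def test_relay_chain_uses_middle_burst_twice(self):
        """T -> S -> T: the source burst responds backward and initiates
        forward, yielding one pair of each direction."""
        s = [Burst(onset=1.13, offset=1.46, chamber=Chamber.SOURCE)]
        t = [Burst(onset=1.00, offset=1.20, chamber=Chamber.TARGET),
             Burst(onset=1.26, offset=1.46, chamber=Chamber.TARGET)]
        pairs = mf.match_bursts(s, t)
        assert sorted(p.direction for p in pairs) == ["S_to_T", "T_to_S"]

    def test_equals_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            ns, nt = rng.integers(0, 21, size=2)
            s = random_burst_log(rng, ns, Chamber.SOURCE)
            t = random_burst_log(rng, nt, Chamber.TARGET)
            fast = sorted((p.source_index, p.target_index)
                          for p in mf.match_bursts(s, t))
            assert fast == match_bursts_bruteforce(s, t)

    def test_antisymmetry_under_chamber_swap(self):
        rng = np.random.default_rng(7)
        s = random_burst_log(rng, 40, Chamber.SOURCE)
        t = random_burst_log(rng, 40, Chamber.TARGET)
        fwd = {(p.source_index, p.target_index, round(p.delay, 9))
               for p in mf.match_bursts(s, t)}
        rev = {(p.target_index, p.source_index, round(-p.delay, 9))
               for p in mf.match_bursts(t, s)}
        assert fwd == rev


class TestPropagationProbabilities:
    def test_worked_example_forward(self):
        src, tgt = div20_reference_session()
        pairs = mf.match_bursts(src, tgt, 0.5)
        s = mf.propagation_probabilities(pairs, len(src), len(tgt))
        assert s.n_forward == 170 and s.n_source_bursts == 193
        assert round(100 * s.pp_st) == 88

    def test_worked_example_backward(self):
        src, tgt = div20_reference_session()
        pairs = mf.match_bursts(src, tgt, 0.5)
        s = mf.propagation_probabilities(pairs, len(src), len(tgt))
        assert s.n_backward == 143 and s.n_target_bursts == 409
        assert round(100 * s.pp_ts) == 35

    def test_dpi_is_ratio_of_probabilities(self):
        src, tgt = build_session(20, 20, 10, 4)
        pairs = mf.match_bursts(src, tgt, 0.5)
        s = mf.propagation_probabilities(pairs, len(src), len(tgt))
        assert s.dpi == pytest.approx(s.pp_st / s.pp_ts)

    def test_dpi_infinite_without_backward_pairs(self):
        src, tgt = build_session(10, 10, 5, 0)
        pairs = mf.match_bursts(src, tgt, 0.5)
        s = mf.propagation_probabilities(pairs, len(src), len(tgt))
        assert math.isinf(s.dpi)
        assert s.to_dict()["dpi"] == "inf"

    def test_swap_inverts_dpi(self):
        src, tgt = build_session(30, 30, 12, 6)
        fwd = mf.propagation_probabilities(
            mf.match_bursts(src, tgt, 0.5), len(src), len(tgt))
        rev = mf.propagation_probabilities(
            mf.match_bursts(tgt, src, 0.5), len(tgt), len(src))
        assert rev.pp_st == pytest.approx(fwd.pp_ts)
        assert rev.pp_ts == pytest.approx(fwd.pp_st)
        assert rev.dpi == pytest.approx(1.0 / fwd.dpi)

    def test_zero_denominators_rejected(self):
        with pytest.raises(ValueError):
            mf.propagation_probabilities([], 0, 10)


class TestSurrogateTest:
    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(3)
        s = random_burst_log(rng, 30, Chamber.SOURCE, rate=0.2)
        t = random_burst_log(rng, 30, Chamber.TARGET, rate=0.2)
        cfg = PropagationConfig(n_surrogates=5)
        a = mf.surrogate_test(s, t, cfg, seed=99, duration=300.0)
        b = mf.surrogate_test(s, t, cfg, seed=99, duration=300.0)
        np.testing.assert_array_equal(a.surr_mean, b.surr_mean)
        np.testing.assert_array_equal(a.significant, b.significant)

    def test_planted_delay_bin_is_significant(self, layout):
        """Strong forward coupling at ~130 ms lights up the matching bin."""
        params = mf.SimulationParams(p_fwd=0.8, p_bwd=0.0, seed=31)
        _, truth = mf.simulate_recording(params, layout, 1800.0)
        cfg = PropagationConfig(n_surrogates=200)
        null = mf.surrogate_test(truth.source_bursts, truth.target_bursts,
                                 cfg, seed=5, duration=1800.0)
        centres = (null.delay_bin_edges_ms[:-1] + null.delay_bin_edges_ms[1:]) / 2
        bin_130 = int(np.argmin(np.abs(centres - 130.0)))
        assert null.significant[bin_130]
        # and nothing on the anticausal side
        assert not np.any(null.significant[centres < -50.0])

    def test_observed_probabilities_normalized(self):
        src, tgt = div20_reference_session()
        cfg = PropagationConfig(n_surrogates=2)
        null = mf.surrogate_test(src, tgt, cfg, seed=1, duration=2900.0)
        assert np.all(null.p_observed >= 0) and np.all(null.p_observed <= 1)
        assert null.p_observed.sum() == pytest.approx(
            (170 + 143) / 409)


class TestEvokedPropagation:
    def build_evoked(self, n_stim=10, n_linked=4):
        """Stimuli evoke a source burst 20 ms later; the first `n_linked`
        source bursts each trigger a target response at +130 ms."""
        stim = [10.0 * k for k in range(n_stim)]
        src, tgt = [], []
        for k, ts in enumerate(stim):
            on = ts + 0.02
            src.append(Burst(onset=on, offset=on + 0.2, chamber=Chamber.SOURCE))
            if k < n_linked:
                tgt.append(Burst(onset=on + 0.13, offset=on + 0.33,
                                 chamber=Chamber.TARGET))
        return stim, src, tgt

    def test_fully_propagated_evoked_bursts(self):
        stim, src, tgt = self.build_evoked(10, 10)
        out = mf.evoked_propagation(stim, ["source"] * 10, src, tgt,
                                    window=0.1)
        assert out["evoked_pp_st"] == pytest.approx(1.0)
        assert out["n_evoked_source"] == 10

    def test_partial_propagation_fraction(self):
        stim, src, tgt = self.build_evoked(10, 4)
        out = mf.evoked_propagation(stim, ["source"] * 10, src, tgt,
                                    window=0.1)
        assert out["evoked_pp_st"] == pytest.approx(0.4)

    def test_direction_without_evoked_bursts_is_missing(self):
        stim, src, tgt = self.build_evoked(10, 4)
        out = mf.evoked_propagation(stim, ["source"] * 10, src, tgt,
                                    window=0.1)
        assert out["evoked_pp_ts"] is None
        assert out["n_evoked_target"] == 0

    def test_no_stimuli_rejected(self):
        with pytest.raises(ValueError):
            mf.evoked_propagation([], [], [], [], window=0.1)
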