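"""Ground-truth properties of the synthetic recording generator."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import meaflow as mf
from meaflow.model import Region
from meaflow.synthetic import GrowthSimParams, spike_waveform


class TestSimulateRecording:
    def test_certain_forward_no_backward(self, layout):
        """p_fwd=1, p_bwd=0, no spontaneous target bursts: every source
        burst isolated from its neighbours carries exactly one forward
        link, and no backward links exist.  (Bursts packed closer than a
        response window can lose their link to collision-free placement.)"""
        params = mf.SimulationParams(
            p_fwd=1.0, p_bwd=0.0, burst_rate_target=0.0,
            background_rate=0.0, seed=5,
        )
        _, truth = mf.simulate_recording(params, layout, 1200.0)
        assert len(truth.backward_links) == 0
        assert truth.forward_links
        initiators = {l.initiator_index for l in truth.forward_links}
        assert len(initiators) == len(truth.forward_links)  # one link each
        onsets = np.array([b.onset for b in truth.source_bursts])
        for i, b in enumerate(truth.source_bursts):
            gaps = np.abs(onsets - b.onset)
            gaps[i] = np.inf
            if gaps.min() > 1.5:  # no neighbour within a response window
                assert i in initiators
        assert len(truth.forward_links) >= 0.9 * len(truth.source_bursts)

    def test_forward_link_count_within_binomial_ci(self, layout):
        """p_fwd=0.5: the number of linked source bursts stays inside the
        99% binomial envelope of the spontaneous-burst count."""
        params = mf.SimulationParams(
            p_fwd=0.5, p_bwd=0.0, burst_rate_target=0.0,
            background_rate=0.0, seed=11,
        )
        _, truth = mf.simulate_recording(params, layout, 2000.0)
        n = len(truth.source_bursts)
        assert n > 150
        k = len(truth.forward_links)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.5)
        assert lo <= k <= hi

    def test_link_delay_mean_matches_truncated_normal(self, layout):
        """Empirical link delays over >=500 links match the truncated
        normal law within 3 standard errors."""
        delays = []
        for seed in range(4):
            params = mf.SimulationParams(p_fwd=1.0, p_bwd=0.0,
                                         burst_rate_target=0.0,
                                         background_rate=0.0, seed=seed)
            _, truth = mf.simulate_recording(params, layout, 1800.0)
            delays += [l.delay for l in truth.links]
        delays = np.asarray(delays)
        assert delays.size >= 500
        law = mf.SimulationParams().delay_distribution()
        se = delays.std(ddof=1) / np.sqrt(delays.size)
        assert abs(delays.mean() - law.mean()) < 3 * se
        assert delays.min() > 0 and delays.max() < 0.5

    def test_same_seed_bit_identical(self, layout):
        params = mf.SimulationParams(seed=21)
        s1, t1 = mf.simulate_recording(params, layout, 300.0)
        s2, t2 = mf.simulate_recording(params, layout, 300.0)
        for eid in layout.electrode_ids:
            np.testing.assert_array_equal(s1.spikes[eid], s2.spikes[eid])
        assert t1.links == t2.links
        assert t1.source_bursts == t2.source_bursts

    def test_all_spikes_in_burst_windows_without_background(self, clean_recording):
        _, spikes, truth = clean_recording
        layout = spikes.layout
        windows = {
            Region.SOURCE: [(b.onset, b.offset) for b in truth.source_bursts],
            Region.TARGET: [(b.onset, b.offset) for b in truth.target_bursts],
        }
        for region in (Region.SOURCE, Region.TARGET):
            pooled = spikes.region_spikes(region)
            on = np.array([w[0] for w in windows[region]])
            off = np.array([w[1] for w in windows[region]])
            k = np.searchsorted(on, pooled, side="right") - 1
            assert np.all(k >= 0)
            assert np.all(pooled <= off[k])
        # channel relay spikes sit inside their initiator window
        # (plus conduction offsets below 2 ms)
        all_on = np.sort(np.concatenate([
            [b.onset for b in truth.source_bursts],
            [b.onset for b in truth.target_bursts]]))
        all_off = np.sort(np.concatenate([
            [b.offset for b in truth.source_bursts],
            [b.offset for b in truth.target_bursts]]))
        pooled = spikes.region_spikes(Region.CHANNEL)
        k = np.searchsorted(all_on, pooled, side="right") - 1
        assert np.all(k >= 0)
        assert np.all(pooled <= np.sort(all_off)[-1] + 0.002)

    def test_relay_offsets_ordered_by_rank(self, layout):
        """Forward relay events hit the three channel electrodes in rank
        order with lags of pitch/velocity (0.5 ms at 400 mm/s)."""
        params = mf.SimulationParams(p_fwd=1.0, p_bwd=0.0,
                                     burst_rate_target=0.0,
                                     background_rate=0.0, seed=9)
        spikes, truth = mf.simulate_recording(params, layout, 300.0)
        ch = 1
        trains = [spikes.spikes[eid] for eid in layout.channel_ids(ch)]
        all_ev = np.sort(np.concatenate(
            [v for (_, c), v in truth.relay_events.items() if c == ch]))
        checked = 0
        for t in all_ev:
            others = all_ev[all_ev != t]
            if others.size and np.min(np.abs(others - t)) < 0.005:
                continue  # skip events too close to a neighbour
            hits = [tr[np.argmin(np.abs(tr - t))] for tr in trains]
            assert hits[0] < hits[1] < hits[2]
            np.testing.assert_allclose(np.diff(hits), 200.0 / 400e3,
                                       atol=1e-9)
            checked += 1
            if checked >= 10:
                break
        assert checked >= 5

    def test_overlapping_rate_rejected(self, layout):
        params = mf.SimulationParams(burst_rate_source=200.0)
        with pytest.raises(ValueError, match="overlap"):
            mf.simulate_recording(params, layout, 60.0)

    def test_probability_validation(self):
        with pytest.raises(ValueError):
            mf.SimulationParams(p_fwd=1.5)


class TestSimulateRawTrace:
    def test_silent_noiseless_trace_is_zero(self):
        params = mf.SimulationParams(noise_sigma_uv=0.0, seed=0)
        trace = mf.simulate_raw_trace([], params, 0.1)
        assert trace.shape == (2000,)
        assert np.all(trace == 0.0)

    def test_single_spike_extremum_at_plant(self):
        params = mf.SimulationParams(noise_sigma_uv=0.0, seed=0)
        trace = mf.simulate_raw_trace([0.5], params, 1.0)
        t_ext = np.argmin(trace) / params.sample_rate
        assert abs(t_ext - 0.5) <= 1e-3
        assert trace.min() == pytest.approx(-params.spike_amplitude_uv, rel=0.05)

    def test_close_spikes_sum(self):
        params = mf.SimulationParams(noise_sigma_uv=0.0, seed=0)
        single = mf.simulate_raw_trace([0.5], params, 1.0)
        double = mf.simulate_raw_trace([0.5, 0.5], params, 1.0)
        np.testing.assert_allclose(double, 2 * single)

    def test_out_of_range_plants_rejected(self):
        params = mf.SimulationParams(seed=0)
        with pytest.raises(ValueError):
            mf.simulate_raw_trace([2.0], params, 1.0)

    def test_waveform_is_biphasic_about_1ms(self):
        w, peak = spike_waveform(20_000.0, 40.0)
        assert 15 <= w.size <= 25          # ~1 ms support at 20 kHz
        assert w.min() == -40.0
        assert w.max() > 0                 # positive rebound


class TestTipTrajectories:
    def test_forward_traversal_time(self):
        geom = mf.ChannelGeometry()
        tracks = mf.simulate_tip_trajectories(
            geom, 1, 0, GrowthSimParams(forward_speed_um_h=10.0))
        (fwd,) = tracks
        assert fwd.t_h[-1] == pytest.approx(60.0)  # 600 um at 10 um/h
        assert fwd.x_um[-1] == pytest.approx(600.0)

    def test_backward_halt_sets_max_growth(self):
        geom = mf.ChannelGeometry()
        tracks = mf.simulate_tip_trajectories(
            geom, 0, 1, GrowthSimParams(backward_stop_frac=0.45))
        (bwd,) = tracks
        assert mf.max_backward_growth(bwd, 600.0) == pytest.approx(45.0)

    def test_configured_crossing_position_recovered(self):
        geom = mf.ChannelGeometry()
        params = GrowthSimParams(forward_speed_um_h=10.0,
                                 backward_speed_um_h=6.0,
                                 backward_stop_frac=0.8,
                                 crossing_frac=2 / 3)
        fwd, bwd = mf.simulate_tip_trajectories(geom, 1, 1, params)
        mp = mf.meeting_point(fwd, bwd, 600.0)
        # crossing at 400 um from Start = 200/600 from the End junction
        assert mp == pytest.approx(100.0 * 200.0 / 600.0, abs=1e-6)

    def test_unreachable_crossing_rejected(self):
        geom = mf.ChannelGeometry()
        with pytest.raises(ValueError, match="crossing"):
            mf.simulate_tip_trajectories(
                geom, 1, 1,
                GrowthSimParams(forward_speed_um_h=100.0,
                                backward_speed_um_h=1.0,
                                crossing_frac=0.9))
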