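"""Synthetic two-chamber recordings with known ground truth.

The generator emulates the spontaneous activity regime of two cultured
networks coupled by eight microchannels:

* each chamber emits network bursts as a Poisson process (per-minute rate),
  burst envelopes lasting 100-200 ms;
* a source burst evokes a target burst with probability ``p_fwd`` after a
  delay drawn from a normal distribution (mean 130 ms, SD 80 ms, matching
  the reported 129 +- 83 ms) truncated to (0, max_lag); backward
  propagation happens with the weaker probability ``p_bwd``;
* within a burst every chamber electrode fires as an inhomogeneous
  Poisson process under a half-sine envelope;
* during every propagating burst the microchannel electrodes relay
  axonal spikes with rank-ordered offsets set by the conduction velocity
  (400 mm/s default, after the measured 398 +- 98.8 mm/s);
* independent background spikes are superposed on all electrodes.

When a sampled delay exceeds the initiator's envelope the initiator is
kept spiking until the response begins (plus a 20 ms margin), so that
every generated propagation link satisfies the burst-overlap matching
rule and the ground truth is recoverable by the analysis.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .growth import TipTrajectory
from .model import Burst, Chamber, ChannelGeometry, MEALayout, Region, SpikeTrainSet

_OVERLAP_MARGIN_S = 0.08   # initiator keeps spiking this long past the response onset
_RELAY_GUARD_S = 0.002     # relay events end before the initiator envelope does


@dataclass
class SimulationParams:
    """Generator settings; defaults are the emulated study conditions."""

    burst_rate_source: float = 6.0    # bursts/min
    burst_rate_target: float = 6.0    # bursts/min
    burst_duration_ms: Tuple[float, float] = (100.0, 200.0)
    p_fwd: float = 0.6
    p_bwd: float = 0.1
    delay_mean_ms: float = 130.0
    delay_sd_ms: float = 80.0
    max_lag_ms: float = 500.0         # delay truncation = matching window
    within_burst_rate: float = 50.0   # spikes/s per chamber electrode
    background_rate: float = 0.2      # spikes/s per electrode
    channel_velocity_mm_s: float = 400.0
    relay_rate: float = 50.0          # axonal relay events/s during a link
    noise_sigma_uv: float = 3.0
    spike_amplitude_uv: float = 40.0
    sample_rate: float = 20_000.0
    # quiescent interval separating bursts within a chamber, as observed
    # between network bursts in culture; keeps distinct bursts resolvable
    min_interburst_gap_s: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_fwd <= 1.0 and 0.0 <= self.p_bwd <= 1.0):
            raise ValueError("propagation probabilities must lie in [0, 1]")
        for name in ("burst_rate_source", "burst_rate_target",
                     "within_burst_rate", "background_rate", "relay_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.burst_duration_ms
        if not (0 < lo <= hi):
            raise ValueError("burst_duration_ms must be an increasing positive range")
        if self.delay_sd_ms <= 0 or self.max_lag_ms <= 0:
            raise ValueError("delay_sd_ms and max_lag_ms must be positive")

    def delay_distribution(self) -> stats.rv_continuous:
        """The truncated-normal link-delay law on (0, max_lag), seconds."""
        mu = self.delay_mean_ms / 1e3
        sd = self.delay_sd_ms / 1e3
        hi = self.max_lag_ms / 1e3
        return stats.truncnorm((0.0 - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd)


@dataclass(frozen=True)
class PropagationLink:
    """A ground-truth evoked-burst relation."""

    direction: str        # "S_to_T" | "T_to_S"
    initiator_index: int  # index into the initiator chamber's burst list
    responder_index: int  # index into the responder chamber's burst list
    delay: float          # s, responder onset - initiator onset


@dataclass
class GroundTruth:
    source_bursts: List[Burst]
    target_bursts: List[Burst]
    links: List[PropagationLink]
    # per (link order, channel_index) -> relay event entry times (s)
    relay_events: Dict[Tuple[int, int], np.ndarray] = field(default_factory=dict)

    @property
    def forward_links(self) -> List[PropagationLink]:
        return [l for l in self.links if l.direction == "S_to_T"]

    @property
    def backward_links(self) -> List[PropagationLink]:
        return [l for l in self.links if l.direction == "T_to_S"]


class _Timeline:
    """Sorted burst intervals of one chamber, kept ``gap`` seconds apart."""

    def __init__(self, duration: float, gap: float = 0.0):
        self.duration = duration
        self.gap = gap
        self.records: List[dict] = []   # {"onset", "offset", "uid"}
        self._onsets: List[float] = []

    def can_place(self, onset: float, offset: float) -> bool:
        if onset < 0 or offset > self.duration:
            return False
        k = bisect.bisect_left(self._onsets, onset)
        if k > 0 and self.records[k - 1]["offset"] + self.gap > onset:
            return False
        if k < len(self.records) and self.records[k]["onset"] < offset + self.gap:
            return False
        return True

    def can_extend(self, uid: int, new_offset: float) -> bool:
        k = next(i for i, r in enumerate(self.records) if r["uid"] == uid)
        if new_offset > self.duration:
            return False
        if (k + 1 < len(self.records)
                and self.records[k + 1]["onset"] < new_offset + self.gap):
            return False
        return True

    def extend(self, uid: int, new_offset: float) -> None:
        for r in self.records:
            if r["uid"] == uid:
                r["offset"] = max(r["offset"], new_offset)
                return
        raise KeyError(uid)

    def add(self, onset: float, offset: float, uid: int) -> None:
        k = bisect.bisect_left(self._onsets, onset)
        self.records.insert(
            k, {"onset": onset, "offset": offset,
                "nominal_offset": offset, "uid": uid})
        self._onsets.insert(k, onset)


def _spontaneous_onsets(rate_per_min: float, duration: float,
                        rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(rate_per_min / 60.0 * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def _burst_spike_times(onset: float, dur: float, n_electrodes: int,
                       rate: float, rng: np.random.Generator) -> List[np.ndarray]:
    """Half-sine inhomogeneous-Poisson spikes for each chamber electrode."""
    out = []
    for _ in range(n_electrodes):
        n = rng.poisson(rate * dur)
        u = rng.uniform(0.0, 1.0, size=n)
        t = onset + dur / math.pi * np.arccos(1.0 - 2.0 * u)
        out.append(np.sort(t))
    return out


def simulate_recording(
    params: SimulationParams,
    layout: MEALayout,
    duration: float,
    seed: Optional[int] = None,
) -> Tuple[SpikeTrainSet, GroundTruth]:
    """Simulate a two-chamber recording of ``duration`` seconds.

    Returns the spike trains plus the generating ground truth (burst
    windows, propagation links, channel relay events).  Identical seeds
    give bit-identical event lists.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    max_dur = params.burst_duration_ms[1] / 1e3 + params.max_lag_ms / 1e3
    for rate in (params.burst_rate_source, params.burst_rate_target):
        if rate / 60.0 * max_dur > 0.5:
            raise ValueError(
                "burst rate so high that bursts would permanently overlap"
            )
    rng = np.random.default_rng(params.seed if seed is None else seed)
    lo_dur, hi_dur = (d / 1e3 for d in params.burst_duration_ms)
    delay_law = params.delay_distribution()

    gap = params.min_interburst_gap_s
    timelines = {Chamber.SOURCE: _Timeline(duration, gap),
                 Chamber.TARGET: _Timeline(duration, gap)}
    spont: Dict[Chamber, List[int]] = {Chamber.SOURCE: [], Chamber.TARGET: []}
    uid = 0
    # spontaneous bursts stay clear of the recording tail so an evoked
    # response (delay up to max_lag) never runs past the end
    tail = (params.burst_duration_ms[1] + params.max_lag_ms) / 1e3 \
        + _OVERLAP_MARGIN_S + 0.01
    horizon = max(duration - tail, 0.0)
    for chamber, rate in ((Chamber.SOURCE, params.burst_rate_source),
                          (Chamber.TARGET, params.burst_rate_target)):
        for onset in _spontaneous_onsets(rate, horizon, rng):
            dur = rng.uniform(lo_dur, hi_dur)
            if timelines[chamber].can_place(onset, onset + dur):
                timelines[chamber].add(onset, onset + dur, uid)
                spont[chamber].append(uid)
                uid += 1

    # propagation links: spontaneous bursts evoke a response in the other
    # chamber; the initiator envelope is stretched when the delay outlasts it
    links_raw: List[Tuple[str, int, int, float]] = []
    for chamber, p in ((Chamber.SOURCE, params.p_fwd),
                       (Chamber.TARGET, params.p_bwd)):
        other = chamber.other
        for init_uid in spont[chamber]:
            if rng.uniform() >= p:
                continue
            delay = float(delay_law.rvs(random_state=rng))
            rec = next(r for r in timelines[chamber].records
                       if r["uid"] == init_uid)
            resp_onset = rec["onset"] + delay
            resp_dur = rng.uniform(lo_dur, hi_dur)
            need_offset = max(rec["offset"], resp_onset + _OVERLAP_MARGIN_S)
            if not timelines[chamber].can_extend(init_uid, need_offset):
                continue
            if not timelines[other].can_place(resp_onset, resp_onset + resp_dur):
                continue
            timelines[chamber].extend(init_uid, need_offset)
            timelines[other].add(resp_onset, resp_onset + resp_dur, uid)
            direction = "S_to_T" if chamber is Chamber.SOURCE else "T_to_S"
            links_raw.append((direction, init_uid, uid, delay))
            uid += 1

    # chamber spikes
    region_of = {Chamber.SOURCE: Region.SOURCE, Chamber.TARGET: Region.TARGET}
    spikes: Dict[str, List[np.ndarray]] = {
        eid: [] for eid in layout.electrode_ids
    }
    bursts: Dict[Chamber, List[Burst]] = {}
    index_of_uid: Dict[int, Tuple[Chamber, int]] = {}
    for chamber in (Chamber.SOURCE, Chamber.TARGET):
        ids = layout.region_ids(region_of[chamber])
        blist: List[Burst] = []
        for k, rec in enumerate(timelines[chamber].records):
            env_dur = rec["nominal_offset"] - rec["onset"]
            per_elec = _burst_spike_times(
                rec["onset"], env_dur, len(ids), params.within_burst_rate, rng
            )
            # a stretched initiator keeps spiking at a flat rate until the
            # response has begun, so the burst-overlap rule stays satisfiable
            sustain = rec["offset"] - rec["nominal_offset"]
            if sustain > 0:
                for m in range(len(per_elec)):
                    n_extra = rng.poisson(params.within_burst_rate * sustain)
                    extra = rng.uniform(rec["nominal_offset"], rec["offset"],
                                        size=n_extra)
                    per_elec[m] = np.sort(
                        np.concatenate([per_elec[m], extra]))
            n_spikes = sum(t.size for t in per_elec)
            n_active = sum(1 for t in per_elec if t.size)
            for eid, t in zip(ids, per_elec):
                spikes[eid].append(t)
            blist.append(Burst(onset=rec["onset"], offset=rec["offset"],
                               chamber=chamber, n_spikes=int(n_spikes),
                               n_electrodes=int(n_active)))
            index_of_uid[rec["uid"]] = (chamber, k)
        bursts[chamber] = blist

    links: List[PropagationLink] = []
    for direction, init_uid, resp_uid, delay in links_raw:
        _, i = index_of_uid[init_uid]
        _, j = index_of_uid[resp_uid]
        links.append(PropagationLink(direction, i, j, delay))
    links.sort(key=lambda l: (
        bursts[Chamber.SOURCE if l.direction == "S_to_T" else Chamber.TARGET]
        [l.initiator_index].onset))

    # microchannel relays: axonal spikes with rank-ordered conduction offsets
    relay_events: Dict[Tuple[int, int], np.ndarray] = {}
    v_um_s = params.channel_velocity_mm_s * 1e3
    chan_len = 600.0
    for li, link in enumerate(links):
        init_chamber = (Chamber.SOURCE if link.direction == "S_to_T"
                        else Chamber.TARGET)
        init = bursts[init_chamber][link.initiator_index]
        t_hi = init.offset - _RELAY_GUARD_S
        if t_hi <= init.onset:
            t_hi = init.offset
        for ch in layout.channel_indices:
            n_ev = max(1, rng.poisson(params.relay_rate * init.duration))
            t0 = np.sort(rng.uniform(init.onset, t_hi, size=n_ev))
            relay_events[(li, ch)] = t0
            for eid in layout.channel_ids(ch):
                e = layout[eid]
                x = 100.0 + 200.0 * (e.channel_rank - 1)   # um from Start
                dist = x if link.direction == "S_to_T" else chan_len - x
                spikes[eid].append(t0 + dist / v_um_s)

    # background spikes on every electrode
    if params.background_rate > 0:
        for eid in layout.electrode_ids:
            n = rng.poisson(params.background_rate * duration)
            spikes[eid].append(rng.uniform(0.0, duration, size=n))

    merged = {}
    for eid, parts in spikes.items():
        t = np.concatenate(parts) if parts else np.array([])
        t = t[(t >= 0.0) & (t <= duration)]
        merged[eid] = np.sort(t)

    trains = SpikeTrainSet(merged, duration=duration, layout=layout,
                           sample_rate=params.sample_rate)
    truth = GroundTruth(
        source_bursts=bursts[Chamber.SOURCE],
        target_bursts=bursts[Chamber.TARGET],
        links=links,
        relay_events=relay_events,
    )
    return trains, truth


# ---------------------------------------------------------------------------
# raw-trace synthesis (fixture for the spike detector)

def spike_waveform(sample_rate: float, amplitude: float) -> Tuple[np.ndarray, int]:
    """Stereotyped ~1 ms biphasic extracellular waveform.

    Negative lobe of 0.4 ms (amplitude ``-amplitude``) followed by a
    positive rebound of 0.6 ms at 35% amplitude.  Returns the sampled
    waveform and the index of its negative peak (the spike timestamp).
    """
    n_neg = max(2, int(round(0.4e-3 * sample_rate)))
    n_pos = max(2, int(round(0.6e-3 * sample_rate)))
    neg = -amplitude * np.sin(np.pi * np.arange(n_neg) / n_neg)
    pos = 0.35 * amplitude * np.sin(np.pi * np.arange(n_pos) / n_pos)
    w = np.concatenate([neg, pos])
    return w, int(np.argmin(w))


def simulate_raw_trace(
    spike_times: Sequence[float],
    params: SimulationParams,
    duration: float,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Gaussian noise plus a biphasic waveform at each planted time (uV).

    The waveform's negative peak lands on the planted timestamp; waveforms
    of spikes closer than the ~1 ms support simply sum.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size and (spike_times.min() < 0 or spike_times.max() > duration):
        raise ValueError("spike_times must lie within [0, duration]")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = int(round(duration * params.sample_rate))
    trace = (rng.normal(0.0, params.noise_sigma_uv, size=n)
             if params.noise_sigma_uv > 0 else np.zeros(n))
    w, peak = spike_waveform(params.sample_rate, params.spike_amplitude_uv)
    for t in spike_times:
        start = int(round(t * params.sample_rate)) - peak
        a = max(start, 0)
        b = min(start + w.size, n)
        if b > a:
            trace[a:b] += w[a - start:b - start]
    return trace


# ---------------------------------------------------------------------------
# neurite-tip trajectories

@dataclass
class GrowthSimParams:
    """Piecewise-linear tip-path generator settings.

    Speeds are micrometres per hour on the scale of channels filling over
    a few days; the backward tip halts ``backward_stop_frac`` of the
    channel length away from the End junction.  ``crossing_frac``
    (fraction of the channel length from the Start junction) optionally
    pins the position where forward and backward tips meet by delaying
    the backward track's entry.
    """

    forward_speed_um_h: float = 10.0
    backward_speed_um_h: float = 6.0
    backward_stop_frac: float = 0.46
    crossing_frac: Optional[float] = None
    dt_h: float = 1.0 / 3.0  # 20-min imaging interval
    seed: int = 0


def _sampled_line(t0: float, t1: float, x0: float, x1: float,
                  dt: float) -> Tuple[np.ndarray, np.ndarray]:
    n = max(1, int(math.ceil((t1 - t0) / dt)))
    t = t0 + np.arange(n + 1) * dt
    t[-1] = t1
    x = x0 + (x1 - x0) * (t - t0) / (t1 - t0)
    return t, x


def simulate_tip_trajectories(
    geometry: ChannelGeometry,
    n_forward: int,
    n_backward: int,
    params: GrowthSimParams,
) -> List[TipTrajectory]:
    """Generate forward (Start->End) and backward (End->halt) tip paths."""
    if n_forward < 0 or n_backward < 0:
        raise ValueError("track counts must be >= 0")
    L = geometry.total_length_um
    v_f = params.forward_speed_um_h
    v_b = params.backward_speed_um_h
    tracks: List[TipTrajectory] = []

    t_end_f = L / v_f
    for k in range(n_forward):
        t, x = _sampled_line(0.0, t_end_f, 0.0, L, params.dt_h)
        tracks.append(TipTrajectory(f"fwd{k:02d}", "forward", t, x))

    x_stop = L * (1.0 - params.backward_stop_frac)
    if params.crossing_frac is not None:
        x_c = params.crossing_frac * L
        t_star = x_c / v_f
        t0_b = t_star - (L - x_c) / v_b
        if t0_b < 0:
            raise ValueError(
                "crossing_frac unreachable: backward track would need to "
                "start before t=0 at these speeds"
            )
    else:
        t0_b = 0.0
    t_end_b = t0_b + (L - x_stop) / v_b
    for k in range(n_backward):
        t, x = _sampled_line(t0_b, t_end_b, L, x_stop, params.dt_h)
        # hold at the stop point so the track coexists with late forward growth
        t = np.append(t, t[-1] + params.dt_h)
        x = np.append(x, x_stop)
        tracks.append(TipTrajectory(f"bwd{k:02d}", "backward", t, x))
    return tracks
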