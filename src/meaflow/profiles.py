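"""Firing-rate profiles, spatial activity maps and microchannel
conduction velocity.

Profiles are peri-burst time histograms: spikes of each electrode group
(source chamber, microchannels, target chamber) are binned relative to
burst onsets and averaged over bursts (20 ms bins by default).  Spatial
maps place per-electrode counts on the 8x8 grid in 5 ms frames.  The
conduction velocity through a microchannel is estimated from single
spikes relayed across its three rank-ordered electrodes (200 um pitch):
spikes are chained when successive lags fall in ``(0, match_window]`` and
each chain's velocity is the least-squares slope of electrode position
against spike time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import Burst, GRID_PITCH_UM, MEALayout, Region, SpikeTrainSet

GROUPS = {
    "source": Region.SOURCE,
    "channels": Region.CHANNEL,
    "target": Region.TARGET,
}


@dataclass
class RateProfile:
    group: str
    bin_ms: float
    t_axis_ms: np.ndarray    # bin centres relative to burst onset
    mean_rate: np.ndarray    # spikes per bin, averaged over bursts
    n_bursts: int


@dataclass
class SpatialFrames:
    frames: np.ndarray       # (n_frames, 8, 8) spike counts
    bin_ms: float
    t0: float                # s, start of the first frame


@dataclass
class VelocityEstimate:
    channel_index: int
    n_events: int            # forward chains used
    velocity_mean: float     # mm/s, nan when insufficient
    velocity_sd: float       # mm/s
    n_backward: int = 0
    velocities: List[float] = field(default_factory=list)
    insufficient: bool = False


def firing_rate_profile(
    spikes: SpikeTrainSet,
    bursts: Sequence[Burst],
    layout: MEALayout,
    bin_ms: float = 20.0,
    window_ms: Tuple[float, float] = (-100.0, 500.0),
) -> Dict[str, RateProfile]:
    """Burst-onset-aligned average firing rate per electrode group."""
    if not bursts:
        raise ValueError("at least one burst is required")
    w0, w1 = (w / 1e3 for w in window_ms)
    bin_s = bin_ms / 1e3
    n_bins = int(round((w1 - w0) / bin_s))
    edges = w0 + bin_s * np.arange(n_bins + 1)
    centres_ms = (edges[:-1] + edges[1:]) / 2 * 1e3

    out: Dict[str, RateProfile] = {}
    for name, region in GROUPS.items():
        pooled = spikes.region_spikes(region)
        acc = np.zeros(n_bins)
        for b in bursts:
            rel = pooled[np.searchsorted(pooled, b.onset + w0):
                         np.searchsorted(pooled, b.onset + w1)] - b.onset
            counts, _ = np.histogram(rel, bins=edges)
            acc += counts
        out[name] = RateProfile(
            group=name, bin_ms=bin_ms, t_axis_ms=centres_ms,
            mean_rate=acc / len(bursts), n_bursts=len(bursts),
        )
    return out


def spatial_map(
    spikes: SpikeTrainSet,
    layout: MEALayout,
    t0: float,
    t1: float,
    bin_ms: float = 5.0,
) -> SpatialFrames:
    """Per-5-ms 8x8 spike-count frames over ``[t0, t1)``.

    Grid cells with no electrode (the four corners) stay zero in every
    frame.
    """
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    bin_s = bin_ms / 1e3
    n_frames = int(np.ceil((t1 - t0) / bin_s - 1e-9))
    frames = np.zeros((n_frames, 8, 8))
    edges = t0 + bin_s * np.arange(n_frames + 1)
    for eid in layout.electrode_ids:
        t = spikes.spikes[eid]
        seg = t[(t >= t0) & (t < t1)]
        if seg.size == 0:
            continue
        row, col = layout.grid_position(eid)
        counts, _ = np.histogram(seg, bins=edges)
        frames[:, row, col] += counts
    return SpatialFrames(frames=frames, bin_ms=bin_ms, t0=t0)


def _chain_events(
    trains: List[np.ndarray],
    match_window: float,
) -> List[List[float]]:
    """Greedily chain one spike per electrode with lags in (0, window]."""
    used = [np.zeros(t.size, dtype=bool) for t in trains]
    chains: List[List[float]] = []
    first = trains[0]
    for i0, t_prev in enumerate(first):
        if used[0][i0]:
            continue
        chain = [float(t_prev)]
        ok = True
        prev = t_prev
        picks = [(0, i0)]
        for r in range(1, len(trains)):
            t = trains[r]
            k = int(np.searchsorted(t, prev, side="right"))
            while k < t.size and used[r][k]:
                k += 1
            if k >= t.size or t[k] - prev > match_window or t[k] <= prev:
                ok = False
                break
            chain.append(float(t[k]))
            picks.append((r, k))
            prev = t[k]
        if ok:
            for r, k in picks:
                used[r][k] = True
            chains.append(chain)
    return chains


def channel_velocity(
    spikes: SpikeTrainSet,
    layout: MEALayout,
    channel_index: int,
    match_window_ms: float = 2.0,
    pitch_um: float = GRID_PITCH_UM,
) -> VelocityEstimate:
    """Spike conduction velocity through one microchannel (mm/s).

    Forward chains run rank 1 -> rank 3 with strictly increasing times;
    reversed-order chains are counted separately as backward events.  At
    least two forward chains are needed for a mean +- SD; otherwise the
    estimate is flagged insufficient.
    """
    ids = layout.channel_ids(channel_index)
    if len(ids) < 2:
        raise ValueError(f"channel {channel_index} has fewer than 2 electrodes")
    trains = [spikes.spikes[eid] for eid in ids]
    w = match_window_ms / 1e3
    positions = pitch_um * np.arange(1, len(ids) + 1)  # rank * pitch

    fwd = _chain_events(trains, w)
    bwd = _chain_events(trains[::-1], w)

    velocities: List[float] = []
    for chain in fwd:
        slope, _ = np.polyfit(np.asarray(chain), positions, 1)  # um/s
        velocities.append(slope / 1e3)  # -> mm/s
    insufficient = len(velocities) < 2
    if velocities:
        mean = float(np.mean(velocities))
        sd = float(np.std(velocities, ddof=1)) if len(velocities) > 1 else 0.0
    else:
        mean = sd = float("nan")
    return VelocityEstimate(
        channel_index=channel_index,
        n_events=len(fwd),
        velocity_mean=mean,
        velocity_sd=sd,
        n_backward=len(bwd),
        velocities=velocities,
        insufficient=insufficient,
    )
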