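"""Chamber-level network-burst detection on pooled spike trains.

Spikes of all electrodes of a chamber are pooled into a binned population
rate (50 ms bins by default).  A burst is a maximal run of bins at or
above a rate threshold, extended to the first and last spike inside the
run, merged with its neighbour when the gap between them is shorter than
``merge_gap``, and discarded when it holds fewer than ``min_spikes``
spikes.  The burst onset — the reference point for all propagation
delays — is the time of the first spike of the burst.

The default threshold adapts to the recording: ``max(10 spikes/bin,
5 x median bin count)``.  The median over all bins tracks the background
rate (it is 0 for silent backgrounds, where the 10-spike floor applies)
while staying far below within-burst bin counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .model import (
    Burst,
    BurstConfig,
    Chamber,
    Region,
    SpikeTrainSet,
)


@dataclass
class RateSeries:
    """Binned population spike counts of one region."""

    bin_edges: np.ndarray  # s, len = n_bins + 1
    counts: np.ndarray     # spikes per bin, pooled over the region

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def population_rate(
    spikes: SpikeTrainSet,
    region: Region | str,
    bin_ms: float = 50.0,
) -> RateSeries:
    """Histogram of all spikes on the region's electrodes."""
    if bin_ms <= 0:
        raise ValueError("bin width must be positive")
    pooled = spikes.region_spikes(region)  # raises if region empty
    bin_s = bin_ms / 1e3
    n_bins = max(1, int(np.ceil(spikes.duration / bin_s)))
    edges = bin_s * np.arange(n_bins + 1)
    counts, _ = np.histogram(pooled, bins=edges)
    return RateSeries(bin_edges=edges, counts=counts)


def detect_bursts(
    spikes: SpikeTrainSet,
    region: Region | str,
    cfg: BurstConfig | None = None,
) -> List[Burst]:
    """Detect network bursts in one chamber; returns sorted disjoint bursts."""
    cfg = cfg or BurstConfig()
    region = Region(region)
    chamber = Chamber.SOURCE if region is Region.SOURCE else Chamber.TARGET
    series = population_rate(spikes, region, cfg.bin_ms)
    counts = series.counts
    if cfg.rate_threshold is None:
        threshold = max(10.0, 5.0 * float(np.median(counts)))
    else:
        threshold = float(cfg.rate_threshold)

    ids = spikes.layout.region_ids(region)
    pooled = spikes.region_spikes(region)
    if pooled.size == 0:
        return []

    hot = counts >= threshold
    # maximal supra-threshold runs -> candidate [t0, t1) windows
    edges = series.bin_edges
    runs: List[tuple] = []
    k = 0
    while k < hot.size:
        if hot[k]:
            j = k
            while j + 1 < hot.size and hot[j + 1]:
                j += 1
            runs.append((edges[k], edges[j + 1]))
            k = j + 1
        else:
            k += 1

    # extend each run to the first/last spike inside it
    extended: List[tuple] = []
    for t0, t1 in runs:
        a = np.searchsorted(pooled, t0, side="left")
        b = np.searchsorted(pooled, t1, side="left")
        if b <= a:
            continue
        extended.append((pooled[a], pooled[b - 1]))

    # merge neighbouring bursts separated by less than merge_gap
    gap_s = cfg.merge_gap_ms / 1e3
    merged: List[list] = []
    for on, off in extended:
        if merged and on - merged[-1][1] < gap_s:
            merged[-1][1] = off
        else:
            merged.append([on, off])

    out: List[Burst] = []
    for on, off in merged:
        a = np.searchsorted(pooled, on, side="left")
        b = np.searchsorted(pooled, off, side="right")
        n_spikes = int(b - a)
        if n_spikes < cfg.min_spikes:
            continue
        n_active = sum(
            1 for eid in ids
            if np.searchsorted(spikes.spikes[eid], off, side="right")
            > np.searchsorted(spikes.spikes[eid], on, side="left")
        )
        off_excl = off if off > on else on + 1.0 / spikes.sample_rate
        out.append(Burst(onset=float(on), offset=float(off_excl),
                         chamber=chamber, n_spikes=n_spikes,
                         n_electrodes=n_active))
    return out


def burst_rate(bursts: Sequence[Burst], duration: float) -> float:
    """Bursts per minute over a recording of ``duration`` seconds."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return len(bursts) / duration * 60.0
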