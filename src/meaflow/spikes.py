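"""Threshold spike detection with the median-based noise estimate.

The noise level of an extracellular trace is estimated robustly as
``sigma = median(|x|) / 0.6745`` — the median absolute deviation of a
zero-mean Gaussian rescaled to its standard deviation, insensitive to the
spikes themselves.  Spikes are threshold crossings of ``k * sigma``
(negative polarity by default), time-stamped at the waveform extremum
within 1 ms of the crossing, with a refractory ``dead_time`` suppressing
secondary crossings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

MAD_SCALE = 0.6745  # Phi^-1(0.75): MAD -> sigma for Gaussian noise


@dataclass
class DetectionResult:
    electrode_id: str
    timestamps: np.ndarray  # s
    threshold: float        # uV
    sigma: float            # uV


def estimate_noise_sigma(trace: np.ndarray) -> float:
    """Median-based noise standard deviation, ``median(|x|)/0.6745``."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("trace is empty")
    return float(np.median(np.abs(trace)) / MAD_SCALE)


def _crossing_events(
    below: np.ndarray,
    trace: np.ndarray,
    sample_rate: float,
    find_min: bool,
) -> List[int]:
    """Sample index of the local extremum for every threshold crossing."""
    idx = np.flatnonzero(below)
    if idx.size == 0:
        return []
    starts = idx[np.concatenate(([True], np.diff(idx) > 1))]
    half = int(round(1e-3 * sample_rate))  # extremum search: +-1 ms
    events = []
    for s in starts:
        a = max(s - half, 0)
        b = min(s + half + 1, trace.size)
        seg = trace[a:b]
        k = int(np.argmin(seg) if find_min else np.argmax(seg))
        events.append(a + k)
    return events


def detect_spikes(
    trace: np.ndarray,
    sample_rate: float,
    k: float = 8.0,
    dead_time_ms: float = 1.0,
    polarity: str = "neg",
    center_median: bool = False,
    electrode_id: str = "",
) -> DetectionResult:
    """Detect spikes as ``+-k*sigma`` threshold crossings.

    Parameters
    ----------
    trace
        Sampled voltage in microvolts.
    sample_rate
        Samples per second.
    k
        Threshold multiplier on the median-based noise sigma (default 8).
    dead_time_ms
        Refractory interval; crossings within it after an accepted event
        are suppressed.
    polarity
        ``"neg"`` (default), ``"pos"`` or ``"both"``.
    center_median
        Subtract the trace median first, making detection invariant to a
        constant offset.
    """
    if k <= 0 or sample_rate <= 0:
        raise ValueError("k and sample_rate must be positive")
    if polarity not in ("neg", "pos", "both"):
        raise ValueError(f"unknown polarity {polarity!r}")
    trace = np.asarray(trace, dtype=float)
    if center_median:
        trace = trace - np.median(trace)
    sigma = estimate_noise_sigma(trace)
    if sigma == 0.0:
        raise ValueError("degenerate noise estimate (sigma = 0)")
    threshold = k * sigma

    events: List[int] = []
    if polarity in ("neg", "both"):
        events += _crossing_events(trace < -threshold, trace, sample_rate, True)
    if polarity in ("pos", "both"):
        events += _crossing_events(trace > threshold, trace, sample_rate, False)
    events.sort()

    dead = dead_time_ms / 1e3
    accepted: List[float] = []
    last = -np.inf
    for e in events:
        t = e / sample_rate
        if t - last >= dead:
            accepted.append(t)
            last = t
    return DetectionResult(
        electrode_id=electrode_id,
        timestamps=np.asarray(accepted),
        threshold=threshold,
        sigma=sigma,
    )
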