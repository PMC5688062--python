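"""Inter-chamber burst propagation: matching, probabilities, surrogate null.

A burst in one chamber is considered propagated to the other when two
conditions hold simultaneously:

1. the two burst onsets differ by at most ``max_lag`` (default 0.5 s), and
2. the later burst starts no later than the earlier one ends, i.e. the
   initiator is still spiking when the response begins.

Matched pairs are directional: a positive delay ``onset(target) -
onset(source)`` is a forward (source-to-target) propagation, a negative
delay a backward one.  The forward propagation probability ``PP_S-T`` is
the fraction of source-chamber bursts with a forward match; ``PP_T-S`` is
the fraction of target-chamber bursts with a backward match; their ratio
is the directional propagation index (DPI).

Matching is one-to-one per role: each burst initiates at most one response
and responds to at most one initiator, so a burst evoked from the opposite
chamber may itself evoke the next burst (a relay chain), but no burst has
two causes and no burst causes two responses in the same direction.
Conflicts are resolved greedily in order of increasing ``|delay|``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import Burst, Chamber, PropagationConfig


@dataclass(frozen=True)
class MatchedBurstPair:
    """One matched (source burst, target burst) pair."""

    source_index: int
    target_index: int
    source_burst: Burst
    target_burst: Burst
    delay: float  # s, onset(target) - onset(source)

    @property
    def direction(self) -> str:
        return "S_to_T" if self.delay > 0 else "T_to_S"

    @property
    def delay_ms(self) -> float:
        return self.delay * 1e3


@dataclass
class PropagationSummary:
    pp_st: float
    pp_ts: float
    dpi: float  # math.inf when pp_ts == 0
    n_source_bursts: int
    n_target_bursts: int
    n_forward: int
    n_backward: int
    delays_ms: List[float] = field(default_factory=list)  # forward delays
    delay_mean_ms: float = math.nan
    delay_sd_ms: float = math.nan

    def to_dict(self) -> dict:
        return {
            "pp_st": self.pp_st,
            "pp_ts": self.pp_ts,
            "dpi": "inf" if math.isinf(self.dpi) else self.dpi,
            "n_source_bursts": self.n_source_bursts,
            "n_target_bursts": self.n_target_bursts,
            "n_forward": self.n_forward,
            "n_backward": self.n_backward,
            "delay_mean_ms": None if math.isnan(self.delay_mean_ms) else self.delay_mean_ms,
            "delay_sd_ms": None if math.isnan(self.delay_sd_ms) else self.delay_sd_ms,
        }


@dataclass
class SurrogateNull:
    """Observed vs jitter-surrogate delay probabilities per delay bin."""

    delay_bin_edges_ms: np.ndarray
    p_observed: np.ndarray
    surr_mean: np.ndarray
    surr_sd: np.ndarray
    significant: np.ndarray  # boolean per bin
    n_surrogates: int
    sig_factor: float


def _candidate_pairs(
    source_onsets: np.ndarray,
    source_offsets: np.ndarray,
    target_onsets: np.ndarray,
    target_offsets: np.ndarray,
    max_lag: float,
) -> List[Tuple[float, int, int]]:
    """All (|delay|, i_source, j_target) satisfying both matching rules."""
    out: List[Tuple[float, int, int]] = []
    lo = np.searchsorted(source_onsets, target_onsets - max_lag, side="left")
    hi = np.searchsorted(source_onsets, target_onsets + max_lag, side="right")
    for j in range(target_onsets.size):
        for i in range(lo[j], hi[j]):
            delay = target_onsets[j] - source_onsets[i]
            if abs(delay) > max_lag:
                continue
            if delay >= 0:
                overlap = target_onsets[j] <= source_offsets[i]
            else:
                overlap = source_onsets[i] <= target_offsets[j]
            if overlap:
                out.append((abs(delay), i, j))
    return out


def _greedy_resolve(
    candidates: List[Tuple[float, int, int]],
    source_onsets: np.ndarray,
    target_onsets: np.ndarray,
) -> List[Tuple[int, int]]:
    """One-to-one-per-role greedy assignment, smallest |delay| first.

    Ties broken on the earlier onset then the later onset of the pair so
    that the result is invariant under swapping the chamber labels.
    """
    def key(c):
        adelay, i, j = c
        s, t = source_onsets[i], target_onsets[j]
        return (adelay, min(s, t), max(s, t))

    used_initiator: set = set()  # ("S", i) or ("T", j)
    used_responder: set = set()
    pairs: List[Tuple[int, int]] = []
    for adelay, i, j in sorted(candidates, key=key):
        delay = target_onsets[j] - source_onsets[i]
        if delay > 0:
            initiator, responder = ("S", i), ("T", j)
        else:
            initiator, responder = ("T", j), ("S", i)
        if initiator in used_initiator or responder in used_responder:
            continue
        used_initiator.add(initiator)
        used_responder.add(responder)
        pairs.append((i, j))
    return pairs


def match_bursts(
    source_bursts: Sequence[Burst],
    target_bursts: Sequence[Burst],
    max_lag: float = 0.5,
) -> List[MatchedBurstPair]:
    """Match bursts across chambers under the lag and overlap rules.

    Parameters
    ----------
    source_bursts, target_bursts
        Sorted, non-overlapping burst lists of the two chambers.
    max_lag
        Matching window in seconds (0.5 s = the +-500 ms rule).

    Returns
    -------
    Pairs sorted by source onset; ``delay > 0`` marks forward propagation.
    """
    s_on = np.array([b.onset for b in source_bursts], dtype=float)
    s_off = np.array([b.offset for b in source_bursts], dtype=float)
    t_on = np.array([b.onset for b in target_bursts], dtype=float)
    t_off = np.array([b.offset for b in target_bursts], dtype=float)
    cands = _candidate_pairs(s_on, s_off, t_on, t_off, max_lag)
    pairs = _greedy_resolve(cands, s_on, t_on)
    out = [
        MatchedBurstPair(
            source_index=i,
            target_index=j,
            source_burst=source_bursts[i],
            target_burst=target_bursts[j],
            delay=t_on[j] - s_on[i],
        )
        for i, j in pairs
    ]
    out.sort(key=lambda p: (p.source_burst.onset, p.target_burst.onset))
    return out


def match_bursts_bruteforce(
    source_bursts: Sequence[Burst],
    target_bursts: Sequence[Burst],
    max_lag: float = 0.5,
) -> List[Tuple[int, int]]:
    """Exhaustive O(n*m) reference matcher (oracle for tests).

    Enumerates every cross-chamber burst pair, filters on the two rules,
    then applies the same smallest-|delay|-first greedy assignment.
    Returns (source_index, target_index) pairs.
    """
    s_on = np.array([b.onset for b in source_bursts], dtype=float)
    t_on = np.array([b.onset for b in target_bursts], dtype=float)
    cands: List[Tuple[float, int, int]] = []
    for i, s in enumerate(source_bursts):
        for j, t in enumerate(target_bursts):
            delay = t.onset - s.onset
            if abs(delay) > max_lag:
                continue
            earlier, later = (s, t) if delay >= 0 else (t, s)
            if later.onset <= earlier.offset:
                cands.append((abs(delay), i, j))
    return sorted(_greedy_resolve(cands, s_on, t_on))


def propagation_probabilities(
    pairs: Sequence[MatchedBurstPair],
    n_source: int,
    n_target: int,
) -> PropagationSummary:
    """PP_S-T, PP_T-S and DPI from matched pairs and chamber burst totals."""
    if n_source <= 0:
        raise ValueError("n_source must be positive")
    if n_target <= 0:
        raise ValueError("n_target must be positive")
    forward = [p for p in pairs if p.delay > 0]
    backward = [p for p in pairs if p.delay < 0]
    pp_st = len(forward) / n_source
    pp_ts = len(backward) / n_target
    dpi = pp_st / pp_ts if pp_ts > 0 else math.inf
    delays_ms = [p.delay_ms for p in forward]
    if delays_ms:
        delay_mean = float(np.mean(delays_ms))
        delay_sd = float(np.std(delays_ms, ddof=1)) if len(delays_ms) > 1 else 0.0
    else:
        delay_mean = delay_sd = math.nan
    return PropagationSummary(
        pp_st=pp_st,
        pp_ts=pp_ts,
        dpi=dpi,
        n_source_bursts=n_source,
        n_target_bursts=n_target,
        n_forward=len(forward),
        n_backward=len(backward),
        delays_ms=delays_ms,
        delay_mean_ms=delay_mean,
        delay_sd_ms=delay_sd,
    )


def _delay_histogram(
    pairs: Sequence[MatchedBurstPair],
    edges_s: np.ndarray,
    n_target: int,
) -> np.ndarray:
    delays = np.array([p.delay for p in pairs], dtype=float)
    counts, _ = np.histogram(delays, bins=edges_s)
    return counts / max(n_target, 1)


def surrogate_test(
    source_bursts: Sequence[Burst],
    target_bursts: Sequence[Burst],
    cfg: PropagationConfig,
    seed: int,
    duration: Optional[float] = None,
) -> SurrogateNull:
    """Jitter-surrogate significance test for the observed delay histogram.

    Target burst onsets are jittered by U(-J, +J) (J =
    ``cfg.jitter_half_width_s``), durations preserved, the list re-sorted
    and re-matched; per-delay-bin match probabilities (matches per target
    burst) are accumulated over ``cfg.n_surrogates`` iterations.  A bin is
    significant when the observed probability exceeds the surrogate mean
    by ``sig_factor`` surrogate standard deviations (or, under the
    ``sd_only`` rule, exceeds ``sig_factor`` standard deviations outright).
    """
    if cfg.n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    if cfg.jitter_half_width_s <= 0:
        raise ValueError("jitter_half_width_s must be positive")
    max_lag = cfg.max_lag_ms / 1e3
    bin_s = cfg.delay_bin_ms / 1e3
    n_bins = int(round(2 * max_lag / bin_s))
    edges_s = -max_lag + bin_s * np.arange(n_bins + 1)

    n_target = len(target_bursts)
    observed = match_bursts(source_bursts, target_bursts, max_lag)
    p_obs = _delay_histogram(observed, edges_s, n_target)

    if duration is None:
        ends = [b.offset for b in list(source_bursts) + list(target_bursts)]
        duration = max(ends) if ends else 0.0

    rng = np.random.default_rng(seed)
    t_on = np.array([b.onset for b in target_bursts], dtype=float)
    t_dur = np.array([b.duration for b in target_bursts], dtype=float)
    acc = np.zeros((cfg.n_surrogates, n_bins))
    for it in range(cfg.n_surrogates):
        jitter = rng.uniform(-cfg.jitter_half_width_s,
                             cfg.jitter_half_width_s, size=t_on.size)
        on = t_on + jitter
        np.clip(on, 0.0, np.maximum(duration - t_dur, 0.0), out=on)
        order = np.argsort(on, kind="stable")
        surr = [
            Burst(onset=float(on[k]), offset=float(on[k] + t_dur[k]),
                  chamber=Chamber.TARGET)
            for k in order
        ]
        acc[it] = _delay_histogram(
            match_bursts(source_bursts, surr, max_lag), edges_s, n_target
        )
    surr_mean = acc.mean(axis=0)
    surr_sd = acc.std(axis=0, ddof=1) if cfg.n_surrogates > 1 else np.zeros(n_bins)
    if cfg.sig_rule == "sd_only":
        significant = p_obs > cfg.sig_factor * surr_sd
    elif cfg.sig_rule == "mean_offset":
        significant = p_obs > surr_mean + cfg.sig_factor * surr_sd
    else:
        raise ValueError(f"unknown sig_rule {cfg.sig_rule!r}")
    return SurrogateNull(
        delay_bin_edges_ms=edges_s * 1e3,
        p_observed=p_obs,
        surr_mean=surr_mean,
        surr_sd=surr_sd,
        significant=significant,
        n_surrogates=cfg.n_surrogates,
        sig_factor=cfg.sig_factor,
    )


def evoked_propagation(
    stim_times: Sequence[float],
    stim_chambers: Sequence[Chamber | str],
    source_bursts: Sequence[Burst],
    target_bursts: Sequence[Burst],
    window: float = 0.1,
    max_lag: float = 0.5,
) -> Dict[str, Optional[float]]:
    """Propagation probability of stimulus-evoked bursts.

    An evoked burst is the first burst in the stimulated chamber with
    onset within ``window`` seconds after the stimulus.  The evoked
    PP_S-T (PP_T-S) is the fraction of evoked source (target) bursts that
    have a forward (backward) matched pair under the usual rules.  A
    direction with no evoked bursts is reported as ``None``.
    """
    if len(stim_times) == 0:
        raise ValueError("no stimuli supplied")
    if window <= 0:
        raise ValueError("window must be positive")
    if len(stim_times) != len(stim_chambers):
        raise ValueError("stim_times and stim_chambers must align")

    pairs = match_bursts(source_bursts, target_bursts, max_lag)
    fwd_initiators = {p.source_index for p in pairs if p.delay > 0}
    bwd_initiators = {p.target_index for p in pairs if p.delay < 0}

    onsets = {
        Chamber.SOURCE: np.array([b.onset for b in source_bursts]),
        Chamber.TARGET: np.array([b.onset for b in target_bursts]),
    }
    evoked: Dict[Chamber, set] = {Chamber.SOURCE: set(), Chamber.TARGET: set()}
    for t, ch in zip(stim_times, stim_chambers):
        ch = Chamber(ch)
        on = onsets[ch]
        k = int(np.searchsorted(on, t, side="left"))
        if k < on.size and on[k] <= t + window:
            evoked[ch].add(k)

    def rate(evoked_idx: set, initiators: set) -> Optional[float]:
        if not evoked_idx:
            return None
        return len(evoked_idx & initiators) / len(evoked_idx)

    return {
        "evoked_pp_st": rate(evoked[Chamber.SOURCE], fwd_initiators),
        "evoked_pp_ts": rate(evoked[Chamber.TARGET], bwd_initiators),
        "n_evoked_source": len(evoked[Chamber.SOURCE]),
        "n_evoked_target": len(evoked[Chamber.TARGET]),
    }
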