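"""Deterministic burst-log fixtures with a prescribed match structure.

:func:`build_session` lays out source/target burst logs so that the
matching rules recover exactly the requested number of forward and
backward propagated bursts out of the requested chamber totals.  Bursts
come in well-separated blocks (10 s apart, far beyond the +-500 ms
matching window):

* a *relay chain* block ``T -> S -> T``: the first target burst evokes a
  source burst (one backward pair) which in turn evokes a second target
  burst (one forward pair) — the source burst responds and initiates;
* forward-only and backward-only blocks holding one pair each;
* isolated single bursts making up the chamber totals.

``div20_reference_session`` reproduces the match structure of the
worked-example DIV-20 recording: 170 of 193 source bursts propagated
forward (88%) and 143 of 409 target bursts propagated backward (35%).
"""

from __future__ import annotations

from typing import List, Tuple

from .model import Burst, Chamber

DIV20_COUNTS = {
    "n_source": 193,
    "n_target": 409,
    "n_forward": 170,
    "n_backward": 143,
}


def build_session(
    n_source: int,
    n_target: int,
    n_forward: int,
    n_backward: int,
    delay: float = 0.13,
    burst_duration: float = 0.2,
    spacing: float = 10.0,
) -> Tuple[List[Burst], List[Burst]]:
    """Burst logs realizing the requested match structure.

    Every generated pair has ``|delay|`` equal to ``delay`` seconds and
    satisfies both matching rules (the response starts ``delay`` after
    the initiator, inside its ``burst_duration`` envelope).
    """
    if delay <= 0 or delay >= burst_duration:
        raise ValueError("need 0 < delay < burst_duration for the overlap rule")
    if n_forward > n_source or n_backward > n_target:
        raise ValueError("more pairs requested than initiator bursts")
    n_chains = max(0, n_forward + n_backward - n_source)
    if n_chains > min(n_forward, n_backward):
        raise ValueError("match structure infeasible: too few source bursts")
    if n_chains > 0 and 2 * delay <= burst_duration:
        raise ValueError("relay chains need 2*delay > burst_duration to keep "
                         "same-chamber bursts disjoint")
    n_fwd_only = n_forward - n_chains
    n_bwd_only = n_backward - n_chains
    matched_targets = n_forward + n_backward  # chains use two targets each
    if matched_targets > n_target:
        raise ValueError("match structure infeasible: too few target bursts")
    n_lone_source = n_source - n_forward - n_bwd_only
    n_lone_target = n_target - matched_targets

    source: List[Burst] = []
    target: List[Burst] = []
    t = 0.0

    def s_burst(onset: float) -> None:
        source.append(Burst(onset=onset, offset=onset + burst_duration,
                            chamber=Chamber.SOURCE, n_spikes=100,
                            n_electrodes=14))

    def t_burst(onset: float) -> None:
        target.append(Burst(onset=onset, offset=onset + burst_duration,
                            chamber=Chamber.TARGET, n_spikes=100,
                            n_electrodes=22))

    for _ in range(n_chains):          # T -> S -> T relay chains
        t_burst(t)
        s_burst(t + delay)
        t_burst(t + 2 * delay)
        t += spacing
    for _ in range(n_fwd_only):        # S -> T
        s_burst(t)
        t_burst(t + delay)
        t += spacing
    for _ in range(n_bwd_only):        # T -> S
        t_burst(t)
        s_burst(t + delay)
        t += spacing
    for _ in range(n_lone_source):
        s_burst(t)
        t += spacing
    for _ in range(n_lone_target):
        t_burst(t)
        t += spacing

    source.sort(key=lambda b: b.onset)
    target.sort(key=lambda b: b.onset)
    return source, target


def div20_reference_session() -> Tuple[List[Burst], List[Burst]]:
    """The worked-example session: 170/193 forward, 143/409 backward."""
    return build_session(**DIV20_COUNTS)
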