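"""Neurite-growth morphometrics from tip-trajectory annotations.

A trajectory is a sequence of time-stamped positions of one neurite tip
along the microchannel axis: ``x = 0`` at the source-side junction
(*Start*), ``x = L`` at the target-side junction (*End*).  Forward tracks
grow Start->End, backward tracks End->Start.  All along-channel metrics
(meeting point, maximum backward growth, segment velocities) use the 1-D
axis coordinate; only the bottleneck exit angle needs 2-D samples.

Percentages are measured from the End junction: a backward tip that
reaches 270 um into a 600 um channel has grown 45% of the channel length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import ChannelGeometry


@dataclass
class TipTrajectory:
    """Time-stamped neurite-tip positions in channel coordinates."""

    track_id: str
    direction: str             # "forward" (Source->Target) | "backward"
    t_h: np.ndarray            # hours, strictly increasing
    x_um: np.ndarray           # position along the channel axis
    y_um: Optional[np.ndarray] = None  # lateral position, only for angles

    def __post_init__(self) -> None:
        self.t_h = np.asarray(self.t_h, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        if self.y_um is not None:
            self.y_um = np.asarray(self.y_um, dtype=float)
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.t_h.size != self.x_um.size or self.t_h.size < 2:
            raise ValueError("trajectory needs >= 2 aligned (t, x) samples")
        if np.any(np.diff(self.t_h) <= 0):
            raise ValueError("time samples must be strictly increasing")

    def x_at(self, t: np.ndarray) -> np.ndarray:
        """Piecewise-linear position at times within the sampled span."""
        return np.interp(t, self.t_h, self.x_um)


@dataclass
class GrowthSummary:
    meeting_point_pct: Optional[float]
    max_backward_pct: float
    segment_velocities: Dict[Tuple[str, int], float] = field(default_factory=dict)
    exit_angles_deg: List[float] = field(default_factory=list)


def meeting_point(
    fwd: Optional[TipTrajectory],
    bwd: Optional[TipTrajectory],
    L: float,
) -> Optional[float]:
    """Forward/backward meeting point as % of channel length from the End.

    The meeting point is the position where the backward-growing tip first
    crosses the forward-growing tip (piecewise-linear interpolation over
    the common time span), expressed as the distance the backward neurite
    covered from the End junction relative to ``L``.  When the forward tip
    reaches the End with no crossing (in particular with no backward track
    at all) the meeting point is 0%.  Returns ``None`` when the two tracks
    never coexist in time and the forward tip does not reach the End.
    """
    if fwd is None:
        raise ValueError("a forward trajectory is required")
    fwd_reaches_end = bool(np.max(fwd.x_um) >= L - 1e-9)
    if bwd is None:
        return 0.0 if fwd_reaches_end else None

    t0 = max(fwd.t_h[0], bwd.t_h[0])
    t1 = min(fwd.t_h[-1], bwd.t_h[-1])
    if t0 <= t1:
        # breakpoints of the piecewise-linear difference x_fwd - x_bwd
        knots = np.union1d(fwd.t_h, bwd.t_h)
        knots = knots[(knots >= t0) & (knots <= t1)]
        knots = np.union1d(knots, [t0, t1])
        d = fwd.x_at(knots) - bwd.x_at(knots)
        for k in range(knots.size):
            if d[k] >= 0:
                if k == 0 or d[k] == 0:
                    t_star = knots[k]
                else:  # linear root between knots k-1 and k
                    frac = -d[k - 1] / (d[k] - d[k - 1])
                    t_star = knots[k - 1] + frac * (knots[k] - knots[k - 1])
                x_star = float(fwd.x_at(np.array([t_star]))[0])
                return (L - x_star) / L * 100.0
    return 0.0 if fwd_reaches_end else None


def max_backward_growth(bwd: TipTrajectory, L: float) -> float:
    """Deepest penetration of a backward track, % of channel length."""
    if bwd.direction != "backward":
        raise ValueError("max_backward_growth is defined for backward tracks")
    return (L - float(np.min(bwd.x_um))) / L * 100.0


def segment_velocity(
    traj: TipTrajectory,
    geometry: ChannelGeometry,
) -> Dict[int, float]:
    """Mean tip velocity (um/h) in every fully traversed segment.

    Segment ``k`` spans ``[k*seg, (k+1)*seg)`` um from the Start junction.
    Entry/exit times are linearly interpolated from the first passage of
    each boundary in the track's growth direction; segments the tip never
    fully crosses are skipped.
    """
    seg = geometry.segment_length_um
    bounds = geometry.segment_boundaries()
    x = traj.x_um
    t = traj.t_h

    def first_passage(level: float, forward: bool) -> Optional[float]:
        # first time the tip reaches `level` moving in its growth direction
        if forward:
            hit = np.nonzero(x >= level - 1e-12)[0]
        else:
            hit = np.nonzero(x <= level + 1e-12)[0]
        if hit.size == 0:
            return None
        k = int(hit[0])
        if k == 0:
            return float(t[0])
        x0, x1 = x[k - 1], x[k]
        if x1 == x0:
            return float(t[k])
        frac = (level - x0) / (x1 - x0)
        return float(t[k - 1] + frac * (t[k] - t[k - 1]))

    forward = traj.direction == "forward"
    out: Dict[int, float] = {}
    for k in range(geometry.n_segments):
        lo, hi = bounds[k], bounds[k + 1]
        entry_level, exit_level = (lo, hi) if forward else (hi, lo)
        t_in = first_passage(entry_level, forward)
        t_out = first_passage(exit_level, forward)
        if t_in is None or t_out is None or t_out <= t_in:
            continue
        out[k] = seg / (t_out - t_in)
    return out


def bottleneck_exit_angle(
    t: Sequence[float],
    x: Sequence[float],
    y: Sequence[float],
    bottleneck_x: float,
    step: float = 10.0,
) -> float:
    """Growth angle just past a bottleneck, degrees off the channel axis.

    The angle is measured between the channel axis (+x, toward the Target
    chamber) and the displacement from the bottleneck crossing point to
    the first position ``step`` micrometres away from it along the
    subsequent path (linear interpolation between samples).  0 deg is
    straight forward, 90 deg fully lateral, up to 180 deg for reversal.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (t.size == x.size == y.size):
        raise ValueError("t, x, y must have equal length")
    cross = np.nonzero((x[:-1] < bottleneck_x) & (x[1:] >= bottleneck_x))[0]
    if cross.size == 0:
        raise ValueError("track never crosses the bottleneck")
    k = int(cross[0])
    frac = (bottleneck_x - x[k]) / (x[k + 1] - x[k])
    px = bottleneck_x
    py = y[k] + frac * (y[k + 1] - y[k])

    # walk the remaining polyline until Euclidean distance >= step
    prev = np.array([px, py])
    for m in range(k + 1, t.size):
        cur = np.array([x[m], y[m]])
        d = float(np.hypot(cur[0] - px, cur[1] - py))
        if d >= step:
            # interpolate along [prev, cur] to the exact step distance
            lo, hi = 0.0, 1.0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                p = prev + mid * (cur - prev)
                if np.hypot(p[0] - px, p[1] - py) < step:
                    lo = mid
                else:
                    hi = mid
            p = prev + hi * (cur - prev)
            dx, dy = p[0] - px, p[1] - py
            return float(np.degrees(np.arctan2(abs(dy), dx)))
        prev = cur
    raise ValueError("track ends within `step` um of the bottleneck")


def summarize_growth(
    tracks: Sequence[TipTrajectory],
    geometry: ChannelGeometry,
) -> GrowthSummary:
    """Per-channel summary: meeting point, max backward growth, velocities."""
    fwd = next((tr for tr in tracks if tr.direction == "forward"), None)
    bwd = next((tr for tr in tracks if tr.direction == "backward"), None)
    L = geometry.total_length_um
    mp = meeting_point(fwd, bwd, L) if fwd is not None else None
    mb = max_backward_growth(bwd, L) if bwd is not None else 0.0
    seg_v: Dict[Tuple[str, int], float] = {}
    for tr in tracks:
        for k, v in segment_velocity(tr, geometry).items():
            seg_v[(tr.track_id, k)] = v
    return GrowthSummary(meeting_point_pct=mp, max_backward_pct=mb,
                         segment_velocities=seg_v)
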