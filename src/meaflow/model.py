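"""Domain types shared by all analysis stages.

Conventions
-----------
Time is seconds (float) everywhere inside the library; user-facing
summaries convert to milliseconds.  Spatial coordinates are micrometres
on the 8x8 electrode grid (200 um pitch).  The two cell compartments are
called the *source* and *target* chambers; the microchannels connecting
them hold three electrodes each, ordered by ``channel_rank`` with
increasing distance from the source-side junction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

GRID_PITCH_UM = 200.0
DEFAULT_SAMPLE_RATE = 20_000.0


class Region(str, Enum):
    SOURCE = "source"
    CHANNEL = "channel"
    TARGET = "target"


class Chamber(str, Enum):
    SOURCE = "source"
    TARGET = "target"

    @property
    def other(self) -> "Chamber":
        return Chamber.TARGET if self is Chamber.SOURCE else Chamber.SOURCE


@dataclass(frozen=True)
class Electrode:
    """One recording site on the 8x8 grid (corners absent)."""

    electrode_id: str
    x_um: float
    y_um: float
    region: Region
    channel_index: Optional[int] = None  # 1..8, set iff region == CHANNEL
    channel_rank: Optional[int] = None   # 1..3 from the source junction

    def __post_init__(self) -> None:
        in_channel = self.region is Region.CHANNEL
        has_idx = self.channel_index is not None and self.channel_rank is not None
        if in_channel != has_idx:
            raise ValueError(
                f"electrode {self.electrode_id}: channel_index/rank must be "
                "set iff region == channel"
            )


class MEALayout:
    """Electrode positions plus their chamber/microchannel assignment."""

    def __init__(self, electrodes: Sequence[Electrode]):
        ids = [e.electrode_id for e in electrodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate electrode ids in layout")
        self.electrodes: Tuple[Electrode, ...] = tuple(electrodes)
        self._by_id = {e.electrode_id: e for e in self.electrodes}

    def __len__(self) -> int:
        return len(self.electrodes)

    def __contains__(self, electrode_id: str) -> bool:
        return electrode_id in self._by_id

    def __getitem__(self, electrode_id: str) -> Electrode:
        return self._by_id[electrode_id]

    @property
    def electrode_ids(self) -> List[str]:
        return [e.electrode_id for e in self.electrodes]

    def region_ids(self, region: Region | str) -> List[str]:
        region = Region(region)
        return [e.electrode_id for e in self.electrodes if e.region is region]

    def chamber_ids(self, chamber: Chamber | str) -> List[str]:
        chamber = Chamber(chamber)
        region = Region.SOURCE if chamber is Chamber.SOURCE else Region.TARGET
        return self.region_ids(region)

    def channel_ids(self, channel_index: int) -> List[str]:
        """Electrode ids of one microchannel, ordered by channel_rank."""
        members = [
            e for e in self.electrodes
            if e.region is Region.CHANNEL and e.channel_index == channel_index
        ]
        members.sort(key=lambda e: e.channel_rank)
        return [e.electrode_id for e in members]

    @property
    def channel_indices(self) -> List[int]:
        return sorted({
            e.channel_index for e in self.electrodes
            if e.region is Region.CHANNEL
        })

    def grid_position(self, electrode_id: str) -> Tuple[int, int]:
        """(row, col) indices on the 8x8 grid, 0-based."""
        e = self._by_id[electrode_id]
        return int(round(e.y_um / GRID_PITCH_UM)), int(round(e.x_um / GRID_PITCH_UM))

    def validate(self) -> None:
        for e in self.electrodes:
            if e.region is Region.CHANNEL:
                if not (1 <= e.channel_index <= 8 and 1 <= e.channel_rank <= 3):
                    raise ValueError(
                        f"electrode {e.electrode_id}: channel_index/rank out of range"
                    )


def default_layout() -> MEALayout:
    """The 60-electrode fixture used throughout.

    The 8x8 grid has its four corners absent (standard 60-electrode MEA).
    Columns 1-2 lie in the source chamber (14 electrodes), columns 3-5
    cross the eight microchannels (8 channels x 3 electrodes = 24, one
    channel per grid row, rank increasing with column), and columns 6-8
    lie in the target chamber (22 electrodes).  Labels follow the
    "e<col><row>" grid convention.
    """
    electrodes: List[Electrode] = []
    for col in range(1, 9):
        for row in range(1, 9):
            if (col, row) in {(1, 1), (1, 8), (8, 1), (8, 8)}:
                continue  # corner sites absent on a 60-electrode array
            x = (col - 1) * GRID_PITCH_UM
            y = (row - 1) * GRID_PITCH_UM
            if col <= 2:
                region, ch_idx, ch_rank = Region.SOURCE, None, None
            elif col <= 5:
                region, ch_idx, ch_rank = Region.CHANNEL, row, col - 2
            else:
                region, ch_idx, ch_rank = Region.TARGET, None, None
            electrodes.append(
                Electrode(f"e{col}{row}", x, y, region, ch_idx, ch_rank)
            )
    layout = MEALayout(electrodes)
    layout.validate()
    return layout


class SpikeTrainSet:
    """Per-electrode sorted spike timestamps for one recording.

    Parameters
    ----------
    spikes
        Mapping electrode id -> array of spike times in seconds.
        Electrodes of the layout absent from the mapping get empty trains.
    duration
        Recording length in seconds.
    sample_rate
        Acquisition rate in Hz (20 kHz by default).
    layout
        The electrode layout the ids refer to.
    """

    def __init__(
        self,
        spikes: Mapping[str, Iterable[float]],
        duration: float,
        layout: MEALayout,
        sample_rate: float = DEFAULT_SAMPLE_RATE,
    ):
        if duration <= 0:
            raise ValueError("duration must be positive")
        self.duration = float(duration)
        self.sample_rate = float(sample_rate)
        self.layout = layout
        self.spikes: Dict[str, np.ndarray] = {}
        for eid in layout.electrode_ids:
            self.spikes[eid] = np.asarray(spikes.get(eid, ()), dtype=float)
        unknown = set(spikes) - set(layout.electrode_ids)
        if unknown:
            raise ValueError(f"unknown electrode labels: {sorted(unknown)}")
        self._validate()

    def _validate(self) -> None:
        for eid, t in self.spikes.items():
            if t.size and np.any(np.diff(t) < 0):
                raise ValueError(f"electrode {eid}: timestamps not sorted")
            if t.size and (t[0] < 0 or t[-1] > self.duration):
                raise ValueError(
                    f"electrode {eid}: timestamps outside [0, duration]"
                )

    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.spikes.values()))

    def region_spikes(self, region: Region | str) -> np.ndarray:
        """All spike times on electrodes of a region, pooled and sorted."""
        ids = self.layout.region_ids(region)
        if not ids:
            raise ValueError(f"no electrodes in region {region!r}")
        pooled = np.concatenate([self.spikes[i] for i in ids]) if ids else np.array([])
        return np.sort(pooled)


@dataclass(frozen=True, order=True)
class Burst:
    """A chamber-level network burst."""

    onset: float           # s, time of the first spike in the burst
    offset: float          # s
    chamber: Chamber = field(compare=False, default=Chamber.SOURCE)
    n_spikes: int = field(compare=False, default=0)
    n_electrodes: int = field(compare=False, default=0)

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("burst offset must exceed onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def check_bursts_sorted_disjoint(bursts: Sequence[Burst]) -> None:
    for a, b in zip(bursts, bursts[1:]):
        if b.onset < a.onset:
            raise ValueError("bursts not sorted by onset")
        if b.onset < a.offset:
            raise ValueError("bursts overlap within a chamber")


@dataclass(frozen=True)
class ChannelGeometry:
    """Geometry of one asymmetric microchannel (a chain of segments)."""

    shape: str = "triangle_narrow"   # zigzag | spines | triangle | triangle_narrow
    segment_length_um: float = 200.0  # one of 66, 70, 100, 200
    segment_width_um: float = 40.0    # one of 40, 60, 80, 160
    bottleneck_width_um: float = 7.0  # 5 or 7
    total_length_um: float = 600.0
    n_segments: int = 3

    def __post_init__(self) -> None:
        if self.bottleneck_width_um >= self.segment_width_um:
            raise ValueError("bottleneck must be narrower than the segment")
        if abs(self.n_segments * self.segment_length_um - self.total_length_um) \
                > self.segment_length_um:
            raise ValueError("n_segments x segment_length inconsistent with total length")

    def segment_boundaries(self) -> np.ndarray:
        """Segment boundary positions in um from the source-side junction."""
        return np.arange(self.n_segments + 1) * self.segment_length_um


# ---------------------------------------------------------------------------
# analysis configuration

@dataclass
class DetectionConfig:
    k_threshold: float = 8.0   # multiplier on the median-based noise sigma
    dead_time_ms: float = 1.0
    polarity: str = "neg"      # neg | pos | both


@dataclass
class BurstConfig:
    bin_ms: float = 50.0
    # None -> adaptive: max(10 spikes/bin, 5x the median bin count)
    rate_threshold: Optional[float] = None
    min_spikes: int = 50
    merge_gap_ms: float = 100.0


@dataclass
class PropagationConfig:
    max_lag_ms: float = 500.0       # the +-500 ms matching window
    n_surrogates: int = 1000
    sig_factor: float = 5.0
    delay_bin_ms: float = 50.0
    jitter_half_width_s: float = 10.0
    # "mean_offset": p_obs > surr_mean + sig_factor*surr_sd (default)
    # "sd_only":     p_obs > sig_factor*surr_sd
    sig_rule: str = "mean_offset"


@dataclass
class ProfileConfig:
    profile_bin_ms: float = 20.0
    map_bin_ms: float = 5.0
    window_ms: Tuple[float, float] = (-100.0, 500.0)


@dataclass
class AnalysisConfig:
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    bursts: BurstConfig = field(default_factory=BurstConfig)
    propagation: PropagationConfig = field(default_factory=PropagationConfig)
    profiles: ProfileConfig = field(default_factory=ProfileConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        p = self.propagation
        for name, val in (
            ("detection.k_threshold", self.detection.k_threshold),
            ("bursts.bin_ms", self.bursts.bin_ms),
            ("propagation.max_lag_ms", p.max_lag_ms),
            ("propagation.n_surrogates", p.n_surrogates),
            ("propagation.delay_bin_ms", p.delay_bin_ms),
            ("propagation.jitter_half_width_s", p.jitter_half_width_s),
            ("profiles.profile_bin_ms", self.profiles.profile_bin_ms),
            ("profiles.map_bin_ms", self.profiles.map_bin_ms),
        ):
            if val <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["profiles"]["window_ms"] = list(d["profiles"]["window_ms"])  # YAML-safe
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        d = dict(d)
        kwargs = {}
        for name, sub in (
            ("detection", DetectionConfig),
            ("bursts", BurstConfig),
            ("propagation", PropagationConfig),
            ("profiles", ProfileConfig),
        ):
            if name in d:
                payload = dict(d.pop(name))
                if name == "profiles" and "window_ms" in payload:
                    payload["window_ms"] = tuple(payload["window_ms"])
                kwargs[name] = sub(**payload)
        if "seed" in d:
            kwargs["seed"] = int(d.pop("seed"))
        if d:
            raise ValueError(f"unknown config keys: {sorted(d)}")
        return cls(**kwargs)
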