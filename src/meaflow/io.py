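"""File formats: layout JSON, spike logs (HDF5/CSV), burst and stimulus CSV,
configuration YAML.

Spike logs come in two equivalent dialects:

* HDF5 — one dataset per electrode under the group ``/spikes`` (float64
  seconds), with ``duration_s`` and ``sample_rate_hz`` root attributes.
* CSV — header ``electrode,time_s``, one spike per row; duration and sample
  rate ride in ``# duration_s=...`` / ``# sample_rate_hz=...`` comment lines
  before the header.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import h5py
import numpy as np
import pandas as pd
import yaml

from .model import (
    AnalysisConfig,
    Burst,
    Chamber,
    Electrode,
    MEALayout,
    Region,
    SpikeTrainSet,
)

PathLike = Union[str, Path]


class SchemaError(ValueError):
    """Input file does not match the documented schema."""


# ---------------------------------------------------------------------------
# layout JSON

def write_layout(layout: MEALayout, path: PathLike) -> None:
    payload = {
        "electrodes": [
            {
                "id": e.electrode_id,
                "x_um": e.x_um,
                "y_um": e.y_um,
                "region": e.region.value,
                "channel_index": e.channel_index,
                "channel_rank": e.channel_rank,
            }
            for e in layout.electrodes
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_layout(path: PathLike) -> MEALayout:
    try:
        payload = json.loads(Path(path).read_text())
        electrodes = [
            Electrode(
                electrode_id=rec["id"],
                x_um=float(rec["x_um"]),
                y_um=float(rec["y_um"]),
                region=Region(rec["region"]),
                channel_index=rec.get("channel_index"),
                channel_rank=rec.get("channel_rank"),
            )
            for rec in payload["electrodes"]
        ]
    except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
        raise SchemaError(f"bad layout file {path}: {exc}") from exc
    layout = MEALayout(electrodes)
    layout.validate()
    return layout


# ---------------------------------------------------------------------------
# spike logs

def write_spike_trains(spikes: SpikeTrainSet, path: PathLike) -> None:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            f.attrs["duration_s"] = spikes.duration
            f.attrs["sample_rate_hz"] = spikes.sample_rate
            grp = f.create_group("spikes")
            for eid, t in spikes.spikes.items():
                grp.create_dataset(eid, data=np.asarray(t, dtype="f8"))
    elif path.suffix == ".csv":
        rows = []
        for eid in spikes.layout.electrode_ids:
            for t in spikes.spikes[eid]:
                rows.append((eid, t))
        with open(path, "w") as f:
            f.write(f"# duration_s={spikes.duration!r}\n")
            f.write(f"# sample_rate_hz={spikes.sample_rate!r}\n")
            f.write("electrode,time_s\n")
            for eid, t in rows:
                f.write(f"{eid},{float(t)!r}\n")
    else:
        raise SchemaError(f"unsupported spike-file extension: {path.suffix}")


def read_spike_trains(path: PathLike, layout: MEALayout) -> SpikeTrainSet:
    """Read a spike log; layout electrodes absent from the file get empty
    trains, unknown labels raise :class:`SchemaError`."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            try:
                duration = float(f.attrs["duration_s"])
                sample_rate = float(f.attrs["sample_rate_hz"])
            except KeyError as exc:
                raise SchemaError(f"{path}: missing duration/sample_rate attrs") from exc
            spikes = {eid: np.asarray(ds[()], dtype=float)
                      for eid, ds in f["spikes"].items()}
    elif path.suffix == ".csv":
        duration = sample_rate = None
        with open(path) as f:
            for line in f:
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].strip().partition("=")
                if key.strip() == "duration_s":
                    duration = float(val)
                elif key.strip() == "sample_rate_hz":
                    sample_rate = float(val)
        if duration is None:
            raise SchemaError(f"{path}: missing '# duration_s=' header")
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        if list(df.columns) != ["electrode", "time_s"]:
            raise SchemaError(f"{path}: expected header 'electrode,time_s'")
        spikes = {
            eid: np.asarray(grp["time_s"], dtype=float)
            for eid, grp in df.groupby("electrode", sort=True)
        }
        sample_rate = sample_rate or 20_000.0
    else:
        raise SchemaError(f"unsupported spike-file extension: {path.suffix}")

    unknown = set(spikes) - set(layout.electrode_ids)
    if unknown:
        raise SchemaError(f"{path}: unknown electrode labels {sorted(unknown)}")
    for eid, t in spikes.items():
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError(f"{path}: unsorted timestamps on electrode {eid}")
    return SpikeTrainSet(spikes, duration=duration, layout=layout,
                         sample_rate=sample_rate)


# ---------------------------------------------------------------------------
# burst and stimulus CSV

BURST_COLUMNS = ["chamber", "onset_s", "offset_s", "n_spikes", "n_electrodes"]


def write_bursts(bursts: Sequence[Burst], path: PathLike) -> None:
    df = pd.DataFrame(
        [(b.chamber.value, b.onset, b.offset, b.n_spikes, b.n_electrodes)
         for b in bursts],
        columns=BURST_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_bursts(path: PathLike) -> List[Burst]:
    df = pd.read_csv(path)
    if list(df.columns) != BURST_COLUMNS:
        raise SchemaError(f"{path}: expected columns {BURST_COLUMNS}")
    return [
        Burst(
            chamber=Chamber(row.chamber),
            onset=float(row.onset_s),
            offset=float(row.offset_s),
            n_spikes=int(row.n_spikes),
            n_electrodes=int(row.n_electrodes),
        )
        for row in df.itertuples()
    ]


def read_stimuli(path: PathLike) -> pd.DataFrame:
    """Stimulus log: columns ``time_s,electrode``."""
    df = pd.read_csv(path)
    if list(df.columns) != ["time_s", "electrode"]:
        raise SchemaError(f"{path}: expected columns ['time_s', 'electrode']")
    return df


# ---------------------------------------------------------------------------
# raw trace (binary float32 + JSON sidecar) and trajectory CSV

def write_raw_trace(trace: np.ndarray, sample_rate: float, path: PathLike) -> None:
    path = Path(path)
    np.asarray(trace, dtype="<f4").tofile(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"dtype": "float32", "sample_rate_hz": sample_rate,
         "n_samples": int(np.size(trace)), "units": "uV"}) + "\n")


def read_raw_trace(path: PathLike) -> Tuple[np.ndarray, float]:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    try:
        meta = json.loads(sidecar.read_text())
        sample_rate = float(meta["sample_rate_hz"])
    except (OSError, KeyError, json.JSONDecodeError) as exc:
        raise SchemaError(f"bad or missing sidecar for {path}: {exc}") from exc
    trace = np.fromfile(path, dtype="<f4").astype(float)
    if "n_samples" in meta and trace.size != int(meta["n_samples"]):
        raise SchemaError(f"{path}: sample count disagrees with sidecar")
    return trace, sample_rate


# ---------------------------------------------------------------------------
# configuration YAML

def read_config(path: Optional[PathLike]) -> AnalysisConfig:
    if path is None:
        return AnalysisConfig()
    payload = yaml.safe_load(Path(path).read_text()) or {}
    return AnalysisConfig.from_dict(payload)


def write_config(config: AnalysisConfig, path: PathLike) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
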