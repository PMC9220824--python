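"""Containers for multi-ROI fluorescence recordings and stimulus protocols.

A recording is a set of per-ROI time series organised by *channel role*:

``ex430`` / ``ex500``
    raw emission under 430 nm / 500 nm excitation (Fura Red),
``ratio``
    the ratiometric Ca2+ readout R500/430,
``infrared``
    the near-infrared label channel used to demultiplex two animals
    imaged in the same chamber.

All channels share a single, strictly increasing time grid in seconds.
Tables round-trip through tidy CSV (``time_s, roi_id, channel, value``)
and wide CSV (one column per ROI for a single channel).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Iterator, List, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

CHANNEL_ROLES = ("ex430", "ex500", "ratio", "infrared")


@dataclass
class TraceSet:
    """Time-indexed multi-ROI recording with channel roles.

    Parameters
    ----------
    time
        Frame timestamps in seconds (acquisition start of each frame),
        strictly increasing and nominally uniform.
    channels
        Mapping from channel role to a frame x ROI DataFrame. All
        channels share ``time`` as their grid and the same ROI columns.
    animal_of
        ROI id -> animal id, filled by demultiplexing.
    metadata
        Free-form provenance (detrending flags, demux diagnostics, ...).
    """

    time: np.ndarray
    channels: Dict[str, pd.DataFrame]
    animal_of: Dict[str, str] = field(default_factory=dict)
    metadata: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or len(self.time) == 0:
            raise ValueError("time must be a non-empty 1-D array")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if not self.channels:
            raise ValueError("at least one channel is required")
        rois = None
        for role, df in self.channels.items():
            if len(df) != len(self.time):
                raise ValueError(
                    f"channel {role!r} has {len(df)} frames, expected {len(self.time)}"
                )
            cols = list(df.columns)
            if rois is None:
                rois = cols
            elif set(cols) != set(rois):
                raise ValueError(f"channel {role!r} has a different ROI set")

    @property
    def rois(self) -> List[str]:
        first = next(iter(self.channels.values()))
        return [str(c) for c in first.columns]

    @property
    def frame_interval(self) -> float:
        return float(np.median(np.diff(self.time)))

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0] + self.frame_interval)

    def channel(self, role: str) -> pd.DataFrame:
        try:
            return self.channels[role]
        except KeyError:
            raise KeyError(
                f"channel {role!r} not present; have {sorted(self.channels)}"
            ) from None

    def with_channel(self, role: str, values: pd.DataFrame) -> "TraceSet":
        channels = dict(self.channels)
        channels[role] = values
        return TraceSet(
            time=self.time.copy(),
            channels=channels,
            animal_of=dict(self.animal_of),
            metadata=dict(self.metadata),
        )

    # ------------------------------------------------------------------ I/O

    def to_tidy(self) -> pd.DataFrame:
        frames = []
        for role in sorted(self.channels):
            df = self.channels[role]
            long = df.copy()
            long.insert(0, "time_s", self.time)
            long = long.melt(id_vars="time_s", var_name="roi_id", value_name="value")
            long.insert(2, "channel", role)
            frames.append(long)
        out = pd.concat(frames, ignore_index=True)
        return out.sort_values(["channel", "roi_id", "time_s"]).reset_index(drop=True)

    @classmethod
    def from_tidy(cls, df: pd.DataFrame, **kwargs: Any) -> "TraceSet":
        required = {"time_s", "roi_id", "channel", "value"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"tidy trace table is missing columns {sorted(missing)}")
        channels = {}
        time = None
        for role, grp in df.groupby("channel"):
            wide = grp.pivot(index="time_s", columns="roi_id", values="value")
            wide = wide.sort_index()
            if time is None:
                time = wide.index.to_numpy(dtype=float)
            channels[str(role)] = wide.reset_index(drop=True)
        return cls(time=time, channels=channels, **kwargs)

    def to_wide(self, role: str) -> pd.DataFrame:
        df = self.channel(role).copy()
        df.insert(0, "time_s", self.time)
        return df

    @classmethod
    def from_wide(cls, df: pd.DataFrame, role: str = "ratio", **kwargs: Any) -> "TraceSet":
        if "time_s" not in df.columns:
            raise ValueError("wide trace table must contain a 'time_s' column")
        time = df["time_s"].to_numpy(dtype=float)
        values = df.drop(columns="time_s").reset_index(drop=True)
        values.columns = [str(c) for c in values.columns]
        return cls(time=time, channels={role: values}, **kwargs)

    def write_tidy_csv(self, path: str | Path) -> None:
        self.to_tidy().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def read_tidy_csv(cls, path: str | Path, **kwargs: Any) -> "TraceSet":
        return cls.from_tidy(pd.read_csv(path), **kwargs)


class StimulusSegment(BaseModel):
    """One stimulus condition: a labelled half-open time window [start_s, end_s)."""

    label: str
    concentration: float = Field(ge=0)
    units: str = "mM"
    start_s: float
    end_s: float

    @model_validator(mode="after")
    def _check_span(self) -> "StimulusSegment":
        if not np.isfinite([self.start_s, self.end_s, self.concentration]).all():
            raise ValueError(f"segment {self.label!r} has non-finite fields")
        if self.end_s <= self.start_s:
            raise ValueError(f"segment {self.label!r} has non-positive duration")
        return self

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


class Protocol(BaseModel):
    """Ordered stimulus segments plus the equilibration lag discarded at
    the start of each segment (solution-exchange settling time)."""

    segments: List[StimulusSegment]
    equilibration_lag_s: float = Field(default=60.0, ge=0)

    @model_validator(mode="after")
    def _check_segments(self) -> "Protocol":
        if not self.segments:
            raise ValueError("protocol must contain at least one segment")
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start_s < a.end_s:
                raise ValueError(
                    f"segments {a.label!r} and {b.label!r} overlap or are out of order"
                )
        for seg in self.segments:
            if self.equilibration_lag_s >= seg.duration:
                raise ValueError(
                    f"equilibration lag {self.equilibration_lag_s} s is not shorter "
                    f"than segment {seg.label!r} ({seg.duration} s)"
                )
        return self

    @property
    def span(self) -> Tuple[float, float]:
        return self.segments[0].start_s, self.segments[-1].end_s

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "Protocol":
        return cls.model_validate(json.loads(Path(path).read_text()))


@dataclass
class SegmentWindow:
    """The frames of one protocol segment (after the equilibration lag),
    for all ROIs of one channel."""

    label: str
    concentration: float
    start_s: float
    end_s: float
    time: np.ndarray
    data: pd.DataFrame  # frame x ROI

    @property
    def rois(self) -> List[str]:
        return [str(c) for c in self.data.columns]

    def roi(self, roi_id: str) -> np.ndarray:
        return self.data[roi_id].to_numpy(dtype=float)

    def iter_rois(self) -> Iterator[Tuple[str, np.ndarray]]:
        for roi_id in self.data.columns:
            yield str(roi_id), self.data[roi_id].to_numpy(dtype=float)


def ramp_protocol(
    concentrations: Sequence[float],
    segment_duration_s: float = 960.0,
    equilibration_lag_s: float = 60.0,
    units: str = "mM",
    start_s: float = 0.0,
) -> Protocol:
    """Build a back-to-back ramp protocol (one segment per concentration)."""
    segments = []
    t = start_s
    for c in concentrations:
        segments.append(
            StimulusSegment(
                label=f"{c:g}{units}",
                concentration=float(c),
                units=units,
                start_s=t,
                end_s=t + segment_duration_s,
            )
        )
        t += segment_duration_s
    return Protocol(segments=segments, equilibration_lag_s=equilibration_lag_s)
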