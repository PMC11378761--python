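"""Reading and writing wearable-sensor logs.

A recording session produces one delimited text log per sensor placement
(left/right x upper arm/forearm/hand).  Each log row holds a timestamp,
three acceleration channels (g), three angular-velocity channels (deg/s)
and three Euler-angle channels (deg) sampled nominally at 10 Hz.  The
reader is deliberately lossless: unparseable numeric cells become NaN
("missing") and are repaired later by the segmentation stage, never here.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "SIDES",
    "SEGMENTS",
    "Placement",
    "SensorStream",
    "FormatError",
    "parse_sensor_log",
    "serialize_stream",
]

#: canonical channel order: accel (g), gyro (deg/s), Euler angles (deg)
CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz", "roll", "pitch", "yaw")

SIDES = ("left", "right")
SEGMENTS = ("upper_arm", "forearm", "hand")

#: sensor quantization steps used when simulating streams
ACCEL_RESOLUTION_G = 0.005
GYRO_RESOLUTION_DPS = 0.61
ANGLE_RESOLUTION_DEG = 0.05


class FormatError(ValueError):
    """Raised when a sensor log violates the format contract."""


@dataclass(frozen=True)
class Placement:
    """One of the six sensor positions on the body."""

    side: str
    segment: str

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.segment not in SEGMENTS:
            raise ValueError(
                f"segment must be one of {SEGMENTS}, got {self.segment!r}"
            )

    def __str__(self) -> str:  # e.g. "right_upper_arm"
        return f"{self.side}_{self.segment}"


def all_placements() -> list[Placement]:
    """The six placements in a fixed canonical order."""
    return [Placement(side, seg) for side in SIDES for seg in SEGMENTS]


@dataclass
class SensorStream:
    """An ordered 9-channel sample sequence from one sensor placement.

    ``data`` is a DataFrame with columns ``t`` plus :data:`CHANNELS`;
    missing channel values are NaN.  Timestamps are strictly increasing.
    """

    placement: Placement
    data: pd.DataFrame
    nominal_rate: float = 10.0

    def __post_init__(self) -> None:
        missing_cols = {"t", *CHANNELS} - set(self.data.columns)
        if missing_cols:
            raise FormatError(f"stream missing columns: {sorted(missing_cols)}")
        t = self.data["t"].to_numpy(float)
        if t.size and not np.all(np.diff(t) > 0):
            row = int(np.argmax(np.diff(t) <= 0)) + 1
            raise FormatError(
                f"timestamps must be strictly increasing (violated at row {row + 1})"
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean per-channel missing flags (True where the value is absent)."""
        return self.data[list(CHANNELS)].isna()

    def channel(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(float)

    def accel(self) -> np.ndarray:
        """Nx3 acceleration matrix (x, y, z) in g."""
        return self.data[["ax", "ay", "az"]].to_numpy(float)


def parse_sensor_log(
    raw_text: str,
    column_map: Mapping[str, str],
    placement: Placement | None = None,
    nominal_rate: float = 10.0,
) -> SensorStream:
    """Parse a delimited (comma or tab) sensor log into a :class:`SensorStream`.

    ``column_map`` maps header names in the file to canonical channel names
    (``t`` plus any of :data:`CHANNELS`), decoupling the reader from vendor
    header conventions.  Unparseable numeric cells are flagged missing
    rather than raising; a missing timestamp column or non-increasing
    timestamps are format errors.
    """
    if "t" not in column_map.values():
        raise FormatError("column_map must map some column to the timestamp 't'")
    unknown = set(column_map.values()) - {"t", *CHANNELS}
    if unknown:
        raise FormatError(f"column_map targets unknown channels: {sorted(unknown)}")

    sep = "\t" if "\t" in raw_text.splitlines()[0] else ","
    frame = pd.read_csv(_io.StringIO(raw_text), sep=sep, dtype=str)
    frame.columns = [c.strip() for c in frame.columns]

    absent = [src for src in column_map if src not in frame.columns]
    if absent:
        raise FormatError(f"log header lacks mapped columns: {absent}")

    out = pd.DataFrame(index=frame.index)
    for src, dst in column_map.items():
        out[dst] = pd.to_numeric(frame[src], errors="coerce")
    for ch in CHANNELS:
        if ch not in out.columns:
            out[ch] = np.nan
    out = out[["t", *CHANNELS]]

    t = out["t"].to_numpy(float)
    if np.isnan(t).any():
        row = int(np.argmax(np.isnan(t)))
        raise FormatError(f"unparseable timestamp at data row {row + 1}")
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise FormatError(
            f"timestamps not strictly increasing at data row {int(bad[0]) + 2}"
        )

    if placement is None:
        placement = Placement("right", "upper_arm")
    return SensorStream(placement=placement, data=out, nominal_rate=nominal_rate)


def serialize_stream(stream: SensorStream, sep: str = ",") -> str:
    """Write a stream back to delimited text; round-trips through the parser."""
    return stream.data.to_csv(sep=sep, index=False, na_rep="")
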