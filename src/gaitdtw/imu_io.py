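"""Reading, writing and preprocessing of 6-axis IMU recordings and label tracks.

A recording is a fixed-rate (100 Hz) table of six channels named
``AccX, AccY, AccZ, GyroX, GyroY, GyroZ`` with z vertical, y mediolateral and
x anterior-posterior. Preprocessing covers two steps: rotating arbitrarily
oriented sensor axes onto that convention, and removing a constant
accelerometer offset estimated from quiet-standing reference frames (the
standing mean on the vertical axis should read 9.81 m/s^2, the horizontal
axes 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import ACC_AXES, AXES, DEFAULT_SAMPLING_RATE_HZ, GRAVITY_MS2, GYRO_AXES

__all__ = [
    "ImuRecording",
    "LabelInterval",
    "LabelTrack",
    "read_recording",
    "write_recording",
    "read_labels",
    "write_labels",
    "rotate_axes",
    "invert_rotation",
    "correct_standing_offset",
]

#: Nominal accelerometer reading during upright quiet standing, per axis.
NOMINAL_STANDING = {"AccX": 0.0, "AccY": 0.0, "AccZ": GRAVITY_MS2}


@dataclass(frozen=True)
class ImuRecording:
    """Fixed-rate 6-channel inertial recording.

    Parameters
    ----------
    samples
        Array of shape ``(n_frames, 6)`` with columns in canonical
        :data:`~gaitdtw.constants.AXES` order.
    sampling_rate_hz
        Sampling rate; the recognition pipeline assumes 100 Hz.
    """

    samples: np.ndarray
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(AXES):
            raise ValueError(
                f"samples must have shape (n_frames, {len(AXES)}), got {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            bad = int(np.argwhere(~np.isfinite(arr))[0, 0])
            raise ValueError(f"non-finite sample value at frame {bad}")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        object.__setattr__(self, "samples", arr)

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]

    def channel(self, axis: str) -> np.ndarray:
        """Return one axis as a 1-D view."""
        return self.samples[:, AXES.index(axis)]

    @classmethod
    def from_channels(
        cls, channels: Mapping[str, Sequence[float]], sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    ) -> "ImuRecording":
        missing = [a for a in AXES if a not in channels]
        if missing:
            raise ValueError(f"missing channel(s): {', '.join(missing)}")
        cols = [np.asarray(channels[a], dtype=float) for a in AXES]
        lengths = {len(c) for c in cols}
        if len(lengths) != 1:
            raise ValueError(f"channels have unequal lengths: {sorted(lengths)}")
        return cls(np.column_stack(cols), sampling_rate_hz)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=list(AXES))


@dataclass(frozen=True)
class LabelInterval:
    """Half-open labelled interval ``[start_frame, end_frame)`` (0-based)."""

    activity: str
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_frame < self.end_frame):
            raise ValueError(
                f"invalid interval [{self.start_frame}, {self.end_frame}) "
                f"for activity {self.activity!r}"
            )

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass(frozen=True)
class LabelTrack:
    """Sorted, non-overlapping activity intervals over one recording."""

    intervals: tuple[LabelInterval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ivs = tuple(
            iv if isinstance(iv, LabelInterval) else LabelInterval(*iv)
            for iv in self.intervals
        )
        for a, b in zip(ivs, ivs[1:]):
            if b.start_frame < a.start_frame:
                raise ValueError("intervals must be sorted by start frame")
            if b.start_frame < a.end_frame:
                raise ValueError(
                    f"overlapping intervals at frames {b.start_frame} < {a.end_frame}"
                )
        object.__setattr__(self, "intervals", ivs)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def frame_labels(self, n_frames: int, fill: str | None = None) -> np.ndarray:
        """Expand intervals to one label per frame.

        Frames not covered by any interval receive ``fill`` (``None`` keeps
        the empty string).
        """
        out = np.full(n_frames, fill if fill is not None else "", dtype=object)
        for iv in self.intervals:
            if iv.end_frame > n_frames:
                raise ValueError(
                    f"interval end {iv.end_frame} exceeds recording length {n_frames}"
                )
            out[iv.start_frame : iv.end_frame] = iv.activity
        return out

    def total_frames(self, activities: Iterable[str] | None = None) -> int:
        acts = set(activities) if activities is not None else None
        return sum(
            iv.n_frames for iv in self.intervals if acts is None or iv.activity in acts
        )


def read_recording(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
) -> ImuRecording:
    """Load a recording from CSV (one row per frame).

    Parameters
    ----------
    column_map
        Optional mapping ``{file column name -> canonical axis name}`` so
        files with foreign column names/orders can be loaded. Unmapped extra
        columns (e.g. a time column) are ignored.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [a for a in AXES if a not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    sub = df[list(AXES)]
    numeric = sub.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~sub.isna()
    if bad.any().any():
        row = int(bad.any(axis=1).idxmax())
        raise ValueError(f"{path}: non-numeric value at row {row}")
    if numeric.isna().any().any():
        row = int(numeric.isna().any(axis=1).idxmax())
        raise ValueError(f"{path}: missing/NaN value at row {row}")
    return ImuRecording(numeric.to_numpy(dtype=float), sampling_rate_hz)


def write_recording(rec: ImuRecording, path: str | Path) -> None:
    """Write a recording to CSV with full float round-trip precision."""
    rec.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_labels(path: str | Path) -> LabelTrack:
    """Load a label track from CSV (``activity,start_frame,end_frame``) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        records = pd.read_csv(path).to_dict("records")
    return LabelTrack(
        tuple(
            LabelInterval(str(r["activity"]), int(r["start_frame"]), int(r["end_frame"]))
            for r in records
        )
    )


def write_labels(track: LabelTrack, path: str | Path) -> None:
    path = Path(path)
    records = [
        {"activity": iv.activity, "start_frame": iv.start_frame, "end_frame": iv.end_frame}
        for iv in track.intervals
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(records, indent=1))
    else:
        pd.DataFrame(records, columns=["activity", "start_frame", "end_frame"]).to_csv(
            path, index=False
        )


def _parse_rotation(rotation: Mapping[str, str]) -> dict[str, tuple[str, float]]:
    """Normalise ``{target axis: 'SourceAxis' | '-SourceAxis'}`` and validate."""
    parsed: dict[str, tuple[str, float]] = {}
    for target in AXES:
        spec = rotation.get(target, target)
        sign = 1.0
        if spec.startswith("-"):
            sign, spec = -1.0, spec[1:]
        if spec not in AXES:
            raise ValueError(f"unknown source axis {spec!r} for target {target!r}")
        acc_t, acc_s = target in ACC_AXES, spec in ACC_AXES
        if acc_t != acc_s:
            raise ValueError(
                f"rotation may not mix accelerometer and gyroscope axes "
                f"({target!r} <- {spec!r})"
            )
        parsed[target] = (spec, sign)
    sources = [s for s, _ in parsed.values()]
    if len(set(sources)) != len(AXES):
        dup = next(s for s in sources if sources.count(s) > 1)
        raise ValueError(f"rotation is not a bijection: source {dup!r} used twice")
    return parsed


def rotate_axes(rec: ImuRecording, rotation: Mapping[str, str]) -> ImuRecording:
    """Permute and/or sign-flip axes onto the canonical orientation.

    ``rotation`` maps each target axis to its source, e.g.
    ``{"AccX": "-AccY", "AccY": "AccX"}``; omitted axes stay in place.
    Accelerometer axes may only be sourced from accelerometer axes (same for
    gyroscope). Applying a rotation followed by :func:`invert_rotation` of it
    restores the original recording.
    """
    parsed = _parse_rotation(rotation)
    cols = [
        sign * rec.channel(source) for _, (source, sign) in
        ((t, parsed[t]) for t in AXES)
    ]
    return ImuRecording(np.column_stack(cols), rec.sampling_rate_hz)


def invert_rotation(rotation: Mapping[str, str]) -> dict[str, str]:
    """Return the rotation mapping that undoes ``rotation``."""
    parsed = _parse_rotation(rotation)
    inv: dict[str, str] = {}
    for target, (source, sign) in parsed.items():
        inv[source] = ("-" if sign < 0 else "") + target
    return inv


def correct_standing_offset(
    rec: ImuRecording, standing_intervals: Sequence[tuple[int, int]]
) -> ImuRecording:
    """Remove constant accelerometer offsets estimated from standing frames.

    The mean of each accelerometer axis over all standing frames is compared
    with its nominal quiet-standing value (9.81 m/s^2 vertical, 0 horizontal)
    and the difference is subtracted from the whole axis. Gyroscope channels
    pass through unchanged. Idempotent: a corrected recording has standing
    means exactly at nominal, so re-applying is a no-op.
    """
    if len(standing_intervals) == 0:
        raise ValueError("no standing reference: standing_intervals is empty")
    mask = np.zeros(rec.n_frames, dtype=bool)
    for start, end in standing_intervals:
        if not (0 <= start < end <= rec.n_frames):
            raise ValueError(f"standing interval [{start}, {end}) out of bounds")
        mask[start:end] = True
    out = rec.samples.copy()
    for axis in ACC_AXES:
        col = AXES.index(axis)
        offset = out[mask, col].mean() - NOMINAL_STANDING[axis]
        out[:, col] -= offset
    return ImuRecording(out, rec.sampling_rate_hz)
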