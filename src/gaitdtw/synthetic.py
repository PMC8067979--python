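"""Seeded synthetic 6-axis IMU generator with exact ground truth.

Emulates the structure of free-living lower-back recordings: quasi-periodic
stride waveforms for walking, ascending and descending stairs — each axis a
low-order harmonic mix with per-stride duration and amplitude variability —
interleaved with non-periodic segments (quiet standing on the upright gravity
vector, sitting on a tilted one). The three locomotion classes differ in
stride duration and in their vertical / anterior-posterior amplitude ratios
and harmonic content, deliberately kept similar enough that the classes can
be confused, as they are in real data. The first and last stride of every
locomotion segment is attenuated and shortened, mimicking gait initiation
and termination.

Not modelled: biomechanical detail, sensor drift, magnetometer channels.
Ground-truth labels and per-stride boundary frames are exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import json
import numpy as np
from pathlib import Path
from scipy.spatial.transform import Rotation

from .constants import ACC_AXES, ACTIVITIES, AXES, DEFAULT_SAMPLING_RATE_HZ, GRAVITY_MS2, GYRO_AXES
from .imu_io import ImuRecording, LabelInterval, LabelTrack

__all__ = [
    "Harmonic",
    "ActivityProfile",
    "SimulationConfig",
    "generate_recording",
    "apply_tilt",
    "default_schedule",
]


@dataclass(frozen=True)
class Harmonic:
    """One sinusoidal component: ``amplitude * sin(2*pi*cycles*phase + phase_rad)``."""

    cycles: float
    amplitude: float
    phase_rad: float = 0.0


@dataclass(frozen=True)
class ActivityProfile:
    """Stride-timing distribution and per-axis harmonic shape of one class."""

    stride_duration_mean_s: float
    stride_duration_sd_s: float
    axes: Mapping[str, tuple[Harmonic, ...]]

    def __post_init__(self) -> None:
        if self.stride_duration_mean_s <= 0 or self.stride_duration_sd_s < 0:
            raise ValueError("stride duration mean must be > 0 and sd >= 0")


def _h(*comps: tuple[float, float, float]) -> tuple[Harmonic, ...]:
    return tuple(Harmonic(c, a, p) for c, a, p in comps)


def _default_profiles() -> dict[str, ActivityProfile]:
    """Typical older-adult lower-back signatures of the three classes.

    Walking: ~1.0 s strides, vertical acceleration dominated by the step
    (2/stride) harmonic. Ascending stairs: slower (~1.4 s) strides with a
    stronger anterior-posterior component. Descending stairs: ~1.15 s strides
    with larger vertical impact transients (higher harmonics). Gyroscope
    amplitudes are tens of deg/s, largest about the vertical axis during
    walking (pelvic rotation).
    """
    return {
        "walking": ActivityProfile(
            1.00, 0.05,
            {
                "AccX": _h((1, 0.9, 0.0), (2, 1.1, 1.1)),
                "AccY": _h((1, 1.2, 2.0), (2, 0.4, 0.3)),
                "AccZ": _h((2, 2.6, 0.0), (4, 0.7, 0.9), (1, 0.35, 0.5)),
                "GyroX": _h((1, 18.0, 0.8), (2, 7.0, 0.0)),
                "GyroY": _h((2, 14.0, 1.9), (1, 6.0, 0.2)),
                "GyroZ": _h((1, 28.0, 0.0), (2, 6.0, 2.4)),
            },
        ),
        "ascending_stairs": ActivityProfile(
            1.40, 0.07,
            {
                "AccX": _h((1, 1.8, 0.4), (2, 1.6, 2.2)),
                "AccY": _h((1, 1.5, 1.2), (2, 0.5, 2.8)),
                "AccZ": _h((2, 1.9, 0.7), (1, 0.8, 0.0), (3, 0.5, 1.5)),
                "GyroX": _h((1, 12.0, 0.1), (2, 5.0, 1.0)),
                "GyroY": _h((1, 20.0, 2.6), (2, 9.0, 0.6)),
                "GyroZ": _h((1, 14.0, 1.4)),
            },
        ),
        "descending_stairs": ActivityProfile(
            1.15, 0.06,
            {
                "AccX": _h((1, 1.1, 2.8), (2, 1.3, 0.9)),
                "AccY": _h((1, 1.0, 0.6), (2, 0.6, 1.7)),
                "AccZ": _h((2, 3.4, 1.2), (4, 1.3, 0.3), (6, 0.5, 2.0)),
                "GyroX": _h((1, 10.0, 1.6), (2, 6.0, 2.5)),
                "GyroY": _h((2, 16.0, 0.4), (1, 8.0, 1.1)),
                "GyroZ": _h((1, 19.0, 2.1), (3, 5.0, 0.0)),
            },
        ),
    }


def default_schedule() -> list[tuple[str, float]]:
    """A ~10-minute free-living-style mixed schedule (seconds per segment)."""
    return [
        ("standing", 30), ("walking", 120), ("standing", 20),
        ("ascending_stairs", 45), ("walking", 90), ("sitting", 60),
        ("descending_stairs", 45), ("walking", 60), ("standing", 30),
        ("ascending_stairs", 40), ("descending_stairs", 40), ("sitting", 30),
    ]


@dataclass
class SimulationConfig:
    """Everything the generator needs; deterministic given ``seed``."""

    seed: int = 0
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    schedule: list[tuple[str, float]] = field(default_factory=default_schedule)
    activities: dict[str, ActivityProfile] = field(default_factory=_default_profiles)
    amplitude_jitter_fraction: float = 0.10
    acc_noise_sd: float = 0.30       # m/s^2, locomotion segments
    gyro_noise_sd: float = 3.0       # deg/s, locomotion segments
    static_acc_noise_sd: float = 0.05
    static_gyro_noise_sd: float = 0.5
    edge_stride_amp_scale: float = 0.7   # gait initiation/termination strides
    edge_stride_dur_scale: float = 0.85
    sitting_tilt_deg: float = 20.0
    sensor_tilt_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.schedule:
            raise ValueError("schedule must be non-empty")
        for activity, dur in self.schedule:
            if dur <= 0:
                raise ValueError(f"segment duration must be > 0 ({activity!r}: {dur})")
            if activity not in ACTIVITIES and activity not in {"standing", "sitting"}:
                raise ValueError(f"unknown schedule activity {activity!r}")
        if any(abs(t) > 30 for t in self.sensor_tilt_deg):
            raise ValueError("sensor_tilt_deg components must lie within +-30 degrees")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["schedule"] = [[a, float(s)] for a, s in self.schedule]
        d["activities"] = {
            act: {
                "stride_duration_mean_s": p.stride_duration_mean_s,
                "stride_duration_sd_s": p.stride_duration_sd_s,
                "axes": {ax: [[h.cycles, h.amplitude, h.phase_rad] for h in hs]
                         for ax, hs in p.axes.items()},
            }
            for act, p in self.activities.items()
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        d = json.loads(Path(path).read_text())
        d["schedule"] = [(a, float(s)) for a, s in d["schedule"]]
        d["sensor_tilt_deg"] = tuple(d.get("sensor_tilt_deg", (0.0, 0.0, 0.0)))
        d["activities"] = {
            act: ActivityProfile(
                p["stride_duration_mean_s"], p["stride_duration_sd_s"],
                {ax: _h(*[tuple(c) for c in hs]) for ax, hs in p["axes"].items()},
            )
            for act, p in d["activities"].items()
        }
        return cls(**d)


def _stride_waveform(
    profile: ActivityProfile, n: int, amp_scale: float
) -> dict[str, np.ndarray]:
    phase = np.arange(n) / n
    out: dict[str, np.ndarray] = {}
    for axis in AXES:
        sig = np.zeros(n)
        for h in profile.axes.get(axis, ()):
            sig += h.amplitude * np.sin(2 * np.pi * h.cycles * phase + h.phase_rad)
        out[axis] = amp_scale * sig
    out["AccZ"] = out["AccZ"] + GRAVITY_MS2
    return out


def _locomotion_segment(
    rng: np.random.Generator, cfg: SimulationConfig, activity: str, n_target: int
) -> tuple[np.ndarray, list[int]]:
    """Return (samples (n_target, 6), stride start/end boundaries within segment)."""
    profile = cfg.activities[activity]
    fs = cfg.sampling_rate_hz

    # draw stride durations until the segment is filled
    durations: list[int] = []
    total = 0
    while total < n_target:
        dur_s = rng.normal(profile.stride_duration_mean_s, profile.stride_duration_sd_s)
        dur_s = max(dur_s, 0.4 * profile.stride_duration_mean_s)
        n = max(int(round(dur_s * fs)), 2)
        durations.append(n)
        total += n

    seg = np.zeros((total, len(AXES)))
    boundaries = [0]
    pos = 0
    for k, n in enumerate(durations):
        amp = 1.0 + cfg.amplitude_jitter_fraction * rng.standard_normal()
        amp = max(amp, 0.2)
        n_eff = n
        if k == 0 or k == len(durations) - 1:  # initiation / termination stride
            amp *= cfg.edge_stride_amp_scale
            n_eff = max(int(round(n * cfg.edge_stride_dur_scale)), 2)
        wave = _stride_waveform(profile, n_eff, amp)
        for c, axis in enumerate(AXES):
            seg[pos : pos + n_eff, c] = wave[axis]
        if n_eff < n:
            # shortened edge stride: pad the remainder with its end posture
            seg[pos + n_eff : pos + n, :] = seg[pos + n_eff - 1, :]
        pos += n
        boundaries.append(pos)
    # a final stride cut by the segment border is not a complete stride
    return seg[:n_target], [b for b in boundaries if b <= n_target]


def _static_segment(cfg: SimulationConfig, activity: str, n: int) -> np.ndarray:
    seg = np.zeros((n, len(AXES)))
    if activity == "sitting":
        theta = np.deg2rad(cfg.sitting_tilt_deg)
        gravity = np.array([GRAVITY_MS2 * np.sin(theta), 0.0, GRAVITY_MS2 * np.cos(theta)])
    else:
        gravity = np.array([0.0, 0.0, GRAVITY_MS2])
    seg[:, :3] = gravity
    return seg


def generate_recording(
    config: SimulationConfig,
) -> tuple[ImuRecording, LabelTrack, list[list[int] | None]]:
    """Generate one recording with labels and per-interval stride boundaries.

    Returns ``(recording, labels, boundaries)`` where ``boundaries`` runs
    parallel to ``labels.intervals``: ``None`` for static segments, else the
    global frame indices delimiting complete strides (segment start, each
    subsequent stride start, and the last complete stride's end). Deterministic
    for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate_hz

    chunks: list[np.ndarray] = []
    intervals: list[LabelInterval] = []
    boundaries: list[list[int] | None] = []
    pos = 0
    for activity, dur_s in config.schedule:
        n = int(round(dur_s * fs))
        if activity in ACTIVITIES:
            seg, local_bounds = _locomotion_segment(rng, config, activity, n)
            noise = np.column_stack(
                [rng.normal(0.0, config.acc_noise_sd, n) for _ in ACC_AXES]
                + [rng.normal(0.0, config.gyro_noise_sd, n) for _ in GYRO_AXES]
            )
            boundaries.append([pos + b for b in local_bounds])
        else:
            seg = _static_segment(config, activity, n)
            noise = np.column_stack(
                [rng.normal(0.0, config.static_acc_noise_sd, n) for _ in ACC_AXES]
                + [rng.normal(0.0, config.static_gyro_noise_sd, n) for _ in GYRO_AXES]
            )
            boundaries.append(None)
        chunks.append(seg + noise)
        intervals.append(LabelInterval(activity, pos, pos + n))
        pos += n

    rec = ImuRecording(np.vstack(chunks), fs)
    if any(t != 0.0 for t in config.sensor_tilt_deg):
        rec = apply_tilt(rec, config.sensor_tilt_deg)
    return rec, LabelTrack(tuple(intervals)), boundaries


def apply_tilt(
    rec: ImuRecording, tilt_deg: Sequence[float]
) -> ImuRecording:
    """Rotate the sensor frame by intrinsic x-y-z Euler angles (degrees).

    Models sensor misplacement: both the accelerometer and the gyroscope
    3-vectors are rotated rigidly, frame by frame.
    """
    rot = Rotation.from_euler("xyz", list(tilt_deg), degrees=True)
    out = rec.samples.copy()
    out[:, 0:3] = rot.apply(rec.samples[:, 0:3])
    out[:, 3:6] = rot.apply(rec.samples[:, 3:6])
    return ImuRecording(out, rec.sampling_rate_hz)


def write_simulation(
    config: SimulationConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Generate and write recording/labels/boundaries/config files."""
    from .imu_io import write_labels, write_recording

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec, labels, bounds = generate_recording(config)
    paths = {
        "recording": out / "recording.csv",
        "labels": out / "labels.csv",
        "boundaries": out / "stride_boundaries.json",
        "config": out / "sim_config.json",
    }
    write_recording(rec, paths["recording"])
    write_labels(labels, paths["labels"])
    paths["boundaries"].write_text(json.dumps(bounds, indent=1))
    config.to_json(paths["config"])
    return paths
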