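"""Reference-template construction by DTW barycenter averaging (DBA).

One reference template per locomotion class and per sensor axis is averaged
from a database of single-stride snippets (left heel strike to the next left
heel strike). DBA iteratively aligns every snippet to the current average and
replaces each average sample by the mean of the snippet samples warped onto
it, shrinking the mean DTW distance from the snippet set to the average.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .constants import ACTIVITIES, AXES
from .dtw_core import dtw_align, dtw_distance
from .imu_io import ImuRecording, LabelTrack

__all__ = [
    "StrideSnippet",
    "ActivityTemplate",
    "TemplateSet",
    "extract_snippets",
    "dba_average",
    "build_template_set",
]


@dataclass(frozen=True)
class StrideSnippet:
    """One single-stride waveform on one axis, with provenance."""

    activity: str
    axis: str
    samples: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise ValueError(f"unknown activity {self.activity!r}")
        if self.axis not in AXES:
            raise ValueError(f"unknown axis {self.axis!r}")
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("snippet samples must be non-empty 1-D")
        object.__setattr__(self, "samples", arr)


@dataclass(frozen=True)
class ActivityTemplate:
    """Per-axis reference waveforms of one activity, all of one length."""

    reference_length: int
    axes: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        axes = {a: np.asarray(v, dtype=float) for a, v in self.axes.items()}
        for a, v in axes.items():
            if v.shape != (self.reference_length,):
                raise ValueError(
                    f"axis {a}: template length {v.size} != "
                    f"reference_length {self.reference_length}"
                )
        object.__setattr__(self, "axes", axes)


@dataclass(frozen=True)
class TemplateSet:
    """Reference templates keyed by activity."""

    activities: Mapping[str, ActivityTemplate] = field(default_factory=dict)

    def __getitem__(self, activity: str) -> ActivityTemplate:
        return self.activities[activity]

    def __contains__(self, activity: str) -> bool:
        return activity in self.activities

    def to_json(self, path: str | Path) -> None:
        payload = {
            act: {
                "reference_length": tpl.reference_length,
                "axes": {a: [float(x) for x in v] for a, v in tpl.axes.items()},
            }
            for act, tpl in self.activities.items()
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TemplateSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            {
                act: ActivityTemplate(
                    reference_length=int(entry["reference_length"]),
                    axes={a: np.asarray(v, dtype=float) for a, v in entry["axes"].items()},
                )
                for act, entry in payload.items()
            }
        )


def extract_snippets(
    rec: ImuRecording,
    labels: LabelTrack,
    stride_boundaries: Sequence[Sequence[int] | None],
) -> list[StrideSnippet]:
    """Cut single-stride snippets out of a labelled recording.

    ``stride_boundaries`` runs parallel to ``labels.intervals``: for each
    labelled interval either ``None`` (no strides, e.g. standing) or a
    strictly increasing list of frame indices within the interval; every
    consecutive boundary pair yields one snippet per axis.
    """
    if len(stride_boundaries) != len(labels.intervals):
        raise ValueError(
            f"need one boundary list per interval: "
            f"{len(stride_boundaries)} != {len(labels.intervals)}"
        )
    snippets: list[StrideSnippet] = []
    for k, (iv, bounds) in enumerate(zip(labels.intervals, stride_boundaries)):
        if bounds is None:
            continue
        bounds = [int(b) for b in bounds]
        for b in bounds:
            if not (iv.start_frame <= b <= iv.end_frame):
                raise ValueError(
                    f"stride boundary {b} outside interval "
                    f"[{iv.start_frame}, {iv.end_frame}) of {iv.activity!r}"
                )
        if any(b1 <= b0 for b0, b1 in zip(bounds, bounds[1:])):
            raise ValueError(f"stride boundaries of interval {k} are not increasing")
        for b0, b1 in zip(bounds, bounds[1:]):
            for axis in AXES:
                snippets.append(
                    StrideSnippet(
                        activity=iv.activity,
                        axis=axis,
                        samples=rec.channel(axis)[b0:b1].copy(),
                        source=f"interval[{k}]:{b0}-{b1}",
                    )
                )
    return snippets


def _resample(seq: np.ndarray, length: int) -> np.ndarray:
    if seq.size == length:
        return seq.copy()
    old = np.linspace(0.0, 1.0, seq.size)
    new = np.linspace(0.0, 1.0, length)
    return np.interp(new, old, seq)


def _medoid(seqs: list[np.ndarray]) -> int:
    if len(seqs) == 1:
        return 0
    totals = np.zeros(len(seqs))
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            d = dtw_distance(seqs[i], seqs[j])
            totals[i] += d
            totals[j] += d
    return int(np.argmin(totals))  # first index on ties


def dba_average(
    snippets: Sequence[Sequence[float]],
    target_length: int,
    max_iters: int = 30,
    tol: float = 1e-6,
    return_history: bool = False,
) -> np.ndarray | tuple[np.ndarray, list[float]]:
    """DTW barycenter average of a set of 1-D sequences.

    Initialised with the medoid snippet (smallest summed DTW distance to the
    rest; first index on ties) linearly resampled to ``target_length``, so the
    procedure is fully deterministic. Each iteration aligns every snippet to
    the current average and replaces every average sample by the mean of the
    snippet samples aligned to it. Iteration stops when the mean DTW distance
    improves by less than ``tol``; an iterate that fails to improve is
    discarded, so the objective history is non-increasing.

    With ``return_history=True`` also returns the mean DTW distance of each
    accepted average, in iteration order.
    """
    seqs = [np.asarray(s, dtype=float) for s in snippets]
    if len(seqs) == 0:
        raise ValueError("dba_average requires at least one snippet")
    if any(s.ndim != 1 or s.size == 0 for s in seqs):
        raise ValueError("all snippets must be non-empty 1-D sequences")
    if target_length < 2:
        raise ValueError("target_length must be >= 2")

    average = _resample(seqs[_medoid(seqs)], target_length)
    history: list[float] = []
    prev_obj = np.inf
    prev_average = average
    for _ in range(max_iters):
        sums = np.zeros(target_length)
        counts = np.zeros(target_length)
        total = 0.0
        for s in seqs:
            align = dtw_align(s, average)
            total += align.distance
            np.add.at(sums, align.path[:, 1], s[align.path[:, 0]])
            np.add.at(counts, align.path[:, 1], 1.0)
        obj = total / len(seqs)
        if obj > prev_obj:  # mean update overshot: keep the best average seen
            average = prev_average
            break
        history.append(obj)
        if prev_obj - obj < tol:
            break
        prev_obj, prev_average = obj, average
        average = sums / counts  # every template index lies on some path
    if return_history:
        return average, history
    return average


def build_template_set(
    snippets: Sequence[StrideSnippet],
    length_rule: str = "median",
    max_iters: int = 30,
    tol: float = 1e-6,
) -> TemplateSet:
    """Build per-activity, per-axis reference templates from stride snippets.

    The reference length of an activity is the median stride length of its
    snippets (rounded to the nearest integer) — robust to outlier strides.
    Every required ``(activity, axis)`` pair must be represented.
    """
    if length_rule != "median":
        raise ValueError(f"unsupported length_rule {length_rule!r}")
    by_act: dict[str, dict[str, list[np.ndarray]]] = {}
    for sn in snippets:
        by_act.setdefault(sn.activity, {}).setdefault(sn.axis, []).append(sn.samples)

    templates: dict[str, ActivityTemplate] = {}
    for activity, by_axis in by_act.items():
        missing = [a for a in AXES if a not in by_axis]
        if missing:
            raise ValueError(
                f"activity {activity!r}: no snippets for axis "
                f"{', '.join(missing)}"
            )
        # stride lengths are axis-independent; use one axis's multiset
        lengths = [s.size for s in by_axis[AXES[0]]]
        ref_len = int(round(statistics.median(lengths)))
        axes = {
            axis: dba_average(by_axis[axis], ref_len, max_iters=max_iters, tol=tol)
            for axis in AXES
        }
        templates[activity] = ActivityTemplate(reference_length=ref_len, axes=axes)
    return TemplateSet(templates)
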