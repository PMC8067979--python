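"""Two-layer locomotion recognition.

Layer 1 slides a window of 1.5 template lengths along each used axis,
trims every window to its best-matching section via stretch-region
refinement, and assigns that section's accumulated DTW distance (ED) to each
of its frames; gaps between sections are re-examined or filled so every frame
carries an ED, the smallest ED always winning on overlap.

Layer 2 converts each frame's ED into a per-axis probability

    P = 101 - 101 ** (ED / threshold_maxED)      (0 for ED >= threshold),

combines the used axes by a weighted mean (vertical accelerometer counted
double for walking; overall P forced to 0 when >= 3 axes read 0), penalises
matched sections shorter than half the reference length by the factor
f = 2 * section_length / reference_length, and labels every frame with the
arg-max activity — or ``no_selected_activity`` when no class scores above 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .constants import ACTIVITIES, AXES, NO_ACTIVITY
from .dtw_core import refine_and_score, dtw_distance
from .imu_io import ImuRecording
from .template import StrideSnippet, TemplateSet

__all__ = [
    "ThresholdTable",
    "AxisConfig",
    "RecognitionConfig",
    "FrameScores",
    "sliding_match",
    "frame_probability",
    "combine_axes",
    "length_penalty",
    "classify",
    "recognize",
    "calibrate_thresholds",
]

#: Maximum acceptable accumulated DTW distance per (activity, axis), tuned on
#: the reference population's 100 Hz lower-back recordings. Valid only for
#: signals in m/s^2 / deg/s at 100 Hz with the canonical axis convention.
DEFAULT_THRESHOLDS: dict[str, dict[str, float]] = {
    "walking": {"AccX": 120, "AccY": 70, "AccZ": 80, "GyroX": 13, "GyroY": 12, "GyroZ": 21},
    "ascending_stairs": {"AccX": 110, "AccY": 110, "AccZ": 120, "GyroX": 14, "GyroY": 14, "GyroZ": 20},
    "descending_stairs": {"AccX": 110, "AccY": 90, "AccZ": 120, "GyroX": 14, "GyroY": 11, "GyroZ": 25},
}

#: Axes used per activity. The vertical and anterior-posterior accelerometer
#: axes carry the dominant pattern and are used everywhere; the vertical axis
#: is weighted double for walking, where it is the strongest single predictor.
DEFAULT_AXES: dict[str, dict] = {
    "walking": {"used": ["AccX", "AccZ", "GyroX", "GyroY", "GyroZ"], "weights": {"AccZ": 2.0}},
    "ascending_stairs": {"used": ["AccX", "AccY", "AccZ", "GyroY"], "weights": {}},
    "descending_stairs": {"used": ["AccX", "AccY", "AccZ", "GyroY", "GyroZ"], "weights": {}},
}

ThresholdTable = Mapping[str, Mapping[str, float]]


@dataclass(frozen=True)
class AxisConfig:
    """Axes and weights used to combine per-axis probabilities for one activity."""

    used: tuple[str, ...]
    weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [a for a in self.used if a not in AXES]
        if unknown:
            raise ValueError(f"unknown axis name(s): {', '.join(unknown)}")
        if not self.used:
            raise ValueError("used axes must be non-empty")
        object.__setattr__(self, "used", tuple(self.used))
        object.__setattr__(self, "weights", dict(self.weights))

    def weight(self, axis: str) -> float:
        return float(self.weights.get(axis, 1.0))


@dataclass
class RecognitionConfig:
    """All tunables of the two-layer recogniser, defaulting to the reference
    configuration for 100 Hz lower-back signals."""

    thresholds: dict[str, dict[str, float]] = field(
        default_factory=lambda: {a: dict(t) for a, t in DEFAULT_THRESHOLDS.items()}
    )
    axes: dict[str, AxisConfig] = field(
        default_factory=lambda: {
            a: AxisConfig(tuple(c["used"]), dict(c["weights"])) for a, c in DEFAULT_AXES.items()
        }
    )
    window_factor: float = 1.5
    overlap_fraction: float = 0.25
    stretch_min_fraction: float = 0.10
    min_window_fraction: float = 0.40
    gap_fill_fraction: float = 0.25   # gaps shorter than this x reference: copy neighbours
    gap_rescan_fraction: float = 0.75  # gaps up to this x reference: one refinement pass
    zero_axes_cutoff: int = 3
    length_cutoff_fraction: float = 0.5

    def __post_init__(self) -> None:
        for activity, cfg in self.axes.items():
            if not isinstance(cfg, AxisConfig):
                cfg = AxisConfig(tuple(cfg["used"]), dict(cfg.get("weights", {})))
                self.axes[activity] = cfg
            thr = self.thresholds.get(activity, {})
            missing = [a for a in cfg.used if a not in thr]
            if missing:
                raise ValueError(
                    f"activity {activity!r}: no threshold for axis {', '.join(missing)}"
                )
            if any(thr[a] <= 0 for a in cfg.used):
                raise ValueError(f"activity {activity!r}: thresholds must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["axes"] = {
            a: {"used": list(c.used), "weights": dict(c.weights)} for a, c in self.axes.items()
        }
        return d

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() in {".yml", ".yaml"}:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_file(cls, path: str | Path) -> "RecognitionConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix.lower() in {".yml", ".yaml"} else json.loads(text)
        axes = {
            a: AxisConfig(tuple(c["used"]), dict(c.get("weights", {})))
            for a, c in data.pop("axes", DEFAULT_AXES).items()
        }
        thresholds = {
            a: {ax: float(v) for ax, v in t.items()}
            for a, t in data.pop("thresholds", DEFAULT_THRESHOLDS).items()
        }
        return cls(thresholds=thresholds, axes=axes, **data)


@dataclass(frozen=True)
class FrameScores:
    """Per-frame scores of one recognition run.

    ``ed`` and ``p_axis`` are keyed ``(activity, axis)``; ``p_overall`` and
    ``section_length`` are keyed by activity; ``labels`` holds the final
    per-frame decision.
    """

    n_frames: int
    ed: Mapping[tuple[str, str], np.ndarray]
    p_axis: Mapping[tuple[str, str], np.ndarray]
    p_overall: Mapping[str, np.ndarray]
    section_length: Mapping[str, np.ndarray]
    labels: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        short = {"walking": "walking", "ascending_stairs": "ascending", "descending_stairs": "descending"}
        data: dict[str, object] = {"frame": np.arange(self.n_frames), "label": self.labels}
        for act in ACTIVITIES:
            if act in self.p_overall:
                data[f"p_{short[act]}"] = self.p_overall[act]
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _assign(ed: np.ndarray, seclen: np.ndarray, start: int, end: int, d: float, length: int) -> None:
    """Assign one matched section; on overlap the smaller ED always wins."""
    sl = slice(start, end)
    better = d < ed[sl]
    ed[sl][better] = d
    seclen[sl][better] = length


def _sweep(
    signal: np.ndarray,
    template: np.ndarray,
    ed: np.ndarray,
    seclen: np.ndarray,
    start: int,
    end: int,
    window_len: int,
    overlap: int,
    stretch_min_fraction: float,
    min_window_fraction: float,
) -> None:
    pos = start
    while pos < end:
        w = signal[pos : min(pos + window_len, end)]
        bs, be, d = refine_and_score(
            w, template,
            min_window_fraction=min_window_fraction,
            stretch_min_fraction=stretch_min_fraction,
        )
        _assign(ed, seclen, pos + bs, pos + be, d, be - bs)
        nxt = pos + be - overlap
        pos = nxt if nxt > pos else pos + max(1, window_len - overlap)


def sliding_match(
    signal_axis: Sequence[float],
    template_axis: Sequence[float],
    window_factor: float = 1.5,
    overlap_fraction: float = 0.25,
    stretch_min_fraction: float = 0.10,
    min_window_fraction: float = 0.40,
    gap_fill_fraction: float = 0.25,
    gap_rescan_fraction: float = 0.75,
) -> tuple[np.ndarray, np.ndarray]:
    """Layer-1 matching of one axis against one template.

    Returns ``(ed, section_length)`` arrays over all signal frames. Windows of
    ``window_factor`` template lengths are refined to their best section; the
    next window starts ``overlap_fraction`` of a template length before the
    previous section's end. Remaining gaps are handled by length: short gaps
    (< ``gap_fill_fraction`` x reference) inherit the better bordering
    section's values, medium gaps get one refinement pass, long gaps
    (> ``gap_rescan_fraction`` x reference) re-enter the sliding loop.
    """
    signal = np.asarray(signal_axis, dtype=float)
    template = np.asarray(template_axis, dtype=float)
    if signal.ndim != 1 or signal.size == 0:
        raise ValueError("signal must be non-empty 1-D")
    n = signal.size
    L = template.size
    window_len = max(2, int(round(window_factor * L)))
    overlap = int(round(overlap_fraction * L))

    ed = np.full(n, np.inf)
    seclen = np.zeros(n, dtype=int)
    _sweep(signal, template, ed, seclen, 0, n, window_len, overlap,
           stretch_min_fraction, min_window_fraction)

    for _ in range(10):  # gap handling converges quickly; bounded for safety
        if not np.any(np.isinf(ed)):
            break
        gaps = _unassigned_runs(ed)
        for gs, ge in gaps:
            glen = ge - gs
            if glen < gap_fill_fraction * L:
                _fill_gap_from_borders(ed, seclen, gs, ge)
            elif glen <= gap_rescan_fraction * L:
                bs, be, d = refine_and_score(
                    signal[gs:ge], template,
                    min_window_fraction=min_window_fraction,
                    stretch_min_fraction=stretch_min_fraction,
                )
                _assign(ed, seclen, gs + bs, gs + be, d, be - bs)
            else:
                _sweep(signal, template, ed, seclen, gs, ge, window_len, overlap,
                       stretch_min_fraction, min_window_fraction)
    # safety net: any frame still unassigned inherits its nearest section
    if np.any(np.isinf(ed)):
        for gs, ge in _unassigned_runs(ed):
            _fill_gap_from_borders(ed, seclen, gs, ge)
    return ed, seclen


def _unassigned_runs(ed: np.ndarray) -> list[tuple[int, int]]:
    un = np.isinf(ed)
    edges = np.flatnonzero(np.diff(np.concatenate(([False], un, [False])).astype(int)))
    return [(int(edges[k]), int(edges[k + 1])) for k in range(0, len(edges), 2)]


def _fill_gap_from_borders(ed: np.ndarray, seclen: np.ndarray, gs: int, ge: int) -> None:
    left = (ed[gs - 1], seclen[gs - 1]) if gs > 0 else (np.inf, 0)
    right = (ed[ge], seclen[ge]) if ge < ed.size else (np.inf, 0)
    best = left if left[0] <= right[0] else right
    ed[gs:ge] = best[0]
    seclen[gs:ge] = best[1]


def frame_probability(ed, threshold: float):
    """Map an accumulated DTW distance to a probability in [0, 100].

    ``P = 101 - 101 ** (ed / threshold)`` for ``ed < threshold`` and 0
    otherwise: a perfect match (ed = 0) scores exactly 100 and the score
    decays strictly (and increasingly steeply) to 0 at the threshold.
    Accepts scalars or arrays.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    arr = np.asarray(ed, dtype=float)
    if np.any(arr < 0):
        raise ValueError("ed must be non-negative")
    with np.errstate(over="ignore"):
        p = np.where(arr < threshold, 101.0 - np.power(101.0, np.minimum(arr, threshold) / threshold), 0.0)
    return float(p) if np.isscalar(ed) or arr.ndim == 0 else p


def combine_axes(
    p_axis: Mapping[str, float], config: AxisConfig, zero_axes_cutoff: int = 3
) -> float:
    """Combine per-axis probabilities into one activity probability.

    Weighted arithmetic mean of the used axes; if at least
    ``zero_axes_cutoff`` axes read zero, the combined probability is zero
    outright (too many axes vetoing the activity).
    """
    missing = [a for a in config.used if a not in p_axis]
    if missing:
        raise ValueError(f"missing probability for axis {', '.join(missing)}")
    values = np.array([p_axis[a] for a in config.used], dtype=float)
    if int(np.sum(values == 0.0)) >= zero_axes_cutoff:
        return 0.0
    weights = np.array([config.weight(a) for a in config.used])
    return float(np.sum(weights * values) / np.sum(weights))


def length_penalty(
    p, section_length, reference_length: int, cutoff_fraction: float = 0.5
):
    """Down-weight matches much shorter than a reference stride.

    Sections shorter than ``cutoff_fraction`` of the reference length scale
    the probability by ``f = 2 * section_length / reference_length`` (a
    regular stride in under half the reference time is implausible). Output
    clamped to [0, 100]. Accepts scalars or arrays.
    """
    if reference_length <= 0:
        raise ValueError("reference_length must be positive")
    p_arr = np.asarray(p, dtype=float)
    sl = np.asarray(section_length, dtype=float)
    factor = np.where(sl < cutoff_fraction * reference_length, 2.0 * sl / reference_length, 1.0)
    out = np.clip(p_arr * factor, 0.0, 100.0)
    return float(out) if p_arr.ndim == 0 else out


def classify(
    p_overall: Mapping[str, np.ndarray], order: Sequence[str] = ACTIVITIES
) -> np.ndarray:
    """Per-frame arg-max over activity probabilities.

    Ties are broken by the fixed activity order; frames where every activity
    scores 0 are labelled ``no_selected_activity``.
    """
    acts = [a for a in order if a in p_overall]
    if not acts:
        raise ValueError("p_overall is empty")
    stacked = np.vstack([np.asarray(p_overall[a], dtype=float) for a in acts])
    winner = np.argmax(stacked, axis=0)  # first max wins -> fixed-order tie-break
    labels = np.array([acts[k] for k in winner], dtype=object)
    labels[stacked.max(axis=0) <= 0.0] = NO_ACTIVITY
    return labels


def recognize(
    rec: ImuRecording,
    templates: TemplateSet,
    config: RecognitionConfig | None = None,
) -> FrameScores:
    """Run the full two-layer recognition over a preprocessed recording."""
    if config is None:
        config = RecognitionConfig()
    n = rec.n_frames
    ed_map: dict[tuple[str, str], np.ndarray] = {}
    p_map: dict[tuple[str, str], np.ndarray] = {}
    p_overall: dict[str, np.ndarray] = {}
    sec_map: dict[str, np.ndarray] = {}

    for activity, axis_cfg in config.axes.items():
        if activity not in templates:
            raise ValueError(f"no template for activity {activity!r}")
        tpl = templates[activity]
        p_rows = []
        sec_rows = []
        for axis in axis_cfg.used:
            ed, seclen = sliding_match(
                rec.channel(axis),
                tpl.axes[axis],
                window_factor=config.window_factor,
                overlap_fraction=config.overlap_fraction,
                stretch_min_fraction=config.stretch_min_fraction,
                min_window_fraction=config.min_window_fraction,
                gap_fill_fraction=config.gap_fill_fraction,
                gap_rescan_fraction=config.gap_rescan_fraction,
            )
            p = frame_probability(ed, config.thresholds[activity][axis])
            ed_map[(activity, axis)] = ed
            p_map[(activity, axis)] = p
            p_rows.append(p)
            sec_rows.append(seclen)
        p_mat = np.vstack(p_rows)
        weights = np.array([axis_cfg.weight(a) for a in axis_cfg.used])[:, None]
        combined = np.sum(weights * p_mat, axis=0) / np.sum(weights)
        combined[np.sum(p_mat == 0.0, axis=0) >= config.zero_axes_cutoff] = 0.0
        # one section length per activity: the median over its axes' matches
        section = np.median(np.vstack(sec_rows), axis=0)
        p_overall[activity] = length_penalty(
            combined, section, tpl.reference_length, config.length_cutoff_fraction
        )
        sec_map[activity] = section

    labels = classify(p_overall)
    return FrameScores(
        n_frames=n, ed=ed_map, p_axis=p_map, p_overall=p_overall,
        section_length=sec_map, labels=labels,
    )


def calibrate_thresholds(
    templates: TemplateSet,
    snippets: Sequence[StrideSnippet],
    percentile: float = 95.0,
) -> dict[str, dict[str, float]]:
    """Derive maximum-acceptable-ED thresholds from a stride database.

    For every (activity, axis), aligns each stride snippet to the reference
    template and takes the given percentile of the within-class accumulated
    distances. Useful whenever the default table does not apply (different
    population, units or simulated signals).
    """
    dists: dict[tuple[str, str], list[float]] = {}
    for sn in snippets:
        if sn.activity not in templates:
            continue
        tpl = templates[sn.activity]
        dists.setdefault((sn.activity, sn.axis), []).append(
            dtw_distance(sn.samples, tpl.axes[sn.axis])
        )
    out: dict[str, dict[str, float]] = {}
    for (activity, axis), values in dists.items():
        thr = float(np.percentile(values, percentile))
        out.setdefault(activity, {})[axis] = max(thr, 1e-9)  # keep positive
    return out
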