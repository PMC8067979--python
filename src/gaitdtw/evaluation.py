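"""Frame-level evaluation of predicted locomotion labels against a gold track.

Builds a confusion matrix (performed activity x recognised activity, counts
and row percentages) and per-activity one-vs-rest sensitivity and
specificity. Gold labels outside the three locomotion classes act as
negatives only; configurable labels (by default ``undefined`` and
``walking with transition``) are excluded from all counts, as is every frame
not covered by a gold interval. The first/last second of each locomotion
period can be excluded to ignore gait initiation/termination strides.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import ACTIVITIES, NO_ACTIVITY
from .imu_io import LabelInterval, LabelTrack

__all__ = ["ConfusionMatrix", "evaluate", "exclude_boundary_frames"]

DEFAULT_EXCLUDED_LABELS = frozenset({"undefined", "walking with transition"})

#: Row label aggregating all evaluable non-locomotion gold frames.
OTHERS_ROW = "others"


@dataclass(frozen=True)
class ConfusionMatrix:
    """Frame-count confusion matrix plus derived per-activity metrics.

    ``counts`` rows are the performed (gold) classes — the three locomotion
    classes plus an ``others`` row for evaluable non-locomotion frames;
    columns are the recognised classes plus ``no_selected_activity``.
    ``sensitivity``/``specificity`` are percentages per locomotion class
    (``nan`` where undefined). ``empty`` flags the degenerate no-evaluable-
    frames case.
    """

    counts: pd.DataFrame
    row_percent: pd.DataFrame
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    n_evaluable: int

    @property
    def empty(self) -> bool:
        return self.n_evaluable == 0

    def to_text(self) -> str:
        lines = ["Confusion matrix (row %):", self.row_percent.round(1).to_string(), ""]
        if self.empty:
            lines.append("no evaluable frames")
        for act in ACTIVITIES:
            lines.append(
                f"{act}: sensitivity {self.sensitivity[act]:.1f}%  "
                f"specificity {self.specificity[act]:.1f}%"
            )
        return "\n".join(lines)

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.counts.to_csv(f"{prefix}_counts.csv")
        self.row_percent.to_csv(f"{prefix}_row_percent.csv")
        Path(f"{prefix}_summary.txt").write_text(self.to_text() + "\n")


def evaluate(
    predicted: Sequence[str],
    gold: LabelTrack,
    excluded_labels: Iterable[str] = DEFAULT_EXCLUDED_LABELS,
) -> ConfusionMatrix:
    """Score per-frame predictions against a gold label track.

    ``predicted`` must cover the whole recording (one label per frame, each a
    locomotion class or ``no_selected_activity``). Only frames covered by a
    gold interval whose label is not excluded are counted. For each
    locomotion class, one-vs-rest at frame level: a frame is a true positive
    when prediction and gold agree on that class; every evaluable frame whose
    gold label differs is a negative for it.
    """
    predicted = np.asarray(predicted, dtype=object)
    n = predicted.size
    excluded = set(excluded_labels)
    gold_frames = gold.frame_labels(n, fill="")

    evaluable = (gold_frames != "") & ~np.isin(gold_frames, sorted(excluded))
    g = gold_frames[evaluable]
    p = predicted[evaluable]
    n_eval = int(evaluable.sum())

    g_rows = np.where(np.isin(g, ACTIVITIES), g, OTHERS_ROW)
    rows = list(ACTIVITIES) + [OTHERS_ROW]
    cols = list(ACTIVITIES) + [NO_ACTIVITY]
    counts = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for row in rows:
        sel = p[g_rows == row]
        for col in cols:
            counts.loc[row, col] = int(np.sum(sel == col))
        # any stray prediction label outside the vocabulary counts as none
        counts.loc[row, NO_ACTIVITY] += int(np.sum(~np.isin(sel, cols)))

    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        row_percent = counts.div(totals.replace(0, np.nan), axis=0) * 100.0

    sensitivity: dict[str, float] = {}
    specificity: dict[str, float] = {}
    for act in ACTIVITIES:
        tp = int(np.sum((g_rows == act) & (p == act)))
        fn = int(np.sum((g_rows == act) & (p != act)))
        fp = int(np.sum((g_rows != act) & (p == act)))
        tn = int(np.sum((g_rows != act) & (p != act)))
        sensitivity[act] = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
        specificity[act] = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")

    return ConfusionMatrix(
        counts=counts,
        row_percent=row_percent,
        sensitivity=sensitivity,
        specificity=specificity,
        n_evaluable=n_eval,
    )


def exclude_boundary_frames(
    gold: LabelTrack,
    n_frames: int = 100,
    activities: Iterable[str] = ACTIVITIES,
) -> LabelTrack:
    """Shrink locomotion intervals by ``n_frames`` (1 s at 100 Hz) per side.

    Gait initiation and termination strides differ from steady-state strides;
    trimming them from the gold track removes the trimmed frames from the
    evaluation entirely. Intervals of at most ``2 * n_frames`` disappear;
    non-locomotion intervals are untouched.
    """
    if n_frames < 0:
        raise ValueError("n_frames must be >= 0")
    acts = set(activities)
    out: list[LabelInterval] = []
    for iv in gold.intervals:
        if iv.activity in acts:
            start, end = iv.start_frame + n_frames, iv.end_frame - n_frames
            if end - start <= 0:
                continue
            out.append(LabelInterval(iv.activity, start, end))
        else:
            out.append(iv)
    return LabelTrack(tuple(out))
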