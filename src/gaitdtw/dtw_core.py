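"""Dynamic time warping primitives: alignment, stretch regions, window refinement.

DTW aligns a query snippet to a reference template by a monotone warping path
through the local-cost grid; the accumulated cost along the optimal path (the
sum of absolute sample differences, the "Euclidean distance" of the matching
layer) is the similarity measure every downstream decision is based on.

Runs in the path where one template frame absorbs many query frames
("stretched areas") indicate a locally poor fit; their borders are used to
trim a sliding window down to the best-matching section.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

__all__ = [
    "WarpAlignment",
    "StretchRegion",
    "dtw_align",
    "dtw_distance",
    "find_stretch_regions",
    "refine_and_score",
]


@dataclass(frozen=True)
class WarpAlignment:
    """Optimal warping path and its accumulated cost.

    ``path`` has shape ``(L, 2)``; column 0 is the query index ``i``, column 1
    the template index ``j``. The path starts at ``(0, 0)``, ends at
    ``(n-1, m-1)`` and each step increments ``i``, ``j`` or both by one.
    ``distance`` is the sum of ``|query[i] - template[j]|`` over all pairs.
    """

    path: np.ndarray
    distance: float


@dataclass(frozen=True)
class StretchRegion:
    """Maximal run of query frames aligned to a single template frame.

    ``[start_query, end_query)`` is half-open; ``length_frames`` is the number
    of query frames absorbed by the repeated template frame.
    """

    side: str
    start_query: int
    end_query: int
    length_frames: int


@njit(cache=True)
def _acc_cost(q, t):  # pragma: no cover - numba
    n, m = q.shape[0], t.shape[0]
    acc = np.empty((n, m))
    acc[0, 0] = abs(q[0] - t[0])
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + abs(q[0] - t[j])
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + abs(q[i] - t[0])
        for j in range(1, m):
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = best + abs(q[i] - t[j])
    return acc


@njit(cache=True)
def _backtrack(acc):  # pragma: no cover - numba
    n, m = acc.shape
    path = np.empty((n + m - 1, 2), dtype=np.int64)
    i, j = n - 1, m - 1
    k = path.shape[0] - 1
    path[k, 0] = i
    path[k, 1] = j
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            d = acc[i - 1, j - 1]
            u = acc[i - 1, j]
            l = acc[i, j - 1]
            # tie-break: diagonal, then query-advance, then template-advance
            if d <= u and d <= l:
                i -= 1
                j -= 1
            elif u <= l:
                i -= 1
            else:
                j -= 1
        k -= 1
        path[k, 0] = i
        path[k, 1] = j
    return path[k:]


@njit(cache=True)
def _distance_only(q, t):  # pragma: no cover - numba
    n, m = q.shape[0], t.shape[0]
    prev = np.empty(m)
    cur = np.empty(m)
    prev[0] = abs(q[0] - t[0])
    for j in range(1, m):
        prev[j] = prev[j - 1] + abs(q[0] - t[j])
    for i in range(1, n):
        cur[0] = prev[0] + abs(q[i] - t[0])
        for j in range(1, m):
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = best + abs(q[i] - t[j])
        prev, cur = cur, prev
    return prev[m - 1]


def _as_1d(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D sequence")
    return arr


def dtw_align(query: Sequence[float], template: Sequence[float]) -> WarpAlignment:
    """Globally optimal DTW alignment of two scalar sequences.

    Local cost is the absolute sample difference; allowed steps are
    ``(i+1, j)``, ``(i, j+1)`` and ``(i+1, j+1)`` with no slope constraint.
    The returned distance is the raw accumulated cost (not length-normalised).
    Equal-cost predecessors are resolved deterministically: diagonal first,
    then query-advance, then template-advance.
    """
    q = _as_1d(query, "query")
    t = _as_1d(template, "template")
    acc = _acc_cost(q, t)
    path = _backtrack(acc)
    return WarpAlignment(path=path, distance=float(acc[-1, -1]))


def dtw_distance(query: Sequence[float], template: Sequence[float]) -> float:
    """DTW distance only (two-row DP, no path) — used for bulk comparisons."""
    q = _as_1d(query, "query")
    t = _as_1d(template, "template")
    return float(_distance_only(q, t))


def find_stretch_regions(
    align: WarpAlignment, template_length: int, min_fraction: float = 0.10
) -> list[StretchRegion]:
    """Locate template frames repeated against long runs of query frames.

    Only runs of at least ``ceil(min_fraction * template_length)`` query
    frames are reported (shorter repetitions are ordinary warping); regions
    are returned in query-index order.
    """
    if not (0.0 < min_fraction < 1.0):
        raise ValueError("min_fraction must be in (0, 1)")
    min_len = math.ceil(min_fraction * template_length)
    path = align.path
    regions: list[StretchRegion] = []
    start = 0
    for k in range(1, len(path) + 1):
        if k == len(path) or path[k, 1] != path[start, 1]:
            run = k - start
            if run >= min_len:
                regions.append(
                    StretchRegion(
                        side="template",
                        start_query=int(path[start, 0]),
                        end_query=int(path[k - 1, 0]) + 1,
                        length_frames=run,
                    )
                )
            start = k
    return regions


def refine_and_score(
    window: Sequence[float],
    template: Sequence[float],
    min_window_fraction: float = 0.40,
    stretch_min_fraction: float = 0.10,
) -> tuple[int, int, float]:
    """Find the best-matching section of ``window`` against ``template``.

    The window is first aligned whole; the borders of stretched path regions
    then propose trimmed sub-windows (every pair of proposed borders is a
    candidate). Because surplus frames sit at the window borders by
    construction, the two template-length sections flush with either window
    border are always evaluated as well — warping an extra quasi-periodic
    cycle can spread its cost so evenly that no single stretch run crosses
    the detection size. Candidates shorter than ``min_window_fraction`` of
    the template are rejected — genuinely shorter strides are implausible.
    Each surviving candidate is re-aligned and the smallest accumulated
    distance wins (ties: earliest start, then shortest section). Returns
    ``(start, end, distance)`` with window-relative half-open borders; the
    untrimmed window is always a candidate, so the result never scores worse
    than the full window.
    """
    w = _as_1d(window, "window")
    t = _as_1d(template, "template")
    base = dtw_align(w, t)
    n = w.size
    regions = find_stretch_regions(base, t.size, stretch_min_fraction)

    borders = {0, n}
    for r in regions:
        borders.add(r.start_query)
        borders.add(r.end_query)
    border_list = sorted(borders)

    candidates = {
        (s, e)
        for a_idx, s in enumerate(border_list)
        for e in border_list[a_idx + 1 :]
    }
    if n > t.size:  # border-anchored template-length sections
        candidates.add((0, t.size))
        candidates.add((n - t.size, n))

    min_len = min_window_fraction * t.size
    best = (base.distance, 0, n)  # (distance, start, length) sort key
    for s, e in sorted(candidates):
        if s == 0 and e == n:
            continue
        if (e - s) < min_len:
            continue
        d = dtw_distance(w[s:e], t)
        key = (d, s, e - s)
        if key < best:
            best = key
    return best[1], best[1] + best[2], best[0]
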