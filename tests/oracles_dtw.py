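"""Independent DTW oracles used only by tests.

Two deliberately naive formulations, kept separate from the package's DP
implementation: literal enumeration of every monotone boundary-respecting
warping path (exponential; tiny inputs only), and a top-down memoized
minimum-cost recursion (lengths up to ~10).
"""

from __future__ import annotations

from functools import lru_cache


def min_cost_by_path_enumeration(q, t) -> float:
    """Minimum accumulated |q[i]-t[j]| over ALL monotone paths, by brute force."""
    n, m = len(q), len(t)
    best = [float("inf")]

    def walk(i: int, j: int, cost: float) -> None:
        cost += abs(q[i] - t[j])
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cost)
        if i + 1 < n:
            walk(i + 1, j, cost)
        if j + 1 < m:
            walk(i, j + 1, cost)

    walk(0, 0, 0.0)
    return best[0]


def min_cost_by_recursion(q, t) -> float:
    """Minimum accumulated cost via top-down recursion with memoisation."""
    q = tuple(q)
    t = tuple(t)

    @lru_cache(maxsize=None)
    def f(i: int, j: int) -> float:
        c = abs(q[i] - t[j])
        if i == 0 and j == 0:
            return c
        options = []
        if i > 0 and j > 0:
            options.append(f(i - 1, j - 1))
        if i > 0:
            options.append(f(i - 1, j))
        if j > 0:
            options.append(f(i, j - 1))
        return c + min(options)

    return f(len(q) - 1, len(t) - 1)
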