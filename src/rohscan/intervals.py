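"""Half-open genomic interval arithmetic on (start, end) integer arrays.

All functions operate on intervals of one chromosome at a time; callers
group by chromosome. Intervals are 0-based half-open, as everywhere in
this package.
"""

from __future__ import annotations

import numpy as np


def _as_arrays(intervals) -> tuple[np.ndarray, np.ndarray]:
    if len(intervals) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    arr = np.asarray(intervals, dtype=np.int64)
    return arr[:, 0], arr[:, 1]


def merge(intervals) -> list[tuple[int, int]]:
    """Sort and merge overlapping or adjacent intervals."""
    starts, ends = _as_arrays(intervals)
    if starts.size == 0:
        return []
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out: list[tuple[int, int]] = []
    cur_s, cur_e = int(starts[0]), int(ends[0])
    for s, e in zip(starts[1:], ends[1:]):
        if s <= cur_e:
            cur_e = max(cur_e, int(e))
        else:
            out.append((cur_s, cur_e))
            cur_s, cur_e = int(s), int(e)
    out.append((cur_s, cur_e))
    return out


def intersect(a, b) -> list[tuple[int, int]]:
    """Base-pair intersection of two interval sets (each merged first)."""
    a = merge(a)
    b = merge(b)
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def intersect_many(sets) -> list[tuple[int, int]]:
    """Intersection across an arbitrary number of interval sets."""
    sets = list(sets)
    if not sets:
        return []
    acc = merge(sets[0])
    for s in sets[1:]:
        acc = intersect(acc, s)
        if not acc:
            break
    return acc


def subtract(a, b) -> list[tuple[int, int]]:
    """Parts of `a` not covered by `b`."""
    a = merge(a)
    b = merge(b)
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            if b[k][0] > cur:
                out.append((cur, b[k][0]))
            cur = max(cur, b[k][1])
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def total_length(intervals) -> int:
    """Total bp covered (after merging)."""
    return sum(e - s for s, e in merge(intervals))


def overlaps_any(start: int, end: int, intervals) -> bool:
    """True if [start, end) overlaps any interval by >= 1 bp."""
    starts, ends = _as_arrays(merge(intervals))
    if starts.size == 0:
        return False
    i = int(np.searchsorted(starts, end))  # first interval starting >= end
    return bool(i > 0 and ends[i - 1] > start)
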