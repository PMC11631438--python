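"""Half-open interval arithmetic on sorted (start, end) lists.

All coordinates are 0-based, half-open. These helpers are the substrate for
accessible-region bookkeeping; they always return merged, sorted, disjoint
interval lists.
"""

from __future__ import annotations

Interval = tuple[int, int]


def merge(intervals: list[Interval]) -> list[Interval]:
    """Sort and merge overlapping or abutting intervals."""
    out: list[Interval] = []
    for start, end in sorted(intervals):
        if end <= start:
            continue
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def union(a: list[Interval], b: list[Interval]) -> list[Interval]:
    return merge(list(a) + list(b))


def intersect(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Intersection of two merged interval lists (linear sweep)."""
    out: list[Interval] = []
    i = j = 0
    a = merge(a)
    b = merge(b)
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Parts of ``a`` not covered by ``b``."""
    a = merge(a)
    b = merge(b)
    out: list[Interval] = []
    j = 0
    for start, end in a:
        cur = start
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < end:
            if b[k][0] > cur:
                out.append((cur, b[k][0]))
            cur = max(cur, b[k][1])
            k += 1
        if cur < end:
            out.append((cur, end))
    return out


def total_length(intervals: list[Interval]) -> int:
    return sum(end - start for start, end in intervals)


def contains(intervals: list[Interval], pos: int) -> bool:
    import bisect

    idx = bisect.bisect_right([s for s, _ in intervals], pos) - 1
    return idx >= 0 and intervals[idx][0] <= pos < intervals[idx][1]
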