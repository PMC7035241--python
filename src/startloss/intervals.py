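"""Set algebra on 0-based half-open genomic intervals.

All functions take and return lists of ``(start, end)`` tuples with
``start < end``. Inputs need not be sorted or disjoint; outputs are
sorted and disjoint.
"""

from __future__ import annotations

Interval = tuple[int, int]


def merge(intervals: list[Interval]) -> list[Interval]:
    """Union of intervals as a sorted, disjoint list. Adjacent intervals coalesce."""
    out: list[Interval] = []
    for start, end in sorted(intervals):
        if start >= end:
            raise ValueError(f"empty or inverted interval ({start}, {end})")
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def subtract(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Bases covered by ``a`` but not by ``b``."""
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
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= end:
                break
            k += 1
        if cur < end:
            out.append((cur, end))
    return out


def intersect(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Bases covered by both ``a`` and ``b``."""
    a = merge(a)
    b = merge(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals: list[Interval]) -> int:
    return sum(end - start for start, end in merge(intervals))


def overlaps(interval: Interval, others: list[Interval]) -> bool:
    """True if ``interval`` shares at least one base with any of ``others``."""
    s, e = interval
    return any(s < oe and os_ < e for os_, oe in others)
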