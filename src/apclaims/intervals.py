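"""Integer-day interval algebra.

All functions operate on inclusive integer intervals ``(lo, hi)`` with
``lo <= hi``.  Coverage sets, hospital stays and follow-up windows are all
expressed this way; the per-day boolean-array enumeration used in the test
suite is the independent oracle these routines are checked against.
"""

from __future__ import annotations

from typing import Iterable, List, Set, Tuple

Interval = Tuple[int, int]


def normalize(intervals: Iterable[Interval], gap: int = 1) -> List[Interval]:
    """Sort and merge intervals.

    Two intervals merge when the next one starts within ``gap`` days of the
    end of the current one: ``gap=1`` merges touching day ranges (the union
    of covered days is unchanged either way), ``gap=0`` merges only
    intervals that share at least one day — the convention for inpatient
    stays, where back-to-back admissions on consecutive days remain two
    stays.
    """
    ivs = sorted((int(lo), int(hi)) for lo, hi in intervals if lo <= hi)
    if not ivs:
        return []
    out = [ivs[0]]
    for lo, hi in ivs[1:]:
        clo, chi = out[-1]
        if lo <= chi + gap:
            out[-1] = (clo, max(chi, hi))
        else:
            out.append((lo, hi))
    return out


def clip(intervals: Iterable[Interval], lo: int, hi: int) -> List[Interval]:
    """Restrict intervals to the inclusive window ``lo..hi``."""
    out = []
    for a, b in intervals:
        a2, b2 = max(a, lo), min(b, hi)
        if a2 <= b2:
            out.append((a2, b2))
    return out


def total_days(intervals: Iterable[Interval]) -> int:
    """Number of distinct days covered (input need not be normalized)."""
    return sum(hi - lo + 1 for lo, hi in normalize(intervals))


def intersect(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    """Pairwise intersection of two interval sets (result normalized)."""
    na, nb = normalize(a), normalize(b)
    out: List[Interval] = []
    i = j = 0
    while i < len(na) and j < len(nb):
        lo = max(na[i][0], nb[j][0])
        hi = min(na[i][1], nb[j][1])
        if lo <= hi:
            out.append((lo, hi))
        if na[i][1] < nb[j][1]:
            i += 1
        else:
            j += 1
    return out


def union(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    return normalize(list(a) + list(b))


def to_day_set(intervals: Iterable[Interval]) -> Set[int]:
    days: Set[int] = set()
    for lo, hi in intervals:
        days.update(range(lo, hi + 1))
    return days
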