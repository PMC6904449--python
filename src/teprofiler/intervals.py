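"""Small vectorized interval-set arithmetic on 0-based half-open intervals.

An interval set is ``{chrom: (starts, ends)}`` with ``starts`` sorted and
the intervals disjoint after :func:`merge`.  These primitives back the
base-counting analyses; per-TE annotation has its own code path.
"""

from __future__ import annotations


from typing import Iterable

import numpy as np

from .core import GenomicInterval

IntervalArrays = dict[str, tuple[np.ndarray, np.ndarray]]


def merge(intervals: Iterable[GenomicInterval]) -> IntervalArrays:
    """Coordinate-collapse intervals into disjoint sorted runs per chromosome."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: IntervalArrays = {}
    for chrom, pairs in per_chrom.items():
        pairs.sort()
        starts, ends = [], []
        cs, ce = pairs[0]
        for s, e in pairs[1:]:
            if s <= ce:
                ce = max(ce, e)
            else:
                starts.append(cs)
                ends.append(ce)
                cs, ce = s, e
        starts.append(cs)
        ends.append(ce)
        out[chrom] = (np.array(starts, dtype=np.int64),
                      np.array(ends, dtype=np.int64))
    return out


def total_bp(arrays: IntervalArrays) -> int:
    return int(sum((e - s).sum() for s, e in arrays.values()))


def overlap_bp(a: IntervalArrays, b: IntervalArrays) -> int:
    """Total bp in the intersection of two merged interval sets."""
    total = 0
    for chrom in set(a) & set(b):
        sa, ea = a[chrom]
        sb, eb = b[chrom]
        i = j = 0
        while i < len(sa) and j < len(sb):
            lo = max(sa[i], sb[j])
            hi = min(ea[i], eb[j])
            if hi > lo:
                total += int(hi - lo)
            if ea[i] < eb[j]:
                i += 1
            else:
                j += 1
    return total


def contains(arrays: IntervalArrays, chrom: str,
             positions: np.ndarray) -> np.ndarray:
    """Bool mask: which single-base positions fall inside the set."""
    if chrom not in arrays:
        return np.zeros(len(positions), dtype=bool)
    starts, ends = arrays[chrom]
    idx = np.searchsorted(starts, positions, side="right") - 1
    ok = idx >= 0
    idx = np.clip(idx, 0, len(starts) - 1)
    return ok & (positions < ends[idx])


def segment_overlap_bp(arrays: IntervalArrays, chrom: str,
                       bounds: np.ndarray) -> np.ndarray:
    """Per segment [bounds[i], bounds[i+1]), bp overlapped by the set."""
    out = np.zeros(len(bounds) - 1, dtype=np.int64)
    if chrom not in arrays:
        return out
    starts, ends = arrays[chrom]
    for s, e in zip(starts, ends):
        lo = int(np.searchsorted(bounds, s, side="right")) - 1
        hi = int(np.searchsorted(bounds, e, side="left"))
        for i in range(max(lo, 0), min(hi, len(out))):
            a = max(int(s), int(bounds[i]))
            b = min(int(e), int(bounds[i + 1]))
            if b > a:
                out[i] += b - a
    return out
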