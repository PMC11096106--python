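"""Interval-set arithmetic on 1-based inclusive coordinates.

Interval sets are ``(k, 2)`` integer arrays of ``[start, end]`` rows. All
functions return normalised sets: sorted by start, non-overlapping,
non-adjacent runs merged. An empty set is a ``(0, 2)`` array.
"""

from __future__ import annotations

import numpy as np

EMPTY = np.empty((0, 2), dtype=np.int64)


def as_intervals(pairs) -> np.ndarray:
    iv = np.asarray(pairs, dtype=np.int64)
    if iv.size == 0:
        return EMPTY.copy()
    iv = iv.reshape(-1, 2)
    if (iv[:, 0] > iv[:, 1]).any():
        raise ValueError("interval with start > end")
    return iv


def merge(iv) -> np.ndarray:
    """Normalise: sort and merge overlapping or bookended intervals."""
    iv = as_intervals(iv)
    if len(iv) == 0:
        return iv
    iv = iv[np.argsort(iv[:, 0], kind="stable")]
    out = [iv[0].copy()]
    for s, e in iv[1:]:
        if s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e], dtype=np.int64))
    return np.array(out, dtype=np.int64)


def total_length(iv) -> int:
    iv = merge(iv)
    if len(iv) == 0:
        return 0
    return int((iv[:, 1] - iv[:, 0] + 1).sum())


def intersect(a, b) -> np.ndarray:
    """Intersection of two normalised interval sets (two-pointer sweep)."""
    a, b = merge(a), merge(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s <= e:
            out.append((s, e))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return as_intervals(out) if out else EMPTY.copy()


def clip(iv, start: int, end: int) -> np.ndarray:
    """Restrict an interval set to the window [start, end]."""
    return intersect(iv, [(start, end)])


def overlap_length(iv, start: int, end: int) -> int:
    """Covered bp of a normalised set inside [start, end] without materialising."""
    iv = merge(iv)
    if len(iv) == 0:
        return 0
    s = np.maximum(iv[:, 0], start)
    e = np.minimum(iv[:, 1], end)
    d = e - s + 1
    return int(d[d > 0].sum())


def complement(iv, start: int, end: int) -> np.ndarray:
    """Positions of [start, end] not covered by the set."""
    iv = clip(iv, start, end)
    out = []
    cursor = start
    for s, e in iv:
        if s > cursor:
            out.append((cursor, s - 1))
        cursor = e + 1
    if cursor <= end:
        out.append((cursor, end))
    return as_intervals(out) if out else EMPTY.copy()


def to_mask(iv, length: int) -> np.ndarray:
    """Boolean per-position vector (index i = position i + 1) — test oracle helper."""
    mask = np.zeros(length, dtype=bool)
    for s, e in merge(iv):
        mask[s - 1 : e] = True
    return mask
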