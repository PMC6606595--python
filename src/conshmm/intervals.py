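"""Small interval-set utilities on 0-based half-open coordinates.

Interval maps are ``dict[chrom] -> (n, 2) int64 array``, sorted and merged,
so a base is counted at most once per set.  These back the base-resolution
enrichment and precision-recall counting.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

IntervalMap = dict[str, np.ndarray]


def merge_records(records: Iterable[tuple[str, int, int]]) -> IntervalMap:
    """Sort and merge (chrom, start, end) records into an interval map."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in records:
        if end <= start:
            raise ValueError(f"empty or inverted interval {chrom}:{start}-{end}")
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    out: IntervalMap = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.asarray(merged, dtype=np.int64)
    return out


def total_bases(ivmap: Mapping[str, np.ndarray]) -> int:
    return int(sum((arr[:, 1] - arr[:, 0]).sum() for arr in ivmap.values()))


def intersect(a: Mapping[str, np.ndarray], b: Mapping[str, np.ndarray]) -> IntervalMap:
    """Interval-set intersection of two merged maps."""
    out: IntervalMap = {}
    for chrom in a.keys() & b.keys():
        ivs = []
        ia, ib = a[chrom], b[chrom]
        i = j = 0
        while i < len(ia) and j < len(ib):
            s = max(ia[i, 0], ib[j, 0])
            e = min(ia[i, 1], ib[j, 1])
            if s < e:
                ivs.append((s, e))
            if ia[i, 1] <= ib[j, 1]:
                i += 1
            else:
                j += 1
        if ivs:
            out[chrom] = np.asarray(ivs, dtype=np.int64)
    return out


def intersect_bases(a: Mapping[str, np.ndarray], b: Mapping[str, np.ndarray]) -> int:
    return total_bases(intersect(a, b))


def mask_from(ivmap: Mapping[str, np.ndarray], chrom: str, length: int) -> np.ndarray:
    """Boolean per-base membership mask for one chromosome."""
    mask = np.zeros(length, dtype=bool)
    for s, e in ivmap.get(chrom, np.empty((0, 2), dtype=np.int64)):
        mask[s:e] = True
    return mask


def from_mask(mask: np.ndarray) -> np.ndarray:
    """Run-length encode a boolean mask into an (n, 2) interval array."""
    padded = np.concatenate([[False], mask.astype(bool), [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return np.stack([starts, ends], axis=1).astype(np.int64)
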