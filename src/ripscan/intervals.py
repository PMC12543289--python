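"""Exact interval arithmetic on genomic coordinates.

All coordinates are 0-based, half-open ``[start, end)``. Sets of intervals
are stored per scaffold as sorted, merged (non-overlapping, non-abutting)
arrays, so every operation below is exact integer arithmetic.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Tuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["Interval", "IntervalSet"]


@dataclass(frozen=True)
class Interval:
    """A half-open genomic interval ``[start, end)`` on one scaffold."""

    scaffold: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.scaffold}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def _merge_pairs(pairs: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Merge overlapping or abutting [start, end) pairs."""
    if not pairs:
        return []
    pairs = sorted(pairs)
    merged = [pairs[0]]
    for s, e in pairs[1:]:
        ls, le = merged[-1]
        if s <= le:  # overlap or abut
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


class IntervalSet:
    """A per-scaffold collection of merged half-open intervals.

    Construction merges overlapping and abutting intervals, so instances
    always satisfy: per scaffold, intervals are sorted by start and pairwise
    separated by at least one base.
    """

    def __init__(self, intervals: Iterable[Interval] = ()) -> None:
        raw: Dict[str, List[Tuple[int, int]]] = {}
        for iv in intervals:
            raw.setdefault(iv.scaffold, []).append((iv.start, iv.end))
        self._data: Dict[str, List[Tuple[int, int]]] = {
            scaf: _merge_pairs(pairs) for scaf, pairs in raw.items()
        }

    # -- construction helpers ------------------------------------------------
    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, int, int]]) -> "IntervalSet":
        return cls(Interval(s, a, b) for s, a, b in pairs)

    @classmethod
    def _from_data(cls, data: Dict[str, List[Tuple[int, int]]]) -> "IntervalSet":
        out = cls()
        out._data = {s: list(p) for s, p in data.items() if p}
        return out

    # -- basic protocol ------------------------------------------------------
    def __iter__(self) -> Iterator[Interval]:
        for scaf in sorted(self._data):
            for s, e in self._data[scaf]:
                yield Interval(scaf, s, e)

    def __len__(self) -> int:
        return sum(len(p) for p in self._data.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._data == other._data

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals, {self.total_bp} bp)"

    @property
    def scaffolds(self) -> List[str]:
        return sorted(self._data)

    @property
    def total_bp(self) -> int:
        return sum(e - s for p in self._data.values() for s, e in p)

    def pairs(self, scaffold: str) -> List[Tuple[int, int]]:
        return list(self._data.get(scaffold, []))

    def contains(self, scaffold: str, pos: int) -> bool:
        for s, e in self._data.get(scaffold, []):
            if s <= pos < e:
                return True
        return False

    # -- set algebra ---------------------------------------------------------
    def union(self, other: "IntervalSet") -> "IntervalSet":
        data: Dict[str, List[Tuple[int, int]]] = {}
        for scaf in set(self._data) | set(other._data):
            data[scaf] = _merge_pairs(
                self._data.get(scaf, []) + other._data.get(scaf, [])
            )
        return IntervalSet._from_data(data)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        data: Dict[str, List[Tuple[int, int]]] = {}
        for scaf in set(self._data) & set(other._data):
            out: List[Tuple[int, int]] = []
            a, b = self._data[scaf], other._data[scaf]
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
            if out:
                data[scaf] = out
        return IntervalSet._from_data(data)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Bases of ``self`` not covered by ``other``."""
        data: Dict[str, List[Tuple[int, int]]] = {}
        for scaf, a in self._data.items():
            b = other._data.get(scaf, [])
            out: List[Tuple[int, int]] = []
            j = 0
            for s, e in a:
                cur = s
                while j < len(b) and b[j][1] <= cur:
                    j += 1
                jj = j
                while jj < len(b) and b[jj][0] < e:
                    bs, be = b[jj]
                    if bs > cur:
                        out.append((cur, bs))
                    cur = max(cur, be)
                    jj += 1
                if cur < e:
                    out.append((cur, e))
            if out:
                data[scaf] = out
        return IntervalSet._from_data(data)

    def complement(self, lengths: Mapping[str, int]) -> "IntervalSet":
        """Bases of each scaffold in ``lengths`` not covered by ``self``."""
        full = IntervalSet.from_pairs((s, 0, n) for s, n in lengths.items() if n > 0)
        return full.subtract(self)

    # -- restriction ---------------------------------------------------------
    def restrict_scaffolds(self, keep: Iterable[str]) -> "IntervalSet":
        keep = set(keep)
        return IntervalSet._from_data(
            {s: p for s, p in self._data.items() if s in keep}
        )

    def clip_to(self, lengths: Mapping[str, int], warn: bool = True) -> "IntervalSet":
        """Clip intervals to scaffold bounds; drop intervals on unknown scaffolds."""
        data: Dict[str, List[Tuple[int, int]]] = {}
        for scaf, pairs in self._data.items():
            if scaf not in lengths:
                if warn:
                    logger.warning("dropping intervals on unknown scaffold %r", scaf)
                continue
            n = lengths[scaf]
            out = []
            for s, e in pairs:
                if s >= n:
                    if warn:
                        logger.warning(
                            "interval %s:%d-%d beyond scaffold end (%d bp), dropped",
                            scaf, s, e, n,
                        )
                    continue
                if e > n:
                    if warn:
                        logger.warning(
                            "interval %s:%d-%d clipped to scaffold end (%d bp)",
                            scaf, s, e, n,
                        )
                    e = n
                out.append((s, e))
            if out:
                data[scaf] = _merge_pairs(out)
        return IntervalSet._from_data(data)

    # -- utilities -----------------------------------------------------------
    def coverage_mask(self, scaffold: str, length: int) -> np.ndarray:
        """Boolean per-base membership vector (used by oracle tests and masking)."""
        mask = np.zeros(length, dtype=bool)
        for s, e in self._data.get(scaffold, []):
            mask[s:min(e, length)] = True
        return mask
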