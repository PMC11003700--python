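"""Overlap analysis between two peak sets with "min" connected-component
counting.

Two peaks are linked when their intervals share at least ``min_overlap_bp``
bases; the connected components of the resulting bipartite graph group
peaks that chain together through mutual overlaps. The overlapped-peak
count is the sum over components of min(|A side|, |B side|), the
conservative convention for reporting "common" peaks between two
experiments, which makes the count symmetric in the two sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .formats_io import Peak

__all__ = ["OverlapResult", "find_overlaps", "overlap_fraction", "overlap_by_category"]


@dataclass(frozen=True)
class OverlapResult:
    """Connected-component overlap summary of two peak sets."""

    n_a: int
    n_b: int
    #: per component, the member peaks from each side (index lists)
    components: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]
    peaks_a: tuple[Peak, ...]
    peaks_b: tuple[Peak, ...]

    @property
    def n_overlap_min(self) -> int:
        return sum(min(len(a), len(b)) for a, b in self.components)

    @property
    def unique_a(self) -> int:
        return self.n_a - sum(len(a) for a, _ in self.components)

    @property
    def unique_b(self) -> int:
        return self.n_b - sum(len(b) for _, b in self.components)

    def overlapped_peaks(self, side: str) -> list[Peak]:
        """Peaks of one side that sit in any overlap component."""
        peaks, pos = (self.peaks_a, 0) if side == "A" else (self.peaks_b, 1)
        return [peaks[i] for comp in self.components for i in comp[pos]]


class _DisjointSet:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: int, y: int) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


def find_overlaps(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    min_overlap_bp: int = 1,
) -> OverlapResult:
    """Connected-component overlap of two peak sets.

    Edges join an A peak and a B peak sharing >= min_overlap_bp bases;
    components are found per chromosome with a sorted sweep. Empty inputs
    give an empty component list.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    n_a, n_b = len(peaks_a), len(peaks_b)
    dsu = _DisjointSet(n_a + n_b)
    linked = [False] * (n_a + n_b)

    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, p in enumerate(peaks_a):
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end, i))
    b_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, p in enumerate(peaks_b):
        b_by_chrom.setdefault(p.chrom, []).append((p.start, p.end, n_a + j))

    for chrom, a_items in by_chrom.items():
        b_items = b_by_chrom.get(chrom)
        if not b_items:
            continue
        a_items.sort()
        b_items.sort()
        for a_start, a_end, ai in a_items:
            # B sorted by start: stop once b_start passes a_end
            for b_start, b_end, bj in b_items:
                if b_start >= a_end:
                    break
                if min(a_end, b_end) - max(a_start, b_start) >= min_overlap_bp:
                    dsu.union(ai, bj)
                    linked[ai] = linked[bj] = True

    groups: dict[int, tuple[list[int], list[int]]] = {}
    for node in range(n_a + n_b):
        if not linked[node]:
            continue
        root = dsu.find(node)
        sides = groups.setdefault(root, ([], []))
        if node < n_a:
            sides[0].append(node)
        else:
            sides[1].append(node - n_a)
    components = tuple(
        (tuple(a), tuple(b)) for a, b in groups.values() if a and b
    )
    return OverlapResult(n_a, n_b, components, tuple(peaks_a), tuple(peaks_b))


def overlap_fraction(result: OverlapResult, side: str) -> float:
    """Fraction of one side's peaks that fall in any overlap component."""
    if side not in {"A", "B"}:
        raise ValueError("side must be 'A' or 'B'")
    n_side = result.n_a if side == "A" else result.n_b
    if n_side == 0:
        raise ValueError(f"side {side} is empty")
    pos = 0 if side == "A" else 1
    in_components = sum(len(comp[pos]) for comp in result.components)
    return in_components / n_side


def overlap_by_category(
    result: OverlapResult,
    categories: Mapping[str, set[str]],
    side: str = "A",
) -> dict[str, tuple[int, float]]:
    """Per-tag counts and percentages among one side's overlapped peaks.

    ``categories`` maps peak name to a set of tags (promoter, enhancer,
    super_enhancer, ...). A peak may carry several tags, so percentages can
    sum past 100. Untagged peaks contribute to the denominator only.
    """
    overlapped = result.overlapped_peaks(side)
    n = len(overlapped)
    if n == 0:
        raise ValueError("no overlapped peaks on this side")
    all_tags = sorted({t for tags in categories.values() for t in tags})
    out: dict[str, tuple[int, float]] = {}
    for tag in all_tags:
        count = sum(1 for p in overlapped if tag in categories.get(p.name, ()))
        out[tag] = (count, round(100.0 * count / n, 1))
    return out
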