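"""Rank-order super-enhancer calling.

The procedure follows the standard rank-ordering approach: H3K27ac peaks
far from any TSS (> 2.5 kb) are stitched into enhancer regions when their
gaps are at most 12.5 kb, each stitched region is scored by its
input-subtracted RPKM ChIP signal, regions are ranked by signal, and the
super-enhancer cutoff is placed at the inflection of the unit-scaled
rank/signal curve where the tangent slope reaches 1. Regions with signal
at or above the cutoff are super-enhancers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .formats_io import CoverageTrack, GeneModel, GenomicInterval, Peak
from .signal_matrix import peak_anchor, rpkm_value

logger = logging.getLogger(__name__)

__all__ = [
    "StitchedEnhancer",
    "distal_filter",
    "stitch",
    "score_stitched",
    "call_supers",
]


@dataclass(frozen=True)
class StitchedEnhancer:
    """A stitched cluster of distal enhancer peaks with ranking metadata."""

    interval: GenomicInterval
    constituent_peak_ids: tuple[str, ...]
    constituent_intervals: tuple[GenomicInterval, ...] = ()
    signal: float = float("nan")  # input-subtracted RPKM, floored at 0
    rank: int = -1  # ascending by signal, unique
    is_super: bool = False


def distal_filter(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    tss_exclusion: int = 2500,
) -> list[Peak]:
    """Keep peaks whose anchor lies more than ``tss_exclusion`` bp from
    every TSS (TSS distance is genomic, strand-ignorant here)."""
    tss_lists: dict[str, list[int]] = {}
    for g in genes:
        tss_lists.setdefault(g.chrom, []).append(g.tss)
    tss_by_chrom = {c: np.sort(np.asarray(v)) for c, v in tss_lists.items()}
    kept = []
    for p in peaks:
        tss = tss_by_chrom.get(p.chrom)
        if tss is None or len(tss) == 0:
            kept.append(p)
            continue
        anchor = peak_anchor(p)
        i = int(np.searchsorted(tss, anchor))
        nearest = min(
            abs(anchor - tss[j]) for j in (i - 1, i) if 0 <= j < len(tss)
        )
        if nearest > tss_exclusion:
            kept.append(p)
    return kept


def stitch(peaks: Sequence[Peak], stitch_distance: int = 12500) -> list[StitchedEnhancer]:
    """Greedily chain peaks whose gap is at most ``stitch_distance``.

    Peaks are sorted per chromosome; consecutive peaks merge when
    ``next.start - previous_span.end <= stitch_distance``. The operation is
    idempotent on its own output spans and the number of regions is
    non-increasing in the stitch distance.
    """
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    regions: list[StitchedEnhancer] = []
    for chrom in sorted(by_chrom):
        chrom_peaks = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end))
        current: list[Peak] = []
        span_end = -1
        for p in chrom_peaks:
            if current and p.start - span_end <= stitch_distance:
                current.append(p)
                span_end = max(span_end, p.end)
            else:
                if current:
                    regions.append(_region(chrom, current))
                current = [p]
                span_end = p.end
        if current:
            regions.append(_region(chrom, current))
    return regions


def _region(chrom: str, peaks: list[Peak]) -> StitchedEnhancer:
    start = min(p.start for p in peaks)
    end = max(p.end for p in peaks)
    return StitchedEnhancer(
        GenomicInterval(chrom, start, end),
        tuple(p.name for p in peaks),
        tuple(p.interval for p in peaks),
    )


def score_stitched(
    stitched: Sequence[StitchedEnhancer],
    chip_track: CoverageTrack,
    input_track: CoverageTrack,
) -> list[StitchedEnhancer]:
    """Attach input-subtracted RPKM signal to stitched regions.

    Signal = max(0, sum over constituent peaks of RPKM(chip) - RPKM(input));
    summing per-constituent RPKM keeps the score extensive in the number
    of constituents (a cluster of several enhancers outranks one enhancer
    of the same density), and negative enrichment after input subtraction
    is treated as noise and floored at 0. The per-base coverage integral
    over each constituent stands in for its raw read count.
    """
    def rpkm_sum(track: CoverageTrack, region: StitchedEnhancer) -> float:
        ivs = region.constituent_intervals or (region.interval,)
        return sum(
            rpkm_value(track.integral(iv.chrom, iv.start, iv.end), len(iv),
                       track.total_reads)
            for iv in ivs
        )

    return [
        replace(region, signal=max(0.0, rpkm_sum(chip_track, region)
                                   - rpkm_sum(input_track, region)))
        for region in stitched
    ]


def call_supers(
    stitched: Sequence[StitchedEnhancer],
) -> tuple[list[StitchedEnhancer], float]:
    """Split stitched regions into typical and super-enhancers.

    Regions are sorted by signal ascending and both the rank and the
    signal are rescaled to [0, 1]. The slope of the scaled curve is
    estimated by central finite differences (one-sided at the ends);
    scanning from the top rank downward, the cutoff is the signal at the
    first position whose slope exceeds 1, and every region with signal at
    or above the cutoff is a super-enhancer. Plateaus have slope 0 and
    never trigger the cutoff; if no position has slope > 1 (including the
    all-equal-signal case) no region is called super.

    Returns the regions (signal-ascending, ranks assigned) and the cutoff
    (NaN when no cutoff fires).
    """
    regions = sorted(
        stitched,
        key=lambda r: (r.signal, r.interval.chrom, r.interval.start),
    )
    n = len(regions)
    if n == 0:
        return [], float("nan")
    if n < 2:
        logger.warning("fewer than 2 stitched regions; all typical")
        return [replace(regions[0], rank=0, is_super=False)], float("nan")

    signals = np.array([r.signal for r in regions])
    lo, hi = signals[0], signals[-1]
    cutoff = float("nan")
    if hi > lo:
        x = np.arange(n) / (n - 1)
        y = (signals - lo) / (hi - lo)
        slopes = np.gradient(y, x)  # central differences, one-sided at ends
        above = np.nonzero(slopes > 1.0)[0]
        if len(above):
            cutoff = float(signals[above[-1]])  # first position from the top
    out = []
    for rank, region in enumerate(regions):
        is_super = (not np.isnan(cutoff)) and region.signal >= cutoff
        out.append(replace(region, rank=rank, is_super=is_super))
    return out, cutoff
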