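"""Positional annotation of peaks: promoter vs distal assignment, nearest
gene, signed distance to the TSS, and summary fractions.

The promoter window is -1 kb to +100 bp around the TSS, strand-aware; a
peak overlapping any promoter window (>= 1 bp) is promoter-class,
everything else is distal. Distances are measured from the peak anchor
(summit or midpoint) to the TSS, with the sign flipped on minus-strand
genes so that negative always means upstream of the gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .formats_io import GeneModel, GenomicInterval, Peak
from .signal_matrix import peak_anchor

__all__ = [
    "PeakAnnotation",
    "promoter_window",
    "annotate_peak",
    "annotate_peaks",
    "tss_distance_fractions",
    "class_fractions",
]


@dataclass(frozen=True)
class PeakAnnotation:
    """Element class, assigned gene and signed TSS distance for one peak."""

    peak_id: str
    element_class: str  # "promoter" or "distal"
    assigned_gene_id: str
    distance_to_tss: int  # negative = upstream of the TSS, strand-aware


def promoter_window(
    gene: GeneModel, upstream: int = 1000, downstream: int = 100
) -> GenomicInterval:
    """Strand-aware promoter interval around the TSS, clipped at 0.

    On the + strand this is [tss - upstream, tss + downstream); on the -
    strand the window is mirrored about the TSS base.
    """
    tss = gene.tss
    if gene.strand == "+":
        start, end = tss - upstream, tss + downstream
    else:
        start, end = tss - downstream + 1, tss + upstream + 1
    return GenomicInterval(gene.chrom, max(0, start), end, gene.strand)


def _signed_distance(anchor: int, gene: GeneModel) -> int:
    d = anchor - gene.tss
    return -d if gene.strand == "-" else d


def annotate_peak(
    peak: Peak,
    genes: Sequence[GeneModel],
    upstream: int = 1000,
    downstream: int = 100,
) -> PeakAnnotation:
    """Assign one peak to a gene and to the promoter or distal class.

    If the peak overlaps >= 1 promoter window it is promoter-class and the
    assigned gene is the overlapping-promoter gene whose TSS is nearest the
    peak anchor; otherwise it is distal and assigned to the nearest TSS
    overall. Genes on other chromosomes are never assigned. The result is
    invariant to the order of the gene list (nearest-TSS ties break to the
    smaller gene_id).
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    anchor = peak_anchor(peak)
    same_chrom = [g for g in genes if g.chrom == peak.chrom]
    if not same_chrom:
        raise ValueError(f"no genes on chromosome {peak.chrom}")

    def nearest(candidates: Sequence[GeneModel]) -> GeneModel:
        return min(candidates, key=lambda g: (abs(anchor - g.tss), g.gene_id))

    overlapping = [
        g for g in same_chrom
        if peak.interval.overlaps(promoter_window(g, upstream, downstream))
    ]
    if overlapping:
        gene = nearest(overlapping)
        cls = "promoter"
    else:
        gene = nearest(same_chrom)
        cls = "distal"
    return PeakAnnotation(peak.name, cls, gene.gene_id, _signed_distance(anchor, gene))


def annotate_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    upstream: int = 1000,
    downstream: int = 100,
) -> list[PeakAnnotation]:
    """Annotate every peak (see :func:`annotate_peak`)."""
    return [annotate_peak(p, genes, upstream, downstream) for p in peaks]


def tss_distance_fractions(
    annotations: Sequence[PeakAnnotation], near: int = 5000
) -> tuple[float, float]:
    """Fraction of peaks within |distance| <= near of a TSS, and beyond.

    The two fractions are complementary and sum to 1.
    """
    if not annotations:
        raise ValueError("no annotations")
    within = sum(1 for a in annotations if abs(a.distance_to_tss) <= near)
    frac = within / len(annotations)
    return frac, 1.0 - frac


def class_fractions(count: int, total: int) -> tuple[int, float]:
    """A count and its percentage of total, rounded to 1 decimal.

    Classes may overlap (a peak can carry both a promoter and an enhancer
    tag under the overlap-reporting scheme), so percentages across classes
    need not sum to 100.
    """
    if total == 0:
        raise ValueError("total must be > 0")
    if count > total:
        raise ValueError("count cannot exceed total")
    return count, round(100.0 * count / total, 1)
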