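"""Integration of TF binding with differential expression.

This is the pipeline's central step: genes bound by the TF at promoter or
enhancer elements are crossed with the direction of their expression
change after TF knockdown, yielding the four regulatory quadrants
(promoter-bound down/up, enhancer-bound down/up). A gene bound at both
element types contributes to both element tallies. The module also bins
cofactor occupancy changes between conditions and compares peak-class
distributions between conditions with a chi-square test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .formats_io import DERecord

__all__ = [
    "RegulatoryCall",
    "OccupancyChange",
    "QuadrantSummary",
    "classify_de",
    "build_quadrants",
    "bin_occupancy_change",
    "compare_class_distribution",
]

UP, DOWN, NOT_DE = "up", "down", "not_de"


@dataclass(frozen=True)
class RegulatoryCall:
    """Per-gene bound-element set, DE direction and quadrant membership."""

    gene_id: str
    bound_elements: frozenset[str]  # subset of {"promoter", "enhancer"}
    de_direction: str
    quadrants: frozenset[str]


@dataclass(frozen=True)
class OccupancyChange:
    """Peak-center signal in two conditions and its change category."""

    peak_id: str
    signal_ctrl: float
    signal_kd: float
    category: str  # down / stable / up / unclassified


@dataclass(frozen=True)
class QuadrantSummary:
    """Quadrant counts with within-element-class percentages."""

    counts: dict[str, int]  # promoter_down, promoter_up, enhancer_down, enhancer_up
    percentages: dict[str, float | None]  # None when the class has no DE genes
    n_de_genes: int
    n_de_bound: int  # DE genes bound at promoter, enhancer or both
    n_dual_bound: int  # DE genes bound at both element classes
    calls: tuple[RegulatoryCall, ...]


def classify_de(
    record: DERecord,
    fold_threshold: float = 1.5,
    padj_threshold: float = 0.05,
) -> str:
    """DE direction of a gene under the fold/padj thresholds.

    Up when fold_change >= +threshold and padj < padj_threshold, down when
    fold_change <= -threshold likewise; anything else is not_de.
    """
    if record.padj < padj_threshold:
        if record.fold_change >= fold_threshold:
            return UP
        if record.fold_change <= -fold_threshold:
            return DOWN
    return NOT_DE


def build_quadrants(
    de_records: Sequence[DERecord],
    gene_to_elements: Mapping[str, set[str]],
    fold_threshold: float = 1.5,
    padj_threshold: float = 0.05,
) -> QuadrantSummary:
    """Cross bound-element classes with DE direction into quadrant counts.

    ``gene_to_elements`` maps gene_id to the element classes ("promoter",
    "enhancer") at which the TF binds the gene. Percentages are computed
    within each element class over its up+down genes, to 1 decimal; a
    class with no DE bound genes reports None instead of 0/0. Dual-bound
    genes count once in each class, so the four counts can sum to more
    than the number of distinct bound DE genes (reported separately).
    """
    calls = []
    counts = {"promoter_down": 0, "promoter_up": 0, "enhancer_down": 0, "enhancer_up": 0}
    n_de = n_bound = n_dual = 0
    for rec in de_records:
        direction = classify_de(rec, fold_threshold, padj_threshold)
        elements = frozenset(gene_to_elements.get(rec.gene_id, ()))
        quadrants: set[str] = set()
        if direction != NOT_DE:
            n_de += 1
            if elements:
                n_bound += 1
                if {"promoter", "enhancer"} <= elements:
                    n_dual += 1
                for element in elements:
                    quadrant = f"{element}_{direction}"
                    counts[quadrant] += 1
                    quadrants.add(quadrant)
            else:
                quadrants.add("unbound_de")
        elif elements:
            quadrants.add("bound_not_de")
        calls.append(RegulatoryCall(rec.gene_id, elements, direction,
                                    frozenset(quadrants)))
    percentages: dict[str, float | None] = {}
    for element in ("promoter", "enhancer"):
        total = counts[f"{element}_down"] + counts[f"{element}_up"]
        for direction in (DOWN, UP):
            key = f"{element}_{direction}"
            percentages[key] = round(100.0 * counts[key] / total, 1) if total else None
    return QuadrantSummary(counts, percentages, n_de, n_bound, n_dual, tuple(calls))


def bin_occupancy_change(
    signal_ctrl: float,
    signal_kd: float,
    change_fold: float = 1.2,
    stable_fold: float = 1.1,
) -> str:
    """Categorize a peak's between-condition signal ratio.

    With r = kd/ctrl: down when the signal drops at least change_fold
    (r <= 1/1.2), up when it rises at least as much (r >= 1.2), stable
    when the change is under stable_fold in either direction
    (1/1.1 < r < 1.1). The two bands between stable_fold and change_fold
    are deliberately reported as "unclassified" - the three named bins do
    not tile the ratio line.
    """
    if signal_ctrl <= 0:
        raise ValueError("control signal must be > 0")
    r = signal_kd / signal_ctrl
    if r <= 1.0 / change_fold:
        return "down"
    if r >= change_fold:
        return "up"
    if 1.0 / stable_fold < r < stable_fold:
        return "stable"
    return "unclassified"


def compare_class_distribution(
    counts_ctrl: tuple[int, int],
    counts_kd: tuple[int, int],
) -> tuple[float, int, float]:
    """Pearson chi-square on the 2x2 (condition x element class) table.

    No continuity correction; df = 1. Returns (statistic, df, p). A zero
    marginal makes the expected counts degenerate and raises.
    """
    table = np.array([counts_ctrl, counts_kd], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise ValueError("zero marginal in the contingency table")
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)
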