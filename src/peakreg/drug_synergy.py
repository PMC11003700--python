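"""Bliss-independence synergy scoring of checkerboard viability matrices.

Under Bliss independence two drugs with fractional inhibitions e_a and e_b
combine to E = e_a + e_b - e_a*e_b. The synergy excess of a combination
cell is its observed inhibition minus this expectation, in percentage
points; the average excess over all combination cells (both doses > 0) is
the matrix's synergy score. Scores in (-10, 10] are additive, above 10
synergistic, and at or below -10 antagonistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .formats_io import DoseMatrix

__all__ = ["SynergyResult", "inhibition", "bliss_expected", "score_matrix",
           "average_replicates"]


@dataclass(frozen=True)
class SynergyResult:
    """Per-cell Bliss excess and the matrix-level synergy call."""

    excess_matrix: np.ndarray  # (n_a - 1, n_b - 1) percentage points
    average_score: float
    classification: str  # antagonistic / additive / synergistic


def inhibition(viability_percent: float | np.ndarray) -> float | np.ndarray:
    """Fractional inhibition from % viability; growth above the untreated
    control clamps to 0 inhibition."""
    v = np.asarray(viability_percent, dtype=float)
    if np.any(v < 0):
        raise ValueError("negative viability")
    out = np.maximum(0.0, 1.0 - v / 100.0)
    return float(out) if out.ndim == 0 else out


def bliss_expected(e_a: float | np.ndarray, e_b: float | np.ndarray):
    """Bliss-independence expected inhibition e_a + e_b - e_a*e_b."""
    a = np.asarray(e_a, dtype=float)
    b = np.asarray(e_b, dtype=float)
    if np.any((a < 0) | (a > 1)) or np.any((b < 0) | (b > 1)):
        raise ValueError("inhibitions must lie in [0, 1]")
    out = a + b - a * b
    return float(out) if out.ndim == 0 else out


def classify_score(average_score: float, band: tuple[float, float] = (-10.0, 10.0)) -> str:
    lo, hi = band
    if average_score > hi:
        return "synergistic"
    if average_score <= lo:
        return "antagonistic"
    return "additive"


def average_replicates(matrices: Sequence[DoseMatrix]) -> DoseMatrix:
    """Cell-wise mean of replicate checkerboards (same dose ladders)."""
    first = matrices[0]
    for m in matrices[1:]:
        if m.drug_a_doses != first.drug_a_doses or m.drug_b_doses != first.drug_b_doses:
            raise ValueError("replicates must share dose ladders")
    mean = np.mean([m.viability for m in matrices], axis=0)
    return DoseMatrix(first.drug_a_doses, first.drug_b_doses, mean)


def score_matrix(
    matrix: DoseMatrix,
    additive_band: tuple[float, float] = (-10.0, 10.0),
) -> SynergyResult:
    """Score one checkerboard against the Bliss independence model.

    Row 0 / column 0 provide the single-agent inhibitions; for every
    combination cell (i > 0, j > 0) the excess over the Bliss expectation
    is computed in percentage points, and the average over combination
    cells gives the synergy score and its classification.
    """
    v = matrix.viability
    if v.shape[0] < 2 or v.shape[1] < 2:
        raise ValueError("matrix needs single-agent row/column plus combinations")
    e_a = inhibition(v[1:, 0])  # drug A alone, by dose
    e_b = inhibition(v[0, 1:])  # drug B alone, by dose
    expected = bliss_expected(e_a[:, None], e_b[None, :])
    observed = inhibition(v[1:, 1:])
    excess = (observed - expected) * 100.0
    avg = float(excess.mean())
    return SynergyResult(excess, avg, classify_score(avg, additive_band))
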