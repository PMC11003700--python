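"""Chromatin-state segmentation of TF peaks.

TF binding sites are partitioned into promoter-like and enhancer-like
classes by k-means over the concatenated, per-mark standardized binned
histone signal around the peaks; the clusters are then labeled from the
H3K4me3 / H3K4me1 contrast (high me3/me1 ratio marks active promoters,
the reverse marks enhancers). A separate positional rule defines active
enhancers as H3K27ac peaks free of any H3K4me3 overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .formats_io import Peak
from .signal_matrix import SignalMatrix

__all__ = [
    "ClusterAssignment",
    "build_feature_table",
    "kmeans_segment",
    "label_clusters",
    "active_enhancer_peaks",
    "PROMOTER_LIKE",
    "ENHANCER_LIKE",
    "UNLABELED",
]

PROMOTER_LIKE = "promoter_like"
ENHANCER_LIKE = "enhancer_like"
UNLABELED = "unlabeled"


@dataclass(frozen=True)
class ClusterAssignment:
    """Per-peak cluster indices plus semantic cluster labels."""

    peak_ids: tuple[str, ...]
    cluster_index: np.ndarray  # int per peak, 0..k-1
    cluster_labels: dict[int, str] = field(default_factory=dict)
    feature_description: str = ""
    inertia: float = float("nan")  # within-cluster sum of squares, for audit

    def __post_init__(self) -> None:
        if len(self.peak_ids) != len(self.cluster_index):
            raise ValueError("one cluster index per peak required")

    @property
    def k(self) -> int:
        return int(self.cluster_index.max()) + 1 if len(self.cluster_index) else 0

    def labels_per_peak(self) -> list[str]:
        return [self.cluster_labels.get(int(c), UNLABELED) for c in self.cluster_index]


def build_feature_table(
    matrices: Mapping[str, SignalMatrix], log_transform: bool = True
) -> np.ndarray:
    """Concatenate per-mark binned rows into a peak feature table.

    Bin values are log1p-compressed by default (ChIP signal spans orders
    of magnitude, and without compression a handful of very tall loci,
    e.g. super-enhancer constituents, dominate the Euclidean geometry),
    then each mark's block is standardized to zero mean / unit variance
    with one mean/sd per block (a constant block becomes all zeros), so
    marks with different dynamic ranges contribute comparably to the
    clustering. Block-level rather than per-bin scaling keeps bins that
    are empty in almost every peak from being amplified into dominant
    features.
    """
    if not matrices:
        raise ValueError("at least one mark matrix required")
    reference: tuple[str, ...] | None = None
    blocks = []
    for mark, matrix in matrices.items():
        if reference is None:
            reference = matrix.peak_ids
        elif matrix.peak_ids != reference:
            raise ValueError(f"mark {mark}: peak order differs from the first matrix")
        block = np.log1p(matrix.values) if log_transform else matrix.values
        sd = block.std()
        blocks.append((block - block.mean()) / (sd if sd > 0 else 1.0))
    return np.hstack(blocks)


def _deterministic_init(features: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Greedy farthest-point initial centers from a seeded random start."""
    rng = np.random.default_rng(seed)
    n = features.shape[0]
    centers = [int(rng.integers(n))]
    dist = np.linalg.norm(features - features[centers[0]], axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(dist))  # argmax ties break to the lowest index
        centers.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(features - features[nxt], axis=1))
    return features[centers]


def kmeans_segment(
    features: np.ndarray,
    peak_ids: Sequence[str],
    k: int = 2,
    seed: int = 0,
) -> ClusterAssignment:
    """Cluster peak feature rows with k-means.

    Initialization is deterministic (greedy farthest-point from a seeded
    random start), so the assignment is bit-stable across runs for a given
    seed. Identical rows collapse to a single effective center; that
    degenerate case is allowed and yields a deterministic assignment.
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} peaks, got {n}")
    if k == 1:
        return ClusterAssignment(tuple(peak_ids), np.zeros(n, dtype=int),
                                 inertia=float(((features - features.mean(0)) ** 2).sum()))
    init = _deterministic_init(features, k, seed)
    km = KMeans(n_clusters=k, init=init, n_init=1, random_state=seed)
    idx = km.fit_predict(features)
    return ClusterAssignment(tuple(peak_ids), idx.astype(int), inertia=float(km.inertia_))


def label_clusters(
    assignment: ClusterAssignment,
    center_scores: Mapping[str, np.ndarray],
    epsilon: float = 1e-9,
) -> ClusterAssignment:
    """Name clusters from mark semantics.

    For each cluster the ratio mean(H3K4me3) / (mean(H3K4me1) + epsilon) is
    computed over its peaks; the cluster with the highest ratio is
    promoter_like and the lowest enhancer_like. With k > 2 the middle
    clusters stay unlabeled; exact ratio ties leave the tied clusters
    unlabeled.
    """
    for mark in ("H3K4me3", "H3K4me1"):
        if mark not in center_scores:
            raise ValueError(f"center scores for {mark} are required")
    me3 = np.asarray(center_scores["H3K4me3"], dtype=float)
    me1 = np.asarray(center_scores["H3K4me1"], dtype=float)
    if len(me3) != len(assignment.peak_ids) or len(me1) != len(assignment.peak_ids):
        raise ValueError("score vectors must match the peak list")
    ratios: dict[int, float] = {}
    for c in range(assignment.k):
        mask = assignment.cluster_index == c
        ratios[c] = float(me3[mask].mean() / (me1[mask].mean() + epsilon))
    labels: dict[int, str] = {c: UNLABELED for c in ratios}
    ordered = sorted(ratios, key=ratios.get)
    hi, lo = ordered[-1], ordered[0]
    tie = any(ratios[c] == ratios[hi] for c in ratios if c != hi) or \
        any(ratios[c] == ratios[lo] for c in ratios if c != lo)
    if not tie and hi != lo:
        labels[hi] = PROMOTER_LIKE
        labels[lo] = ENHANCER_LIKE
    return ClusterAssignment(
        assignment.peak_ids,
        assignment.cluster_index,
        labels,
        assignment.feature_description,
        assignment.inertia,
    )


def active_enhancer_peaks(
    h3k27ac_peaks: Sequence[Peak],
    h3k4me3_peaks: Sequence[Peak],
) -> list[Peak]:
    """H3K27ac peaks that overlap no H3K4me3 peak (active enhancers).

    Overlap is >= 1 bp in half-open coordinates, so abutting intervals do
    not exclude. Output order follows the input; the operation is
    idempotent on its own output.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in h3k4me3_peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    starts_ends: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        arr = np.array(ivs)
        starts_ends[chrom] = (arr[:, 0], np.maximum.accumulate(arr[:, 1]))
    kept = []
    for p in h3k27ac_peaks:
        if p.chrom not in starts_ends:
            kept.append(p)
            continue
        starts, cummax_ends = starts_ends[p.chrom]
        # candidate me3 peaks starting before p.end; overlap iff any of
        # them extends past p.start
        i = int(np.searchsorted(starts, p.end, side="left"))
        if i == 0 or cummax_ends[i - 1] <= p.start:
            kept.append(p)
    return kept
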