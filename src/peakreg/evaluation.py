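"""Recovery metrics: compare a pipeline report against planted ground truth.

Used to quantify how well the analysis recovers the structure the
synthetic generator planted - cluster labels per TF peak, regulatory
quadrant membership per gene, and occupancy-change categories per
cofactor peak.
"""

from __future__ import annotations

import numpy as np

from .synthetic_data import SyntheticDataset

__all__ = ["recovery_metrics"]

_QUADRANTS = {"promoter_down", "promoter_up", "enhancer_down", "enhancer_up"}


def recovery_metrics(dataset: SyntheticDataset, report: dict) -> dict:
    """Cluster-label accuracy, quadrant recall/precision and occupancy
    recovery of one analysis report against the dataset's truth.

    Occupancy recovery is measured over the planted down and stable peaks
    (the categories with a planted fold change of 1.5x and 1.0x).
    """
    labels = report["clusters"]["label_per_peak"]
    truth_class = dataset.truth.peak_class
    cluster_accuracy = float(np.mean(
        [labels[p] == cls for p, cls in truth_class.items()]))

    truth_pairs = {
        (gene, q)
        for gene, quads in dataset.truth.gene_quadrants.items()
        for q in quads if q in _QUADRANTS
    }
    called_pairs = {
        (gene, q)
        for gene, quads in report["quadrants"]["quadrants_per_gene"].items()
        for q in quads if q in _QUADRANTS
    }
    hit = len(truth_pairs & called_pairs)
    quadrant_recall = hit / len(truth_pairs) if truth_pairs else float("nan")
    quadrant_precision = hit / len(called_pairs) if called_pairs else float("nan")

    called_cat = report["occupancy"].get("categories", {})
    planted = {p: c for p, c in dataset.truth.occupancy_category.items()
               if c in ("down", "stable")}
    occupancy_recovery = float(np.mean(
        [called_cat.get(p) == c for p, c in planted.items()])) if planted \
        else float("nan")

    return {
        "cluster_accuracy": cluster_accuracy,
        "quadrant_recall": quadrant_recall,
        "quadrant_precision": quadrant_precision,
        "occupancy_recovery": occupancy_recovery,
    }
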