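"""Analysis configuration: every numeric threshold of the pipeline in one place.

The defaults encode the standard published conventions for promoter windows,
differential-expression calling, super-enhancer stitching and synergy
classification, so a reader can audit all cutoffs without chasing them
through the code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass(frozen=True)
class AnalysisConfig:
    """Numeric thresholds shared by the whole pipeline.

    Distances are in base pairs; fold thresholds are linear ratios.
    """

    #: DE calling: |linear fold change| at or above this, with padj below
    #: ``de_padj_threshold``, marks a gene as differentially expressed.
    de_fold_threshold: float = 1.5
    de_padj_threshold: float = 0.05

    #: Promoter window around the TSS, strand-aware: upstream/downstream extents.
    promoter_upstream: int = 1000
    promoter_downstream: int = 100

    #: "Near TSS" radius used for peak-distance distribution binning.
    tss_near_bin: int = 5000

    #: Signal-matrix geometry around peak centers.
    matrix_flank: int = 3000
    matrix_bin: int = 10
    #: Half-width of the window used for accumulated peak-center scores.
    center_window: int = 500

    #: Number of k-means clusters for chromatin-state segmentation.
    cluster_k: int = 2

    #: Super-enhancer stitching distance and TSS exclusion radius.
    stitch_distance: int = 12500
    tss_exclusion: int = 2500

    #: Occupancy-change binning: >=1.2-fold moves a peak to up/down,
    #: <1.1-fold change keeps it stable; the bands between are unclassified.
    occupancy_change_fold: float = 1.2
    occupancy_stable_fold: float = 1.1

    #: Average Bliss excess (percentage points) inside this open/closed band
    #: is called additive; above it synergistic, at or below the lower edge
    #: antagonistic.
    synergy_additive_band: tuple[float, float] = (-10.0, 10.0)

    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "promoter_upstream",
            "promoter_downstream",
            "tss_near_bin",
            "matrix_flank",
            "matrix_bin",
            "center_window",
            "stitch_distance",
            "tss_exclusion",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.matrix_flank % self.matrix_bin != 0:
            raise ValueError("matrix_flank must be divisible by matrix_bin")
        if not self.occupancy_stable_fold < self.occupancy_change_fold:
            raise ValueError("occupancy_stable_fold must be < occupancy_change_fold")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "AnalysisConfig":
        """Build a config from a flat dict, ignoring unknown keys."""
        known = {f.name for f in fields(cls)}
        kwargs = {k: v for k, v in mapping.items() if k in known}
        if "synergy_additive_band" in kwargs:
            kwargs["synergy_additive_band"] = tuple(kwargs["synergy_additive_band"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
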