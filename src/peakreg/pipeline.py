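"""End-to-end orchestration: from peak sets, coverage tracks, gene model,
DE table and dose matrices to the summary report.

Stage order mirrors the analysis design: signal matrices around TF peaks
-> chromatin-state clustering -> positional annotation -> super-enhancers
-> cofactor overlap -> regulatory quadrants -> occupancy changes -> drug
synergy. :func:`analyze` runs on in-memory objects; :func:`run_pipeline`
wraps it with file loading, report/manifest writing and stage-level
logging so the narrative numbers ("X of Y peaks ...") are auditable.
"""

from __future__ import annotations

import glob
import hashlib
import json
import logging
import os
import time
from typing import Mapping, Sequence

import numpy as np

from . import formats_io as fio
from .chromatin_state import (
    active_enhancer_peaks,
    build_feature_table,
    kmeans_segment,
    label_clusters,
)
from .config import AnalysisConfig
from .drug_synergy import score_matrix
from .formats_io import CoverageTrack, DERecord, DoseMatrix, GeneModel, Peak
from .peak_annotation import annotate_peaks, class_fractions, tss_distance_fractions
from .peak_overlap import find_overlaps, overlap_by_category, overlap_fraction
from .regulatory_integration import (
    bin_occupancy_change,
    build_quadrants,
    compare_class_distribution,
)
from .signal_matrix import compute_matrix, metagene, peak_center_score, summit_change
from .super_enhancers import call_supers, distal_filter, score_stitched, stitch

logger = logging.getLogger(__name__)

__all__ = ["load_inputs", "analyze", "run_pipeline", "PipelineError", "MARKS"]

MARKS = ("h3k4me3", "h3k4me1", "h3k27ac")
_MARK_LABEL = {"h3k4me3": "H3K4me3", "h3k4me1": "H3K4me1", "h3k27ac": "H3K27ac"}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_inputs(data_dir: str) -> dict:
    """Load a data directory laid out as ``synthetic_data.generate`` writes it.

    Expects genes.tsv, de_table.tsv, ``<name>_peaks.narrowPeak`` peak sets,
    ``<name>.bedgraph`` tracks with library sizes in tracks.json, and
    ``combo_*.csv`` dose matrices.
    """
    def need(name: str) -> str:
        path = os.path.join(data_dir, name)
        if not os.path.exists(path):
            raise PipelineError(f"load: missing input file {path}")
        return path

    genes = fio.read_gene_model(need("genes.tsv"))
    de_records = fio.read_de_table(need("de_table.tsv"))
    with open(need("tracks.json")) as fh:
        library_sizes = json.load(fh)
    tracks = {
        name: fio.read_bedgraph(need(f"{name}.bedgraph"), total_reads)
        for name, total_reads in library_sizes.items()
    }
    peaks = {}
    for path in sorted(glob.glob(os.path.join(data_dir, "*_peaks.narrowPeak"))):
        name = os.path.basename(path)[: -len("_peaks.narrowPeak")]
        peaks[name] = fio.read_peaks(path, "narrowPeak")
    dose_matrices = {
        os.path.basename(p)[:-4]: fio.read_dose_matrix(p)
        for p in sorted(glob.glob(os.path.join(data_dir, "combo_*.csv")))
    }
    digests = {
        os.path.basename(p): _sha256(p)
        for p in sorted(glob.glob(os.path.join(data_dir, "*")))
        if os.path.isfile(p)
    }
    return {
        "genes": genes,
        "de_records": de_records,
        "tracks": tracks,
        "peaks": peaks,
        "dose_matrices": dose_matrices,
        "digests": digests,
    }


def analyze(
    genes: Sequence[GeneModel],
    peaks: Mapping[str, Sequence[Peak]],
    tracks: Mapping[str, CoverageTrack],
    de_records: Sequence[DERecord],
    dose_matrices: Mapping[str, DoseMatrix] | None = None,
    config: AnalysisConfig | None = None,
) -> dict:
    """Run every analysis stage on in-memory inputs and return the report.

    The peak mapping must hold a "tf" set; mark sets (h3k4me3/h3k4me1/
    h3k27ac), cofactor sets and knockdown tracks are used when present.
    Deterministic for a given input and config.
    """
    cfg = config or AnalysisConfig()
    dose_matrices = dose_matrices or {}
    report: dict = {"config": cfg.to_dict(), "stage_counts": {}}
    stage_counts = report["stage_counts"]

    if "tf" not in peaks:
        raise PipelineError("matrix: no TF peak set provided")
    tf_peaks = list(peaks["tf"])

    # ---- signal matrices -------------------------------------------------
    stage = "matrix"
    try:
        matrices = {
            mark: compute_matrix(tracks[f"{mark}_ctrl"], tf_peaks,
                                 cfg.matrix_flank, cfg.matrix_bin)
            for mark in MARKS
        }
        center_scores = {
            _MARK_LABEL[m]: peak_center_score(matrices[m], cfg.center_window)
            for m in MARKS
        }
        stage_counts[stage] = {"n_peaks": len(tf_peaks),
                               "n_bins": matrices["h3k4me3"].n_bins}
        logger.info("matrix: %d TF peaks x %d bins x %d marks",
                    len(tf_peaks), matrices["h3k4me3"].n_bins, len(MARKS))
    except Exception as exc:
        raise PipelineError(f"{stage}: {exc}") from exc

    # ---- chromatin-state clustering -------------------------------------
    stage = "cluster"
    try:
        features = build_feature_table(matrices)
        assignment = kmeans_segment(features, [p.name for p in tf_peaks],
                                    cfg.cluster_k, cfg.random_seed)
        assignment = label_clusters(assignment, center_scores)
        labels = assignment.labels_per_peak()
        report["clusters"] = {
            "k": cfg.cluster_k,
            "n_promoter_like": labels.count("promoter_like"),
            "n_enhancer_like": labels.count("enhancer_like"),
            "inertia": assignment.inertia,
            "label_per_peak": dict(zip(assignment.peak_ids, labels)),
        }
        stage_counts[stage] = {"promoter_like": labels.count("promoter_like"),
                               "enhancer_like": labels.count("enhancer_like")}
        logger.info("cluster: %s", stage_counts[stage])
    except Exception as exc:
        raise PipelineError(f"{stage}: {exc}") from exc

    # ---- positional annotation ------------------------------------------
    stage = "annotate"
    try:
        annotations = annotate_peaks(tf_peaks, genes, cfg.promoter_upstream,
                                     cfg.promoter_downstream)
        n_total = len(annotations)
        n_promoter = sum(1 for a in annotations if a.element_class == "promoter")
        count_p, pct_p = class_fractions(n_promoter, n_total)
        count_d, pct_d = class_fractions(n_total - n_promoter, n_total)
        by_label: dict[str, list] = {}
        for ann, label in zip(annotations, labels):
            by_label.setdefault(label, []).append(ann)
        near_fracs = {
            label: round(tss_distance_fractions(anns, cfg.tss_near_bin)[0], 3)
            for label, anns in by_label.items() if anns
        }
        report["annotation"] = {
            "n_peaks": n_total,
            "promoter": {"count": count_p, "percent": pct_p},
            "distal": {"count": count_d, "percent": pct_d},
            "fraction_within_near_tss_by_cluster": near_fracs,
        }
        stage_counts[stage] = {"promoter": count_p, "distal": count_d}
        logger.info("annotate: %d promoter (%.1f%%), %d distal (%.1f%%)",
                    count_p, pct_p, count_d, pct_d)
    except Exception as exc:
        raise PipelineError(f"{stage}: {exc}") from exc

    # ---- super-enhancers (tags feed the overlap reporting) --------------
    stage = "superenh"
    try:
        active_enh = active_enhancer_peaks(peaks.get("h3k27ac", []),
                                           peaks.get("h3k4me3", []))
        distal_k27 = distal_filter(active_enh, genes, cfg.tss_exclusion)
        stitched = stitch(distal_k27, cfg.stitch_distance)
        if "h3k27ac_ctrl" in tracks and "input" in tracks:
            scored = score_stitched(stitched, tracks["h3k27ac_ctrl"], tracks["input"])
            ranked, cutoff = call_supers(scored)
        else:
            ranked, cutoff = [], float("nan")
        supers = [r for r in ranked if r.is_super]
        super_spans = [r.interval for r in supers]
        report["super_enhancers"] = {
            "n_active_enhancer_peaks": len(active_enh),
            "n_distal_k27ac_peaks": len(distal_k27),
            "n_stitched": len(stitched),
            "n_super": len(supers),
            "cutoff_signal": None if np.isnan(cutoff) else cutoff,
        }
        stage_counts[stage] = {"stitched": len(stitched), "super": len(supers)}
        logger.info("superenh: %d stitched, %d super", len(stitched), len(supers))
    except Exception as exc:
        raise PipelineError(f"{stage}: {exc}") from exc

    # ---- TF x cofactor overlap ------------------------------------------
    stage = "overlap"
    try:
        ann_by_name = {a.peak_id: a for a in annotations}
        tags: dict[str, set[str]] = {}
        for p in tf_peaks:
            tag = {"promoter"} if ann_by_name[p.name].element_class == "promoter" \
                else {"enhancer"}
            if any(p.interval.overlaps(iv) for iv in super_spans):
                tag.add("super_enhancer")
            tags[p.name] = tag
        report["overlap"] = {}
        for cof in ("cofactor_a", "cofactor_b"):
            if cof not in peaks:
                continue
            result = find_overlaps(tf_peaks, peaks[cof])
            report["overlap"][cof] = {
                "n_tf": result.n_a,
                "n_cofactor": result.n_b,
                "n_overlap_min": result.n_overlap_min,
                "cofactor_fraction_overlapping": round(
                    overlap_fraction(result, "B"), 3),
                "by_category": {
                    tag: {"count": c, "percent": pct}
                    for tag, (c, pct) in overlap_by_category(result, tags, "A").items()
                },
            }
        if {"cofactor_a", "cofactor_b"} <= report["overlap"].keys():
            def pe_counts(cof: str) -> tuple[int, int]:
                cat = report["overlap"][cof]["by_category"]
                return (cat.get("promoter", {"count": 0})["count"],
                        cat.get("enhancer", {"count": 0})["count"])
            chi2, df, p = compare_class_distribution(pe_counts("cofactor_a"),
                                                     pe_counts("cofactor_b"))
            report["overlap"]["class_distribution_chi2"] = {
                "statistic": chi2, "df": df, "p": p}
        stage_counts[stage] = {
            cof: report["overlap"][cof]["n_overlap_min"]
            for cof in ("cofactor_a", "cofactor_b") if cof in report["overlap"]
        }
    except Exception as exc:
        raise PipelineError(f"{stage}: {exc}") from exc

    # ---- regulatory quadrants -------------------------------------------
    stage = "integrate"
    try:
        gene_to_elements: dict[str, set[str]] = {}
        for ann in annotations:
            element = "promoter" if ann.element_class == "promoter" else "enhancer"
            gene_to_elements.setdefault(ann.assigned_gene_id, set()).add(element)
        summary = build_quadrants(de_records, gene_to_elements,
                                  cfg.de_fold_threshold, cfg.de_padj_threshold)
        report["quadrants"] = {
            "counts": summary.counts,
            "percentages": summary.percentages,
            "n_de_genes": summary.n_de_genes,
            "n_de_bound": summary.n_de_bound,
            "n_dual_bound": summary.n_dual_bound,
            "quadrants_per_gene": {
                call.gene_id: sorted(call.quadrants) for call in summary.calls
            },
        }
        stage_counts[stage] = dict(summary.counts)
        logger.info("integrate: %s (of %d DE genes, %d bound)",
                    summary.counts, summary.n_de_genes, summary.n_de_bound)
    except Exception as exc:
        raise PipelineError(f"{stage}: {exc}") from exc

    # ---- occupancy changes + summit changes ------------------------------
    stage = "occupancy"
    try:
        report["occupancy"] = {}
        if {"cofactor_b_ctrl", "cofactor_b_kd"} <= tracks.keys() \
                and "cofactor_b" in peaks:
            cof_b = list(peaks["cofactor_b"])
            s_ctrl = peak_center_score(
                compute_matrix(tracks["cofactor_b_ctrl"], cof_b,
                               cfg.matrix_flank, cfg.matrix_bin),
                cfg.center_window)
            s_kd = peak_center_score(
                compute_matrix(tracks["cofactor_b_kd"], cof_b,
                               cfg.matrix_flank, cfg.matrix_bin),
                cfg.center_window)
            categories = [
                bin_occupancy_change(c, k, cfg.occupancy_change_fold,
                                     cfg.occupancy_stable_fold)
                for c, k in zip(s_ctrl, s_kd)
            ]
            report["occupancy"]["cofactor_b"] = {
                cat: categories.count(cat)
                for cat in ("down", "stable", "up", "unclassified")
            }
            report["occupancy"]["categories"] = {
                p.name: cat for p, cat in zip(cof_b, categories)
            }
        for name in ("tf", "cofactor_a"):
            if {f"{name}_ctrl", f"{name}_kd"} <= tracks.keys() and name in peaks:
                prof_c = metagene(compute_matrix(tracks[f"{name}_ctrl"],
                                                 list(peaks[name]),
                                                 cfg.matrix_flank, cfg.matrix_bin))
                prof_k = metagene(compute_matrix(tracks[f"{name}_kd"],
                                                 list(peaks[name]),
                                                 cfg.matrix_flank, cfg.matrix_bin))
                report["occupancy"][f"{name}_summit_decrease_percent"] = round(
                    summit_change(prof_c, prof_k), 1)
        stage_counts[stage] = report["occupancy"].get("cofactor_b", {})
    except Exception as exc:
        raise PipelineError(f"{stage}: {exc}") from exc

    # ---- drug synergy ----------------------------------------------------
    stage = "synergy"
    try:
        report["synergy"] = {}
        for name, matrix in dose_matrices.items():
            res = score_matrix(matrix, cfg.synergy_additive_band)
            report["synergy"][name] = {
                "average_score": round(res.average_score, 2),
                "classification": res.classification,
            }
        stage_counts[stage] = {"n_matrices": len(dose_matrices)}
    except Exception as exc:
        raise PipelineError(f"{stage}: {exc}") from exc

    return report


def run_pipeline(
    data_dir: str,
    config: AnalysisConfig | None = None,
    out_dir: str | None = None,
) -> dict:
    """Load a data directory, run :func:`analyze`, optionally write outputs.

    When ``out_dir`` is given, writes ``report.json`` and ``manifest.json``
    there. The report is deterministic for a given input directory and
    config; the manifest additionally carries a timestamp.
    """
    cfg = config or AnalysisConfig()
    inputs = load_inputs(data_dir)
    report = analyze(inputs["genes"], inputs["peaks"], inputs["tracks"],
                     inputs["de_records"], inputs["dose_matrices"], cfg)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=float)
        manifest = {
            "config": cfg.to_dict(),
            "inputs": inputs["digests"],
            "stage_counts": report["stage_counts"],
            "package": "peakreg 0.1.0",
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        }
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True, default=float)
    return report
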