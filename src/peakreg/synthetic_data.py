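"""Synthetic regulatory-genomics dataset with machine-readable ground truth.

The generator emulates the study design the pipeline targets: a toy
two-chromosome genome with a regular gene grid; a transcription factor
bound both at promoters (of genes it activates, which therefore go down
on knockdown) and at distal enhancers (of differentiation genes it
represses, which go up on knockdown); promoter sites carrying
H3K4me3 + H3K27ac and enhancer sites carrying H3K4me1 + H3K27ac; a
promoter-biased cofactor covering ~70% of the TF's promoter peaks and an
enhancer-restricted cofactor covering its enhancer peaks; knockdown
coverage with planted fold changes (TF signal halved, the promoter
cofactor barely reduced, the enhancer cofactor split into down / stable /
up peaks); a differential-expression table with planted quadrant
membership; and checkerboard dose matrices with planted Bliss excess.

Every record traces to one truth entry, and all randomness flows from a
single seed through named per-file-type streams, so regeneration with the
same seed is byte-identical and adding a file type never perturbs the
others.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import formats_io as fio
from .formats_io import (
    CoverageTrack,
    DERecord,
    DoseMatrix,
    GeneModel,
    GenomicInterval,
    Peak,
)

__all__ = ["SyntheticConfig", "SyntheticDataset", "SyntheticTruth",
           "make_dataset", "generate", "synthesize_dose_matrix"]

# fixed stream ids: appending new file types must not disturb existing ones
_STREAMS = {
    "roles": 0,
    "coverage_ctrl": 1,
    "coverage_kd": 2,
    "de": 3,
    "dose": 4,
    "occupancy": 5,
    "strands": 6,
    "cofactors": 7,
    "supers": 8,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the synthetic dataset.

    The defaults define the generated conditions: gene spacing wide enough
    that each planted enhancer (5.6 kb downstream of its gene's TSS) is
    closer to its own TSS than to any neighbor yet beyond the 5-kb
    near-TSS bin, signal amplitudes with strong promoter/enhancer mark
    contrast, and multiplicative log-normal bin noise (sigma 0.25) at
    which the planted structure is recoverable but not trivially so.
    """

    n_chromosomes: int = 2
    chromosome_length: int = 1_400_000
    #: one gene per slot, TSS at slot + 3000; wider than the 12.5-kb stitch
    #: distance so isolated enhancer peaks in adjacent slots stay unstitched
    slot_width: int = 14_000
    gene_length: int = 2_000

    # gene role counts (must sum to genes available: 100 per chromosome)
    n_promoter_down: int = 60   # TF promoter peak, DE down on knockdown
    n_dual_up: int = 10         # TF promoter + enhancer peaks, DE up
    n_enhancer_up: int = 50     # TF enhancer peak, DE up
    n_bound_not_de: int = 8     # TF promoter peak, no expression change
    n_unbound_de: int = 12      # DE without any TF peak (half up, half down)
    n_background: int = 60      # neither bound nor DE

    # signal geometry
    bump_sd: float = 150.0      # Gaussian bump sd, bp
    bump_halfwidth: int = 450   # truncation at 3 sd
    coverage_bin: int = 10
    peak_halfwidth: int = 200   # emitted TF/cofactor peak half-width
    mark_peak_halfwidth: int = 300
    #: enhancer anchor downstream of the TSS: beyond the 5-kb near-TSS bin
    #: yet closer to its own TSS than to the next gene's
    enhancer_offset: int = 6_500
    promoter_peak_offset: int = -200  # TF promoter anchor relative to TSS

    # amplitudes (arbitrary depth units)
    amp_tf_promoter: float = 30.0
    amp_tf_enhancer: float = 20.0
    amp_k4me3_promoter: float = 40.0
    amp_k4me3_enhancer: float = 1.5
    amp_k4me1_promoter: float = 3.0
    amp_k4me1_enhancer: float = 35.0
    amp_k27ac: float = 30.0
    amp_k27ac_super: float = 45.0
    n_super_sites: int = 6      # enhancer sites promoted to super-enhancer level
    #: extra super-enhancer constituents relative to the site center;
    #: outside the +-3-kb matrix window yet > 2.5 kb from every TSS
    super_flank_offsets: tuple[int, ...] = (-3500, 3500)
    amp_cofactor: float = 25.0
    input_depth: float = 0.5    # flat background/input coverage

    #: log-normal sigma per coverage bin; at 0.2 the resulting peak-center
    #: score noise is ~2.7% multiplicative, a realistic replicate-level
    #: wobble under which the planted structure is recoverable but not
    #: trivially so. 0 = noise-free.
    noise_sigma: float = 0.2

    # knockdown effects
    kd_tf_factor: float = 0.5        # 50% TF signal loss
    kd_cofactor_a_factor: float = 0.95  # 5% loss for the promoter cofactor
    cofactor_a_coverage: float = 0.7    # fraction of TF promoter peaks covered
    occupancy_down_fold: float = 1.5    # planted decrease for "down" peaks
    occupancy_up_fold: float = 1.5      # planted increase for "up" peaks
    occupancy_fractions: tuple[float, float, float] = (0.5, 1 / 3, 1 / 6)  # down/stable/up

    # differential expression
    de_fold_location: float = 0.8   # |FC| = 1.5 + |N(0, location)|
    de_padj_range: tuple[float, float] = (1e-5, 1e-2)
    not_de_fold_max: float = 1.19
    mean_expr_log_mu: float = 4.0
    mean_expr_log_sd: float = 1.0

    # drug synergy
    doses: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 8.0)
    single_agent_emax: tuple[float, float] = (0.45, 0.40)
    single_agent_ec50: tuple[float, float] = (4.0, 3.0)
    planted_excess: tuple[float, ...] = (0.0, 15.0)  # one matrix per value
    viability_noise_sd: float = 0.0  # multiplicative; written matrices are clean

    @property
    def genes_per_chromosome(self) -> int:
        return self.chromosome_length // self.slot_width

    @property
    def n_genes(self) -> int:
        return self.genes_per_chromosome * self.n_chromosomes

    def role_counts(self) -> dict[str, int]:
        return {
            "promoter_down": self.n_promoter_down,
            "dual_up": self.n_dual_up,
            "enhancer_up": self.n_enhancer_up,
            "bound_not_de": self.n_bound_not_de,
            "unbound_de": self.n_unbound_de,
            "background": self.n_background,
        }


@dataclass
class SyntheticTruth:
    """Planted ground truth keyed by emitted record identifiers."""

    seed: int
    params: dict
    peak_class: dict[str, str] = field(default_factory=dict)      # TF peak -> class
    gene_role: dict[str, str] = field(default_factory=dict)
    gene_quadrants: dict[str, list[str]] = field(default_factory=dict)
    occupancy_category: dict[str, str] = field(default_factory=dict)  # cofB peaks
    bliss_excess: dict[str, float] = field(default_factory=dict)      # matrix -> delta
    super_sites: list[str] = field(default_factory=list)  # boosted K27ac peak ids

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


@dataclass
class SyntheticDataset:
    """In-memory view of one generated dataset."""

    config: SyntheticConfig
    genes: list[GeneModel]
    peaks: dict[str, list[Peak]]          # tf, cofactor_a, cofactor_b, h3k4me3, ...
    tracks: dict[str, CoverageTrack]      # tf_ctrl, tf_kd, h3k27ac_ctrl, input, ...
    de_records: list[DERecord]
    dose_matrices: dict[str, DoseMatrix]
    truth: SyntheticTruth


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[name]]))


def _anchor(p: Peak) -> int:
    return p.start + (p.summit_offset or 0)


def _assign_roles(config: SyntheticConfig, seed: int) -> list[str]:
    counts = config.role_counts()
    total = sum(counts.values())
    if total != config.n_genes:
        raise ValueError(
            f"role counts sum to {total} but the genome holds {config.n_genes} genes"
        )
    roles = [role for role, n in counts.items() for _ in range(n)]
    _stream(seed, "roles").shuffle(roles)
    return roles


def _make_genes(config: SyntheticConfig, seed: int) -> list[GeneModel]:
    rng = _stream(seed, "strands")
    genes = []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        for i in range(config.genes_per_chromosome):
            tss = i * config.slot_width + 3000
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                iv = GenomicInterval(chrom, tss, tss + config.gene_length, "+")
            else:
                iv = GenomicInterval(chrom, tss - config.gene_length + 1, tss + 1, "-")
            genes.append(GeneModel(f"g{c + 1:d}_{i:03d}", iv))
    return genes


def _bump_sites(config: SyntheticConfig, genes: Sequence[GeneModel],
                roles: Sequence[str]) -> dict[str, list[tuple[str, int, str]]]:
    """Site lists (gene_id, center, chrom) per site kind."""
    promoter_sites, enhancer_sites = [], []
    for gene, role in zip(genes, roles):
        if role in {"promoter_down", "dual_up", "bound_not_de"}:
            promoter_sites.append((gene.gene_id, gene.tss + config.promoter_peak_offset,
                                   gene.chrom))
        if role in {"enhancer_up", "dual_up"}:
            enhancer_sites.append((gene.gene_id, gene.tss + config.enhancer_offset,
                                   gene.chrom))
    return {"promoter": promoter_sites, "enhancer": enhancer_sites}


def _site_peaks(sites: Sequence[tuple[str, int, str]], prefix: str,
                halfwidth: int) -> list[Peak]:
    peaks = []
    for gene_id, center, chrom in sites:
        iv = GenomicInterval(chrom, center - halfwidth, center + halfwidth)
        peaks.append(Peak(iv, f"{prefix}_{gene_id}", 100.0, halfwidth))
    return peaks


def _coverage(
    config: SyntheticConfig,
    sites: Sequence[tuple[int, float, str]],  # (center, amplitude, chrom)
    rng: np.random.Generator,
    baseline: float = 0.0,
    chrom_names: Sequence[str] = (),
) -> CoverageTrack:
    """Sum of truncated Gaussian bumps, binned, with multiplicative noise.

    A flat ``baseline`` adds coarse 1-kb steps over the whole genome (used
    for the input track). total_reads is set to the realized coverage
    integral so RPKM scaling is self-consistent with the emitted track.
    """
    bin_w = config.coverage_bin
    per_chrom: dict[str, list[np.ndarray]] = {c: [] for c in chrom_names}
    for center, amplitude, chrom in sites:
        lo = (center - config.bump_halfwidth) // bin_w * bin_w
        hi = (center + config.bump_halfwidth + bin_w - 1) // bin_w * bin_w
        starts = np.arange(max(0, lo), hi, bin_w)
        mids = starts + bin_w / 2.0
        values = amplitude * np.exp(-0.5 * ((mids - center) / config.bump_sd) ** 2)
        if config.noise_sigma > 0:
            values = values * rng.lognormal(0.0, config.noise_sigma, len(values))
        per_chrom.setdefault(chrom, []).append(
            np.column_stack((starts, starts + bin_w, values)))
    if baseline > 0 and sites:
        raise ValueError("baseline tracks carry no bump sites")
    steps: dict[str, np.ndarray] = {}
    for chrom in chrom_names:
        blocks = per_chrom.get(chrom, [])
        if baseline > 0:
            starts = np.arange(0, config.chromosome_length, 1000)
            values = np.full(len(starts), baseline)
            if config.noise_sigma > 0:
                values = values * rng.lognormal(0.0, config.noise_sigma, len(values))
            blocks = [np.column_stack((starts, starts + 1000, values))]
        if blocks:
            steps[chrom] = np.vstack(blocks)
        else:
            steps[chrom] = np.zeros((0, 3))
    track = CoverageTrack(steps, total_reads=1.0)
    total = track.total_signal()
    return CoverageTrack(
        {c: track.steps(c) for c in track.chromosomes},
        total_reads=max(total, 1.0),
        resolution_note=f"{bin_w} bp bins, synthetic",
    )


def synthesize_dose_matrix(
    config: SyntheticConfig,
    delta: float,
    rng: np.random.Generator,
    noise_sd: float | None = None,
) -> DoseMatrix:
    """One checkerboard with a uniform planted Bliss excess of ``delta``
    percentage points over every combination cell.

    Single agents follow saturating Hill-type dose responses; combination
    viability is set to the Bliss expectation minus the planted excess,
    then clipped at 0. Multiplicative Gaussian noise (sd ``noise_sd``)
    perturbs every measured cell when requested.
    """
    noise = config.viability_noise_sd if noise_sd is None else noise_sd
    doses = np.asarray(config.doses)
    emax_a, emax_b = config.single_agent_emax
    ec50_a, ec50_b = config.single_agent_ec50
    inh_a = emax_a * doses / (doses + ec50_a)
    inh_b = emax_b * doses / (doses + ec50_b)
    n = len(doses)
    viability = np.empty((n, n))
    viability[:, 0] = 100.0 * (1.0 - inh_a)
    viability[0, :] = 100.0 * (1.0 - inh_b)
    expected = inh_a[1:, None] + inh_b[None, 1:] - inh_a[1:, None] * inh_b[None, 1:]
    viability[1:, 1:] = np.clip(100.0 * (1.0 - expected - delta / 100.0), 0.0, None)
    if noise > 0:
        factors = 1.0 + noise * rng.standard_normal((n, n))
        viability = np.clip(viability * factors, 0.0, None)
        viability[0, 0] = 100.0
    return DoseMatrix(tuple(doses), tuple(doses), viability)


def make_dataset(config: SyntheticConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """Build the whole dataset in memory (see :func:`generate` for files)."""
    config = config or SyntheticConfig()
    chrom_names = [f"chr{c + 1}" for c in range(config.n_chromosomes)]
    genes = _make_genes(config, seed)
    roles = _assign_roles(config, seed)
    truth = SyntheticTruth(seed=seed, params=dataclasses.asdict(config))
    sites = _bump_sites(config, genes, roles)

    # ---- peaks -----------------------------------------------------------
    tf_promoter = _site_peaks(sites["promoter"], "tf_p", config.peak_halfwidth)
    tf_enhancer = _site_peaks(sites["enhancer"], "tf_e", config.peak_halfwidth)
    tf_peaks = tf_promoter + tf_enhancer
    for p in tf_promoter:
        truth.peak_class[p.name] = "promoter_like"
    for p in tf_enhancer:
        truth.peak_class[p.name] = "enhancer_like"

    rng_cof = _stream(seed, "cofactors")
    n_cof_a = round(config.cofactor_a_coverage * len(tf_promoter))
    cof_a_idx = np.sort(rng_cof.choice(len(tf_promoter), n_cof_a, replace=False))
    cofactor_a = [
        Peak(tf_promoter[i].interval, tf_promoter[i].name.replace("tf_p", "cofa"),
             100.0, tf_promoter[i].summit_offset)
        for i in cof_a_idx
    ]
    cofactor_b = [
        Peak(p.interval, p.name.replace("tf_e", "cofb"), 100.0, p.summit_offset)
        for p in tf_enhancer
    ]

    mark_hw = config.mark_peak_halfwidth
    h3k4me3 = _site_peaks(sites["promoter"], "k4me3", mark_hw)
    h3k4me1 = _site_peaks(sites["enhancer"], "k4me1", mark_hw)
    h3k27ac = (_site_peaks(sites["promoter"], "k27ac_p", mark_hw)
               + _site_peaks(sites["enhancer"], "k27ac_e", mark_hw))

    # ---- occupancy categories for the enhancer cofactor ------------------
    rng_occ = _stream(seed, "occupancy")
    f_down, f_stable, _ = config.occupancy_fractions
    n_b = len(cofactor_b)
    n_down = round(f_down * n_b)
    n_stable = round(f_stable * n_b)
    categories = (["down"] * n_down + ["stable"] * n_stable
                  + ["up"] * (n_b - n_down - n_stable))
    rng_occ.shuffle(categories)
    kd_factor_b = {}
    for peak, cat in zip(cofactor_b, categories):
        truth.occupancy_category[peak.name] = cat
        kd_factor_b[peak.name] = {
            "down": 1.0 / config.occupancy_down_fold,
            "stable": 1.0,
            "up": config.occupancy_up_fold,
        }[cat]

    # ---- super-enhancer sites: boost K27ac at a few enhancer loci --------
    enh_k27 = [p for p in h3k27ac if p.name.startswith("k27ac_e")]
    rng_sup = _stream(seed, "supers")
    super_idx = np.sort(rng_sup.choice(len(enh_k27), config.n_super_sites,
                                       replace=False)) if enh_k27 else []
    super_names = {enh_k27[i].name for i in super_idx}
    truth.super_sites = sorted(super_names)
    # a super-enhancer is a stitched cluster: give each chosen site extra
    # flanking constituents (still distal) plus a modestly taller center
    super_flanks: list[Peak] = []
    for i in super_idx:
        center_peak = enh_k27[i]
        center = _anchor(center_peak)
        for off in config.super_flank_offsets:
            iv = GenomicInterval(center_peak.chrom, center + off - mark_hw,
                                 center + off + mark_hw)
            super_flanks.append(
                Peak(iv, f"{center_peak.name}_f{off:+d}", 100.0, mark_hw))
    h3k27ac = h3k27ac + super_flanks

    # ---- coverage tracks -------------------------------------------------
    def site_list(peaks: Sequence[Peak], amp) -> list[tuple[int, float, str]]:
        if callable(amp):
            return [(_anchor(p), amp(p), p.chrom) for p in peaks]
        return [(_anchor(p), amp, p.chrom) for p in peaks]

    rng_c = _stream(seed, "coverage_ctrl")
    rng_k = _stream(seed, "coverage_kd")
    cov = lambda sites_, rng_, baseline=0.0: _coverage(
        config, sites_, rng_, baseline, chrom_names)

    tf_sites = (site_list(tf_promoter, config.amp_tf_promoter)
                + site_list(tf_enhancer, config.amp_tf_enhancer))
    k27_amp = lambda p: (config.amp_k27ac_super if p.name in super_names
                         else config.amp_k27ac)
    tracks = {
        "tf_ctrl": cov(tf_sites, rng_c),
        "cofactor_a_ctrl": cov(site_list(cofactor_a, config.amp_cofactor), rng_c),
        "cofactor_b_ctrl": cov(site_list(cofactor_b, config.amp_cofactor), rng_c),
        "h3k4me3_ctrl": cov(
            site_list(h3k4me3, config.amp_k4me3_promoter)
            + site_list(h3k4me1, config.amp_k4me3_enhancer), rng_c),
        "h3k4me1_ctrl": cov(
            site_list(h3k4me3, config.amp_k4me1_promoter)
            + site_list(h3k4me1, config.amp_k4me1_enhancer), rng_c),
        "h3k27ac_ctrl": cov(site_list(h3k27ac, k27_amp), rng_c),
        "input": cov([], rng_c, baseline=config.input_depth),
    }
    kd_scale = lambda peaks, base, factor: [
        (_anchor(p), base * factor(p), p.chrom) for p in peaks]
    tracks["tf_kd"] = cov(
        kd_scale(tf_promoter, config.amp_tf_promoter,
                 lambda p: config.kd_tf_factor)
        + kd_scale(tf_enhancer, config.amp_tf_enhancer,
                   lambda p: config.kd_tf_factor), rng_k)
    tracks["cofactor_a_kd"] = cov(
        kd_scale(cofactor_a, config.amp_cofactor,
                 lambda p: config.kd_cofactor_a_factor), rng_k)
    tracks["cofactor_b_kd"] = cov(
        kd_scale(cofactor_b, config.amp_cofactor,
                 lambda p: kd_factor_b[p.name]), rng_k)

    # ---- differential expression ----------------------------------------
    rng_de = _stream(seed, "de")
    lo_p, hi_p = config.de_padj_range
    de_records = []
    unbound_flip = 0
    for gene, role in zip(genes, roles):
        truth.gene_role[gene.gene_id] = role
        quadrants: list[str] = []
        if role == "promoter_down":
            fc = -(1.5 + abs(rng_de.normal(0.0, config.de_fold_location)))
            padj = float(np.exp(rng_de.uniform(np.log(lo_p), np.log(hi_p))))
            quadrants = ["promoter_down"]
        elif role in {"dual_up", "enhancer_up", "unbound_de"}:
            magnitude = 1.5 + abs(rng_de.normal(0.0, config.de_fold_location))
            if role == "unbound_de":
                unbound_flip += 1
                sign = 1.0 if unbound_flip % 2 else -1.0
                quadrants = ["unbound_de"]
            else:
                sign = 1.0
                quadrants = (["promoter_up", "enhancer_up"] if role == "dual_up"
                             else ["enhancer_up"])
            fc = sign * magnitude
            padj = float(np.exp(rng_de.uniform(np.log(lo_p), np.log(hi_p))))
        else:  # bound_not_de, background
            fc = float(rng_de.uniform(1.0, config.not_de_fold_max))
            fc *= 1.0 if rng_de.random() < 0.5 else -1.0
            padj = float(rng_de.uniform(0.2, 1.0))
            quadrants = ["bound_not_de"] if role == "bound_not_de" else []
        mean_expr = float(rng_de.lognormal(config.mean_expr_log_mu,
                                           config.mean_expr_log_sd))
        de_records.append(DERecord(gene.gene_id, float(fc), padj, mean_expr))
        truth.gene_quadrants[gene.gene_id] = quadrants

    # ---- dose matrices ---------------------------------------------------
    rng_dose = _stream(seed, "dose")
    dose_matrices = {}
    for delta in config.planted_excess:
        name = f"combo_excess_{delta:g}"
        dose_matrices[name] = synthesize_dose_matrix(config, delta, rng_dose)
        truth.bliss_excess[name] = float(delta)

    peaks = {
        "tf": tf_peaks,
        "cofactor_a": cofactor_a,
        "cofactor_b": cofactor_b,
        "h3k4me3": h3k4me3,
        "h3k4me1": h3k4me1,
        "h3k27ac": h3k27ac,
    }
    return SyntheticDataset(config, genes, peaks, tracks, de_records,
                            dose_matrices, truth)


def generate(
    config: SyntheticConfig | None = None,
    seed: int = 0,
    out_dir: str = ".",
) -> SyntheticTruth:
    """Generate the dataset and write every file plus ``truth.json``.

    Emits narrowPeak peak sets, bedGraph coverage tracks with a
    ``tracks.json`` of library sizes, the gene-model and DE TSVs, dose
    CSVs and the ground-truth JSON. Deterministic per seed.
    """
    dataset = make_dataset(config, seed)
    os.makedirs(out_dir, exist_ok=True)
    path = lambda name: os.path.join(out_dir, name)
    fio.write_gene_model(dataset.genes, path("genes.tsv"))
    fio.write_de_table(dataset.de_records, path("de_table.tsv"))
    for name, peaks in dataset.peaks.items():
        fio.write_peaks(peaks, path(f"{name}_peaks.narrowPeak"))
    library_sizes = {}
    for name, track in dataset.tracks.items():
        fio.write_bedgraph(track, path(f"{name}.bedgraph"))
        library_sizes[name] = track.total_reads
    with open(path("tracks.json"), "w") as fh:
        json.dump(library_sizes, fh, indent=1, sort_keys=True)
    for name, matrix in dataset.dose_matrices.items():
        fio.write_dose_matrix(matrix, path(f"{name}.csv"))
    with open(path("truth.json"), "w") as fh:
        fh.write(dataset.truth.to_json())
    return dataset.truth
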