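"""Synthetic fixture generator with embedded ground truth.

Emulates the data shapes the pipeline consumes on a small genome:

* clustered vs singleton ChIP-seq peaks for two co-distributed factors
  ("at3" everywhere, "vcp" at the same sites jittered by <= 50 bp), plus
  H3K27ac peaks flanking sites and spanning clusters;
* Poisson-noise coverage tracks for both factors plus an input track,
  binned bedGraphs at a fixed bin size;
* negative-binomial PET loops joining H3K27ac enhancer anchors to promoter
  anchors, with directly assigned per-loop FDRs so a configured number of
  loops passes the high-confidence filter, and a depleted condition in
  which true VCP-loop PET means are multiplied by a depletion factor;
* knockdown expression contrasts whose target-gene effects scale with the
  true aggregate propensity; and spiked-interactor proteomics tables.

Layout is deterministic: loci sit on a jittered grid with spacing far
above the stitch distance, so planted clusters are exactly the stitched
regions a correct caller should recover.  Every operation is a pure
function of (config, seed); each output family draws from its own RNG
stream so adding one output never perturbs another.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import Anchor, Gene, GenomeModel, Loop, Peak
from .tracks import CoverageTrack
from . import io as _io

_STREAMS = {
    "layout": 1,
    "peaks": 2,
    "tracks": 3,
    "loops": 4,
    "expression": 5,
    "proteomics": 6,
}


def _rng(seed: int, family: str) -> np.random.Generator:
    return np.random.default_rng((int(seed), _STREAMS[family]))


@dataclass
class SimulationConfig:
    # genome layout
    n_chromosomes: int = 3
    chromosome_length: int = 15_000_000
    locus_spacing: int = 70_000
    chromosome_margin: int = 200_000
    # peaks
    n_singleton_peaks: int = 200
    frac_singleton_promoter: float = 0.5
    n_clusters: int = 20
    peaks_per_cluster: int = 5
    cluster_span: int = 20_000
    peak_width: int = 500
    vcp_jitter: int = 50
    h3k27ac_width: int = 1000
    promoter_h3k27ac_width: int = 2000
    stitch_distance: int = 40_000  # used only to validate planted geometry
    # coverage signal (counts per bin at a realistic sequencing depth:
    # background ~10 per 50 bp bin, singleton TF peaks ~5x background,
    # cluster constituents signal_fold above singletons)
    background_mean: float = 10.0
    singleton_peak_mean: float = 50.0
    signal_fold: float = 4.0
    site_strength_range: tuple[float, float] = (0.7, 1.5)
    factor_correlation: float = 0.9
    bin_size: int = 50
    noise: bool = True
    # loops
    n_loops: int = 120
    n_loops_pass: int = 100
    frac_loops_vcp: float = 0.5
    loop_pet_mean: float = 24.0
    loop_pet_dispersion: float = 10.0
    loop_strength_range: tuple[float, float] = (0.75, 1.5)
    pass_min_pets: int = 4
    pass_max_fdr: float = 0.01
    depletion_factor: float = 0.5
    # expression
    knockdown_effect: float = 2.0
    knockdown_noise: float = 0.5
    effect_correlation: float = 0.8
    n_background_genes: int = 100
    # proteomics
    n_proteins: int = 1000
    n_interactors: int = 15
    interactor_fc_range: tuple[float, float] = (3.0, 8.0)
    n_ip_channels: int = 3
    n_control_channels: int = 3

    def __post_init__(self) -> None:
        counts = [
            self.n_chromosomes,
            self.n_singleton_peaks,
            self.n_clusters,
            self.peaks_per_cluster,
            self.n_loops,
            self.n_loops_pass,
            self.n_proteins,
            self.n_interactors,
            self.n_background_genes,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if self.n_clusters > 0 and self.peaks_per_cluster < 1:
            raise ValueError("clusters need >= 1 peak")
        if not (0.0 <= self.frac_loops_vcp <= 1.0):
            raise ValueError("frac_loops_vcp must be in [0, 1]")
        if self.n_loops_pass > self.n_loops:
            raise ValueError("n_loops_pass cannot exceed n_loops")
        if not (0.0 < self.depletion_factor <= 1.0):
            raise ValueError("depletion factor must be in (0, 1]")
        if not (-1.0 <= self.factor_correlation <= 1.0):
            raise ValueError("factor_correlation must be in [-1, 1]")
        if not (-1.0 <= self.effect_correlation <= 1.0):
            raise ValueError("effect_correlation must be in [-1, 1]")
        if self.knockdown_noise <= 0:
            raise ValueError("knockdown noise must be > 0")
        if self.peaks_per_cluster > 1:
            gap = (
                self.cluster_span
                - self.peaks_per_cluster * self.peak_width
            ) / (self.peaks_per_cluster - 1)
            if gap < 0:
                raise ValueError("cluster_span too small for its peaks")
            if gap > self.stitch_distance:
                raise ValueError(
                    "cluster_span incompatible with the stitch distance: "
                    f"inter-peak gap {gap:.0f} bp exceeds {self.stitch_distance} bp"
                )
        if self.cluster_span >= self.chromosome_length:
            raise ValueError(
                "cluster_span incompatible with chromosome length"
            )
        if self.signal_fold <= 0 or self.singleton_peak_mean <= 0:
            raise ValueError("signal levels must be positive")


@dataclass
class PlannedLoop:
    """Internal layout record for one planted loop."""

    name: str
    enhancer_anchor: tuple[str, int, int]
    promoter_anchor: tuple[str, int, int]
    gene_id: str
    is_vcp: bool  # enhancer anchor carries VCP peaks
    passes: bool = False
    fail_mode: str = ""  # "" | "pet" | "fdr"
    pet_mean: float = float("nan")
    cluster_index: int = -1


@dataclass
class SimulationTruth:
    true_region_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    true_target_genes: dict[str, float] = field(default_factory=dict)
    true_vcp_loops: list[str] = field(default_factory=list)
    true_control_loops: list[str] = field(default_factory=list)
    depletion_factor: float = 1.0
    interactor_proteins: dict[str, float] = field(default_factory=dict)
    rng_seed: int = 0
    # plumbing needed by downstream stages / acceptance checks
    enhancer_target_genes: list[str] = field(default_factory=list)
    promoter_target_genes: list[str] = field(default_factory=list)
    all_genes: list[str] = field(default_factory=list)
    knockdown_effect: float = 0.0
    knockdown_noise: float = 1.0
    effect_correlation: float = 0.0
    planned_loops: list[PlannedLoop] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_region_intervals": [list(r) for r in self.true_region_intervals],
            "true_target_genes": self.true_target_genes,
            "true_vcp_loops": self.true_vcp_loops,
            "true_control_loops": self.true_control_loops,
            "depletion_factor": self.depletion_factor,
            "interactor_proteins": self.interactor_proteins,
            "rng_seed": self.rng_seed,
            "enhancer_target_genes": self.enhancer_target_genes,
            "promoter_target_genes": self.promoter_target_genes,
            "all_genes": self.all_genes,
            "knockdown_effect": self.knockdown_effect,
            "knockdown_noise": self.knockdown_noise,
            "effect_correlation": self.effect_correlation,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---- genome, peaks and layout ------------------------------------------


def simulate_genome_and_peaks(
    config: SimulationConfig, seed: int
) -> tuple[GenomeModel, dict[str, list[Peak]], SimulationTruth]:
    """Plant the locus layout, emit per-factor peaks and the truth skeleton.

    Factor "at3" peaks appear at every site; "vcp" peaks at the same sites
    jittered by at most ``vcp_jitter`` bp; "h3k27ac" peaks span clusters,
    flank singleton sites, and mark loop-target promoters.  Peak ``score``
    carries the planted mean coverage for the track simulator.
    """
    layout_rng = _rng(seed, "layout")
    peak_rng = _rng(seed, "peaks")

    # VCP loops need a clustered enhancer anchor; with no clusters planted,
    # every loop degrades to a control loop
    if config.n_clusters > 0:
        n_vcp_loops = round(config.n_loops * config.frac_loops_vcp)
    else:
        n_vcp_loops = 0
    n_ctrl_loops = config.n_loops - n_vcp_loops

    n_prom_singletons = round(config.n_singleton_peaks * config.frac_singleton_promoter)
    n_distal_singletons = config.n_singleton_peaks - n_prom_singletons

    # units: list of (kind, payload); each unit occupies consecutive slots
    units: list[tuple[str, int]] = []
    genes_per_cluster = [0] * max(config.n_clusters, 1)
    for i in range(n_vcp_loops):
        genes_per_cluster[i % config.n_clusters] += 1
    for c in range(config.n_clusters):
        units.append(("cluster", c))
    for i in range(n_ctrl_loops):
        units.append(("control_loop", i))
    for i in range(n_prom_singletons):
        units.append(("prom_singleton", i))
    for i in range(n_distal_singletons):
        units.append(("distal_singleton", i))
    for i in range(config.n_background_genes):
        units.append(("background_gene", i))

    def unit_slots(kind: str, idx: int) -> int:
        if kind == "cluster":
            return 1 + genes_per_cluster[idx]
        if kind == "control_loop":
            return 2
        return 1

    usable = config.chromosome_length - 2 * config.chromosome_margin
    slots_per_chrom = usable // config.locus_spacing
    if slots_per_chrom < 1:
        raise ValueError("chromosome too short for the locus spacing")

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    jitter_half = max(config.locus_spacing // 10, 1)

    slot_positions: list[tuple[str, int]] = []  # (chrom, position) per slot
    chrom_i, slot_i = 0, 0
    for kind, idx in units:
        need = unit_slots(kind, idx)
        if slot_i + need > slots_per_chrom:
            chrom_i += 1
            slot_i = 0
        if chrom_i >= config.n_chromosomes or need > slots_per_chrom:
            raise ValueError(
                "genome too small for the configured loci; increase "
                "chromosome_length or n_chromosomes, or reduce counts"
            )
        for _ in range(need):
            pos = (
                config.chromosome_margin
                + slot_i * config.locus_spacing
                + int(layout_rng.integers(-jitter_half, jitter_half + 1))
            )
            slot_positions.append((chrom_names[chrom_i], pos))
            slot_i += 1

    genes: list[Gene] = []
    at3_peaks: list[Peak] = []
    vcp_peaks: list[Peak] = []
    k27_peaks: list[Peak] = []
    truth = SimulationTruth(
        depletion_factor=config.depletion_factor,
        rng_seed=seed,
        knockdown_effect=config.knockdown_effect,
        knockdown_noise=config.knockdown_noise,
        effect_correlation=config.effect_correlation,
    )

    w = config.peak_width
    half_w = w // 2
    s_lo, s_hi = config.site_strength_range
    rho = config.factor_correlation

    def strengths() -> tuple[float, float]:
        sa = float(peak_rng.uniform(s_lo, s_hi))
        u = float(peak_rng.uniform(s_lo, s_hi))
        sb = rho * sa + (1.0 - rho) * u
        return sa, sb

    def add_site(chrom: str, center: int, name: str, fold: float) -> None:
        sa, sb = strengths()
        mean_a = fold * config.singleton_peak_mean * sa
        mean_b = fold * config.singleton_peak_mean * sb
        at3_peaks.append(Peak(chrom, center - half_w, center - half_w + w, name, mean_a))
        jit = int(peak_rng.integers(-config.vcp_jitter, config.vcp_jitter + 1))
        vcp_peaks.append(
            Peak(
                chrom,
                center - half_w + jit,
                center - half_w + w + jit,
                name.replace("at3", "vcp"),
                mean_b,
            )
        )

    si = iter(slot_positions)
    gene_counter = 0

    def new_gene(chrom: str, tss: int, prefix: str) -> Gene:
        nonlocal gene_counter
        gene_counter += 1
        g = Gene(f"{prefix}_{gene_counter:04d}", chrom, tss, "+")
        genes.append(g)
        return g

    k27w = config.h3k27ac_width
    pk27w = config.promoter_h3k27ac_width
    cluster_anchor: list[tuple[str, int, int]] = []
    loop_plan: list[PlannedLoop] = []

    for c in range(config.n_clusters):
        chrom, pos = next(si)
        if config.peaks_per_cluster > 1:
            step = config.cluster_span / (config.peaks_per_cluster - 1)
            centers = [pos + int(round(i * step)) for i in range(config.peaks_per_cluster)]
        else:
            centers = [pos]
        for j, center in enumerate(centers):
            add_site(chrom, center, f"at3_cluster{c:03d}_{j}", config.signal_fold)
        start = centers[0] - half_w
        end = centers[-1] - half_w + w
        truth.true_region_intervals.append((chrom, start, end))
        anchor = (chrom, start - k27w, end + k27w)
        cluster_anchor.append(anchor)
        k27_peaks.append(
            Peak(chrom, anchor[1], anchor[2], f"k27_cluster{c:03d}", None)
        )
        for _ in range(genes_per_cluster[c]):
            gchrom, gpos = next(si)
            g = new_gene(gchrom, gpos, "gene_enh")
            truth.enhancer_target_genes.append(g.gene_id)
            k27_peaks.append(
                Peak(
                    gchrom,
                    gpos - pk27w // 2,
                    gpos + pk27w - pk27w // 2,
                    f"k27_prom_{g.gene_id}",
                    None,
                )
            )
            loop_plan.append(
                PlannedLoop(
                    name=f"loop_{len(loop_plan):04d}",
                    enhancer_anchor=anchor,
                    promoter_anchor=(gchrom, gpos - pk27w // 2, gpos + pk27w - pk27w // 2),
                    gene_id=g.gene_id,
                    is_vcp=True,
                    cluster_index=c,
                )
            )

    for i in range(n_ctrl_loops):
        echrom, epos = next(si)
        enh = (echrom, epos - pk27w // 2, epos + pk27w - pk27w // 2)
        k27_peaks.append(Peak(echrom, enh[1], enh[2], f"k27_ctrlenh{i:03d}", None))
        gchrom, gpos = next(si)
        g = new_gene(gchrom, gpos, "gene_ctrl")
        prom = (gchrom, gpos - pk27w // 2, gpos + pk27w - pk27w // 2)
        k27_peaks.append(Peak(gchrom, prom[1], prom[2], f"k27_prom_{g.gene_id}", None))
        loop_plan.append(
            PlannedLoop(
                name=f"loop_{len(loop_plan):04d}",
                enhancer_anchor=enh,
                promoter_anchor=prom,
                gene_id=g.gene_id,
                is_vcp=False,
            )
        )

    for i in range(n_prom_singletons):
        chrom, pos = next(si)
        g = new_gene(chrom, pos, "gene_prom")
        truth.promoter_target_genes.append(g.gene_id)
        add_site(chrom, pos, f"at3_prom_{g.gene_id}", 1.0)
        for side, lo in (("l", pos - half_w - k27w), ("r", pos + w - half_w)):
            k27_peaks.append(
                Peak(chrom, lo, lo + k27w, f"k27_flank_{g.gene_id}_{side}", None)
            )

    for i in range(n_distal_singletons):
        chrom, pos = next(si)
        add_site(chrom, pos, f"at3_distal{i:03d}", 1.0)
        for side, lo in (("l", pos - half_w - k27w), ("r", pos + w - half_w)):
            k27_peaks.append(
                Peak(chrom, lo, lo + k27w, f"k27_flank_distal{i:03d}_{side}", None)
            )

    for i in range(config.n_background_genes):
        chrom, pos = next(si)
        new_gene(chrom, pos, "gene_bg")

    genome = GenomeModel(
        [(name, config.chromosome_length) for name in chrom_names], genes
    )
    truth.all_genes = [g.gene_id for g in genes]
    truth.planned_loops = loop_plan

    # promoter-context contribution to the true aggregate propensity
    frac_in_window = min(w, 1000) / 1000.0
    bg = config.background_mean
    for p in at3_peaks:
        if p.name.startswith("at3_prom_"):
            gene_id = p.name[len("at3_prom_") :]
            expected = bg + frac_in_window * (p.score - bg)
            truth.true_target_genes[gene_id] = expected

    peaks = {"at3": at3_peaks, "vcp": vcp_peaks, "h3k27ac": k27_peaks}
    for plist in peaks.values():
        plist.sort(key=lambda p: (p.chrom, p.start, p.end, p.name))
    return genome, peaks, truth


# ---- coverage tracks ----------------------------------------------------


def _mean_array(
    genome: GenomeModel, peaks: list[Peak], background: float, bin_size: int
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for chrom, length in genome.chromosomes:
        n_bins = math.ceil(length / bin_size)
        out[chrom] = np.full(n_bins, background, dtype=float)
    for p in peaks:
        if p.score is None:
            continue
        arr = out[p.chrom]
        b0 = p.start // bin_size
        b1 = (p.end - 1) // bin_size
        for b in range(b0, b1 + 1):
            lo = max(p.start, b * bin_size)
            hi = min(p.end, (b + 1) * bin_size)
            frac = (hi - lo) / bin_size
            arr[b] += frac * (p.score - background)
    return out


def simulate_tracks(
    genome: GenomeModel,
    peaks: dict[str, list[Peak]],
    config: SimulationConfig,
    seed: int,
) -> tuple[dict[str, CoverageTrack], CoverageTrack]:
    """Binned coverage for both factors plus input.

    Per-bin values are Poisson draws around the planted means (the peak
    ``score`` inside peaks, the background mean elsewhere; the input track
    is pure background).  With ``noise=False`` values equal the means
    exactly.
    """
    rng = _rng(seed, "tracks")
    bin_size = config.bin_size
    lengths = genome.chrom_lengths
    for plist in peaks.values():
        for p in plist:
            if p.end > lengths.get(p.chrom, -1):
                raise ValueError(f"peak {p.name} outside chromosome {p.chrom}")

    def build(means: dict[str, np.ndarray]) -> CoverageTrack:
        data = {}
        for chrom, length in genome.chromosomes:
            m = means[chrom]
            values = rng.poisson(m).astype(float) if config.noise else m.copy()
            starts = np.arange(len(m), dtype=np.int64) * bin_size
            ends = np.minimum(starts + bin_size, length)
            data[chrom] = (starts, ends, values)
        return CoverageTrack(data)

    chip_tracks = {}
    for factor in ("at3", "vcp"):
        means = _mean_array(genome, peaks[factor], config.background_mean, bin_size)
        chip_tracks[factor] = build(means)
    input_means = {
        chrom: np.full(math.ceil(length / bin_size), config.background_mean)
        for chrom, length in genome.chromosomes
    }
    input_track = build(input_means)
    return chip_tracks, input_track


# ---- loops --------------------------------------------------------------


def _negbin_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """NegBin(mean, dispersion k): var = mean + mean^2 / k."""
    k = dispersion
    p = k / (k + mean)
    return int(rng.negative_binomial(k, p))


def _negbin_at_least(
    rng: np.random.Generator, mean: float, dispersion: float, minimum: int
) -> int:
    for _ in range(10_000):
        x = _negbin_draw(rng, mean, dispersion)
        if x >= minimum:
            return x
    raise RuntimeError("negative-binomial rejection sampling failed to reach minimum")


def simulate_loops(
    genome: GenomeModel,
    peaks: dict[str, list[Peak]],
    config: SimulationConfig,
    seed: int,
    truth: SimulationTruth,
) -> tuple[list[Loop], list[Loop]]:
    """Emit baseline and depleted loop sets; update the truth record.

    A configured number of loops passes the high-confidence filter by
    construction: passing loops draw PET counts conditioned on >= the
    retention minimum (both conditions, so a depletion factor of 1 leaves
    the distributions identical) and FDR below the retention cutoff;
    failing loops alternate between a PET deficit and an FDR excess.
    In the depleted condition the PET mean of true (passing) VCP loops is
    multiplied by the depletion factor and the noise resampled.  Also
    updates the enhancer-loop part of the true target propensities using
    expected normalized loop scores.
    """
    rng = _rng(seed, "loops")
    plan = truth.planned_loops
    if not plan:
        if config.n_loops:
            raise ValueError("no loops planned; run simulate_genome_and_peaks first")
        return [], []

    lo, hi = config.loop_strength_range
    for pl in plan:
        pl.pet_mean = config.loop_pet_mean * float(rng.uniform(lo, hi))

    order = rng.permutation(len(plan))
    for rank, idx in enumerate(order):
        plan[idx].passes = rank < config.n_loops_pass
    fail_toggle = 0
    for pl in plan:
        if not pl.passes:
            pl.fail_mode = "pet" if fail_toggle % 2 == 0 else "fdr"
            fail_toggle += 1

    truth.true_vcp_loops = [pl.name for pl in plan if pl.passes and pl.is_vcp]
    truth.true_control_loops = [pl.name for pl in plan if pl.passes and not pl.is_vcp]
    # only genes whose loop survives the confidence filter are truly
    # enhancer-targeted; failing loops leave their gene untargeted
    truth.enhancer_target_genes = sorted(
        {pl.gene_id for pl in plan if pl.passes and pl.is_vcp}
    )

    fdrs: dict[str, float] = {}
    for pl in plan:
        if pl.passes or pl.fail_mode == "pet":
            fdrs[pl.name] = float(rng.uniform(1e-6, 0.9 * config.pass_max_fdr))
        else:
            fdrs[pl.name] = float(rng.uniform(2 * config.pass_max_fdr, 0.5))

    def draw_condition(depleted: bool) -> list[Loop]:
        out = []
        for pl in plan:
            mean = pl.pet_mean
            if depleted and pl.passes and pl.is_vcp:
                mean *= config.depletion_factor
            if pl.passes:
                pet = _negbin_at_least(
                    rng, mean, config.loop_pet_dispersion, config.pass_min_pets
                )
            elif pl.fail_mode == "pet":
                pet = int(rng.integers(0, config.pass_min_pets))
            else:
                pet = _negbin_draw(rng, mean, config.loop_pet_dispersion)
            out.append(
                Loop(
                    Anchor(*pl.enhancer_anchor),
                    Anchor(*pl.promoter_anchor),
                    pl.name,
                    pet,
                    fdrs[pl.name],
                )
            )
        return out

    baseline = draw_condition(depleted=False)
    depleted = draw_condition(depleted=True)

    # enhancer-loop contribution to true propensity: expected window
    # enrichment of each cluster peak times the loop's expected NLS
    passing = [pl for pl in plan if pl.passes]
    if passing:
        mean_pet = float(np.mean([pl.pet_mean for pl in passing]))
        at3_by_name = {p.name: p for p in peaks["at3"]}
        bg = config.background_mean
        frac = min(config.peak_width, 1000) / 1000.0
        for pl in passing:
            if not pl.is_vcp:
                # control-loop genes are looped but carry no factor signal
                truth.true_target_genes.setdefault(pl.gene_id, 0.0)
                continue
            nls_exp = pl.pet_mean / mean_pet
            contrib = 0.0
            for j in range(config.peaks_per_cluster):
                peak = at3_by_name[f"at3_cluster{pl.cluster_index:03d}_{j}"]
                contrib += (bg + frac * (peak.score - bg)) * nls_exp
            truth.true_target_genes[pl.gene_id] = (
                truth.true_target_genes.get(pl.gene_id, 0.0) + contrib
            )
    return baseline, depleted


# ---- expression and proteomics -----------------------------------------


def simulate_expression_and_proteomics(
    truth: SimulationTruth,
    config: SimulationConfig,
    seed: int,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Knockdown contrasts for two perturbations plus proteomics tables.

    Target-gene log2 fold change is ``-beta * scaled propensity`` plus
    Gaussian noise whose two perturbation components share correlation
    ``effect_correlation``; non-targets are pure noise.  Adjusted p-values
    come from the known noise scale with BH correction.  The protein table
    carries the planted interactor fold enrichments and q-values verbatim;
    the PSM table realizes them at reporter-intensity level.
    """
    rng = _rng(seed, "expression")
    beta = config.knockdown_effect
    sigma = config.knockdown_noise
    rho = config.effect_correlation

    genes = list(truth.all_genes)
    props = np.array([truth.true_target_genes.get(g, 0.0) for g in genes])
    max_prop = props.max() if props.max() > 0 else 1.0
    scaled = props / max_prop

    # rho is the planted total inter-perturbation correlation among target
    # genes; the shared -beta * propensity term already contributes
    # var(effect), so the noise correlation is solved to land the total
    # correlation exactly at rho (clamped when infeasible)
    is_target = props > 0
    v = float(np.var(-beta * scaled[is_target])) if is_target.any() else 0.0
    rho_noise = (rho * (v + sigma**2) - v) / sigma**2
    rho_noise = min(max(rho_noise, -1.0), 1.0)

    z_a = rng.standard_normal(len(genes))
    z_ind = rng.standard_normal(len(genes))
    z_b = np.where(
        is_target,
        rho_noise * z_a + math.sqrt(max(1.0 - rho_noise**2, 0.0)) * z_ind,
        z_ind,
    )

    contrasts: dict[str, pd.DataFrame] = {}
    for label, z in (("siA", z_a), ("siB", z_b)):
        log2fc = -beta * scaled + sigma * z
        p = 2.0 * stats.norm.sf(np.abs(log2fc) / sigma)
        padj = multipletests(p, method="fdr_bh")[1]
        contrasts[label] = pd.DataFrame(
            {"gene_id": genes, "contrast": label, "log2fc": log2fc, "padj": padj}
        )

    prot_rng = _rng(seed, "proteomics")
    n = config.n_proteins
    protein_ids = [f"prot_{i:05d}" for i in range(n)]
    interactor_idx = sorted(
        prot_rng.choice(n, size=config.n_interactors, replace=False).tolist()
    )
    fc_lo, fc_hi = config.interactor_fc_range
    fold = np.exp(prot_rng.normal(0.0, 0.05, size=n))  # nulls centered at 1
    qval = prot_rng.uniform(0.05, 1.0, size=n)
    truth.interactor_proteins = {}
    for i in interactor_idx:
        fold[i] = float(prot_rng.uniform(fc_lo, fc_hi))
        qval[i] = float(10.0 ** prot_rng.uniform(-6, -3))
        truth.interactor_proteins[protein_ids[i]] = float(fold[i])
    proteins = pd.DataFrame(
        {"protein_id": protein_ids, "fold_enrichment": fold, "q_value": qval}
    )

    ip_cols = [f"ip_{i + 1}" for i in range(config.n_ip_channels)]
    ctrl_cols = [f"igg_{i + 1}" for i in range(config.n_control_channels)]
    rows = []
    for i, pid in enumerate(protein_ids):
        n_pep = int(prot_rng.integers(1, 5))
        for j in range(n_pep):
            base = float(2.0 ** prot_rng.normal(16.0, 1.0))
            pep = f"PEP_{pid}_{j}"
            ctrl_level = base * 2.0 ** prot_rng.normal(0.0, 0.25, len(ctrl_cols))
            ip_level = (
                base
                * fold[i]
                * 2.0 ** prot_rng.normal(0.0, 0.25, len(ip_cols))
            )
            n_psm = int(prot_rng.integers(1, 4))
            for _ in range(n_psm):
                row = {"protein_id": pid, "peptide": pep}
                for col, lvl in zip(ctrl_cols, ctrl_level):
                    row[col] = lvl * 2.0 ** prot_rng.normal(0.0, 0.1)
                for col, lvl in zip(ip_cols, ip_level):
                    row[col] = lvl * 2.0 ** prot_rng.normal(0.0, 0.1)
                rows.append(row)
    psm = pd.DataFrame(rows)
    return contrasts, psm, proteins


# ---- one-call pipeline and file emission -------------------------------


@dataclass
class SimulatedDataset:
    genome: GenomeModel
    peaks: dict[str, list[Peak]]
    tracks: dict[str, CoverageTrack]
    input_track: CoverageTrack
    loops_baseline: list[Loop]
    loops_depleted: list[Loop]
    expression: dict[str, pd.DataFrame]
    psm: pd.DataFrame
    proteins: pd.DataFrame
    truth: SimulationTruth


def simulate_dataset(
    config: SimulationConfig | None = None,
    seed: int = 0,
    with_tracks: bool = True,
) -> SimulatedDataset:
    """Run every simulation stage in order on one (config, seed)."""
    config = config or SimulationConfig()
    genome, peaks, truth = simulate_genome_and_peaks(config, seed)
    if with_tracks:
        tracks, input_track = simulate_tracks(genome, peaks, config, seed)
    else:
        tracks, input_track = {}, CoverageTrack({})
    baseline, depleted = simulate_loops(genome, peaks, config, seed, truth)
    expression, psm, proteins = simulate_expression_and_proteomics(truth, config, seed)
    return SimulatedDataset(
        genome,
        peaks,
        tracks,
        input_track,
        baseline,
        depleted,
        expression,
        psm,
        proteins,
        truth,
    )


def write_dataset(data: SimulatedDataset, outdir: str | Path) -> None:
    """Emit the full fixture directory (all plain-text formats)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for factor, plist in data.peaks.items():
        _io.write_narrowpeak(plist, outdir / f"peaks_{factor}.narrowPeak")
    for factor, track in data.tracks.items():
        track.to_bedgraph(outdir / f"coverage_{factor}.bedGraph")
    if data.input_track.chromosomes:
        data.input_track.to_bedgraph(outdir / "input.bedGraph")
    _io.write_bedpe(data.loops_baseline, outdir / "loops_baseline.bedpe")
    _io.write_bedpe(data.loops_depleted, outdir / "loops_depleted.bedpe")
    _io.write_tss_table(data.genome.genes, outdir / "tss.tsv")
    with open(outdir / "genome.tsv", "w") as fh:
        for chrom, length in data.genome.chromosomes:
            fh.write(f"{chrom}\t{length}\n")
    for label, df in data.expression.items():
        df.to_csv(outdir / f"expression_{label}.tsv", sep="\t", index=False)
    data.psm.to_csv(outdir / "psm.tsv", sep="\t", index=False)
    data.proteins.to_csv(outdir / "proteins.tsv", sep="\t", index=False)
    data.truth.to_json(outdir / "truth.json")
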