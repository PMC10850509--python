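"""HiChIP loop filtering, VCP-anchor classification, and loop-weighted
target-gene aggregate scoring.

Loops are retained when they have at least ``min_pets`` paired-end tags and
an FDR strictly below ``max_fdr`` (defaults 4 and 0.01).  H3K27ac anchors
overlapping at least one VCP peak are VCP anchors, the rest control
anchors; a loop with >= 1 VCP anchor is a VCP loop, one with none is a
control loop.  Each retained loop gets a normalized loop score (NLS):
by default its PET count divided by the mean PET count over retained
loops, so the NLS has unit mean and is invariant to sequencing depth.

A gene's aggregate score per ChIP factor sums the factor's mean enrichment
in the 1 kb window around each promoter-context peak center, plus the same
enrichment at looped-enhancer-context peaks weighted by the connecting
loop's NLS.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core import Anchor, Gene, GenomeModel, Loop, Peak
from .tracks import CoverageTrack
from . import io as _io


@dataclass
class LoopFilterConfig:
    min_pets: int = 4
    max_fdr: float = 0.01
    promoter_window: int = 2500  # bp each side of the TSS
    enrichment_window: int = 1000  # total width around peak center
    nls_mode: str = "mean"  # mean | per_million | median

    def __post_init__(self) -> None:
        if self.min_pets < 0:
            raise ValueError("min_pets must be >= 0")
        if not (0.0 < self.max_fdr <= 1.0):
            raise ValueError("max_fdr must be in (0, 1]")
        if self.promoter_window <= 0 or self.enrichment_window <= 0:
            raise ValueError("windows must be positive")
        if self.nls_mode not in ("mean", "per_million", "median"):
            raise ValueError(f"unknown nls_mode {self.nls_mode!r}")


def filter_loops(loops: list[Loop], config: LoopFilterConfig | None = None) -> list[Loop]:
    """Keep high-confidence loops: pet_count >= min_pets and fdr < max_fdr."""
    config = config or LoopFilterConfig()
    kept = [
        lp for lp in loops if lp.pet_count >= config.min_pets and lp.fdr < config.max_fdr
    ]
    dropped = len(loops) - len(kept)
    if dropped:
        warnings.warn(f"dropped {dropped} low-confidence loops of {len(loops)}")
    return kept


def load_filter_loops(path, config: LoopFilterConfig | None = None) -> list[Loop]:
    return filter_loops(_io.read_bedpe(path), config)


def _peak_tree(peaks: list[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
    return trees


def _anchor_hits_peaks(anchor: Anchor, trees: dict[str, IntervalTree]) -> bool:
    tree = trees.get(anchor.chrom)
    return bool(tree and tree.overlap(anchor.start, anchor.end))


def classify_anchors_and_loops(
    loops: list[Loop],
    vcp_peaks: list[Peak],
    restrict_to_regions: list | None = None,
) -> tuple[dict[tuple, str], list[Loop]]:
    """Label anchors as vcp/control and loops by their anchors.

    An anchor is a VCP anchor iff it overlaps >= 1 VCP peak by >= 1 bp.
    A loop is class ``vcp`` iff at least one anchor is a VCP anchor (the
    either-end convention of paired-interval intersection), else
    ``control``.  ``restrict_to_regions`` optionally limits VCP peaks to
    those inside highly-enriched regions, defining superenhancer-grade
    VCP loops.
    """
    peaks = vcp_peaks
    if restrict_to_regions is not None:
        region_tree: dict[str, IntervalTree] = {}
        for r in restrict_to_regions:
            region_tree.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
        peaks = [
            p
            for p in vcp_peaks
            if p.chrom in region_tree and region_tree[p.chrom].overlap(p.start, p.end)
        ]
    trees = _peak_tree(peaks)
    anchor_classes: dict[tuple, str] = {}
    for lp in loops:
        labels = []
        for anchor in (lp.anchor1, lp.anchor2):
            key = (anchor.chrom, anchor.start, anchor.end)
            if key not in anchor_classes:
                anchor_classes[key] = (
                    "vcp_anchor" if _anchor_hits_peaks(anchor, trees) else "control_anchor"
                )
            labels.append(anchor_classes[key])
        lp.loop_class = "vcp" if "vcp_anchor" in labels else "control"
    return anchor_classes, loops


def normalized_loop_score(loops: list[Loop], mode: str = "mean") -> list[Loop]:
    """Attach a depth-normalized per-loop score.

    ``mean`` (default): PET / mean PET over retained loops (unit mean).
    ``per_million``: PET * 1e6 / total PETs.  ``median``: PET / median PET.
    All are invariant to uniform PET scaling.
    """
    if not loops:
        raise ValueError("cannot normalize an empty loop set")
    pets = np.array([lp.pet_count for lp in loops], dtype=float)
    if pets.sum() <= 0:
        raise ValueError("total PET count must be positive")
    if mode == "mean":
        denom = pets.mean()
    elif mode == "median":
        denom = float(np.median(pets))
        if denom <= 0:
            raise ValueError("median PET count must be positive for median mode")
    elif mode == "per_million":
        denom = pets.sum() / 1e6
    else:
        raise ValueError(f"unknown nls mode {mode!r}")
    for lp, pet in zip(loops, pets):
        lp.nls = float(pet / denom)
    return loops


# ---- peak context and gene scoring ------------------------------------


@dataclass
class PeakContext:
    """Regulatory contexts of one peak across genes."""

    peak: Peak
    promoter_genes: set[str] = field(default_factory=set)
    enhancer_pairs: list[tuple[str, Loop]] = field(default_factory=list)  # (gene, loop)

    @property
    def is_unassigned(self) -> bool:
        return not self.promoter_genes and not self.enhancer_pairs


def _promoter_interval(gene: Gene, window: int) -> tuple[int, int]:
    return gene.tss - window, gene.tss + window


def assign_peak_context(
    peaks: list[Peak],
    genome: GenomeModel,
    loops: list[Loop],
    config: LoopFilterConfig | None = None,
) -> list[PeakContext]:
    """Assign promoter / looped-enhancer contexts to each peak.

    Promoter context for gene g: peak center in [tss-W, tss+W).
    Looped-enhancer context for g via loop l: the peak center lies inside
    one anchor of l and the partner anchor intersects g's promoter window.
    A peak may carry several contexts across genes; a peak with none is
    unassigned.
    """
    config = config or LoopFilterConfig()
    W = config.promoter_window
    by_chrom = genome.genes_by_chrom()

    # promoter windows indexed per chromosome
    prom_trees: dict[str, IntervalTree] = {}
    for chrom, genes in by_chrom.items():
        tree = IntervalTree()
        for g in genes:
            lo, hi = _promoter_interval(g, W)
            tree.addi(lo, hi, g.gene_id)
        prom_trees[chrom] = tree

    # anchors indexed per chromosome; each anchor knows its loops + side
    anchor_trees: dict[str, IntervalTree] = {}
    for lp in loops:
        for side, anchor in ((1, lp.anchor1), (2, lp.anchor2)):
            anchor_trees.setdefault(anchor.chrom, IntervalTree()).addi(
                anchor.start, anchor.end, (lp, side)
            )

    contexts: list[PeakContext] = []
    for p in peaks:
        ctx = PeakContext(p)
        tree = prom_trees.get(p.chrom)
        if tree is not None:
            for iv in tree.at(p.center):
                ctx.promoter_genes.add(iv.data)
        atree = anchor_trees.get(p.chrom)
        if atree is not None:
            for iv in atree.at(p.center):
                lp, side = iv.data
                partner = lp.anchor2 if side == 1 else lp.anchor1
                ptree = prom_trees.get(partner.chrom)
                if ptree is None:
                    continue
                for piv in ptree.overlap(partner.start, partner.end):
                    ctx.enhancer_pairs.append((piv.data, lp))
        contexts.append(ctx)
    return contexts


@dataclass
class GeneTargetProfile:
    gene_id: str
    gene_class: str  # promoter_only | looped_enhancer | untargeted
    scores: dict[str, float]  # factor -> aggregate enrichment
    nls_per_promoter: float
    promoter_peaks: list[str]
    enhancer_pairs: list[tuple[str, str]]  # (peak name, loop name)


def window_enrichment(
    track: CoverageTrack, peak: Peak, window: int, chrom_length: int | None = None
) -> float:
    """Mean track value over the ``window`` bp centered on the peak center."""
    half = window // 2
    lo, hi = peak.center - half, peak.center + (window - half)
    if chrom_length is not None and (lo < 0 or hi > chrom_length):
        warnings.warn(
            f"enrichment window for {peak.name} clipped to chromosome bounds"
        )
        lo, hi = max(lo, 0), min(hi, chrom_length)
    return track.window_mean(peak.chrom, lo, hi)


def gene_aggregate_scores(
    contexts: list[PeakContext],
    genome: GenomeModel,
    tracks: dict[str, CoverageTrack],
    loops: list[Loop],
    config: LoopFilterConfig | None = None,
) -> dict[str, GeneTargetProfile]:
    """Aggregate per-gene enrichment scores for each factor.

    score_f(g) = sum over promoter-context peaks of E_f(p)
               + sum over looped-enhancer pairs (p, l) of E_f(p) * NLS_l,
    where E_f(p) is the mean of factor f's track over the 1 kb window
    centered on the peak center.  ``nls_per_promoter`` sums NLS over
    VCP-class loops with an anchor overlapping the gene's promoter window.
    """
    config = config or LoopFilterConfig()
    lengths = genome.chrom_lengths
    factors = list(tracks)
    enrich_cache: dict[tuple[str, str], float] = {}

    def enrich(factor: str, peak: Peak) -> float:
        key = (factor, peak.name)
        if key not in enrich_cache:
            enrich_cache[key] = window_enrichment(
                tracks[factor], peak, config.enrichment_window, lengths.get(peak.chrom)
            )
        return enrich_cache[key]

    profiles: dict[str, GeneTargetProfile] = {}
    for g in genome.genes:
        profiles[g.gene_id] = GeneTargetProfile(
            g.gene_id, "untargeted", {f: 0.0 for f in factors}, 0.0, [], []
        )

    for ctx in contexts:
        for gene_id in sorted(ctx.promoter_genes):
            prof = profiles[gene_id]
            prof.promoter_peaks.append(ctx.peak.name)
            for f in factors:
                prof.scores[f] += enrich(f, ctx.peak)
        for gene_id, lp in ctx.enhancer_pairs:
            if not np.isfinite(lp.nls):
                raise ValueError(f"loop {lp.name} has no NLS; run normalized_loop_score")
            prof = profiles[gene_id]
            prof.enhancer_pairs.append((ctx.peak.name, lp.name))
            for f in factors:
                prof.scores[f] += enrich(f, ctx.peak) * lp.nls

    W = config.promoter_window
    for g in genome.genes:
        prof = profiles[g.gene_id]
        lo, hi = _promoter_interval(g, W)
        nls_sum = 0.0
        for lp in loops:
            if lp.loop_class != "vcp" or not np.isfinite(lp.nls):
                continue
            if lp.anchor1.overlaps(g.chrom, lo, hi) or lp.anchor2.overlaps(g.chrom, lo, hi):
                nls_sum += lp.nls
        prof.nls_per_promoter = nls_sum
        if prof.enhancer_pairs:
            prof.gene_class = "looped_enhancer"
        elif prof.promoter_peaks:
            prof.gene_class = "promoter_only"
    return profiles


def profiles_to_frame(profiles: dict[str, GeneTargetProfile]) -> pd.DataFrame:
    rows = []
    for gene_id in sorted(profiles):
        p = profiles[gene_id]
        row = {
            "gene_id": gene_id,
            "gene_class": p.gene_class,
            "nls_per_promoter": p.nls_per_promoter,
            "n_promoter_peaks": len(p.promoter_peaks),
            "n_enhancer_pairs": len(p.enhancer_pairs),
        }
        for f, s in p.scores.items():
            row[f"score_{f}"] = s
        rows.append(row)
    return pd.DataFrame(rows)


# ---- baseline vs depletion contrast ------------------------------------


@dataclass
class LoopContrastResult:
    table: pd.DataFrame  # matched loops: name, class, pets, log2_ratio
    median_ratio: dict[str, float]  # per loop class
    statistic: float  # two-sided rank-sum (Mann-Whitney U)
    p_value: float
    n_gained: int
    n_lost: int


def loop_class_contrast(
    baseline: list[Loop],
    depleted: list[Loop],
    pseudocount: float = 0.5,
) -> LoopContrastResult:
    """Depth-normalized per-loop log2 PET ratios and a VCP-vs-control test.

    Loops are matched across conditions by exact anchor coordinates;
    unmatched loops are counted as gained/lost.  For a matched loop,
    ratio = log2((pet_d / M_d + eps) / (pet_b / M_b + eps)) with M the
    condition's total PET count and eps the pseudocount on the
    depth-normalized scale.  Classes are compared by a two-sided
    Mann-Whitney rank-sum on the ratios.
    """
    mb = float(sum(lp.pet_count for lp in baseline))
    md = float(sum(lp.pet_count for lp in depleted))
    if mb <= 0 or md <= 0:
        raise ValueError("each condition needs positive total PET count")
    base_by_key = {lp.anchor_key: lp for lp in baseline}
    dep_by_key = {lp.anchor_key: lp for lp in depleted}
    shared = [k for k in base_by_key if k in dep_by_key]
    if not shared:
        raise ValueError("no loops matched between conditions")
    n_lost = len(base_by_key) - len(shared)
    n_gained = len(dep_by_key) - len(shared)

    rows = []
    for key in shared:
        b, d = base_by_key[key], dep_by_key[key]
        ratio = np.log2(
            (d.pet_count / md + pseudocount) / (b.pet_count / mb + pseudocount)
        )
        rows.append(
            {
                "name": b.name,
                "loop_class": b.loop_class,
                "pet_baseline": b.pet_count,
                "pet_depleted": d.pet_count,
                "log2_ratio": float(ratio),
            }
        )
    table = pd.DataFrame(rows)
    medians = table.groupby("loop_class")["log2_ratio"].median().to_dict()
    vcp = table.loc[table.loop_class == "vcp", "log2_ratio"].to_numpy()
    ctrl = table.loc[table.loop_class == "control", "log2_ratio"].to_numpy()
    if len(vcp) and len(ctrl):
        pooled = np.concatenate([vcp, ctrl])
        if np.ptp(pooled) == 0:  # all ratios tie: no evidence either way
            stat, p = len(vcp) * len(ctrl) / 2.0, 1.0
        else:
            stat, p = stats.mannwhitneyu(vcp, ctrl, alternative="two-sided")
    else:
        stat, p = float("nan"), float("nan")
        warnings.warn("one loop class empty; rank-sum test skipped")
    return LoopContrastResult(table, medians, float(stat), float(p), n_gained, n_lost)


def match_loops_reciprocal(
    baseline: list[Loop], depleted: list[Loop], min_overlap: float = 0.5
) -> list[tuple[Loop, Loop]]:
    """Reciprocal-overlap loop matcher for loop sets from external callers
    whose anchor coordinates differ between conditions."""

    def frac(a: Anchor, b: Anchor) -> float:
        if a.chrom != b.chrom:
            return 0.0
        inter = min(a.end, b.end) - max(a.start, b.start)
        if inter <= 0:
            return 0.0
        return min(inter / (a.end - a.start), inter / (b.end - b.start))

    pairs = []
    used: set[int] = set()
    for b in baseline:
        best, best_score = None, min_overlap
        for j, d in enumerate(depleted):
            if j in used:
                continue
            score = min(frac(b.anchor1, d.anchor1), frac(b.anchor2, d.anchor2))
            if score >= best_score:
                best, best_score = j, score
        if best is not None:
            used.add(best)
            pairs.append((b, depleted[best]))
    return pairs


# ---- locus partition for differential acetylation -----------------------


def partition_loci_for_differential(
    h3k27ac_peaks: list[Peak],
    vcp_peaks: list[Peak],
    at3_enrichment: dict[str, float],
    loops: list[Loop],
    top_k: int,
    bottom_k: int,
) -> tuple[list[Peak], list[Peak]]:
    """Split anchor-resident H3K27ac peaks into two disjoint locus sets.

    Set 1: peaks coincident with a VCP peak, inside a loop anchor, ranking
    in the top_k by AT3 enrichment.  Set 2: anchor-resident peaks with no
    VCP overlap, ranking in the bottom_k by AT3 enrichment.
    """
    vcp_trees = _peak_tree(vcp_peaks)
    anchor_trees: dict[str, IntervalTree] = {}
    for lp in loops:
        for anchor in (lp.anchor1, lp.anchor2):
            anchor_trees.setdefault(anchor.chrom, IntervalTree()).addi(
                anchor.start, anchor.end
            )

    def in_anchor(p: Peak) -> bool:
        tree = anchor_trees.get(p.chrom)
        return bool(tree and tree.overlap(p.start, p.end))

    def hits_vcp(p: Peak) -> bool:
        tree = vcp_trees.get(p.chrom)
        return bool(tree and tree.overlap(p.start, p.end))

    anchored = [p for p in h3k27ac_peaks if in_anchor(p)]
    with_vcp = [p for p in anchored if hits_vcp(p)]
    without_vcp = [p for p in anchored if not hits_vcp(p)]

    def rank_value(p: Peak) -> float:
        return at3_enrichment.get(p.name, float("-inf"))

    with_vcp.sort(key=lambda p: (-rank_value(p), p.name))
    without_vcp.sort(key=lambda p: (rank_value(p), p.name))
    if top_k > len(with_vcp) or bottom_k > len(without_vcp):
        warnings.warn("requested locus counts exceed available loci; truncated")
    return with_vcp[:top_k], without_vcp[:bottom_k]
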