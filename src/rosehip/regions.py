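"""Highly-enriched-region calling on stitched ChIP-seq peaks.

The procedure mirrors superenhancer-style calling: filter blacklisted
peaks, stitch peaks whose edge-to-edge gap is at most a stitch distance
(default 40 kb) into regions, score each region by input-subtracted signal
density over constituent peak bases only, rank-normalize the scores, and
flag every region above the point where the rank curve's slope first and
last crosses 1 from below.  Regions are then annotated with the nearest
genes of their constituent peaks.

Conventions that the field leaves open are pinned down here and documented:
gaps are edge-to-edge and merge when ``gap <= D``; the curve derivative is
a centered secant over a configurable rank window; nearest gene is
measured peak-midpoint to TSS with ties to the lower coordinate.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .core import Gene, GenomeModel, Peak
from .tracks import CoverageTrack
from . import io as _io

DEFAULT_STITCH_DISTANCE = 40_000


@dataclass
class StitchedRegion:
    """A maximal run of peaks with inter-peak gaps <= the stitch distance."""

    chrom: str
    start: int
    end: int
    peaks: list[Peak]
    density: float = float("nan")
    fractional_rank: float = float("nan")
    normalized_signal: float = float("nan")
    is_highly_enriched: bool = False

    @property
    def constituent_width(self) -> int:
        return sum(p.width for p in self.peaks)

    @property
    def peak_names(self) -> list[str]:
        return [p.name for p in self.peaks]


@dataclass
class CallerConfig:
    stitch_distance: int = DEFAULT_STITCH_DISTANCE
    threshold_method: str = "tangent"  # tangent | derivative
    derivative_window: int | None = None  # rank points; None -> 1% of n, min 3
    blacklist: list[tuple[str, int, int]] | None = None

    def __post_init__(self) -> None:
        if self.stitch_distance < 0:
            raise ValueError("stitch distance must be >= 0")
        if self.threshold_method not in ("tangent", "derivative"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")
        if self.derivative_window is not None and self.derivative_window < 2:
            raise ValueError("derivative window must be >= 2")


def load_and_filter_peaks(
    path, blacklist: list[tuple[str, int, int]] | None = None
) -> list[Peak]:
    """Read peaks and drop any overlapping a blacklist interval by >= 1 bp."""
    peaks = _io.read_peaks(path)
    return filter_blacklisted(peaks, blacklist)


def filter_blacklisted(
    peaks: list[Peak], blacklist: list[tuple[str, int, int]] | None
) -> list[Peak]:
    if not blacklist:
        return sorted(peaks, key=lambda p: (p.chrom, p.start, p.end, p.name))
    trees: dict[str, IntervalTree] = {}
    peak_chroms = {p.chrom for p in peaks}
    for chrom, start, end in blacklist:
        if chrom not in peak_chroms:
            warnings.warn(f"blacklist chromosome {chrom!r} absent from peaks; ignored")
            continue
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    kept = [
        p
        for p in peaks
        if p.chrom not in trees or not trees[p.chrom].overlap(p.start, p.end)
    ]
    kept.sort(key=lambda p: (p.chrom, p.start, p.end, p.name))
    return kept


def stitch_peaks(peaks: list[Peak], distance: int) -> list[StitchedRegion]:
    """Merge consecutive same-chromosome peaks with gap <= distance.

    Gap is edge-to-edge (``next.start - prev.end``); a gap of exactly
    ``distance`` merges.  Input need not be pre-sorted.
    """
    if distance < 0:
        raise ValueError("stitch distance must be >= 0")
    ordered = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end, p.name))
    regions: list[StitchedRegion] = []
    for p in ordered:
        if (
            regions
            and regions[-1].chrom == p.chrom
            and p.start - regions[-1].end <= distance
        ):
            last = regions[-1]
            last.peaks.append(p)
            last.end = max(last.end, p.end)
        else:
            regions.append(StitchedRegion(p.chrom, p.start, p.end, [p]))
    return regions


def region_density(
    region: StitchedRegion, chip: CoverageTrack, input_track: CoverageTrack
) -> float:
    """Input-subtracted signal per constituent-peak base.

    Only bases inside constituent peaks contribute; inter-peak gaps are
    ignored entirely, so reshaping coverage between peaks cannot change the
    result.  May be negative when input exceeds ChIP.
    """
    chip_sum = 0.0
    input_sum = 0.0
    for p in region.peaks:
        chip_sum += chip.window_sum(p.chrom, p.start, p.end)
        input_sum += input_track.window_sum(p.chrom, p.start, p.end)
    return (chip_sum - input_sum) / region.constituent_width


def attach_densities(
    regions: list[StitchedRegion], chip: CoverageTrack, input_track: CoverageTrack
) -> list[StitchedRegion]:
    for r in regions:
        r.density = region_density(r, chip, input_track)
    return regions


@dataclass
class RankCurveResult:
    threshold: float  # normalized-signal cutoff (nan when no crossing)
    crossing_rank: float  # fractional rank of the crossing (nan if none)
    flagged: np.ndarray  # boolean mask aligned with ascending-density order
    all_below_one: bool  # derivative < 1 everywhere -> nothing flagged
    curve: "np.ndarray"  # (n, 3) columns: fractional_rank, normalized, derivative


_SLOPE_TOL = 1e-9  # floats: treat 1 - eps as reaching slope one


def inflection_threshold(
    densities: np.ndarray,
    derivative_window: int | None = None,
    method: str = "tangent",
) -> RankCurveResult:
    """Slope-1 inflection cutoff on the rank-normalized signal curve.

    Densities are sorted ascending; ``normalized = density / max`` (highest
    region at 1) is plotted against ``fractional_rank = rank / n`` (highest
    at 1).  Regions with normalized signal strictly above the threshold are
    flagged.  Two constructions of the slope-1 point are available:

    ``tangent`` (default): the point where a slope-1 line is tangent to the
    curve, i.e. argmin of (normalized - rank) — the classic superenhancer
    cutoff.  Global, hence robust to local near-ties when the region count
    is small.

    ``derivative``: centered-secant derivative over ``derivative_window``
    rank points (default 1% of n, minimum 3); the threshold sits at the
    largest rank where the derivative transitions from < 1 to >= 1, so flat
    tails do not dilute the cutoff.

    Degenerate curves behave identically under both: a curve whose slope is
    >= 1 everywhere (e.g. exactly linear) flags every region; one whose
    slope stays < 1 (e.g. all-equal signals) flags none and sets
    ``all_below_one``.
    """
    d = np.asarray(densities, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 regions to place a threshold")
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite density")
    dmax = d.max()
    if dmax <= 0:
        raise ValueError("maximum density must be positive to normalize")

    order = np.argsort(d, kind="stable")
    y = d[order] / dmax
    x = np.arange(1, n + 1) / n

    window = derivative_window if derivative_window is not None else max(3, round(0.01 * n))
    window = max(2, min(window, n - 1))
    h = max(1, window // 2)
    lo = np.maximum(np.arange(n) - h, 0)
    hi = np.minimum(np.arange(n) + h, n - 1)
    deriv = (y[hi] - y[lo]) / (x[hi] - x[lo])
    curve = np.column_stack([x, y, deriv])

    if method == "tangent":
        resid = y - x
        spread = resid.max() - resid.min()
        if spread < _SLOPE_TOL:  # exactly linear: slope 1 everywhere
            return RankCurveResult(
                float("nan"), float("nan"), np.ones(n, dtype=bool), False, curve
            )
        i = int(np.flatnonzero(resid == resid.min())[-1])
        threshold = float(y[i])
        flagged = y > threshold + _SLOPE_TOL
        if not flagged.any():
            return RankCurveResult(threshold, float(x[i]), flagged, True, curve)
        return RankCurveResult(threshold, float(x[i]), flagged, False, curve)

    if method != "derivative":
        raise ValueError(f"unknown threshold method {method!r}")

    at_or_above = deriv >= 1.0 - _SLOPE_TOL
    if at_or_above.all():
        flagged = np.ones(n, dtype=bool)
        return RankCurveResult(float("nan"), float("nan"), flagged, False, curve)
    if not at_or_above.any():
        return RankCurveResult(
            float("nan"), float("nan"), np.zeros(n, dtype=bool), True, curve
        )
    transitions = np.flatnonzero(~at_or_above[:-1] & at_or_above[1:]) + 1
    i = int(transitions[-1])
    threshold = float(y[i])
    flagged = y > threshold
    return RankCurveResult(threshold, float(x[i]), flagged, False, curve)


@dataclass
class RegionCallResult:
    regions: list[StitchedRegion]  # ascending by density, ranks attached
    threshold: float
    crossing_rank: float
    no_regions_flagged: bool


def rank_threshold_call(
    regions: list[StitchedRegion], config: CallerConfig | None = None
) -> RegionCallResult:
    """Rank regions by density and flag those above the slope-1 cutoff."""
    config = config or CallerConfig()
    densities = np.array([r.density for r in regions], dtype=float)
    res = inflection_threshold(
        densities, config.derivative_window, config.threshold_method
    )
    order = np.argsort(densities, kind="stable")
    ordered = [regions[i] for i in order]
    n = len(ordered)
    for rank0, r in enumerate(ordered):
        r.fractional_rank = (rank0 + 1) / n
        r.normalized_signal = r.density / densities.max()
        r.is_highly_enriched = bool(res.flagged[rank0])
    if res.all_below_one:
        warnings.warn(
            "rank-curve derivative < 1 everywhere; no region flagged"
        )
    return RegionCallResult(ordered, res.threshold, res.crossing_rank, res.all_below_one)


def annotate_nearest_genes(
    items: list[Peak] | list[StitchedRegion], genome: GenomeModel
) -> tuple[dict[str, str | None], dict[str, set[str]]]:
    """Map peaks (or regions, via their constituent peaks) to nearest genes.

    Distance is from the peak midpoint to the TSS; ties break toward the
    lower TSS coordinate.  Returns (item name -> gene_id or None,
    gene_id -> set of item names).  Items on chromosomes with no annotated
    gene map to None with a warning.
    """
    by_chrom = genome.genes_by_chrom()
    pos: dict[str, np.ndarray] = {}
    glist: dict[str, list[Gene]] = {}
    for chrom, genes in by_chrom.items():
        pos[chrom] = np.array([g.tss for g in genes])
        glist[chrom] = genes

    def nearest(chrom: str, midpoint: int) -> str | None:
        if chrom not in pos:
            return None
        tss = pos[chrom]
        i = int(np.searchsorted(tss, midpoint))
        best: Gene | None = None
        best_d = None
        for j in (i - 1, i):
            if 0 <= j < len(tss):
                g = glist[chrom][j]
                dist = abs(g.tss - midpoint)
                if best is None or dist < best_d or (dist == best_d and g.tss < best.tss):
                    best, best_d = g, dist
        return best.gene_id if best else None

    item_to_gene: dict[str, str | None] = {}
    gene_to_items: dict[str, set[str]] = {}
    warned: set[str] = set()
    for item in items:
        if isinstance(item, StitchedRegion):
            name = f"{item.chrom}:{item.start}-{item.end}"
            hits = {nearest(p.chrom, p.center) for p in item.peaks}
            hits.discard(None)
            item_to_gene[name] = min(hits) if hits else None
            for g in hits:
                gene_to_items.setdefault(g, set()).add(name)
            if not hits and item.chrom not in warned:
                warned.add(item.chrom)
                warnings.warn(f"no genes on {item.chrom}; items unannotated")
        else:
            g = nearest(item.chrom, item.center)
            item_to_gene[item.name] = g
            if g is None:
                if item.chrom not in warned:
                    warned.add(item.chrom)
                    warnings.warn(f"no genes on {item.chrom}; items unannotated")
            else:
                gene_to_items.setdefault(g, set()).add(item.name)
    return item_to_gene, gene_to_items


def region_gene_sets(
    regions: list[StitchedRegion], genome: GenomeModel
) -> dict[str, set[str]]:
    """Per-region union of nearest genes over constituent peaks."""
    out: dict[str, set[str]] = {}
    for region in regions:
        peak_map, _ = annotate_nearest_genes(region.peaks, genome)
        genes = {g for g in peak_map.values() if g is not None}
        out[f"{region.chrom}:{region.start}-{region.end}"] = genes
    return out


def write_regions_bed(regions: list[StitchedRegion], path) -> None:
    """BED6+ with density, normalized signal, fractional rank and flag."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t"
                f"{r.chrom}:{r.start}-{r.end}\t0\t.\t"
                f"{r.density:.6g}\t{r.normalized_signal:.6g}\t"
                f"{r.fractional_rank:.6g}\t{int(r.is_highly_enriched)}\n"
            )
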