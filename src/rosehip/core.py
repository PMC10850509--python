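"""Core genomic value types shared across the pipeline.

All coordinates are 0-based half-open (BED convention).  Peaks, genes and
loop anchors are plain dataclasses; heavier tabular data stays in pandas.
"""
from __future__ import annotations

from dataclasses import dataclass, field


def intervals_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """True if [a_start, a_end) and [b_start, b_end) share >= 1 bp."""
    return a_start < b_end and b_start < a_end


@dataclass
class Peak:
    """A peak-caller interval, optionally with score and summit offset."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float | None = None
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"peak {self.name!r}: start {self.start} >= end {self.end}"
            )
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(
                f"peak {self.name!r}: summit offset {self.summit_offset} "
                f"outside [0, {self.end - self.start})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"


@dataclass
class GenomeModel:
    """Chromosome sizes plus a TSS annotation.

    A deliberately small stand-in for a genome assembly + gene model: only
    what nearest-gene annotation and promoter-window logic need.
    """

    chromosomes: list[tuple[str, int]]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        if len(lengths) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name}: non-positive length {length}")
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.chrom not in lengths:
                raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
            if not (0 <= g.tss < lengths[g.chrom]):
                raise ValueError(f"gene {g.gene_id}: TSS {g.tss} outside {g.chrom}")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def genes_by_chrom(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        for glist in out.values():
            glist.sort(key=lambda g: (g.tss, g.gene_id))
        return out


@dataclass(frozen=True)
class Anchor:
    """One end of a chromatin loop."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"anchor start {self.start} >= end {self.end}")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and intervals_overlap(
            self.start, self.end, start, end
        )


@dataclass
class Loop:
    """A HiChIP loop: two anchors, PET support, FDR, and derived labels.

    ``anchor1`` sorts before ``anchor2`` by (chrom, start); construction
    enforces this so loops from different files match coordinate-wise.
    """

    anchor1: Anchor
    anchor2: Anchor
    name: str
    pet_count: int
    fdr: float
    loop_class: str = "unassigned"  # vcp | control | unassigned
    nls: float = float("nan")

    def __post_init__(self) -> None:
        if self.pet_count < 0:
            raise ValueError(f"loop {self.name}: negative PET count")
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"loop {self.name}: FDR {self.fdr} outside [0, 1]")
        key1 = (self.anchor1.chrom, self.anchor1.start, self.anchor1.end)
        key2 = (self.anchor2.chrom, self.anchor2.start, self.anchor2.end)
        if key2 < key1:
            self.anchor1, self.anchor2 = self.anchor2, self.anchor1

    @property
    def anchor_key(self) -> tuple:
        a, b = self.anchor1, self.anchor2
        return (a.chrom, a.start, a.end, b.chrom, b.start, b.end)
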