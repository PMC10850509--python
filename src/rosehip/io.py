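"""Readers and writers for the plain-text genomics formats the pipeline uses.

Formats handled: BED3/BED6/narrowPeak peaks, blacklist BED, BEDPE loops
(10 anchor/name/strand columns + FDR), TSS and chromosome-size TSVs.
Everything is 0-based half-open on disk and in memory.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .core import Anchor, Gene, GenomeModel, Loop, Peak


def read_peaks(path: str | Path) -> list[Peak]:
    """Read BED3, BED6 or narrowPeak into sorted Peak records.

    narrowPeak column 10 (summit offset) is kept when present and not -1.
    Malformed intervals raise with the offending line number.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = f[3] if len(f) > 3 and f[3] != "." else f"peak_{lineno}"
            score = None
            if len(f) > 4 and f[4] not in (".", ""):
                score = float(f[4])
            summit = None
            if len(f) >= 10 and f[9] not in (".", ""):
                s = int(f[9])
                if s >= 0:
                    summit = s
            peaks.append(Peak(chrom, start, end, name, score, summit))
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end, p.name))
    return peaks


def write_narrowpeak(peaks: list[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            score = int(round(p.score)) if p.score is not None else 0
            summit = p.summit_offset if p.summit_offset is not None else -1
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{score}\t.\t"
                f"0\t-1\t-1\t{summit}\n"
            )


def read_blacklist(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


# ---- loops (BEDPE) -----------------------------------------------------


def read_bedpe(path: str | Path) -> list[Loop]:
    """Read loops from BEDPE: 6 anchor cols, name, PET count, 2 strand
    placeholders, FDR in column 11.  Extra trailing columns (hichipper
    style) are tolerated and ignored."""
    loops: list[Loop] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 8:
                raise ValueError(
                    f"{path}:{lineno}: BEDPE needs >= 8 columns (PET count "
                    "missing)"
                )
            if len(f) < 11:
                raise ValueError(
                    f"{path}:{lineno}: FDR column (11) missing"
                )
            a1 = Anchor(f[0], int(f[1]), int(f[2]))
            a2 = Anchor(f[3], int(f[4]), int(f[5]))
            name = f[6] if f[6] != "." else f"loop_{lineno}"
            loops.append(
                Loop(a1, a2, name, pet_count=int(f[7]), fdr=float(f[10]))
            )
            if a1.chrom == a2.chrom and a1.overlaps(a2.chrom, a2.start, a2.end):
                warnings.warn(f"{path}:{lineno}: loop anchors overlap each other")
    return loops


def write_bedpe(loops: list[Loop], path: str | Path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            a, b = lp.anchor1, lp.anchor2
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t"
                f"{lp.name}\t{lp.pet_count}\t.\t.\t{lp.fdr:.6g}\n"
            )


# ---- annotation tables -------------------------------------------------


def read_tss_table(path: str | Path) -> list[Gene]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: TSS table missing columns {sorted(missing)}")
    return [
        Gene(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
        for r in df.itertuples()
    ]


def write_tss_table(genes: list[Gene], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "tss": [g.tss for g in genes],
            "strand": [g.strand for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_genome_table(path: str | Path, tss_path: str | Path | None = None) -> GenomeModel:
    """Chromosome sizes from a two-column TSV, optionally TSS annotation."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    genes = read_tss_table(tss_path) if tss_path is not None else []
    return GenomeModel(
        [(str(r.chrom), int(r.length)) for r in df.itertuples()], genes
    )


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Expression contrast TSV with gene_id, log2fc, padj (contrast optional)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: expression table missing {sorted(missing)}")
    return df
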