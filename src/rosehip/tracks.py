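"""Piecewise-constant coverage tracks (bedGraph-backed).

A :class:`CoverageTrack` stores, per chromosome, sorted non-overlapping
``(start, end, value)`` intervals as numpy arrays.  Positions not covered by
any interval read as 0, so sparse bedGraphs and dense fixed-bin tracks
behave identically under window queries.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np


class CoverageTrack:
    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if not (len(starts) == len(ends) == len(values)):
                raise ValueError(f"{chrom}: ragged interval arrays")
            if len(starts):
                if np.any(starts >= ends):
                    raise ValueError(f"{chrom}: empty or inverted interval")
                if np.any(starts[1:] < ends[:-1]):
                    raise ValueError(f"{chrom}: unsorted or overlapping intervals")
                if not np.all(np.isfinite(values)):
                    raise ValueError(f"{chrom}: non-finite coverage value")
            self._data[chrom] = (starts, ends, values)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._data)

    def intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._data.get(
            chrom,
            (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.float64)),
        )

    # ---- queries -------------------------------------------------------

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of value x covered-bases over [start, end); gaps count 0."""
        if end <= start:
            return 0.0
        starts, ends, values = self.intervals(chrom)
        if not len(starts):
            return 0.0
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return float(np.sum(values[lo:hi] * np.maximum(e - s, 0)))

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        """Per-base mean over [start, end), gaps counted as 0."""
        if end <= start:
            return 0.0
        return self.window_sum(chrom, start, end) / (end - start)

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            {c: (s, e, v * factor) for c, (s, e, v) in self._data.items()}
        )

    # ---- bedGraph IO ---------------------------------------------------

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "CoverageTrack":
        import pandas as pd

        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        df = df[~df["chrom"].isin(["track", "browser"])]
        df = df.sort_values(["chrom", "start"], kind="mergesort")
        data = {}
        for chrom, grp in df.groupby("chrom", sort=True):
            data[chrom] = (
                grp["start"].to_numpy(np.int64),
                grp["end"].to_numpy(np.int64),
                grp["value"].to_numpy(np.float64),
            )
        return cls(data)

    def to_bedgraph(self, path: str | Path) -> None:
        """Write all intervals, 0-based half-open, tab-separated."""
        import pandas as pd

        frames = []
        for chrom in sorted(self._data):
            starts, ends, values = self._data[chrom]
            frames.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": ends, "value": values}
                )
            )
        df = pd.concat(frames) if frames else pd.DataFrame(
            columns=["chrom", "start", "end", "value"]
        )
        df.to_csv(path, sep="\t", header=False, index=False, float_format="%g")


def average_tracks(
    tracks: list[CoverageTrack], depths: list[float] | None = None
) -> CoverageTrack:
    """Average replicate tracks after reads-per-million depth scaling.

    Each track is scaled by ``1e6 / depth`` (identity if ``depths`` is
    None, for tracks already depth-normalized), then averaged position-wise
    over the union of breakpoints.  A chromosome missing from a track
    contributes 0 there, with a warning.
    """
    if not tracks:
        raise ValueError("need at least one track")
    if depths is not None:
        if len(depths) != len(tracks):
            raise ValueError("depths must match tracks")
        if any(d <= 0 for d in depths):
            raise ValueError("depths must be positive")
        scaled = [t.scaled(1e6 / d) for t, d in zip(tracks, depths)]
    else:
        scaled = tracks

    all_chroms = sorted({c for t in scaled for c in t.chromosomes})
    for t in scaled:
        missing = set(all_chroms) - set(t.chromosomes)
        if missing:
            warnings.warn(
                f"chromosomes {sorted(missing)} missing from a replicate; "
                "treated as zero coverage"
            )

    out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in all_chroms:
        cuts: list[np.ndarray] = []
        for t in scaled:
            s, e, _ = t.intervals(chrom)
            cuts.append(s)
            cuts.append(e)
        bounds = np.unique(np.concatenate(cuts))
        if len(bounds) < 2:
            continue
        seg_start = bounds[:-1]
        seg_end = bounds[1:]
        total = np.zeros(len(seg_start), dtype=np.float64)
        for t in scaled:
            s, e, v = t.intervals(chrom)
            if not len(s):
                continue
            idx = np.searchsorted(s, seg_start, side="right") - 1
            valid = (idx >= 0) & (seg_start < e[np.clip(idx, 0, None)])
            total[valid] += v[idx[valid]]
        total /= len(scaled)
        out[chrom] = (seg_start, seg_end, total)
    return CoverageTrack(out)
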