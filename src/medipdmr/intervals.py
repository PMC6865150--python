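"""Interval tracks, genome annotation container, and BED round-tripping.

All coordinates are 0-based half-open, the BED convention. Tracks are kept as
sorted numpy arrays per chromosome; overlap and distance queries use binary
search with a cumulative-max guard so overlapping input intervals are handled
correctly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

Interval = Tuple[int, int]


class BedFormatError(ValueError):
    """A BED line violates the 0-based half-open contract."""


class IntervalTrack:
    """A set of intervals on one chromosome supporting overlap/distance queries.

    Intervals are sorted by start; ``_cummax_end`` allows overlap queries that
    remain correct when input intervals overlap each other.
    """

    def __init__(self, intervals: Iterable[Interval] = ()) -> None:
        ivs = sorted((int(s), int(e)) for s, e in intervals)
        for s, e in ivs:
            if e <= s:
                raise BedFormatError(f"empty or inverted interval [{s}, {e})")
        self.starts = np.array([s for s, _ in ivs], dtype=np.int64)
        self.ends = np.array([e for _, e in ivs], dtype=np.int64)
        self._cummax_end = (
            np.maximum.accumulate(self.ends) if len(ivs) else self.ends
        )

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self):
        return iter(zip(self.starts.tolist(), self.ends.tolist()))

    def overlaps(self, start: int, end: int) -> bool:
        """True iff [start, end) overlaps any interval by >= 1 bp."""
        return self.overlap_bp(start, end) > 0

    def overlap_bp(self, start: int, end: int) -> int:
        """Overlap (bp) of [start, end) with the union of the intervals."""
        if len(self) == 0 or end <= start:
            return 0
        # intervals with interval.start < end, clipped, merged by sweep
        i = int(np.searchsorted(self.starts, end, side="left"))
        total = 0
        cur_s = cur_e = None
        for j in range(i):
            if self.ends[j] <= start:
                continue
            s = max(int(self.starts[j]), start)
            e = min(int(self.ends[j]), end)
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
        if cur_s is not None:
            total += cur_e - cur_s
        return total

    def distance(self, start: int, end: int) -> float:
        """Edge-to-edge distance from [start, end) to the nearest interval.

        Overlap (or bookended abutment counts as distance 0? No: abutting
        intervals share no base, distance 0 only on true overlap; an interval
        ending exactly at ``start`` is 0 bp away by the edge-gap convention
        used for the repeat-proximity filter). Returns ``inf`` on an empty
        track.
        """
        if len(self) == 0:
            return float("inf")
        if self.overlaps(start, end):
            return 0.0
        gaps_left = start - self.ends  # >=0 where interval entirely left
        gaps_right = self.starts - end  # >=0 where interval entirely right
        gaps = np.where(gaps_left >= 0, gaps_left, np.where(gaps_right >= 0, gaps_right, 0))
        return float(gaps.min())

    def to_frame(self, chrom: str, names: Sequence[str] | None = None) -> pd.DataFrame:
        n = len(self)
        return pd.DataFrame(
            {
                "chrom": [chrom] * n,
                "start": self.starts,
                "end": self.ends,
                "name": list(names) if names is not None else [f"iv{i}" for i in range(n)],
            }
        )


GenomeTrack = Dict[str, IntervalTrack]


@dataclass
class AnnotationSet:
    """CpG site positions plus the interval tracks the selection criteria use.

    ``cpg_sites`` maps chromosome -> sorted array of site positions (bp).
    Every other field maps chromosome -> :class:`IntervalTrack`.
    """

    chrom_sizes: Dict[str, int]
    cpg_sites: Dict[str, np.ndarray] = field(default_factory=dict)
    repeats: GenomeTrack = field(default_factory=dict)
    cnvs: GenomeTrack = field(default_factory=dict)
    gene_bodies: GenomeTrack = field(default_factory=dict)
    exons: GenomeTrack = field(default_factory=dict)
    promoters: GenomeTrack = field(default_factory=dict)
    cgis: GenomeTrack = field(default_factory=dict)

    TRACK_NAMES = ("repeats", "cnvs", "gene_bodies", "exons", "promoters", "cgis")

    def __post_init__(self) -> None:
        for chrom in self.chrom_sizes:
            self.cpg_sites.setdefault(chrom, np.array([], dtype=np.int64))
            for name in self.TRACK_NAMES:
                getattr(self, name).setdefault(chrom, IntervalTrack())
        for chrom, pos in self.cpg_sites.items():
            self.cpg_sites[chrom] = np.sort(np.asarray(pos, dtype=np.int64))

    def track(self, name: str) -> GenomeTrack:
        if name not in self.TRACK_NAMES:
            raise KeyError(f"unknown track {name!r}")
        return getattr(self, name)

    def cpg_count(self, chrom: str, start: int, end: int) -> int:
        """Number of CpG sites p with start <= p < end (binary search)."""
        pos = self.cpg_sites.get(chrom)
        if pos is None or len(pos) == 0:
            return 0
        return int(np.searchsorted(pos, end, "left") - np.searchsorted(pos, start, "left"))


# ---------------------------------------------------------------------------
# BED IO
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read a BED file into a frame with chrom/start/end[/name] columns.

    Comment (#), ``track`` and ``browser`` header lines are skipped (counted
    in the log). Malformed coordinate lines raise :class:`BedFormatError`
    with their line number.
    """
    rows: List[tuple] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                skipped += 1
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedFormatError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise BedFormatError(f"{path}:{lineno}: end {end} <= start {start}")
            name = parts[3] if len(parts) > 3 else f"iv{len(rows)}"
            rows.append((chrom, start, end, name))
    if skipped:
        log.info("read_bed(%s): skipped %d header/comment lines", path, skipped)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(frame: pd.DataFrame, path, extra_cols: Sequence[str] = ()) -> None:
    """Write a chrom/start/end[/name] frame as canonical tab-separated BED."""
    cols = ["chrom", "start", "end"]
    if "name" in frame.columns:
        cols.append("name")
    cols += [c for c in extra_cols if c in frame.columns]
    out = frame[cols].sort_values(["chrom", "start", "end"], kind="mergesort")
    out.to_csv(path, sep="\t", header=False, index=False, lineterminator="\n")


def track_from_frame(frame: pd.DataFrame) -> GenomeTrack:
    """Group a BED frame into per-chromosome :class:`IntervalTrack` objects."""
    out: GenomeTrack = {}
    for chrom, grp in frame.groupby("chrom", sort=True):
        out[str(chrom)] = IntervalTrack(zip(grp["start"], grp["end"]))
    return out


def frame_from_track(track: GenomeTrack, prefix: str = "iv") -> pd.DataFrame:
    frames = []
    counter = 0
    for chrom in sorted(track):
        tr = track[chrom]
        names = [f"{prefix}{counter + i}" for i in range(len(tr))]
        counter += len(tr)
        frames.append(tr.to_frame(chrom, names))
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "name"])
    return pd.concat(frames, ignore_index=True)
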