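"""Fixed-width genomic windows, fragment counting, and rpm normalization.

The discovery stage tests read depth in fixed 100-bp bins tiling the genome.
Each aligned fragment contributes to exactly one window: the window containing
its midpoint ``floor((start + end) / 2)``, which avoids double counting and
fragment-length bias. The last window of a chromosome is truncated at the
chromosome end so the tiling is total.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TISSUES = ("CVS", "WBF", "PL")
COHORTS = ("discovery", "confirmation")


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class SampleMeta:
    """One sequenced sample: id, tissue of origin, cohort, library size."""

    sample_id: str
    tissue: str
    cohort: str = "discovery"
    library_size: int = 0

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValidationError(
                f"unknown tissue {self.tissue!r} for sample {self.sample_id!r}; "
                f"expected one of {TISSUES}"
            )
        if self.cohort not in COHORTS:
            raise ValidationError(f"unknown cohort {self.cohort!r}; expected one of {COHORTS}")
        if self.library_size < 0:
            raise ValidationError(f"negative library size for {self.sample_id!r}")


@dataclass(frozen=True)
class WindowGrid:
    """Non-overlapping fixed-width windows tiling each chromosome."""

    bin_size: int
    chrom_sizes: Dict[str, int]
    chroms: tuple = field(default=(), repr=False)       # per-window chromosome index
    starts: np.ndarray = field(default=None, repr=False)
    ends: np.ndarray = field(default=None, repr=False)

    @property
    def chrom_names(self) -> List[str]:
        return sorted(self.chrom_sizes)

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def window_ids(self) -> List[str]:
        names = self.chrom_names
        return [
            f"{names[c]}:{s}-{e}"
            for c, s, e in zip(self.chroms, self.starts.tolist(), self.ends.tolist())
        ]

    def chrom_of(self, idx: int) -> str:
        return self.chrom_names[self.chroms[idx]]

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous index range of one chromosome's windows."""
        names = self.chrom_names
        ci = names.index(chrom)
        offs = np.cumsum([0] + [n_windows_for(self.chrom_sizes[c], self.bin_size) for c in names])
        return slice(int(offs[ci]), int(offs[ci + 1]))

    def locate(self, chrom: str, position: int) -> int:
        """Global index of the window containing ``position`` on ``chrom``."""
        if chrom not in self.chrom_sizes:
            raise KeyError(chrom)
        if not (0 <= position < self.chrom_sizes[chrom]):
            raise ValidationError(f"position {position} outside {chrom}")
        return self.chrom_slice(chrom).start + position // self.bin_size


def n_windows_for(length: int, bin_size: int) -> int:
    return -(-length // bin_size)  # ceil division


def make_windows(chrom_sizes: Dict[str, int], bin_size: int = 100) -> WindowGrid:
    """Tile every chromosome with ``bin_size`` windows (last one truncated)."""
    if bin_size < 1:
        raise ValidationError(f"bin_size must be >= 1, got {bin_size}")
    for chrom, length in chrom_sizes.items():
        if length < 1:
            raise ValidationError(f"chromosome {chrom!r} has non-positive length {length}")
    chroms: List[int] = []
    starts: List[int] = []
    ends: List[int] = []
    for ci, chrom in enumerate(sorted(chrom_sizes)):
        length = chrom_sizes[chrom]
        s = np.arange(0, length, bin_size, dtype=np.int64)
        e = np.minimum(s + bin_size, length)
        chroms.extend([ci] * len(s))
        starts.append(s)
        ends.append(e)
    return WindowGrid(
        bin_size=int(bin_size),
        chrom_sizes=dict(chrom_sizes),
        chroms=tuple(chroms),
        starts=np.concatenate(starts) if starts else np.array([], dtype=np.int64),
        ends=np.concatenate(ends) if ends else np.array([], dtype=np.int64),
    )


@dataclass
class CountMatrix:
    """Windows x samples raw counts with optional rpm normalization."""

    grid: WindowGrid
    samples: List[SampleMeta]
    raw: np.ndarray                      # (n_windows, n_samples) int64
    rpm: np.ndarray | None = None        # (n_windows, n_samples) float64

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=np.int64)
        if self.raw.shape != (self.grid.n_windows, len(self.samples)):
            raise ValidationError(
                f"raw shape {self.raw.shape} does not match "
                f"{self.grid.n_windows} windows x {len(self.samples)} samples"
            )
        if (self.raw < 0).any():
            raise ValidationError("raw counts must be non-negative")

    @property
    def sample_ids(self) -> List[str]:
        return [s.sample_id for s in self.samples]

    def columns_for(self, tissue: str) -> List[int]:
        return [i for i, s in enumerate(self.samples) if s.tissue == tissue]

    def to_frame(self, which: str = "raw") -> pd.DataFrame:
        mat = self.raw if which == "raw" else self.rpm
        return pd.DataFrame(mat, index=self.grid.window_ids(), columns=self.sample_ids)


def count_fragments(
    read_records: pd.DataFrame,
    grid: WindowGrid,
    samples: Sequence[SampleMeta] | None = None,
) -> CountMatrix:
    """Assign each fragment to the window containing its midpoint.

    ``read_records`` must have columns sample_id / chrom / start / end with
    half-open fragment intervals. Fragments on chromosomes absent from the
    grid are counted, logged and skipped. Unless a sample's ``library_size``
    is supplied (> 0), it is set to its number of assigned fragments.
    """
    required = {"sample_id", "chrom", "start", "end"}
    missing = required - set(read_records.columns)
    if missing:
        raise ValidationError(f"read records missing columns: {sorted(missing)}")
    bad = read_records["end"] <= read_records["start"]
    if bad.any():
        lineno = int(np.flatnonzero(bad.to_numpy())[0])
        row = read_records.iloc[lineno]
        raise ValidationError(
            f"malformed fragment at record {lineno}: "
            f"{row['chrom']}:{row['start']}-{row['end']} (end <= start)"
        )

    if samples is None:
        ids = sorted(read_records["sample_id"].unique())
        samples = [SampleMeta(sample_id=i, tissue="CVS") for i in ids]
    samples = list(samples)
    col_of = {s.sample_id: j for j, s in enumerate(samples)}

    raw = np.zeros((grid.n_windows, len(samples)), dtype=np.int64)
    skipped_chrom = 0
    names = grid.chrom_names
    offs = np.cumsum([0] + [n_windows_for(grid.chrom_sizes[c], grid.bin_size) for c in names])
    offset_of = {c: int(offs[i]) for i, c in enumerate(names)}

    for sid, grp in read_records.groupby("sample_id", sort=False):
        j = col_of.get(str(sid))
        if j is None:
            raise ValidationError(f"read record for unknown sample {sid!r}")
        known = grp["chrom"].isin(grid.chrom_sizes).to_numpy()
        skipped_chrom += int((~known).sum())
        grp = grp.loc[known]
        mid = (grp["start"].to_numpy(np.int64) + grp["end"].to_numpy(np.int64)) // 2
        # clip midpoints of fragments overhanging the chromosome end
        sizes = grp["chrom"].map(grid.chrom_sizes).to_numpy(np.int64)
        mid = np.minimum(mid, sizes - 1)
        gidx = grp["chrom"].map(offset_of).to_numpy(np.int64) + mid // grid.bin_size
        raw[:, j] += np.bincount(gidx, minlength=grid.n_windows)

    if skipped_chrom:
        log.warning("count_fragments: skipped %d fragments on unknown chromosomes", skipped_chrom)

    out_samples = [
        s if s.library_size > 0 else replace(s, library_size=int(raw[:, j].sum()))
        for j, s in enumerate(samples)
    ]
    return CountMatrix(grid=grid, samples=out_samples, raw=raw)


def rpm_normalize(matrix: CountMatrix) -> CountMatrix:
    """Populate reads-per-million: rpm = raw / library_size * 1e6."""
    libs = np.array([s.library_size for s in matrix.samples], dtype=np.float64)
    if (libs <= 0).any():
        offender = matrix.samples[int(np.flatnonzero(libs <= 0)[0])].sample_id
        raise ValidationError(f"sample {offender!r} has zero library size; cannot rpm-normalize")
    rpm = matrix.raw / libs[None, :] * 1e6
    return CountMatrix(grid=matrix.grid, samples=matrix.samples, raw=matrix.raw, rpm=rpm)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_fragments_tsv(path) -> pd.DataFrame:
    """Minimal read-record format: sample_id, chrom, start, end (tab, header)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    return df


def read_fragments_bam(path, sample_id: str, min_mapq: int = 0) -> pd.DataFrame:
    """Extract fragment intervals from proper pairs of a BAM/SAM file."""
    import pysam  # optional dependency, imported lazily

    rows = []
    with pysam.AlignmentFile(str(path)) as bam:
        for rec in bam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            if rec.is_paired:
                if not rec.is_proper_pair or rec.template_length <= 0:
                    continue  # count each pair once, from the leftmost mate
                start = rec.reference_start
                end = start + rec.template_length
            else:
                start, end = rec.reference_start, rec.reference_end
            rows.append((sample_id, rec.reference_name, int(start), int(end)))
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end"])


def write_counts_tsv(matrix: CountMatrix, path, which: str = "raw") -> None:
    frame = matrix.to_frame(which)
    frame.index.name = "window"
    frame.to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")


def read_counts_tsv(path, grid: WindowGrid, samples: Sequence[SampleMeta]) -> CountMatrix:
    """Round-trip counterpart of :func:`write_counts_tsv` (raw counts)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    expected = grid.window_ids()
    if list(frame.index) != expected:
        raise ValidationError("window ids in counts file do not match the grid")
    samples = list(samples)
    frame = frame[[s.sample_id for s in samples]]
    return CountMatrix(grid=grid, samples=samples, raw=frame.to_numpy(dtype=np.int64))


def read_sample_sheet(path) -> List[SampleMeta]:
    """Sample sheet TSV: sample_id, tissue[, cohort, library_size]."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tissue": str})
    metas = []
    for _, row in df.iterrows():
        metas.append(
            SampleMeta(
                sample_id=row["sample_id"],
                tissue=row["tissue"],
                cohort=row.get("cohort", "discovery"),
                library_size=int(row.get("library_size", 0) or 0),
            )
        )
    if len({m.sample_id for m in metas}) != len(metas):
        raise ValidationError("duplicate sample ids in sample sheet")
    return metas
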