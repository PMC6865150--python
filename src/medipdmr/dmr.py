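"""DMR assembly: merging, selection criteria, intersection, annotation.

Significant windows are merged into maximal same-direction runs (gap
tolerance 0 by default, i.e. strictly adjacent bins). A merged region is
retained as a candidate fetal-specific DMR only if it

* contains at least ``min_cpg`` CpG dinucleotides (default 3),
* overlaps no copy-number-variable region,
* lies at least ``min_repeat_distance`` bp (default 200, boundary passes)
  from the nearest repetitive element, and
* reaches Bonferroni-adjusted significance (min member p_adj < threshold).

DMRs surviving both pairwise comparisons (fetal tissue vs whole blood and
fetal tissue vs plasma) with the same direction and >= 1 bp overlap form the
common fetal-specific set; these are annotated against gene body / exon /
promoter / CGI tracks (multi-label: a DMR in an exon inside a gene carries
both labels).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import AnnotationSet, IntervalTrack
from .windows import ValidationError

log = logging.getLogger(__name__)

HYPER = "hyper_in_fetal"
HYPO = "hypo_in_fetal"

LABELS = ("gene_body", "exon", "promoter", "cgi")
LABEL_TRACKS = {"gene_body": "gene_bodies", "exon": "exons", "promoter": "promoters", "cgi": "cgis"}

FLAG_LOW_CPG = "low_cpg"
FLAG_IN_CNV = "in_cnv"
FLAG_NEAR_REPEAT = "near_repeat"
FLAG_NOT_SIGNIFICANT = "not_significant"
FLAG_SINGLE_COMPARISON = "single_comparison"


@dataclass
class Dmr:
    """A merged run of significant windows with statistics and annotations."""

    chrom: str
    start: int
    end: int
    direction: str
    n_windows: int
    min_p_adj: float
    mean_log2_ratio: float
    n_cpg: int = 0
    labels: frozenset = frozenset()
    provenance: frozenset = frozenset()
    filter_fail: frozenset = frozenset()

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Dmr", min_overlap: int = 1) -> bool:
        return (
            self.chrom == other.chrom
            and min(self.end, other.end) - max(self.start, other.start) >= min_overlap
        )


def _direction_from_window(win_direction: str) -> str:
    # group A is the fetal tissue in both pipeline comparisons
    return HYPER if win_direction == "hyper_in_A" else HYPO


def merge_windows(
    significant: pd.DataFrame,
    max_gap: int = 0,
    same_direction: bool = True,
    provenance: str | None = None,
) -> List[Dmr]:
    """Merge sorted significant windows into maximal runs.

    ``significant`` is the frame produced by ``difftest.select_significant``
    (columns chrom/start/end/direction/p_adj/log2_ratio), sorted by
    (chrom, start). Runs break when the inter-window gap exceeds ``max_gap``
    bp or (if ``same_direction``) the direction changes.
    """
    if len(significant) == 0:
        return []
    chroms = significant["chrom"].to_numpy()
    starts = significant["start"].to_numpy(np.int64)
    ends = significant["end"].to_numpy(np.int64)
    order_ok = all(
        (chroms[i] < chroms[i + 1]) or (chroms[i] == chroms[i + 1] and starts[i] <= starts[i + 1])
        for i in range(len(chroms) - 1)
    )
    if not order_ok:
        raise ValidationError("significant windows must be sorted by (chrom, start)")
    directions = [_direction_from_window(d) for d in significant["direction"]]
    p_adj = significant["p_adj"].to_numpy(np.float64)
    l2 = significant["log2_ratio"].to_numpy(np.float64)

    prov = frozenset([provenance]) if provenance else frozenset()
    dmrs: List[Dmr] = []
    run: List[int] = [0]

    def close(run_idx: List[int]) -> None:
        i0, i1 = run_idx[0], run_idx[-1]
        dmrs.append(
            Dmr(
                chrom=str(chroms[i0]),
                start=int(starts[i0]),
                end=int(ends[i1]),
                direction=directions[i0],
                n_windows=len(run_idx),
                min_p_adj=float(p_adj[run_idx].min() if len(run_idx) > 1 else p_adj[i0]),
                mean_log2_ratio=float(np.mean(l2[run_idx])),
                provenance=prov,
            )
        )

    for i in range(1, len(chroms)):
        j = run[-1]
        contiguous = (
            chroms[i] == chroms[j]
            and starts[i] - ends[j] <= max_gap
            and (not same_direction or directions[i] == directions[j])
        )
        if contiguous:
            run.append(i)
        else:
            close(run)
            run = [i]
    close(run)
    return dmrs


def count_cpgs(dmr: Dmr, annotation: AnnotationSet) -> int:
    """CpG sites p with dmr.start <= p < dmr.end (binary search)."""
    return annotation.cpg_count(dmr.chrom, dmr.start, dmr.end)


def attach_cpg_counts(dmrs: Iterable[Dmr], annotation: AnnotationSet) -> List[Dmr]:
    return [replace(d, n_cpg=count_cpgs(d, annotation)) for d in dmrs]


def apply_selection(
    dmrs: Sequence[Dmr],
    annotation: AnnotationSet,
    min_cpg: int = 3,
    min_repeat_distance: int = 200,
    p_threshold: float = 0.10,
) -> Tuple[List[Dmr], Dict[str, int]]:
    """Apply the candidate-DMR selection criteria; audit the removals.

    A DMR passes iff n_cpg >= min_cpg, it overlaps no CNV, its edge distance
    to the nearest repeat (0 when overlapping) is >= min_repeat_distance, and
    min_p_adj < p_threshold. Rejected DMRs carry every applicable flag
    (cumulative, not first-fail).
    """
    selected: List[Dmr] = []
    rejected: List[Dmr] = []
    audit = {FLAG_LOW_CPG: 0, FLAG_IN_CNV: 0, FLAG_NEAR_REPEAT: 0, FLAG_NOT_SIGNIFICANT: 0}
    for d in dmrs:
        flags = set()
        if d.n_cpg < min_cpg:
            flags.add(FLAG_LOW_CPG)
        cnv = annotation.cnvs.get(d.chrom, IntervalTrack())
        if cnv.overlaps(d.start, d.end):
            flags.add(FLAG_IN_CNV)
        rep = annotation.repeats.get(d.chrom, IntervalTrack())
        if rep.distance(d.start, d.end) < min_repeat_distance:
            flags.add(FLAG_NEAR_REPEAT)
        if not (d.min_p_adj < p_threshold):
            flags.add(FLAG_NOT_SIGNIFICANT)
        if flags:
            for f in flags:
                audit[f] += 1
            rejected.append(replace(d, filter_fail=frozenset(flags)))
        else:
            selected.append(d)
    audit["selected"] = len(selected)
    audit["rejected"] = len(rejected)
    log.info("apply_selection: %s", audit)
    return selected, audit


def intersect_comparisons(
    dmrs_vs_wbf: Sequence[Dmr],
    dmrs_vs_pl: Sequence[Dmr],
    min_overlap: int = 1,
    mode: str = "intersection",
) -> List[Dmr]:
    """Common DMRs supported by both pairwise comparisons.

    One output Dmr per same-direction pair overlapping by >= ``min_overlap``
    bp. The reported interval is the intersection of the two intervals
    (``mode='union'`` reports the union instead). The joint min_p_adj is the
    max of the two per-comparison minima (both must be significant); the
    log2 ratio is their mean. Symmetric in its arguments up to ordering.
    """
    if mode not in ("intersection", "union"):
        raise ValidationError(f"mode must be 'intersection' or 'union', got {mode!r}")
    out: List[Dmr] = []
    by_chrom: Dict[str, List[Dmr]] = {}
    for d in dmrs_vs_pl:
        by_chrom.setdefault(d.chrom, []).append(d)
    for a in dmrs_vs_wbf:
        for b in by_chrom.get(a.chrom, ()):
            if a.direction != b.direction:
                continue
            lo, hi = max(a.start, b.start), min(a.end, b.end)
            if hi - lo < min_overlap:
                continue
            if mode == "union":
                lo, hi = min(a.start, b.start), max(a.end, b.end)
            out.append(
                Dmr(
                    chrom=a.chrom,
                    start=lo,
                    end=hi,
                    direction=a.direction,
                    n_windows=min(a.n_windows, b.n_windows),
                    min_p_adj=max(a.min_p_adj, b.min_p_adj),
                    mean_log2_ratio=(a.mean_log2_ratio + b.mean_log2_ratio) / 2.0,
                    provenance=a.provenance | b.provenance | frozenset({"vs_WBF", "vs_PL"}),
                )
            )
    out.sort(key=lambda d: (d.chrom, d.start, d.end))
    return out


def annotate_dmrs(dmrs: Sequence[Dmr], annotation: AnnotationSet) -> List[Dmr]:
    """Attach every genomic-context label whose track overlaps by >= 1 bp."""
    out = []
    for d in dmrs:
        labels = set()
        for label, track_name in LABEL_TRACKS.items():
            track = annotation.track(track_name).get(d.chrom, IntervalTrack())
            if track.overlaps(d.start, d.end):
                labels.add(label)
        out.append(replace(d, labels=frozenset(labels)))
    return out


def summarize_dmrs(dmrs: Sequence[Dmr]) -> Dict:
    """n, length median/IQR/min/max, and counts per direction/label/provenance."""
    if len(dmrs) == 0:
        return {"n": 0}
    lengths = np.array([d.length for d in dmrs], dtype=np.float64)
    q1, q3 = np.percentile(lengths, [25, 75])  # linear-interpolation quantiles
    directions: Dict[str, int] = {}
    labels: Dict[str, int] = {}
    provenance: Dict[str, int] = {}
    for d in dmrs:
        directions[d.direction] = directions.get(d.direction, 0) + 1
        for lab in sorted(d.labels):
            labels[lab] = labels.get(lab, 0) + 1
        for pv in sorted(d.provenance):
            provenance[pv] = provenance.get(pv, 0) + 1
    return {
        "n": len(dmrs),
        "length_median": float(np.median(lengths)),
        "length_iqr": float(q3 - q1),
        "length_min": float(lengths.min()),
        "length_max": float(lengths.max()),
        "by_direction": directions,
        "by_label": labels,
        "by_provenance": provenance,
    }


def select_top_regulatory(dmrs: Sequence[Dmr], k: int | None) -> List[Dmr]:
    """Deterministic stand-in for narrowing to regions in regulatory context.

    Keeps DMRs carrying at least one of the gene body / exon / promoter / CGI
    labels, ranks by min_p_adj ascending (ties by genomic position), and
    takes the top ``k`` (all, if ``k`` is None or exceeds the list).
    """
    regulatory = [d for d in dmrs if d.labels]
    regulatory.sort(key=lambda d: (d.min_p_adj, d.chrom, d.start, d.end))
    if k is None:
        return regulatory
    return regulatory[: int(k)]


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def dmrs_to_frame(dmrs: Sequence[Dmr]) -> pd.DataFrame:
    rows = []
    for d in dmrs:
        rows.append(
            {
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                "length": d.length,
                "direction": d.direction,
                "n_windows": d.n_windows,
                "min_p_adj": d.min_p_adj,
                "mean_log2_ratio": d.mean_log2_ratio,
                "n_cpg": d.n_cpg,
                "labels": ",".join(sorted(d.labels)),
                "provenance": ",".join(sorted(d.provenance)),
                "filter_fail": ",".join(sorted(d.filter_fail)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "length", "direction", "n_windows",
            "min_p_adj", "mean_log2_ratio", "n_cpg", "labels", "provenance",
            "filter_fail",
        ],
    )


def write_dmrs_tsv(dmrs: Sequence[Dmr], path) -> None:
    dmrs_to_frame(dmrs).to_csv(
        path, sep="\t", index=False, float_format="%.10g", lineterminator="\n"
    )


def write_dmrs_bed(dmrs: Sequence[Dmr], path) -> None:
    """BED with name = direction and score = -log10(min p_adj) capped at 1000."""
    with open(path, "w") as fh:
        for d in sorted(dmrs, key=lambda d: (d.chrom, d.start, d.end)):
            if d.min_p_adj > 0:
                score = min(1000.0, -np.log10(d.min_p_adj))
            else:
                score = 1000.0
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.direction}\t{score:.4f}\n")
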