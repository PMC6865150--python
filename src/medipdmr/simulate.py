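"""Seeded synthetic genomes, annotations, MeDIP window counts and panel depths.

The generator plants ground-truth fetal-hypermethylated regions (and decoys
violating one selection criterion each) into a small synthetic genome so
every downstream stage of the pipeline is testable without external data.

Model
-----
MeDIP enrichment scales with the methylated CpG content of a fragment, and
sequencing counts are overdispersed, so window counts are drawn negative
binomial with mean

    lambda(w, s) = L_s * b * (1 + alpha * m_tissue(s)(w) * c(w)) * cnv(w, s)

where ``L_s`` is the sample's library-size factor, ``b`` the baseline window
depth, ``alpha`` the enrichment effect scale, ``m`` the tissue methylation
level of the window (a common low background outside planted regions),
``c(w)`` the window CpG count and ``cnv`` the copy ratio for samples carrying
a CNV over the window. Planted regions live inside CpG islands: enrichment is
CpG-driven, so only CpG-dense regions can show a strong methylation signal.

Targeted-panel depths follow the same enrichment model per region with an
additional per-region multiplicative capture efficiency
``g_d ~ LogNormal(0, sigma_d)`` shared across samples, the motivation for the
random region effect in the confirmation ANOVA. The panel also carries
non-differential control regions used by vertical normalization.

Every stage draws from an independent substream of one global seed, so
stages can be regenerated in isolation and all outputs are byte-identical
for a fixed configuration.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .dmr import Dmr, HYPER
from .intervals import AnnotationSet, IntervalTrack, frame_from_track, write_bed
from .windows import (
    CountMatrix,
    SampleMeta,
    WindowGrid,
    make_windows,
    n_windows_for,
)

log = logging.getLogger(__name__)

STREAMS = ("annotation", "truth", "counts", "panel")

DECOY_NONE = "none"
DECOY_IN_CNV = "in_cnv"
DECOY_NEAR_REPEAT = "near_repeat"
DECOY_LOW_CPG = "low_cpg"
DECOY_SINGLE_COMPARISON = "single_comparison"
DECOY_CLASSES = (DECOY_IN_CNV, DECOY_NEAR_REPEAT, DECOY_LOW_CPG, DECOY_SINGLE_COMPARISON)


class SimConfigError(ValueError):
    pass


class PlacementError(RuntimeError):
    """The requested features do not fit in the synthetic genome."""


@dataclass
class SimConfig:
    """All knobs of the synthetic study.

    Defaults follow the study design: 100-bp bins over a 5-Mb genome
    (~50,000 windows), planted region lengths 100-2300 bp, discovery cohort
    3 CVS / 3 WBF / 2 PL and confirmation cohort 8/8/8. The depth and
    dispersion defaults put the counts in the technical-noise-dominated
    regime in which a per-window test on three-vs-three samples retains
    power after a family-wise adjustment over 50,000 windows; they are
    deliberate design choices for the synthetic study, not estimates of any
    real MeDIP experiment (see docs/methods.md).
    """

    seed: int = 0
    chrom_sizes: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_500_000, "chr2": 2_500_000}
    )
    bin_size: int = 100
    # CpG landscape
    cpg_background_rate: float = 0.01       # sites per bp outside CGIs
    cgi_cpg_rate: float = 0.08              # sites per bp inside CGIs
    n_cgis: int = 300
    cgi_length_range: Tuple[int, int] = (400, 2600)
    # annotation tracks
    n_repeats: int = 300
    repeat_length_range: Tuple[int, int] = (200, 1500)
    n_cnvs: int = 8
    cnv_length_range: Tuple[int, int] = (3_000, 8_000)
    n_genes: int = 120
    gene_length_range: Tuple[int, int] = (2_000, 20_000)
    promoter_length: int = 1000
    # truth
    n_true_dmrs: int = 40
    n_decoys_per_class: int = 3
    dmr_length_range: Tuple[int, int] = (100, 2300)
    tissue_methylation: Dict[str, float] = field(
        default_factory=lambda: {"CVS": 0.85, "WBF": 0.05, "PL": 0.10}
    )
    background_methylation: float = 0.05
    # count model
    effect_scale: float = 0.6               # alpha; ~4x CVS/WBF window ratio at c = 8
    dispersion: float = 1e6                 # negative-binomial size parameter
    baseline_depth: float = 25_000.0        # b, reads per window at L_s = 1
    library_size_range: Tuple[int, int] = (1_000_000_000, 1_500_000_000)
    cnv_affect_prob: float = 0.2
    cnv_copy_ratios: Tuple[float, ...] = (0.5, 1.5, 2.0)
    # confirmation panel
    capture_sigma: float = 0.5              # sigma_d of LogNormal capture efficiency
    panel_baseline: float = 300.0           # panel depth scale at L_s = g_d = 1
    n_panel_controls: int = 200
    control_length: int = 500

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_cgis": self.n_cgis, "n_repeats": self.n_repeats, "n_cnvs": self.n_cnvs,
            "n_genes": self.n_genes, "n_true_dmrs": self.n_true_dmrs,
            "n_decoys_per_class": self.n_decoys_per_class,
            "n_panel_controls": self.n_panel_controls,
        }
        for name, v in counts.items():
            if v < 0:
                raise SimConfigError(f"{name} must be >= 0, got {v}")
        for tissue, m in self.tissue_methylation.items():
            if not 0.0 <= m <= 1.0:
                raise SimConfigError(f"methylation level for {tissue} must be in [0, 1], got {m}")
        if not 0.0 <= self.background_methylation <= 1.0:
            raise SimConfigError("background_methylation must be in [0, 1]")
        if self.effect_scale < 0:
            raise SimConfigError("effect_scale must be >= 0")
        if self.dispersion <= 0:
            raise SimConfigError("dispersion must be > 0")
        if self.capture_sigma < 0:
            raise SimConfigError("capture_sigma must be >= 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise SimConfigError("library_size_range must satisfy 0 < lo <= hi")
        for chrom, length in self.chrom_sizes.items():
            if length < self.bin_size:
                raise SimConfigError(
                    f"chromosome {chrom!r} ({length} bp) shorter than bin size {self.bin_size}"
                )

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, named substream of the global seed."""
        if stream not in STREAMS:
            raise SimConfigError(f"unknown stream {stream!r}")
        root = np.random.SeedSequence(self.seed)
        return np.random.default_rng(root.spawn(len(STREAMS))[STREAMS.index(stream)])

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: Dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SimConfigError(f"unknown simulation keys: {sorted(unknown)}")
        cleaned = dict(raw)
        for key in ("library_size_range", "cgi_length_range", "repeat_length_range",
                    "cnv_length_range", "gene_length_range", "dmr_length_range",
                    "cnv_copy_ratios"):
            if key in cleaned and cleaned[key] is not None:
                cleaned[key] = tuple(cleaned[key])
        return cls(**cleaned)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


@dataclass(frozen=True)
class TruthRecord:
    chrom: str
    start: int
    end: int
    direction: str
    methylation: Tuple[Tuple[str, float], ...]   # per-tissue level, hashable
    decoy_class: str = DECOY_NONE

    @property
    def methylation_map(self) -> Dict[str, float]:
        return dict(self.methylation)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SimTruth:
    """Planted regions: compliant fetal DMRs plus one decoy set per class."""

    records: List[TruthRecord]

    def by_class(self, decoy_class: str) -> List[TruthRecord]:
        return [r for r in self.records if r.decoy_class == decoy_class]

    @property
    def compliant(self) -> List[TruthRecord]:
        return self.by_class(DECOY_NONE)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"chrom": r.chrom, "start": r.start, "end": r.end,
                   "direction": r.direction, "decoy_class": r.decoy_class}
            for tissue, m in r.methylation:
                row[f"m_{tissue}"] = m
            rows.append(row)
        return pd.DataFrame(rows)


def default_samples(cohort: str = "discovery") -> List[SampleMeta]:
    """The study's sample design: discovery 3/3/2, confirmation 8/8/8."""
    design = {"discovery": {"CVS": 3, "WBF": 3, "PL": 2},
              "confirmation": {"CVS": 8, "WBF": 8, "PL": 8}}[cohort]
    metas = []
    for tissue in ("CVS", "WBF", "PL"):
        for i in range(design[tissue]):
            metas.append(SampleMeta(f"{tissue}_{cohort[:4]}_{i + 1}", tissue, cohort=cohort))
    return metas


# ---------------------------------------------------------------------------
# Annotation generation
# ---------------------------------------------------------------------------

def _choose_chrom(rng: np.random.Generator, chrom_sizes: Dict[str, int]) -> str:
    names = sorted(chrom_sizes)
    p = np.array([chrom_sizes[c] for c in names], dtype=float)
    return names[rng.choice(len(names), p=p / p.sum())]

def _clear_of(intervals: List[Tuple[int, int]], start: int, end: int, gap: int) -> bool:
    return all(end + gap <= s or e + gap <= start for s, e in intervals)


def _place_uniform(
    rng: np.random.Generator,
    chrom_sizes: Dict[str, int],
    length_range: Tuple[int, int],
    occupied: Dict[str, List[Tuple[int, int]]],
    gap: int,
    avoid: Dict[str, List[Tuple[int, int]]] | None = None,
    avoid_gap: int = 0,
    max_tries: int = 2000,
) -> Tuple[str, int, int]:
    for _ in range(max_tries):
        chrom = _choose_chrom(rng, chrom_sizes)
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        if chrom_sizes[chrom] <= length:
            continue
        start = int(rng.integers(0, chrom_sizes[chrom] - length))
        end = start + length
        if not _clear_of(occupied.get(chrom, []), start, end, gap):
            continue
        if avoid is not None and not _clear_of(avoid.get(chrom, []), start, end, avoid_gap):
            continue
        occupied.setdefault(chrom, []).append((start, end))
        return chrom, start, end
    raise PlacementError(
        f"could not place a feature of length {length_range} "
        f"after {max_tries} attempts; genome too small or too crowded"
    )


def generate_annotation(config: SimConfig) -> AnnotationSet:
    """Deterministically generate annotation tracks and CpG sites.

    CGIs are placed first (mutually separated so planted regions cannot
    merge across hosts). A few repeats are deliberately placed adjacent to
    CGIs and a few CNVs anchored over CGIs, so that decoy hosts for
    ``plant_truth`` exist for every seed; all remaining features are placed
    uniformly. CpG sites arise from an independent per-bp Bernoulli draw at
    ``cgi_cpg_rate`` inside CGIs and ``cpg_background_rate`` elsewhere.
    """
    rng = config.rng("annotation")
    sizes = config.chrom_sizes

    cgis: Dict[str, List[Tuple[int, int]]] = {}
    cgi_list: List[Tuple[str, int, int]] = []
    for _ in range(config.n_cgis):
        chrom, s, e = _place_uniform(rng, sizes, config.cgi_length_range, cgis, gap=600)
        cgi_list.append((chrom, s, e))

    # repeats: anchors adjacent to CGIs (decoy hosts), remainder uniform but
    # clear of unanchored CGIs so compliant hosts stay compliant
    repeats: Dict[str, List[Tuple[int, int]]] = {}
    n_anchor_rep = min(config.n_repeats, config.n_decoys_per_class + 2) if config.n_repeats else 0
    anchor_cgi_idx = (
        rng.choice(len(cgi_list), size=min(len(cgi_list), n_anchor_rep), replace=False)
        if n_anchor_rep and cgi_list else np.array([], dtype=int)
    )
    for idx in anchor_cgi_idx:
        chrom, cs, ce = cgi_list[int(idx)]
        placed = False
        for _ in range(200):
            length = int(rng.integers(*config.repeat_length_range))
            gap = int(rng.integers(20, 61))
            if rng.random() < 0.5:
                s, e = ce + gap, ce + gap + length
            else:
                s, e = cs - gap - length, cs - gap
            if s < 0 or e > sizes[chrom]:
                continue
            if not _clear_of(repeats.get(chrom, []), s, e, 0):
                continue
            other_cgis = [iv for iv in cgis.get(chrom, []) if iv != (cs, ce)]
            if not _clear_of(other_cgis, s, e, 350):
                continue
            repeats.setdefault(chrom, []).append((s, e))
            placed = True
            break
        if not placed:
            raise PlacementError("could not anchor a repeat next to a CGI")
    for _ in range(config.n_repeats - len(anchor_cgi_idx)):
        _place_uniform(
            rng, sizes, config.repeat_length_range, repeats, gap=0,
            avoid=cgis, avoid_gap=350,
        )

    # CNVs: anchors over CGIs that carry no adjacent repeat, remainder uniform
    cnvs: Dict[str, List[Tuple[int, int]]] = {}
    n_anchor_cnv = min(config.n_cnvs, config.n_decoys_per_class + 1) if config.n_cnvs else 0
    free_idx = [i for i in range(len(cgi_list)) if i not in set(anchor_cgi_idx.tolist())]
    cnv_anchor_idx = (
        rng.choice(free_idx, size=min(len(free_idx), n_anchor_cnv), replace=False)
        if n_anchor_cnv and free_idx else np.array([], dtype=int)
    )
    for idx in cnv_anchor_idx:
        chrom, cs, ce = cgi_list[int(idx)]
        placed = False
        for _ in range(200):
            length = max(int(rng.integers(*config.cnv_length_range)), (ce - cs) + 1000)
            offset = int(rng.integers(int(0.1 * length), int(0.8 * length)))
            s = max(0, cs - offset)
            e = min(sizes[chrom], s + length)
            if e - s < config.cnv_length_range[0] // 2 or e < ce:
                continue
            if not _clear_of(cnvs.get(chrom, []), s, e, 0):
                continue
            cnvs.setdefault(chrom, []).append((s, e))
            placed = True
            break
        if not placed:
            raise PlacementError("could not anchor a CNV over a CGI")
    for _ in range(config.n_cnvs - len(cnv_anchor_idx)):
        _place_uniform(rng, sizes, config.cnv_length_range, cnvs, gap=0)

    # genes with promoters and exons; half anchored so promoters cover CGIs
    genes: Dict[str, List[Tuple[int, int]]] = {}
    promoters: Dict[str, List[Tuple[int, int]]] = {}
    exons: Dict[str, List[Tuple[int, int]]] = {}
    for gi in range(config.n_genes):
        if gi % 2 == 0 and cgi_list:
            chrom, cs, ce = cgi_list[int(rng.integers(len(cgi_list)))]
            length = int(rng.integers(*config.gene_length_range))
            start = (cs + ce) // 2          # promoter then overlaps the CGI
            end = min(sizes[chrom], start + length)
            if end - start < config.gene_length_range[0] // 2 or not _clear_of(
                genes.get(chrom, []), start, end, 200
            ):
                chrom, start, end = _place_uniform(
                    rng, sizes, config.gene_length_range, genes, gap=200
                )
            else:
                genes.setdefault(chrom, []).append((start, end))
        else:
            chrom, start, end = _place_uniform(rng, sizes, config.gene_length_range, genes, gap=200)
        promoters.setdefault(chrom, []).append((max(0, start - config.promoter_length), start))
        pos = start
        while pos < end - 100:
            ex_len = int(rng.integers(100, 401))
            ex_end = min(end, pos + ex_len)
            exons.setdefault(chrom, []).append((pos, ex_end))
            pos = ex_end + int(rng.integers(200, 2001))

    # CpG sites: per-bp Bernoulli at the local rate
    cpg_sites: Dict[str, np.ndarray] = {}
    for chrom in sorted(sizes):
        rate = np.full(sizes[chrom], config.cpg_background_rate, dtype=np.float64)
        for s, e in cgis.get(chrom, []):
            rate[s:e] = config.cgi_cpg_rate
        cpg_sites[chrom] = np.flatnonzero(rng.random(sizes[chrom]) < rate).astype(np.int64)

    def _tracks(d: Dict[str, List[Tuple[int, int]]]) -> Dict[str, IntervalTrack]:
        return {c: IntervalTrack(v) for c, v in d.items()}

    ann = AnnotationSet(
        chrom_sizes=dict(sizes),
        cpg_sites=cpg_sites,
        repeats=_tracks(repeats),
        cnvs=_tracks(cnvs),
        gene_bodies=_tracks(genes),
        exons=_tracks(exons),
        promoters=_tracks(promoters),
        cgis=_tracks(cgis),
    )
    log.info(
        "generate_annotation: %d CGIs, %d repeats, %d CNVs, %d genes, %d CpGs",
        config.n_cgis, config.n_repeats, config.n_cnvs, config.n_genes,
        sum(len(v) for v in cpg_sites.values()),
    )
    return ann


# ---------------------------------------------------------------------------
# Truth planting
# ---------------------------------------------------------------------------

_REPEAT_CLEAR = 300   # compliant host margin; merged DMRs extend <= bin_size - 1 bp
_CNV_CLEAR = 150


def _methylation(config: SimConfig, decoy_class: str) -> Tuple[Tuple[str, float], ...]:
    m = dict(config.tissue_methylation)
    if decoy_class == DECOY_SINGLE_COMPARISON:
        m["PL"] = m["CVS"]   # differential versus WBF only
    return tuple(sorted(m.items()))


def plant_truth(annotation: AnnotationSet, config: SimConfig) -> SimTruth:
    """Choose planted intervals: compliant DMRs plus one decoy set per class.

    Compliant records live inside CpG islands >= 300 bp from repeats and
    clear of CNVs and carry >= 3 CpGs; each decoy class violates exactly the
    criterion it is named after (CNV overlap, repeat proximity, <= 2 CpGs,
    or differential in only one comparison).
    """
    rng = config.rng("truth")
    sizes = annotation.chrom_sizes

    cgi_info = []
    for chrom in sorted(sizes):
        for s, e in annotation.cgis.get(chrom, IntervalTrack()):
            rep = annotation.repeats.get(chrom, IntervalTrack())
            cnv = annotation.cnvs.get(chrom, IntervalTrack())
            cgi_info.append(
                {
                    "chrom": chrom, "start": s, "end": e,
                    "n_cpg": annotation.cpg_count(chrom, s, e),
                    "repeat_dist": rep.distance(s, e),
                    "cnv_dist": cnv.distance(s, e),
                    "in_cnv": cnv.overlap_bp(s, e) >= (e - s),
                }
            )

    def eligible(kind: str):
        out = []
        for info in cgi_info:
            if info["n_cpg"] < 3:
                continue
            if kind == "clean":
                ok = info["repeat_dist"] >= _REPEAT_CLEAR and info["cnv_dist"] >= _CNV_CLEAR
            elif kind == DECOY_IN_CNV:
                ok = info["in_cnv"] and info["repeat_dist"] >= _REPEAT_CLEAR
            elif kind == DECOY_NEAR_REPEAT:
                ok = 0 < info["repeat_dist"] < 200 and info["cnv_dist"] >= _CNV_CLEAR
            else:
                raise ValueError(kind)
            if ok:
                out.append(info)
        return out

    used: set = set()
    records: List[TruthRecord] = []

    def take_hosts(kind: str, n: int) -> List[dict]:
        pool = [i for i in eligible(kind) if (i["chrom"], i["start"]) not in used]
        if len(pool) < n:
            raise PlacementError(
                f"insufficient clean genome space: need {n} hosts of kind {kind!r}, "
                f"found {len(pool)}"
            )
        idx = rng.choice(len(pool), size=n, replace=False)
        hosts = [pool[int(i)] for i in idx]
        for h in hosts:
            used.add((h["chrom"], h["start"]))
        return hosts

    def carve(host: dict, anchor_proximal_repeat: bool = False) -> Tuple[int, int]:
        """Sub-interval of the host CGI with >= 3 CpGs.

        Near-repeat decoys are kept short (<= 120 bp) and anchored at the
        repeat-proximal edge of the island, so that any window run the
        discovery stage recovers from them still lies < 200 bp from the
        repeat after snapping to bin boundaries.
        """
        chrom, cs, ce = host["chrom"], host["start"], host["end"]
        host_len = ce - cs
        lo, hi = config.dmr_length_range
        if anchor_proximal_repeat:
            hi = min(hi, 120)
        for _ in range(20):
            length = min(int(rng.integers(lo, hi + 1)), host_len)
            if anchor_proximal_repeat:
                rep = annotation.repeats[chrom]
                d_start = rep.distance(cs, cs + 1)
                d_end = rep.distance(ce - 1, ce)
                start = cs if d_start <= d_end else ce - length
            else:
                start = cs + int(rng.integers(0, host_len - length + 1))
            end = start + length
            if annotation.cpg_count(chrom, start, end) >= 3:
                return start, end
        if anchor_proximal_repeat:
            raise PlacementError("near-repeat decoy host lacks a CpG-bearing proximal edge")
        return cs, ce   # full island always satisfies the CpG bound

    # compliant planted DMRs
    for host in take_hosts("clean", config.n_true_dmrs):
        s, e = carve(host)
        records.append(
            TruthRecord(host["chrom"], s, e, HYPER, _methylation(config, DECOY_NONE))
        )
    # decoys hosted in CGIs
    for decoy in (DECOY_IN_CNV, DECOY_NEAR_REPEAT, DECOY_SINGLE_COMPARISON):
        kind = "clean" if decoy == DECOY_SINGLE_COMPARISON else decoy
        for host in take_hosts(kind, config.n_decoys_per_class):
            s, e = carve(host, anchor_proximal_repeat=(decoy == DECOY_NEAR_REPEAT))
            records.append(
                TruthRecord(host["chrom"], s, e, HYPER, _methylation(config, decoy), decoy)
            )
    # low-CpG decoys: single background windows holding 1-2 CpG sites
    if config.n_decoys_per_class > 0:
        bins = config.bin_size
        candidates = []
        for chrom in sorted(sizes):
            nb = n_windows_for(sizes[chrom], bins)
            counts = np.bincount(annotation.cpg_sites[chrom] // bins, minlength=nb)
            for w in np.flatnonzero((counts >= 1) & (counts <= 2)):
                candidates.append((chrom, int(w) * bins, min(int(w + 1) * bins, sizes[chrom])))
        rng.shuffle(candidates)
        found = 0
        taken = [(r.chrom, r.start, r.end) for r in records]
        for chrom, s, e in candidates:
            if found >= config.n_decoys_per_class:
                break
            rep = annotation.repeats.get(chrom, IntervalTrack())
            cnv = annotation.cnvs.get(chrom, IntervalTrack())
            cgi = annotation.cgis.get(chrom, IntervalTrack())
            if rep.distance(s, e) < _REPEAT_CLEAR or cnv.distance(s, e) < _CNV_CLEAR:
                continue
            if cgi.distance(s, e) < 300:
                continue
            if any(c == chrom and s - 300 < te and ts < e + 300 for c, ts, te in taken):
                continue
            records.append(
                TruthRecord(chrom, s, e, HYPER, _methylation(config, DECOY_LOW_CPG), DECOY_LOW_CPG)
            )
            taken.append((chrom, s, e))
            found += 1
        if found < config.n_decoys_per_class:
            raise PlacementError(
                f"insufficient clean genome space: only {found} low-CpG decoy windows found"
            )

    records.sort(key=lambda r: (r.chrom, r.start))
    truth = SimTruth(records=records)
    log.info(
        "plant_truth: %d compliant + %s decoys",
        len(truth.compliant),
        {c: len(truth.by_class(c)) for c in DECOY_CLASSES},
    )
    return truth


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

def cpg_counts_per_window(annotation: AnnotationSet, grid: WindowGrid) -> np.ndarray:
    """c(w): CpG sites per window, grid order."""
    parts = []
    for chrom in grid.chrom_names:
        nw = n_windows_for(grid.chrom_sizes[chrom], grid.bin_size)
        pos = annotation.cpg_sites.get(chrom, np.array([], dtype=np.int64))
        parts.append(np.bincount(pos // grid.bin_size, minlength=nw)[:nw])
    return np.concatenate(parts).astype(np.float64)


def _window_range(grid: WindowGrid, chrom: str, start: int, end: int) -> slice:
    """Global indices of windows overlapping [start, end) on chrom."""
    off = grid.chrom_slice(chrom).start
    first = start // grid.bin_size
    last = -(-end // grid.bin_size)     # ceil
    return slice(off + first, off + last)


def methylation_per_window(
    truth: SimTruth, grid: WindowGrid, config: SimConfig
) -> Dict[str, np.ndarray]:
    """Per-tissue methylation level per window (background outside truth)."""
    tissues = sorted(config.tissue_methylation)
    m = {t: np.full(grid.n_windows, config.background_methylation) for t in tissues}
    for rec in truth.records:
        sl = _window_range(grid, rec.chrom, rec.start, rec.end)
        for tissue, level in rec.methylation:
            m[tissue][sl] = level
    return m


def _negbin(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=np.float64)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    p = size_param / (size_param + mean[pos])
    out[pos] = rng.negative_binomial(size_param, p)
    return out


def simulate_counts(
    truth: SimTruth,
    annotation: AnnotationSet,
    samples: Sequence[SampleMeta],
    config: SimConfig,
    grid: WindowGrid | None = None,
) -> CountMatrix:
    """Draw the discovery window-count matrix under the enrichment model."""
    rng = config.rng("counts")
    if grid is None:
        grid = make_windows(config.chrom_sizes, config.bin_size)
    samples = list(samples)
    for s in samples:
        if s.tissue not in config.tissue_methylation:
            raise SimConfigError(f"no methylation level configured for tissue {s.tissue!r}")

    c = cpg_counts_per_window(annotation, grid)
    m = methylation_per_window(truth, grid, config)

    lo, hi = config.library_size_range
    ref = (lo + hi) / 2.0
    libs = np.array(
        [s.library_size if s.library_size > 0 else int(rng.integers(lo, hi + 1)) for s in samples],
        dtype=np.float64,
    )

    # per-(cnv, sample) copy ratios
    cnv_mult = np.ones((grid.n_windows, len(samples)), dtype=np.float64)
    for chrom in sorted(annotation.cnvs):
        for s, e in annotation.cnvs[chrom]:
            affected = rng.random(len(samples)) < config.cnv_affect_prob
            ratios = rng.choice(config.cnv_copy_ratios, size=len(samples))
            mult = np.where(affected, ratios, 1.0)
            cnv_mult[_window_range(grid, chrom, s, e), :] *= mult[None, :]

    # Sequencing yield is fixed by the library, not by the genome: enrichment
    # and copy-number changes redistribute a sample's reads rather than adding
    # reads, so per-sample intensities are rescaled to a common reference sum
    # (the background-methylation genome). With alpha = 0 and no CNVs the
    # rescaling factor is exactly 1, preserving the null embedding.
    ref_intensity = (1.0 + config.effect_scale * config.background_methylation * c).sum()
    raw = np.zeros((grid.n_windows, len(samples)), dtype=np.int64)
    for j, meta in enumerate(samples):
        intensity = (
            1.0 + config.effect_scale * m[meta.tissue] * c
        ) * cnv_mult[:, j]
        lam = (
            (libs[j] / ref)
            * config.baseline_depth
            * intensity
            * (ref_intensity / intensity.sum())
        )
        raw[:, j] = _negbin(rng, lam, config.dispersion)

    out_samples = [
        dataclasses.replace(meta, library_size=int(raw[:, j].sum()))
        for j, meta in enumerate(samples)
    ]
    return CountMatrix(grid=grid, samples=out_samples, raw=raw)


# ---------------------------------------------------------------------------
# Panel simulation
# ---------------------------------------------------------------------------

def simulate_panel(
    selected: Sequence[Dmr],
    truth: SimTruth,
    samples: Sequence[SampleMeta],
    config: SimConfig,
    annotation: AnnotationSet | None = None,
):
    """Targeted-panel depths for the selected DMRs plus control regions.

    Each region d gets a capture efficiency ``g_d ~ LogNormal(0, sigma_d)``
    shared across samples; depths are negative binomial with mean
    ``L_s * panel_baseline * g_d * (1 + alpha * m_tissue(d) * c(d))``.
    Control regions are non-differential background intervals included so
    that total-equalizing normalization does not erase the planted contrast.
    """
    from .confirm import PanelDepthMatrix

    if len(selected) == 0:
        raise SimConfigError("simulate_panel requires a non-empty selected DMR list")
    rng = config.rng("panel")
    samples = list(samples)
    for s in samples:
        if s.tissue not in config.tissue_methylation:
            raise SimConfigError(f"no methylation level configured for tissue {s.tissue!r}")

    regions: List[Tuple[str, int, int, bool]] = [
        (d.chrom, d.start, d.end, False) for d in selected
    ]
    if config.n_panel_controls > 0:
        if annotation is None:
            raise SimConfigError("annotation is required to place panel control regions")
        occupied: Dict[str, List[Tuple[int, int]]] = {}
        for r in truth.records:
            occupied.setdefault(r.chrom, []).append((r.start, r.end))
        controls: Dict[str, List[Tuple[int, int]]] = {}
        for _ in range(config.n_panel_controls):
            chrom, s, e = _place_uniform(
                rng, config.chrom_sizes,
                (config.control_length, config.control_length),
                controls, gap=0, avoid=occupied, avoid_gap=300,
            )
            regions.append((chrom, s, e, True))

    tissues = sorted(config.tissue_methylation)
    n_rows = len(regions)
    cpg = np.zeros(n_rows)
    m = {t: np.full(n_rows, config.background_methylation) for t in tissues}
    truth_by_chrom: Dict[str, List[TruthRecord]] = {}
    for r in truth.records:
        truth_by_chrom.setdefault(r.chrom, []).append(r)
    for i, (chrom, s, e, is_ctrl) in enumerate(regions):
        if annotation is not None:
            cpg[i] = annotation.cpg_count(chrom, s, e)
        else:
            cpg[i] = config.cgi_cpg_rate * (e - s)
        if is_ctrl:
            continue
        best, best_ov = None, 0
        for rec in truth_by_chrom.get(chrom, ()):
            ov = min(e, rec.end) - max(s, rec.start)
            if ov > best_ov:
                best, best_ov = rec, ov
        if best is not None:
            for tissue, level in best.methylation:
                m[tissue][i] = level

    g = rng.lognormal(mean=0.0, sigma=config.capture_sigma, size=n_rows)
    lo, hi = config.library_size_range
    ref = (lo + hi) / 2.0
    libs = np.array(
        [s.library_size if s.library_size > 0 else int(rng.integers(lo, hi + 1)) for s in samples],
        dtype=np.float64,
    )
    depth = np.zeros((n_rows, len(samples)), dtype=np.float64)
    for j, meta in enumerate(samples):
        lam = (
            (libs[j] / ref) * config.panel_baseline * g
            * (1.0 + config.effect_scale * m[meta.tissue] * cpg)
        )
        depth[:, j] = _negbin(rng, lam, config.dispersion)

    ids = [
        f"control_{i}" if is_ctrl else f"{chrom}:{s}-{e}"
        for i, (chrom, s, e, is_ctrl) in enumerate(regions)
    ]
    return PanelDepthMatrix(
        dmr_ids=ids,
        samples=samples,
        depth=depth,
        is_control=np.array([r[3] for r in regions]),
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_annotation_beds(annotation: AnnotationSet, outdir) -> Dict[str, Path]:
    """One BED per track; CpG sites as width-2 intervals."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    for name in AnnotationSet.TRACK_NAMES:
        path = outdir / f"{name}.bed"
        write_bed(frame_from_track(annotation.track(name), prefix=name[:3]), path)
        paths[name] = path
    cpg_frames = []
    for chrom in sorted(annotation.chrom_sizes):
        pos = annotation.cpg_sites[chrom]
        cpg_frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": pos, "end": pos + 2,
                 "name": [f"cpg_{chrom}_{i}" for i in range(len(pos))]}
            )
        )
    path = outdir / "cpg_sites.bed"
    write_bed(pd.concat(cpg_frames, ignore_index=True), path)
    paths["cpg_sites"] = path
    return paths


def write_truth_tsv(truth: SimTruth, path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g",
                            lineterminator="\n")
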