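"""End-to-end pipeline orchestration, configuration and run manifests.

``run_pipeline`` executes the two-stage procedure in order — simulate (or
load) window counts, test both pairwise comparisons (fetal tissue vs whole
blood; fetal tissue vs plasma), merge and filter candidate DMRs, intersect
the comparisons, annotate and summarize, then simulate and analyze the
confirmation panel — writing every artifact plus a manifest with per-file
checksums. Identical config + seed reproduces identical checksums.
"""
from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

from . import confirm as cf
from . import difftest as dt
from . import dmr as dm
from . import simulate as sim
from .intervals import read_bed, track_from_frame
from .windows import rpm_normalize, write_counts_tsv

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Pipeline thresholds (defaults are the study's stated values) + paths."""

    bin_size: int = 100
    p_threshold: float = 0.10
    min_cpg: int = 3
    min_repeat_distance: int = 200
    max_gap: int = 0
    min_total: int = 10
    var_floor: float = 1e-8
    intersection_mode: str = "intersection"
    selection_k: Optional[int] = None
    log1p: bool = False
    seed: int = 0
    simulation: sim.SimConfig = field(default_factory=sim.SimConfig)

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ConfigError("bin_size must be >= 1")
        for name in ("p_threshold", "min_repeat_distance", "var_floor"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 < self.p_threshold <= 1:
            raise ConfigError("p_threshold must lie in (0, 1]")
        if self.min_cpg < 0 or self.min_total < 0 or self.max_gap < 0:
            raise ConfigError("min_cpg, min_total and max_gap must be >= 0")
        if self.intersection_mode not in ("intersection", "union"):
            raise ConfigError("intersection_mode must be 'intersection' or 'union'")
        if self.selection_k is not None and self.selection_k < 1:
            raise ConfigError("selection_k must be >= 1 or null")
        # one global seed drives the simulation substreams
        self.simulation = dataclasses.replace(
            self.simulation, seed=self.seed, bin_size=self.bin_size
        )

    def to_dict(self) -> Dict:
        out = dataclasses.asdict(self)
        return out


def validate_config(raw: Dict | None) -> PipelineConfig:
    """Build a PipelineConfig from raw key-values, rejecting unknown keys."""
    raw = dict(raw or {})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        msgs = []
        for key in sorted(unknown):
            hint = difflib.get_close_matches(key, known, n=1)
            msgs.append(f"{key!r}" + (f" (did you mean {hint[0]!r}?)" if hint else ""))
        raise ConfigError("unknown config keys: " + ", ".join(msgs))
    if "simulation" in raw and not isinstance(raw["simulation"], sim.SimConfig):
        raw["simulation"] = sim.SimConfig.from_dict(raw["simulation"] or {})
    try:
        return PipelineConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> Dict:
    """Execute the full two-stage pipeline on the seeded simulation.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, Path] = {}
    counts_log: Dict[str, object] = {}
    scfg = config.simulation

    log.info("stage simulate: generating annotation and truth (seed %d)", config.seed)
    annotation = sim.generate_annotation(scfg)
    truth = sim.plant_truth(annotation, scfg)
    ann_paths = sim.write_annotation_beds(annotation, outdir / "annotation")
    artifacts.update({f"annotation/{k}": p for k, p in ann_paths.items()})
    sim.write_truth_tsv(truth, outdir / "truth.tsv")
    artifacts["truth"] = outdir / "truth.tsv"
    counts_log["planted_compliant"] = len(truth.compliant)
    counts_log["planted_decoys"] = {c: len(truth.by_class(c)) for c in sim.DECOY_CLASSES}

    log.info("stage counts: simulating discovery window counts")
    discovery = sim.default_samples("discovery")
    matrix = sim.simulate_counts(truth, annotation, discovery, scfg)
    matrix = rpm_normalize(matrix)
    write_counts_tsv(matrix, outdir / "counts.tsv")
    artifacts["counts"] = outdir / "counts.tsv"
    counts_log["windows"] = matrix.grid.n_windows

    comparisons = {"vs_WBF": "WBF", "vs_PL": "PL"}
    selected_per_comp: Dict[str, List[dm.Dmr]] = {}
    audits: Dict[str, Dict] = {}
    for prov, other in comparisons.items():
        log.info("stage difftest: CVS vs %s", other)
        res = dt.test_windows(
            matrix, "CVS", other,
            min_total=config.min_total, var_floor=config.var_floor,
        )
        path = outdir / f"results_cvs_{prov.lower()}.tsv"
        dt.write_results_tsv(res, path)
        artifacts[f"results_{prov}"] = path
        sig = dt.select_significant(res, config.p_threshold)
        counts_log[f"windows_tested_{prov}"] = int(res["tested"].sum())
        counts_log[f"windows_significant_{prov}"] = len(sig)

        merged = dm.merge_windows(sig, max_gap=config.max_gap, provenance=prov)
        merged = dm.attach_cpg_counts(merged, annotation)
        counts_log[f"dmrs_merged_{prov}"] = len(merged)
        kept, audit = dm.apply_selection(
            merged, annotation,
            min_cpg=config.min_cpg,
            min_repeat_distance=config.min_repeat_distance,
            p_threshold=config.p_threshold,
        )
        audits[prov] = audit
        selected_per_comp[prov] = kept
        path = outdir / f"dmrs_{prov.lower()}.tsv"
        dm.write_dmrs_tsv(kept, path)
        artifacts[f"dmrs_{prov}"] = path

    log.info("stage intersect: common fetal-specific DMRs")
    common = dm.intersect_comparisons(
        selected_per_comp["vs_WBF"], selected_per_comp["vs_PL"],
        mode=config.intersection_mode,
    )
    common = dm.attach_cpg_counts(common, annotation)
    common = dm.annotate_dmrs(common, annotation)
    counts_log["dmrs_common"] = len(common)
    if config.selection_k is not None:
        common = dm.select_top_regulatory(common, config.selection_k)
        counts_log["dmrs_top_regulatory"] = len(common)

    dm.write_dmrs_tsv(common, outdir / "common_dmrs.tsv")
    dm.write_dmrs_bed(common, outdir / "common_dmrs.bed")
    artifacts["common_dmrs_tsv"] = outdir / "common_dmrs.tsv"
    artifacts["common_dmrs_bed"] = outdir / "common_dmrs.bed"
    summary = dm.summarize_dmrs(common)
    with open(outdir / "dmr_summary.json", "w") as fh:
        json.dump({"summary": summary, "audit": audits}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    artifacts["dmr_summary"] = outdir / "dmr_summary.json"

    panel_ran = False
    if common:
        log.info("stage confirm: targeted panel on %d DMRs", len(common))
        confirmation = sim.default_samples("confirmation")
        panel = sim.simulate_panel(common, truth, confirmation, scfg, annotation=annotation)
        cf.write_panel_tsv(panel, outdir / "panel_depths.tsv")
        artifacts["panel_depths"] = outdir / "panel_depths.tsv"
        report = cf.confirm_panel(panel, log1p=config.log1p)
        cf.write_report_json(report, outdir / "confirmation.json")
        artifacts["confirmation"] = outdir / "confirmation.json"
        normed = cf.vertical_normalize(panel)
        cf.tissue_quartiles(normed).to_csv(
            outdir / "tissue_quartiles.tsv", sep="\t", index=False,
            float_format="%.10g", lineterminator="\n",
        )
        artifacts["tissue_quartiles"] = outdir / "tissue_quartiles.tsv"
        panel_ran = True
    else:
        log.info("stage confirm: skipped (no common DMRs selected)")

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "stage_counts": counts_log,
        "panel_ran": panel_ran,
        "artifacts": {
            name: {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
            for name, p in sorted(artifacts.items())
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("pipeline complete: %s", counts_log)
    return manifest


def load_annotation_dir(path, chrom_sizes: Dict[str, int]):
    """Reconstruct an AnnotationSet from a directory of BED tracks."""
    from .intervals import AnnotationSet
    import numpy as np

    path = Path(path)
    tracks = {}
    for name in AnnotationSet.TRACK_NAMES:
        bed = path / f"{name}.bed"
        tracks[name] = track_from_frame(read_bed(bed)) if bed.exists() else {}
    cpg_sites = {}
    cpg_bed = path / "cpg_sites.bed"
    if cpg_bed.exists():
        frame = read_bed(cpg_bed)
        for chrom, grp in frame.groupby("chrom"):
            cpg_sites[str(chrom)] = np.sort(grp["start"].to_numpy(np.int64))
    return AnnotationSet(chrom_sizes=dict(chrom_sizes), cpg_sites=cpg_sites, **tracks)
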