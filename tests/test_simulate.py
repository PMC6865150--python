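"""The seeded generator: determinism, planted truth, count and panel models."""
import dataclasses

import numpy as np
import pytest

from medipdmr import SimConfig, default_samples, generate_annotation, plant_truth
from medipdmr import simulate_counts, simulate_panel
from medipdmr.dmr import Dmr
from medipdmr.intervals import IntervalTrack
from medipdmr.simulate import (
    DECOY_CLASSES,
    DECOY_LOW_CPG,
    DECOY_NEAR_REPEAT,
    PlacementError,
    cpg_counts_per_window,
    methylation_per_window,
    write_annotation_beds,
    write_truth_tsv,
)
from medipdmr.windows import make_windows


class TestGenerateAnnotation:
    def test_empty_request_identity(self):
        cfg = SimConfig(seed=1, chrom_sizes={"chr1": 200_000}, n_repeats=0, n_cnvs=0,
                        n_genes=5, n_cgis=10, n_true_dmrs=0, n_decoys_per_class=0)
        ann = generate_annotation(cfg)
        assert len(ann.repeats["chr1"]) == 0 and len(ann.cnvs["chr1"]) == 0

    def test_determinism_byte_identical_beds(self, tmp_path, small_sim_config):
        for d in ("a", "b"):
            write_annotation_beds(generate_annotation(small_sim_config), tmp_path / d)
        for bed in sorted((tmp_path / "a").iterdir()):
            assert bed.read_bytes() == (tmp_path / "b" / bed.name).read_bytes()

    def test_cgi_cpg_rate_binomial_mean(self):
        """Mean CpG count in a 1000-bp CGI across seeds matches Binomial(1000, 0.1)."""
        counts = []
        for seed in range(10):
            cfg = SimConfig(seed=seed, chrom_sizes={"chr1": 100_000}, n_cgis=1,
                            cgi_length_range=(1000, 1000), cgi_cpg_rate=0.1,
                            n_repeats=0, n_cnvs=0, n_genes=0,
                            n_true_dmrs=0, n_decoys_per_class=0)
            ann = generate_annotation(cfg)
            (s, e), = list(ann.cgis["chr1"])
            counts.append(ann.cpg_count("chr1", s, e))
        se_mean = np.sqrt(1000 * 0.1 * 0.9 / len(counts))
        assert abs(np.mean(counts) - 100) < 3 * se_mean

    def test_background_rate(self):
        cfg = SimConfig(seed=3, chrom_sizes={"chr1": 400_000}, n_cgis=0, n_repeats=0,
                        n_cnvs=0, n_genes=0, n_true_dmrs=0, n_decoys_per_class=0)
        ann = generate_annotation(cfg)
        n = len(ann.cpg_sites["chr1"])
        # Binomial(400000, 0.01): mean 4000, sd ~63
        assert abs(n - 4000) < 5 * 63

    def test_chromosome_too_small_raises(self):
        cfg = SimConfig(seed=1, chrom_sizes={"chr1": 3000}, n_cgis=30,
                        n_true_dmrs=0, n_decoys_per_class=0)
        with pytest.raises(PlacementError):
            generate_annotation(cfg)


class TestPlantTruth:
    def test_empty_truth_table(self):
        cfg = SimConfig(seed=2, chrom_sizes={"chr1": 300_000}, n_cgis=20, n_repeats=10,
                        n_cnvs=2, n_genes=5, n_true_dmrs=0, n_decoys_per_class=0)
        truth = plant_truth(generate_annotation(cfg), cfg)
        assert truth.records == []

    def test_compliant_records_verified_by_exhaustive_scan(self, small_sim_config):
        ann = generate_annotation(small_sim_config)
        truth = plant_truth(ann, small_sim_config)
        for rec in truth.compliant:
            reps = list(ann.repeats[rec.chrom])
            dist = min(
                (rec.start - e if e <= rec.start else s - rec.end if s >= rec.end else 0)
                for s, e in reps
            ) if reps else float("inf")
            assert dist >= 200
            n_cpg = sum(1 for p in ann.cpg_sites[rec.chrom] if rec.start <= p < rec.end)
            assert n_cpg >= 3
            assert not any(
                min(rec.end, e) > max(rec.start, s) for s, e in ann.cnvs[rec.chrom]
            )

    def test_decoy_bookkeeping(self, small_sim_config):
        truth = plant_truth(generate_annotation(small_sim_config), small_sim_config)
        for cls in DECOY_CLASSES:
            assert len(truth.by_class(cls)) == small_sim_config.n_decoys_per_class
        assert len(truth.compliant) == small_sim_config.n_true_dmrs
        assert len(truth.records) == (
            small_sim_config.n_true_dmrs + 4 * small_sim_config.n_decoys_per_class
        )

    def test_decoy_geometry_invariants(self, small_sim_config):
        ann = generate_annotation(small_sim_config)
        truth = plant_truth(ann, small_sim_config)
        for rec in truth.by_class(DECOY_NEAR_REPEAT):
            d = ann.repeats[rec.chrom].distance(rec.start, rec.end)
            assert 0 < d < 200
        for rec in truth.by_class(DECOY_LOW_CPG):
            assert ann.cpg_count(rec.chrom, rec.start, rec.end) <= 2

    def test_lengths_within_stated_range(self, small_sim_config):
        truth = plant_truth(generate_annotation(small_sim_config), small_sim_config)
        for rec in truth.records:
            assert 100 <= rec.length <= 2300

    def test_truth_tsv_deterministic(self, tmp_path, small_sim_config):
        ann = generate_annotation(small_sim_config)
        for name in ("a.tsv", "b.tsv"):
            write_truth_tsv(plant_truth(ann, small_sim_config), tmp_path / name)
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()


class TestSimulateCounts:
    def test_null_effect_identity(self, small_sim_config):
        """alpha = 0: all tissues share identical expected counts per window."""
        cfg = dataclasses.replace(small_sim_config, effect_scale=0.0, n_cnvs=0,
                                  n_decoys_per_class=0, dispersion=1e9)
        ann = generate_annotation(cfg)
        truth = plant_truth(ann, cfg)
        samples = default_samples("discovery")
        mat = simulate_counts(truth, ann, samples, cfg)
        rpm = mat.raw / mat.raw.sum(axis=0, keepdims=True)
        cvs = rpm[:, mat.columns_for("CVS")].mean(axis=1)
        wbf = rpm[:, mat.columns_for("WBF")].mean(axis=1)
        # planted windows show no group difference beyond sampling noise
        assert abs(cvs - wbf).max() * mat.grid.n_windows < 0.5

    def test_zero_cpg_limit(self):
        """c(w) = 0 everywhere: expectation independent of methylation."""
        cfg = SimConfig(seed=5, chrom_sizes={"chr1": 100_000}, cpg_background_rate=0.0,
                        cgi_cpg_rate=0.0, n_cgis=5, n_repeats=0, n_cnvs=0, n_genes=0,
                        n_true_dmrs=0, n_decoys_per_class=0, dispersion=1e9,
                        baseline_depth=5000.0)
        ann = generate_annotation(cfg)
        truth = plant_truth(ann, cfg)
        mat = simulate_counts(truth, ann, default_samples("discovery"), cfg)
        share = mat.raw / mat.raw.sum(axis=0, keepdims=True)
        cvs = share[:, mat.columns_for("CVS")].mean(axis=1)
        wbf = share[:, mat.columns_for("WBF")].mean(axis=1)
        # without CpGs there is nothing to enrich: groups agree per window
        assert np.abs(cvs - wbf).max() * mat.grid.n_windows < 0.2

    def test_planted_windows_enriched_in_fetal_tissue(self, small_sim_config):
        """CVS mean exceeds WBF mean in >= 95% of planted regions."""
        cfg = small_sim_config
        ann = generate_annotation(cfg)
        truth = plant_truth(ann, cfg)
        mat = simulate_counts(truth, ann, default_samples("discovery"), cfg)
        grid = mat.grid
        wins = 0
        for rec in truth.compliant:
            sl = slice(grid.locate(rec.chrom, rec.start),
                       grid.locate(rec.chrom, rec.end - 1) + 1)
            cvs = mat.raw[sl][:, mat.columns_for("CVS")].mean()
            wbf = mat.raw[sl][:, mat.columns_for("WBF")].mean()
            wins += cvs > wbf
        assert wins >= 0.95 * len(truth.compliant)

    def test_counts_non_negative_integers_and_deterministic(self, small_sim_config):
        ann = generate_annotation(small_sim_config)
        truth = plant_truth(ann, small_sim_config)
        m1 = simulate_counts(truth, ann, default_samples("discovery"), small_sim_config)
        m2 = simulate_counts(truth, ann, default_samples("discovery"), small_sim_config)
        assert m1.raw.dtype == np.int64 and (m1.raw >= 0).all()
        np.testing.assert_array_equal(m1.raw, m2.raw)

    def test_cnv_windows_scaled(self):
        """A guaranteed-affected CNV multiplies depth by the copy ratio."""
        cfg = SimConfig(seed=8, chrom_sizes={"chr1": 200_000}, n_cgis=10, n_repeats=0,
                        n_cnvs=2, n_genes=0, n_true_dmrs=0, n_decoys_per_class=0,
                        cnv_affect_prob=1.0, cnv_copy_ratios=(2.0,), dispersion=1e9,
                        effect_scale=0.0)
        ann = generate_annotation(cfg)
        truth = plant_truth(ann, cfg)
        mat = simulate_counts(truth, ann, default_samples("discovery"), cfg)
        grid = mat.grid
        in_cnv = np.zeros(grid.n_windows, dtype=bool)
        for s, e in ann.cnvs["chr1"]:
            in_cnv[grid.locate("chr1", s): grid.locate("chr1", e - 1) + 1] = True
        ratio = mat.raw[in_cnv].mean() / mat.raw[~in_cnv].mean()
        assert ratio == pytest.approx(2.0, rel=0.05)


class TestSimulatePanel:
    def _setup(self, **over):
        cfg = SimConfig(seed=9, chrom_sizes={"chr1": 500_000}, n_cgis=40, n_repeats=20,
                        n_cnvs=2, n_genes=5, n_true_dmrs=5, n_decoys_per_class=0,
                        n_panel_controls=10, **over)
        ann = generate_annotation(cfg)
        truth = plant_truth(ann, cfg)
        selected = [
            Dmr(chrom=r.chrom, start=r.start, end=r.end, direction=r.direction,
                n_windows=1, min_p_adj=0.01, mean_log2_ratio=1.0)
            for r in truth.compliant
        ]
        return cfg, ann, truth, selected

    def test_sigma_zero_unit_capture_efficiency(self):
        cfg, ann, truth, selected = self._setup(capture_sigma=0.0, effect_scale=0.0,
                                                dispersion=1e9)
        samples = [dataclasses.replace(s, library_size=10**9)
                   for s in default_samples("confirmation")]
        panel = simulate_panel(selected, truth, samples, cfg, annotation=ann)
        # sigma_d = 0 and alpha = 0 and equal L_s: rows are flat at the baseline
        # up to counting (Poisson-level) noise
        cv = panel.depth.std() / panel.depth.mean()
        assert cv < 2.5 / np.sqrt(panel.depth.mean())

    def test_alpha_zero_equal_tissue_expectations(self):
        cfg, ann, truth, selected = self._setup(effect_scale=0.0, dispersion=1e9)
        samples = [dataclasses.replace(s, library_size=10**9)
                   for s in default_samples("confirmation")]
        panel = simulate_panel(selected, truth, samples, cfg, annotation=ann)
        means = {t: panel.depth[:, panel.columns_for(t)].mean() for t in panel.tissues}
        vals = np.array(list(means.values()))
        assert vals.std() / vals.mean() < 0.02

    def test_capture_sigma_drives_row_mean_variance(self):
        spreads = {}
        for sigma in (0.1, 1.0):
            log_means = []
            for seed in range(20):
                cfg, ann, truth, selected = self._setup(capture_sigma=sigma)
                cfg = dataclasses.replace(cfg, seed=seed)
                panel = simulate_panel(selected, truth,
                                       default_samples("confirmation"), cfg, annotation=ann)
                log_means.extend(np.log(panel.dmr_rows().mean(axis=1)))
            spreads[sigma] = np.var(log_means)
        assert spreads[1.0] > spreads[0.1]

    def test_empty_selection_rejected(self):
        cfg, ann, truth, _ = self._setup()
        from medipdmr.simulate import SimConfigError

        with pytest.raises(SimConfigError):
            simulate_panel([], truth, default_samples("confirmation"), cfg, annotation=ann)

    def test_deterministic(self):
        cfg, ann, truth, selected = self._setup()
        samples = default_samples("confirmation")
        p1 = simulate_panel(selected, truth, samples, cfg, annotation=ann)
        p2 = simulate_panel(selected, truth, samples, cfg, annotation=ann)
        np.testing.assert_array_equal(p1.depth, p2.depth)
        assert p1.dmr_ids == p2.dmr_ids


def test_methylation_map_null_embedding(small_sim_config):
    """Outside planted regions every tissue sits at the common background."""
    cfg = small_sim_config
    ann = generate_annotation(cfg)
    truth = plant_truth(ann, cfg)
    grid = make_windows(cfg.chrom_sizes, cfg.bin_size)
    m = methylation_per_window(truth, grid, cfg)
    planted = np.zeros(grid.n_windows, dtype=bool)
    for rec in truth.records:
        planted[grid.locate(rec.chrom, rec.start): grid.locate(rec.chrom, rec.end - 1) + 1] = True
    for tissue, arr in m.items():
        assert (arr[~planted] == cfg.background_methylation).all()


def test_config_validation_errors():
    with pytest.raises(Exception, match="methylation"):
        SimConfig(tissue_methylation={"CVS": 1.5, "WBF": 0.0, "PL": 0.0})
    with pytest.raises(Exception, match="dispersion"):
        SimConfig(dispersion=0)
    with pytest.raises(Exception, match="library_size_range"):
        SimConfig(library_size_range=(0, 10))
    with pytest.raises(Exception, match="shorter than bin"):
        SimConfig(chrom_sizes={"chr1": 50})
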