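"""DMR merging, selection criteria, intersection, annotation, summaries."""
import numpy as np
import pandas as pd
import pytest

from medipdmr import (
    AnnotationSet,
    Dmr,
    IntervalTrack,
    annotate_dmrs,
    apply_selection,
    count_cpgs,
    intersect_comparisons,
    merge_windows,
    select_top_regulatory,
    summarize_dmrs,
)
from medipdmr.windows import ValidationError


def _sig_frame(rows):
    """rows: (chrom, start, end, direction, p_adj, log2_ratio)."""
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "direction", "p_adj", "log2_ratio"]
    )


def _dmr(start, end, direction="hyper_in_fetal", p=0.01, n_cpg=5, chrom="chr1"):
    return Dmr(chrom=chrom, start=start, end=end, direction=direction,
               n_windows=max(1, (end - start) // 100), min_p_adj=p,
               mean_log2_ratio=1.0, n_cpg=n_cpg)


class TestMergeWindows:
    def test_adjacent_runs_merge_gap_breaks(self):
        sig = _sig_frame([
            ("chr1", 0, 100, "hyper_in_A", 0.01, 2.0),
            ("chr1", 100, 200, "hyper_in_A", 0.02, 1.5),
            ("chr1", 300, 400, "hyper_in_A", 0.03, 1.0),
        ])
        dmrs = merge_windows(sig, max_gap=0)
        assert [(d.start, d.end, d.n_windows) for d in dmrs] == [(0, 200, 2), (300, 400, 1)]
        assert dmrs[0].min_p_adj == pytest.approx(0.01)

    def test_opposite_directions_split(self):
        sig = _sig_frame([
            ("chr1", 0, 100, "hyper_in_A", 0.01, 2.0),
            ("chr1", 100, 200, "hypo_in_A", 0.02, -1.5),
        ])
        dmrs = merge_windows(sig, same_direction=True)
        assert len(dmrs) == 2
        assert {d.direction for d in dmrs} == {"hyper_in_fetal", "hypo_in_fetal"}

    def test_empty_input(self):
        assert merge_windows(_sig_frame([])) == []

    def test_unsorted_input_rejected(self):
        sig = _sig_frame([
            ("chr1", 300, 400, "hyper_in_A", 0.01, 2.0),
            ("chr1", 0, 100, "hyper_in_A", 0.01, 2.0),
        ])
        with pytest.raises(ValidationError):
            merge_windows(sig)

    def test_merging_is_a_partition(self):
        rng = np.random.default_rng(31)
        starts = np.sort(rng.choice(np.arange(0, 5000, 100), size=25, replace=False))
        sig = _sig_frame([("chr1", int(s), int(s) + 100, "hyper_in_A", 0.01, 1.0) for s in starts])
        dmrs = merge_windows(sig, max_gap=0)
        assert sum(d.n_windows for d in dmrs) == len(sig)
        total = sum(d.end - d.start for d in dmrs)
        assert total == 100 * len(sig)  # member windows tile each DMR exactly

    def test_gap_tolerance(self):
        sig = _sig_frame([
            ("chr1", 0, 100, "hyper_in_A", 0.01, 2.0),
            ("chr1", 200, 300, "hyper_in_A", 0.02, 1.5),
        ])
        assert len(merge_windows(sig, max_gap=0)) == 2
        assert len(merge_windows(sig, max_gap=100)) == 1


class TestCountCpgs:
    def test_half_open_counting(self, tiny_annotation):
        # CpGs at 10, 50, 150 inside [0, 200); 250 excluded by the half-open end
        assert count_cpgs(_dmr(0, 200), tiny_annotation) == 3

    def test_no_cpgs_on_chromosome(self, tiny_annotation):
        assert count_cpgs(_dmr(0, 200, chrom="chr9"), tiny_annotation) == 0

    def test_boundary_conventions(self, tiny_annotation):
        assert count_cpgs(_dmr(10, 50), tiny_annotation) == 1   # at start counted
        assert count_cpgs(_dmr(0, 10), tiny_annotation) == 0    # at end not counted


class TestApplySelection:
    def test_constructed_fixture_audit(self):
        ann = AnnotationSet(
            chrom_sizes={"chr1": 100_000},
            cpg_sites={"chr1": np.arange(0, 100_000, 97)},
            repeats={"chr1": IntervalTrack([(10_000, 10_500)])},
            cnvs={"chr1": IntervalTrack([(50_000, 60_000)])},
        )
        dmrs = [
            _dmr(55_000, 55_400),            # inside the CNV
            _dmr(10_550, 10_800),            # 50 bp from the repeat
            _dmr(30_000, 30_300, n_cpg=2),   # too few CpGs
            _dmr(70_000, 70_500),            # clean
            _dmr(80_000, 80_200),            # clean
        ]
        selected, audit = apply_selection(dmrs, ann)
        assert [d.start for d in selected] == [70_000, 80_000]
        assert audit["in_cnv"] == 1 and audit["near_repeat"] == 1 and audit["low_cpg"] == 1
        assert audit["selected"] == 2 and audit["rejected"] == 3

    def test_empty_tracks_identity(self, ):
        ann = AnnotationSet(chrom_sizes={"chr1": 100_000})
        dmrs = [_dmr(0, 300), _dmr(1000, 1300)]
        selected, audit = apply_selection(dmrs, ann)
        assert len(selected) == 2 and audit["rejected"] == 0

    def test_exact_200bp_distance_passes(self):
        ann = AnnotationSet(
            chrom_sizes={"chr1": 100_000},
            repeats={"chr1": IntervalTrack([(10_000, 10_500)])},
        )
        assert len(apply_selection([_dmr(10_700, 11_000)], ann)[0]) == 1   # d = 200
        assert len(apply_selection([_dmr(10_699, 11_000)], ann)[0]) == 0   # d = 199

    def test_flags_are_cumulative(self):
        ann = AnnotationSet(
            chrom_sizes={"chr1": 100_000},
            repeats={"chr1": IntervalTrack([(10_000, 10_500)])},
            cnvs={"chr1": IntervalTrack([(10_400, 11_000)])},
        )
        dmrs = [_dmr(10_550, 10_800, n_cpg=1)]  # near repeat AND in CNV AND low CpG
        selected, audit = apply_selection(dmrs, ann)
        assert selected == []
        assert audit["in_cnv"] == audit["near_repeat"] == audit["low_cpg"] == 1

    def test_selected_and_rejected_partition_input(self):
        rng = np.random.default_rng(32)
        ann = AnnotationSet(
            chrom_sizes={"chr1": 200_000},
            cnvs={"chr1": IntervalTrack([(100_000, 120_000)])},
        )
        dmrs = [_dmr(int(s), int(s) + 200, n_cpg=int(rng.integers(0, 8)))
                for s in rng.choice(np.arange(0, 199_000, 500), 40, replace=False)]
        selected, audit = apply_selection(dmrs, ann)
        assert audit["selected"] + audit["rejected"] == len(dmrs)


class TestIntersectComparisons:
    def test_interval_intersection(self):
        out = intersect_comparisons([_dmr(100, 300)], [_dmr(200, 400)])
        assert [(d.start, d.end) for d in out] == [(200, 300)]
        assert out[0].provenance == frozenset({"vs_WBF", "vs_PL"})

    def test_direction_mismatch_drops(self):
        out = intersect_comparisons([_dmr(100, 300)], [_dmr(200, 400, "hypo_in_fetal")])
        assert out == []

    def test_disjoint_intervals_drop(self):
        assert intersect_comparisons([_dmr(100, 300)], [_dmr(400, 500)]) == []

    def test_union_mode(self):
        out = intersect_comparisons([_dmr(100, 300)], [_dmr(200, 400)], mode="union")
        assert [(d.start, d.end) for d in out] == [(100, 400)]

    def test_symmetric_up_to_ordering(self):
        rng = np.random.default_rng(33)
        a = [_dmr(int(s), int(s + rng.integers(100, 400))) for s in rng.integers(0, 5000, 10)]
        b = [_dmr(int(s), int(s + rng.integers(100, 400))) for s in rng.integers(0, 5000, 10)]
        ab = {(d.chrom, d.start, d.end) for d in intersect_comparisons(a, b)}
        ba = {(d.chrom, d.start, d.end) for d in intersect_comparisons(b, a)}
        assert ab == ba

    def test_joint_significance_is_conservative(self):
        out = intersect_comparisons([_dmr(0, 300, p=0.001)], [_dmr(100, 400, p=0.05)])
        assert out[0].min_p_adj == pytest.approx(0.05)


class TestAnnotateDmrs:
    def test_exon_implies_gene_body_when_nested(self, tiny_annotation):
        out = annotate_dmrs([_dmr(1050, 1150)], tiny_annotation)
        assert out[0].labels >= {"exon", "gene_body"}

    def test_intergenic_dmr_unlabelled(self, tiny_annotation):
        out = annotate_dmrs([_dmr(4000, 4300)], tiny_annotation)
        assert out[0].labels == frozenset()

    def test_label_table_matches_brute_force(self, tiny_annotation):
        rng = np.random.default_rng(34)
        tracks = {
            "gene_body": [(1000, 2000)], "exon": [(1000, 1200), (1800, 2000)],
            "promoter": [(800, 1000)], "cgi": [(950, 1100)],
        }
        dmrs = [_dmr(int(s), int(s) + 150) for s in rng.integers(0, 9800, 10)]
        out = annotate_dmrs(dmrs, tiny_annotation)
        for d_in, d_out in zip(dmrs, out):
            expected = {
                lab for lab, ivs in tracks.items()
                if any(min(d_in.end, e) > max(d_in.start, s) for s, e in ivs)
            }
            assert d_out.labels == frozenset(expected)


class TestSummarize:
    def test_median_of_three(self):
        s = summarize_dmrs([_dmr(0, 100), _dmr(200, 300), _dmr(400, 600)])
        assert s["length_median"] == 100

    def test_quantile_convention(self):
        dmrs = [_dmr(0, 100), _dmr(200, 350), _dmr(400, 600), _dmr(700, 950)]
        s = summarize_dmrs(dmrs)   # lengths 100, 150, 200, 250
        assert s["length_median"] == 175
        assert s["length_iqr"] == pytest.approx(
            np.percentile([100, 150, 200, 250], 75) - np.percentile([100, 150, 200, 250], 25)
        )

    def test_single_dmr_iqr_zero(self):
        s = summarize_dmrs([_dmr(0, 149)])
        assert s["length_iqr"] == 0 and s["length_min"] == s["length_max"] == 149

    def test_empty_summary(self):
        assert summarize_dmrs([]) == {"n": 0}

    def test_multilabel_counts_can_exceed_n(self, tiny_annotation):
        out = annotate_dmrs([_dmr(1050, 1150), _dmr(960, 1060)], tiny_annotation)
        s = summarize_dmrs(out)
        assert sum(s["by_label"].values()) > s["n"]


def test_select_top_regulatory_ranking():
    import dataclasses

    d1 = dataclasses.replace(_dmr(0, 100, p=0.05), labels=frozenset({"cgi"}))
    d2 = dataclasses.replace(_dmr(200, 300, p=0.001), labels=frozenset({"exon"}))
    d3 = _dmr(400, 500, p=0.0001)  # no regulatory label: excluded
    out = select_top_regulatory([d1, d2, d3], k=1)
    assert [d.start for d in out] == [200]
    assert [d.start for d in select_top_regulatory([d1, d2, d3], k=None)] == [200, 0]
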