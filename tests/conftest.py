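"""Shared fixtures: small synthetic configurations and hand-built annotation."""
import numpy as np
import pytest

from medipdmr import AnnotationSet, IntervalTrack, SimConfig


@pytest.fixture
def tiny_annotation():
    """Hand-built annotation on one 10-kb chromosome with known geometry."""
    return AnnotationSet(
        chrom_sizes={"chr1": 10_000},
        cpg_sites={"chr1": np.array([10, 50, 150, 250, 1005, 1010, 1020, 5000])},
        repeats={"chr1": IntervalTrack([(3000, 3500)])},
        cnvs={"chr1": IntervalTrack([(6000, 7000)])},
        gene_bodies={"chr1": IntervalTrack([(1000, 2000)])},
        exons={"chr1": IntervalTrack([(1000, 1200), (1800, 2000)])},
        promoters={"chr1": IntervalTrack([(800, 1000)])},
        cgis={"chr1": IntervalTrack([(950, 1100)])},
    )


@pytest.fixture
def small_sim_config():
    """Down-scaled generator settings for fast unit tests (500-kb genome)."""
    return SimConfig(
        seed=7,
        chrom_sizes={"chr1": 500_000},
        n_cgis=40,
        n_repeats=30,
        n_cnvs=4,
        n_genes=15,
        n_true_dmrs=6,
        n_decoys_per_class=2,
        n_panel_controls=20,
    )
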