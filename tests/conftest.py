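"""Shared fixtures: a small synthetic study and its pipeline run."""

from __future__ import annotations

import numpy as np
import pytest

from mirnaome.pipeline import run_pipeline
from mirnaome.synthetic_data import (GeneratorConfig, StudyDesign, generate,
                                     simulate_libraries)

SMALL_SEED = 7


def small_config() -> GeneratorConfig:
    return GeneratorConfig(
        chrom_sizes={"chr1": 120_000, "chr21": 400_000},
        n_mirna=40, n_cluster=10, cluster_window=(50_000, 250_000),
        n_foreign_sub=6, n_foreign_near=3, n_foreign_ext=2,
        n_novel=2, n_decoy=4, n_ncrna=8, n_genes=6, n_repeats=8,
        n_utr_genes=30, n_gene_sets=4, n_de_pairs=5, n_edited=2)


@pytest.fixture(scope="session")
def small_design() -> StudyDesign:
    return StudyDesign(reads_per_library=5000)


@pytest.fixture(scope="session")
def small_study(small_design):
    """(bundle, truth, reads) for a fast 8-library synthetic study."""
    bundle, truth = generate(small_config(), small_design, seed=SMALL_SEED)
    reads = simulate_libraries(bundle, truth=truth, design=small_design,
                               seed=SMALL_SEED)
    return bundle, truth, reads


@pytest.fixture(scope="session")
def small_pipeline(small_study, small_design):
    """Full pipeline result on the small synthetic study."""
    bundle, truth, reads = small_study
    return run_pipeline(bundle, reads, small_design, novel_seed=SMALL_SEED,
                        n_shuffles=50)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def benchmark_run():
    """Default-condition benchmark: 8 libraries x 200k reads, ~300 miRNAs.

    One full generate + simulate + pipeline pass shared by the acceptance
    tests (the package's standard study conditions).
    """
    design = StudyDesign()
    bundle, truth = generate(GeneratorConfig(), design, seed=1)
    reads = simulate_libraries(bundle, design, truth, seed=1)
    result = run_pipeline(bundle, reads, design, novel_seed=1,
                          n_shuffles=100)
    return bundle, truth, result, design
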