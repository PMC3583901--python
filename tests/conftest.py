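import numpy as np
import pytest

from mirnome import pipeline as pl
from mirnome import synthetic_data as sd


def small_config(**overrides) -> sd.SimulationConfig:
    defaults = dict(
        genome_length=400_000, n_known_mirnas=10, n_novel_hairpins=6,
        n_trna_loci=10, n_rrna_loci=2, n_sn_sno_loci=5, n_repeat_regions=15,
        n_other_loci=10, libraries_per_group=2, reads_per_library=8000,
        n_disease_specific=(2, 3), seed=7)
    defaults.update(overrides)
    return sd.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    """Small planted genome shared across modules (no reads)."""
    cfg = small_config()
    genome, annotations, truth = sd.build_genome(cfg)
    return cfg, genome, annotations, truth


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One small end-to-end pipeline run shared by integration tests."""
    cfg = small_config()
    out = tmp_path_factory.mktemp("pipeline_small")
    pc = pl.PipelineConfig(output_dir=str(out), simulation=cfg, seed=7,
                           write_reads=False)
    return pl.run_pipeline(pc)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
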