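import pytest

from editomescan.pipeline import PipelineConfig, run_pipeline
from editomescan.synthetic_data import SimulationConfig, generate_dataset

#: Reduced-size dataset used by most integration-style tests.
SMALL_SIM = dict(
    n_chromosomes=2,
    chrom_length=40_000,
    n_transcripts=14,
    n_alu=16,
    n_germline_snps=25,
    n_editing_sites=80,
    n_background_positions=80,
)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("smalldata")
    files, truth = generate_dataset(SimulationConfig(seed=11, **SMALL_SIM), outdir)
    return files, truth


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("smallrun")
    config = PipelineConfig(
        seed=11, outdir=str(outdir), sim=SimulationConfig(seed=11, **SMALL_SIM)
    )
    return run_pipeline(config)
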