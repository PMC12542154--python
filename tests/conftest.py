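import pytest

from holosplit.synth import (
    HolobiontConfig,
    generate_chimera_testset,
    generate_holobiont,
)


@pytest.fixture(scope="session")
def holobiont():
    """Default synthetic holobiont (seed 42), shared across the suite."""
    return generate_holobiont(HolobiontConfig(seed=42))


@pytest.fixture(scope="session")
def chimera_testset():
    """50 clean contigs + 5 planted fungal-bacterial chimeras (seed 42)."""
    return generate_chimera_testset(seed=42)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full synthetic pipeline run (seed 42)."""
    from holosplit.pipeline import run_pipeline

    outdir = tmp_path_factory.mktemp("pipeline")
    report = run_pipeline(outdir, seed=42)
    return report, outdir
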