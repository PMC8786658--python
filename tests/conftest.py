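import pytest

from imaclone.pipeline import PipelineConfig, run_pipeline
from imaclone.signatures import load_default_catalog
from imaclone.simulate import simulate_cohort, study_default
from imaclone.variants import load_cohort


@pytest.fixture(scope="session")
def catalog():
    return load_default_catalog()


@pytest.fixture(scope="session")
def sim_cohort(tmp_path_factory):
    """Default study-scale synthetic cohort (7 patients, 24 regions)."""
    outdir = tmp_path_factory.mktemp("sim")
    manifest, truth = simulate_cohort(study_default(seed=11), outdir)
    return manifest, truth


@pytest.fixture(scope="session")
def sim_loaded(sim_cohort):
    manifest, truth = sim_cohort
    return load_cohort(manifest), truth


@pytest.fixture(scope="session")
def pipeline_run(sim_cohort, tmp_path_factory):
    manifest, truth = sim_cohort
    outdir = tmp_path_factory.mktemp("pipeline_out")
    config = PipelineConfig(manifest=str(manifest), outdir=str(outdir), seed=11)
    run_pipeline(config)
    return outdir, truth, config


from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")
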