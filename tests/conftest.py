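import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from photoforge import PipelineConfig, observer, run_pipeline, scenegen

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def exp1_set6():
    """Six scenes, each with all five manipulations: 6 originals + 30 pairs."""
    return scenegen.build_stimulus_set(6, design="exp1", rng=np.random.default_rng(42))


@pytest.fixture(scope="session")
def exp1_set10():
    """Ten scenes (6 manipulated): enough for 10-trial subject sessions."""
    return scenegen.build_stimulus_set(10, design="exp1", rng=np.random.default_rng(42))


@pytest.fixture(scope="session")
def exp1_tables(exp1_set10):
    return observer.prepare_stimulus_table(exp1_set10)


@pytest.fixture(scope="session")
def exp1_bundle(tmp_path_factory):
    cfg = PipelineConfig(
        design="exp1", n_subjects=120, seed=7, mc_draws=100_000, n_boot=100, make_plots=False
    )
    return run_pipeline(cfg, out_dir=tmp_path_factory.mktemp("exp1_out"))


@pytest.fixture(scope="session")
def exp2_bundle(tmp_path_factory):
    cfg = PipelineConfig(
        design="exp2", n_subjects=120, seed=11, mc_draws=100_000, n_boot=100, make_plots=False
    )
    return run_pipeline(cfg, out_dir=tmp_path_factory.mktemp("exp2_out"))
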