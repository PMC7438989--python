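import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

from vtaclust.features import extract_feature_frame
from vtaclust.synthetic import generate_population, ground_truth_frame, paper_presets


@pytest.fixture(scope="session")
def presets():
    return paper_presets()


@pytest.fixture(scope="session")
def paper_cohort(presets):
    """Full three-population cohort (291 neurons), fixed seed."""
    return generate_population(presets, seed=7)


@pytest.fixture(scope="session")
def cohort_features(paper_cohort):
    """(features frame, ground-truth frame) for the shared cohort."""
    feat = extract_feature_frame([n.session for n in paper_cohort])
    return feat, ground_truth_frame(paper_cohort)


@pytest.fixture(scope="session")
def pipeline_report(tmp_path_factory):
    """One full pipeline run on the generated cohort, fixed seed."""
    from vtaclust.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(seed=7, out_dir=str(out), log_level="WARNING")
    return run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
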