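import numpy as np
import pytest

from pulsebp.pipeline import PipelineConfig, run_pipeline
from pulsebp.synthetic import BPCoupling, SyntheticConfig


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_truth_dataset():
    """Feature/response table from ground truth (no optimizer), 20 x 30."""
    from pulsebp.synthetic import synthesize_dataset

    cfg = SyntheticConfig(n_subjects=20, beats_per_subject=30, seed=5)
    return synthesize_dataset(cfg)


@pytest.fixture(scope="session")
def offset_truth_dataset():
    """Truth dataset with 8 mmHg subject-level BP offsets (split studies)."""
    from pulsebp.synthetic import synthesize_dataset

    cfg = SyntheticConfig(
        n_subjects=20,
        beats_per_subject=40,
        seed=21,
        bp_coupling=BPCoupling(subject_offset_sd=8.0),
    )
    return synthesize_dataset(cfg)


@pytest.fixture(scope="session")
def small_results(small_truth_dataset):
    """A fitted BP model on the small truth dataset."""
    from pulsebp.estimation import BloodPressureModel

    return BloodPressureModel(small_truth_dataset, seed=0).fit()


@pytest.fixture(scope="session")
def e2e(tmp_path_factory):
    """Full end-to-end synthetic run at the study conditions.

    50 subjects x 100 beats at 125 Hz, noise sd 0.01, drift 0.05, BP
    coupled to skew and b/a with 2 mmHg response noise; strict
    subject-level split; Shapley attributions over the whole test set.
    """
    outdir = tmp_path_factory.mktemp("e2e")
    cfg = PipelineConfig(synthetic=SyntheticConfig(seed=11), seed=11)
    return run_pipeline(cfg, outdir)
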