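import numpy as np
import pytest

from metabnet.io_config import PipelineConfig
from metabnet.simulate import simulate_study


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    return PipelineConfig(
        n_subjects=80,
        followup_fraction=0.35,
        n_metabolites=10,
        n_ffq_items=12,
        n_factors=2,
        n_snps=8,
        n_modules_true=2,
        n_subsamples=10,
        n_lambda=10,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config, seed=42)


@pytest.fixture(scope="session")
def small_fits(small_study):
    from metabnet.decompose import fit_metabolome

    return fit_metabolome(small_study.dataset, small_study.bundle)


def edge_f1(A_est: np.ndarray, A_true: np.ndarray) -> float:
    tp = ((A_est == 1) & (A_true == 1)).sum() / 2
    fp = ((A_est == 1) & (A_true == 0)).sum() / 2
    fn = ((A_est == 0) & (A_true == 1)).sum() / 2
    return 2 * tp / (2 * tp + fp + fn)
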