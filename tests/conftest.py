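import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import proteorank as pr

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_dataset(
    n_proteins=6,
    groups=("AD", "AD", "Ctl", "Ctl"),
    dataset_id="toy",
    tissue="csf",
    seed=0,
    missing=(),
):
    """Small positive-intensity dataset for unit tests."""
    rng = np.random.default_rng(seed)
    samples = [f"s{i + 1}" for i in range(len(groups))]
    proteins = [f"P{i + 1:03d}" for i in range(n_proteins)]
    vals = rng.uniform(10.0, 1000.0, size=(n_proteins, len(samples)))
    for i, j in missing:
        vals[i, j] = np.nan
    mat = pd.DataFrame(vals, index=proteins, columns=samples)
    return pr.ProteomeDataset(
        dataset_id=dataset_id,
        tissue=tissue,
        species="human",
        cohort_role="discovery",
        intensities=mat,
        sample_groups=pd.Series(groups, index=samples),
    )


@pytest.fixture
def toy_dataset():
    return make_dataset()


@pytest.fixture(scope="session")
def small_study():
    """One small planted study shared by read-only tests."""
    cfg = pr.default_study_config(n_proteins=500, seed=7)
    datasets, truth = pr.generate_study(cfg)
    return cfg, datasets, truth
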