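import numpy as np
import pytest

from nutrihawk import CohortSpec, generate_child_cohort, generate_prevalence_table
from nutrihawk.pipeline import featurize_cohort
from nutrihawk.preprocess import apply_minmax, fit_minmax


@pytest.fixture(scope="session")
def cohort_small():
    """600-child uniform-mixture cohort, fixed seed."""
    return generate_child_cohort(CohortSpec(n_records=600, seed=101))


@pytest.fixture(scope="session")
def cohort_features(cohort_small):
    """Normalized numeric features + labels of the small cohort."""
    X, y = featurize_cohort(cohort_small)
    Xn = apply_minmax(X, fit_minmax(X)).to_numpy()
    return Xn, y


@pytest.fixture(scope="session")
def blobs4():
    """4-blob prevalence table (separation 8) with normalized features."""
    df = generate_prevalence_table(200, 4, 8.0, seed=21)
    X = df.drop(columns=["country_id", "true_cluster"]).to_numpy()
    Xn = apply_minmax(X, fit_minmax(X))
    return Xn, df["true_cluster"].to_numpy()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
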