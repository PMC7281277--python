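import numpy as np
import pandas as pd
import pytest

from cortivoc.cohort import CohortConfig, FeatureTable, generate_cohort


def make_table(abundance, rt1=None, rt2=None, match=None, blank=None):
    """Small FeatureTable from a plain array/DataFrame for unit tests."""
    if not isinstance(abundance, pd.DataFrame):
        abundance = np.asarray(abundance, dtype=float)
        abundance = pd.DataFrame(
            abundance, columns=[f"f{j}" for j in range(abundance.shape[1])]
        )
    abundance = abundance.set_axis([f"s{i}" for i in range(len(abundance))], axis=0)
    p = abundance.shape[1]
    meta = pd.DataFrame(
        {
            "rt1_s": rt1 if rt1 is not None else np.full(p, 500.0),
            "rt2_s": rt2 if rt2 is not None else np.full(p, 1.0),
            "spectral_match": match if match is not None else np.full(p, 700.0),
            "blank_flag": blank if blank is not None else np.zeros(p, dtype=bool),
        },
        index=pd.Index(abundance.columns, name="feature"),
    )
    return FeatureTable(abundance, meta)


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded default cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for pipeline-level tests."""
    cfg = CohortConfig(
        n_subjects=16,
        n_features=40,
        n_informative=4,
        n_sex_interactions=1,
        n_time_interactions=1,
        missing_rate=0.1,
        outlier_rate=0.0,
        seed=7,
    )
    return generate_cohort(cfg)
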