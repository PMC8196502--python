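import numpy as np
import pandas as pd
import pytest

from chdstack.schema import FeatureTable, default_schema
from chdstack.synthetic import default_params, generate_cohort


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def cohort424():
    """Default synthetic cohort: 424 subjects, 217 CHD positive."""
    return generate_cohort(default_params(seed=11))


@pytest.fixture(scope="session")
def cohort_small():
    """60-subject cohort for fast fit/predict checks."""
    return generate_cohort(default_params(n_subjects=60, seed=13))


def make_toy_table(X, y, prefix="f"):
    """Tiny schema-free table: all columns treated as clinical numerics."""
    from chdstack.schema import FeatureSchema

    X = np.asarray(X, dtype=float)
    names = tuple(f"{prefix}{j}" for j in range(X.shape[1]))
    sch = FeatureSchema(clinical_numeric=names)
    feats = pd.DataFrame(X, columns=list(names))
    return FeatureTable(
        subject_ids=list(range(len(X))), features=feats,
        labels=np.asarray(y, dtype=int), schema=sch,
    )


@pytest.fixture
def toy_separable():
    """Linearly separable 2-feature problem, 40 subjects."""
    rng = np.random.default_rng(5)
    n = 40
    y = np.tile([0, 1], n // 2)
    X = rng.normal(size=(n, 2)) + np.where(y[:, None] == 1, 4.0, -4.0)
    return make_toy_table(X, y)
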