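import numpy as np
import pandas as pd
import pytest

from terroirpls import (
    FeatureTable,
    StudyDesign,
    SyntheticSpec,
    dummy_code,
    generate_metabolome,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_xy(rng):
    """Random centered 20 x 8 matrix with a 3-class response."""
    X = rng.normal(size=(20, 8))
    X -= X.mean(axis=0)
    labels = np.array(list("abc") * 7)[:20]
    return X, dummy_code(labels), labels


@pytest.fixture
def two_class_xy(rng):
    X = rng.normal(size=(16, 6))
    X -= X.mean(axis=0)
    labels = np.array(["lo"] * 8 + ["hi"] * 8)
    return X, dummy_code(labels), labels


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study: full design, 60 features, fixed seed."""
    spec = SyntheticSpec(n_features=60, seed=7)
    return generate_metabolome(spec)


@pytest.fixture
def toy_table():
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [10.0, 20.0, 30.0]],
        index=["s1", "s2", "s3"],
        columns=["f1", "f2", "f3"],
    )
    return FeatureTable(df)


@pytest.fixture
def balanced_design():
    """Balanced 3-year x 3-replicate x 7-producer design (63 rows)."""
    rows = []
    for y in (2006, 2007, 2008):
        for r in (1, 2, 3):
            for v in ("AM", "BA", "BM", "CS", "FA", "MN", "PM"):
                rows.append(
                    {
                        "sample": f"{v}_{y}_r{r}",
                        "vineyard": v,
                        "vintage": y,
                        "stage": 3,
                        "replicate": r,
                    }
                )
    return StudyDesign(pd.DataFrame(rows).set_index("sample"))
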