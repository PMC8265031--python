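import numpy as np
import pandas as pd
import pytest

from knnexplain import (
    CohortSpec,
    SubsetKNNClassifier,
    make_reference_set,
    make_uniform_instance,
)


@pytest.fixture(scope="session")
def spec() -> CohortSpec:
    return CohortSpec(seed=0)


@pytest.fixture(scope="session")
def refs(spec):
    """Default synthetic 13+13 reference set."""
    return make_reference_set(spec)


@pytest.fixture(scope="session")
def clf(refs):
    X, y = refs
    return SubsetKNNClassifier().fit(X, y)


@pytest.fixture(scope="session")
def uniform_good_table(refs, clf):
    X, y = refs
    x = make_uniform_instance(X, y, "Good")
    return clf.subset_value_table(x.to_numpy(), instance_id="uniform_good")


@pytest.fixture(scope="session")
def uniform_poor_table(refs, clf):
    X, y = refs
    x = make_uniform_instance(X, y, "Poor")
    return clf.subset_value_table(x.to_numpy(), instance_id="uniform_poor")


def random_sign_table(m: int, rng: np.random.Generator, instance_id: str = ""):
    """Random exact-style game: f(∅)=0, every non-empty subset ±1."""
    from knnexplain import SubsetValueTable

    values = rng.choice([-1.0, 1.0], size=2 ** m)
    values[0] = 0.0
    names = tuple(f"f{i}" for i in range(m))
    return SubsetValueTable(feature_names=names, values=values, instance_id=instance_id)


def random_real_table(m: int, rng: np.random.Generator, instance_id: str = ""):
    """Random real-valued game (expectation-style values in [-1, 1])."""
    from knnexplain import SubsetValueTable

    values = rng.uniform(-1.0, 1.0, size=2 ** m)
    names = tuple(f"f{i}" for i in range(m))
    return SubsetValueTable(feature_names=names, values=values, instance_id=instance_id)


@pytest.fixture
def single_feature_refs():
    """Four-feature reference set where only feature 0 separates the
    classes; used for surrogate-dominance and informativeness checks."""
    rng = np.random.default_rng(42)
    n = 13
    names = ["f0", "f1", "f2", "f3"]
    rows, labels = [], []
    for label, shift in (("Good", 2.0), ("Poor", -2.0)):
        logs = rng.normal(0.0, 0.3, size=(n, 4))
        logs[:, 0] += shift
        rows.append(np.exp(logs))
        labels += [label] * n
    X = pd.DataFrame(np.vstack(rows), columns=names)
    y = pd.Series(labels, name="label")
    return X, y
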