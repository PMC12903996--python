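import numpy as np
import pytest

from photoscreen import classify as C
from photoscreen import synthetic as SYN


@pytest.fixture(scope="session")
def training_records():
    return SYN.generate_training_fixture()


@pytest.fixture(scope="session")
def training_xy(training_records):
    return SYN.records_to_xy(training_records)


@pytest.fixture(scope="session")
def fitted_svm(training_xy):
    """Margin-based model grid-searched on the default fixture (seed 0)."""
    X, y = training_xy
    X_tr, X_te, y_tr, y_te = C.split(X, y, seed=0)
    best, cv_acc, search = C.cross_validate_grid("svm", X_tr, y_tr, seed=0)
    return {
        "model": search.best_estimator_,
        "cv_accuracy": cv_acc,
        "X_train": X_tr,
        "X_test": X_te,
        "y_train": y_tr,
        "y_test": y_te,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
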