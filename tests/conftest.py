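import numpy as np
import pytest

import frailsom as fs


@pytest.fixture(scope="session")
def small_cohort():
    """Compact default-spec cohort for fast model tests."""
    return fs.generate_cohort(90, seed=5)


@pytest.fixture(scope="session")
def small_trained(small_cohort):
    """A small trained map + scaler + labels shared across tests."""
    labels = fs.cohort_labels(small_cohort, "mffp")
    scaler = fs.ZScoreScaler().fit(small_cohort.values)
    som = fs.SupervisedSOM(
        grid_rows=5, grid_cols=5, epochs=30, random_state=17
    ).fit(scaler.transform(small_cohort.values), labels)
    return som, scaler, labels


def make_som_with_weights(w_features, w_classes, rows, cols, classes=(1, 2, 3)):
    """Assemble a SupervisedSOM directly from given weights (no training)."""
    som = fs.SupervisedSOM(grid_rows=rows, grid_cols=cols)
    som.grid_ = fs.HexGrid(rows, cols)
    som.w_features_ = np.asarray(w_features, dtype=float)
    som.w_classes_ = np.asarray(w_classes, dtype=float)
    som.classes_ = np.asarray(classes)
    som.n_features_in_ = som.w_features_.shape[1]
    return som
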