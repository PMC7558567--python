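"""Supervised SOM: BMU search, update rule, determinism, topology."""

import numpy as np
import pytest

import frailsom as fs
from conftest import make_som_with_weights
from reference_som import train_reference


def test_fixed_seed_gives_identical_models(small_cohort):
    labels = fs.cohort_labels(small_cohort, "mffp")
    Z = fs.standardize(small_cohort.values).Z
    kw = dict(grid_rows=4, grid_cols=4, epochs=5, random_state=9)
    a = fs.SupervisedSOM(**kw).fit(Z, labels)
    b = fs.SupervisedSOM(**kw).fit(Z, labels)
    np.testing.assert_array_equal(a.w_features_, b.w_features_)
    np.testing.assert_array_equal(a.w_classes_, b.w_classes_)
    c = fs.SupervisedSOM(grid_rows=4, grid_cols=4, epochs=5, random_state=10).fit(Z, labels)
    assert not np.array_equal(a.w_features_, c.w_features_)


def test_weight_matrix_shapes(small_trained):
    som, _, _ = small_trained
    assert som.w_features_.shape == (25, 28)
    assert som.w_classes_.shape == (25, 3)
    assert np.isfinite(som.w_features_).all()
    assert som.w_classes_.min() >= 0 and som.w_classes_.max() <= som.class_weight


def test_bmu_exact_match_and_tie_rule():
    rng = np.random.default_rng(0)
    W = rng.normal(size=(9, 4))
    som = make_som_with_weights(W, rng.uniform(size=(9, 3)), 3, 3)
    assert som.bmu(W[7]) == 7
    # two units at equal distance: lowest index wins
    W_tie = W.copy()
    W_tie[5] = W_tie[2]
    som_tie = make_som_with_weights(W_tie, rng.uniform(size=(9, 3)), 3, 3)
    assert som_tie.bmu(W_tie[5]) == 2
    with pytest.raises(ValueError):
        som.bmu(np.zeros(5))


def test_bmu_matches_exhaustive_search_across_grids():
    rng = np.random.default_rng(1)
    for rows in (2, 3, 4):
        for cols in (2, 3):
            W = rng.normal(size=(rows * cols, 6))
            som = make_som_with_weights(W, rng.uniform(size=(rows * cols, 3)), rows, cols)
            for _ in range(5):
                x = rng.normal(size=6)
                brute = min(
                    range(rows * cols), key=lambda u: float(((x - W[u]) ** 2).sum())
                )
                assert som.bmu(x) == brute


def test_single_step_single_unit_moves_to_sample():
    """One unit, constant learning rate 1, one presentation: the unit's
    weights land exactly on the joint sample (closed form)."""
    # a 2x2 grid trained on one sample with lr=1 and sigma -> 0 gives the
    # same closed form for the BMU row
    Z = np.array([[0.3, -1.2, 2.0]])
    y = np.array([2])
    som = fs.SupervisedSOM(
        grid_rows=2, grid_cols=2, epochs=1, lr_initial=1.0, lr_final=1.0,
        radius_initial=1e-9, radius_final=1e-9, class_weight=1.0, random_state=0,
    ).fit(Z, y)
    bmu = som.bmu(Z[0])
    np.testing.assert_allclose(som.w_features_[bmu], Z[0], atol=1e-12)
    np.testing.assert_allclose(som.w_classes_[bmu], [0, 1, 0], atol=1e-12)


def test_vanishing_radius_updates_only_the_bmu():
    """As sigma -> 0 the Gaussian neighbourhood collapses onto the BMU:
    the factor at lattice distance >= 1 is below 1e-12."""
    sigma = 0.1
    assert np.exp(-1 / (2 * sigma**2)) < 1e-12
    Z = np.array([[1.0, 1.0], [1.0, 1.0]])
    y = np.array([1, 1])
    som = fs.SupervisedSOM(
        grid_rows=2, grid_cols=2, epochs=1, lr_initial=0.5, lr_final=0.5,
        radius_initial=sigma, radius_final=sigma, random_state=4,
    ).fit(Z, y)
    # exactly one unit moved per presentation: non-BMU units keep init values
    moved = ~np.all(som.w_features_ == som.initial_w_features_, axis=1)
    assert moved.sum() <= 2  # at most one BMU per presentation


def test_training_matches_straight_line_reference():
    """A 3x3 map / 10 samples / 2 epochs run must match an independent
    loop-based implementation of the same update rule to 1e-10."""
    rng = np.random.default_rng(23)
    Z = rng.normal(size=(10, 4))
    labels = rng.integers(1, 4, size=10)
    params = dict(
        grid_rows=3, grid_cols=3, epochs=2, lr_initial=0.4, lr_final=0.05,
        radius_initial=2.0, radius_final=0.4, class_weight=1.0, random_state=77,
    )
    som = fs.SupervisedSOM(**params).fit(Z, labels)

    # replay the RNG protocol to recover the presentation orders
    replay = np.random.default_rng(77)
    replay.uniform(size=(9, 4))
    replay.uniform(size=(9, 3))
    orders = [replay.permutation(10) for _ in range(2)]

    Y = fs.make_class_matrix(labels).Y
    init = np.hstack([som.initial_w_features_, som.initial_w_classes_])
    W_ref = np.array(
        train_reference(
            Z.tolist(), Y.tolist(), init.tolist(), [o.tolist() for o in orders],
            3, 3, 0.4, 0.05, 2.0, 0.4,
        )
    )
    np.testing.assert_allclose(som.w_features_, W_ref[:, :4], atol=1e-10)
    np.testing.assert_allclose(som.w_classes_, np.clip(W_ref[:, 4:], 0, 1), atol=1e-10)


def test_weights_stay_in_convex_hull_of_init_and_samples():
    rng = np.random.default_rng(6)
    Z = rng.uniform(-2, 2, size=(15, 3))
    labels = rng.integers(1, 4, size=15)
    som = fs.SupervisedSOM(grid_rows=3, grid_cols=3, epochs=4, random_state=2).fit(Z, labels)
    lo = np.minimum(som.initial_w_features_.min(axis=0), Z.min(axis=0)) - 1e-9
    hi = np.maximum(som.initial_w_features_.max(axis=0), Z.max(axis=0)) + 1e-9
    assert np.all(som.w_features_ >= lo) and np.all(som.w_features_ <= hi)


def test_predict_argmax_and_tie_rule():
    som = make_som_with_weights(
        np.array([[0.0, 0.0], [5.0, 5.0]] + [[9.0, 9.0]] * 2),
        np.array([[0.9, 0.3, 0.1], [0.5, 0.5, 0.2], [0.1, 0.2, 0.9], [0.3, 0.3, 0.3]]),
        2, 2,
    )
    assert som.predict([[0.1, 0.1]])[0] == 1  # plain argmax
    assert som.predict([[5.0, 5.0]])[0] == 1  # (0.5, 0.5, 0.2): tie -> class 1
    cls, bmu, planes = som.predict_detail([9.1, 8.9])
    assert bmu in (2, 3) and cls == 3


def test_predict_requires_fit_and_valid_input(small_trained):
    som, _, _ = small_trained
    with pytest.raises(Exception):
        fs.SupervisedSOM().predict(np.zeros((2, 28)))
    with pytest.raises(ValueError):
        som.predict(np.zeros((2, 5)))
    with pytest.raises(ValueError):
        fs.SupervisedSOM(epochs=2).fit(np.array([[np.nan, 1.0]]), np.array([1]))


def test_quantization_error_properties(small_cohort):
    labels = fs.cohort_labels(small_cohort, "mffp")
    Z = fs.standardize(small_cohort.values).Z
    drops = []
    for seed in range(5):
        som = fs.SupervisedSOM(grid_rows=4, grid_cols=4, epochs=10, random_state=seed).fit(Z, labels)
        assert som.quantization_error_ >= 0
        drops.append(som.quantization_error_init_ - som.quantization_error_)
    assert np.median(drops) > 0  # training tightens the map
    # samples identical to unit weights -> zero error
    som0 = make_som_with_weights(np.eye(3)[:, :2].repeat(2, axis=0)[:4], np.ones((4, 3)), 2, 2)
    assert som0.quantization_error(som0.w_features_) == 0.0


def test_component_planes_cover_features_and_classes(small_trained):
    som, _, _ = small_trained
    planes = som.component_planes([f"v{j}" for j in range(28)])
    assert len(planes) == 31
    assert sum(p.is_class_plane for p in planes) == 3
    np.testing.assert_array_equal(planes[4].values, som.w_features_[:, 4])
    flat = make_som_with_weights(np.ones((4, 2)), np.ones((4, 3)), 2, 2)
    fp = flat.component_planes(["a", "b"])[0]
    assert fp.vmin == fp.vmax  # degenerate range renders without error


def test_topology_preserved_for_separated_clusters():
    """After training on two well-separated clusters, same-cluster samples
    map closer on the grid than cross-cluster samples."""
    rng = np.random.default_rng(13)
    a = rng.normal(-4, 0.5, size=(20, 3))
    b = rng.normal(4, 0.5, size=(20, 3))
    Z = np.vstack([a, b])
    labels = np.array([1] * 20 + [3] * 20)
    som = fs.SupervisedSOM(grid_rows=4, grid_cols=4, epochs=30, random_state=1).fit(Z, labels)
    bmus = np.array([som.bmu(z) for z in Z])
    D = som.grid_.distances
    same, cross = [], []
    for i in range(40):
        for j in range(i + 1, 40):
            (same if labels[i] == labels[j] else cross).append(D[bmus[i], bmus[j]])
    assert np.mean(same) < np.mean(cross)
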