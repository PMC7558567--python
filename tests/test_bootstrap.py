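"""Bootstrap split protocol and the %PA/%MS/%CC statistics."""

import numpy as np
import pytest

import frailsom as fs
from frailsom.bootstrap import BootstrapResult


def make_result(labels, train_sets, test_sets, train_preds, test_preds):
    plan = fs.SplitPlan(
        n=len(labels), iterations=len(train_sets), seed=0, with_replacement=False,
        train_indices=[np.asarray(t) for t in train_sets],
        test_indices=[np.asarray(t) for t in test_sets],
    )
    return BootstrapResult(
        plan, np.asarray(labels),
        [np.asarray(p) for p in train_preds], [np.asarray(p) for p in test_preds],
    )


def test_two_thirds_split_arithmetic():
    plan = fs.make_split_plan(9, iterations=4, seed=1)
    for tr, te in zip(plan.train_indices, plan.test_indices):
        assert len(tr) == 6 and len(te) == 3
        assert set(tr) | set(te) == set(range(9))
        assert set(tr).isdisjoint(te)


def test_split_plan_seeded_and_replacement_mode():
    a = fs.make_split_plan(30, 5, seed=3)
    b = fs.make_split_plan(30, 5, seed=3)
    for x, y in zip(a.train_indices, b.train_indices):
        np.testing.assert_array_equal(x, y)
    boot = fs.make_split_plan(30, 5, seed=3, with_replacement=True)
    assert all(len(t) == 30 for t in boot.train_indices)
    # out-of-bag test sets are the unselected samples
    for tr, te in zip(boot.train_indices, boot.test_indices):
        assert set(te) == set(range(30)) - set(tr.tolist())
    with pytest.raises(ValueError):
        fs.make_split_plan(2, 5, seed=0)


def test_every_sample_eventually_tested():
    plan = fs.make_split_plan(251, 50, seed=0)
    tested = np.zeros(251, dtype=bool)
    for te in plan.test_indices:
        tested[te] = True
    assert tested.all()  # per-sample miss probability (2/3)^50 ~ 1.6e-9


def test_perfect_classifier_gives_exactly_100():
    labels = np.array([1, 2, 3, 1, 2, 3])
    tr, te = [0, 1, 2, 3], [4, 5]
    res = make_result(
        labels, [tr, tr], [te, te],
        [labels[tr], labels[tr]], [labels[te], labels[te]],
    )
    for which in ("train", "test"):
        assert fs.percent_cc(res, which) == 100.0
        assert fs.percent_pa(res, which) == 100.0
        assert fs.percent_ms(res, which) == 100.0


def test_all_wrong_classifier_gives_zero_cc():
    labels = np.array([1, 1, 1])
    res = make_result(labels, [[0, 1]], [[2]], [np.array([2, 2])], [np.array([3])])
    assert fs.percent_cc(res, "train") == 0.0
    assert fs.percent_cc(res, "test") == 0.0
    assert fs.percent_ms(res, "train") == 100.0  # consistently wrong is stable


def test_cc_simple_fraction():
    labels = np.array([1, 2, 3])
    res = make_result(labels, [[0]], [[0, 1, 2]], [[1]], [np.array([1, 2, 1])])
    assert fs.percent_cc(res, "test") == pytest.approx(100 * 2 / 3, abs=0.01)


def test_pa_macro_average_always_class_1_on_balanced_set():
    labels = np.array([1, 2, 3] * 4)
    idx = np.arange(12)
    res = make_result(labels, [idx], [idx], [np.ones(12, int)], [np.ones(12, int)])
    assert fs.percent_pa(res, "train") == pytest.approx(100 / 3, abs=1e-9)
    # %CC agrees here because classes are equally sized
    assert fs.percent_cc(res, "train") == pytest.approx(100 / 3, abs=1e-9)


def test_ms_modal_agreement_arithmetic():
    labels = np.array([1, 2])
    sets = [[0, 1]] * 4
    preds = [np.array([1, 2]), np.array([1, 2]), np.array([1, 2]), np.array([3, 2])]
    res = make_result(labels, sets, sets, preds, preds)
    # sample 0: modal class 1 in 3/4 -> 75; sample 1: 100
    assert fs.percent_ms(res, "train") == pytest.approx((75 + 100) / 2)


def test_never_evaluated_samples_excluded_with_warning():
    labels = np.array([1, 2, 3])
    res = make_result(labels, [[0, 1]], [[2]], [np.array([1, 2])], [np.array([3])])
    with pytest.warns(RuntimeWarning, match="never evaluated"):
        ms = fs.percent_ms(res, "train")
    assert ms == 100.0


def test_statistics_bounded_under_fuzzing():
    rng = np.random.default_rng(0)
    for trial in range(25):
        n = rng.integers(4, 20)
        labels = rng.integers(1, 4, size=n)
        iters = rng.integers(1, 5)
        trs, tes, trp, tep = [], [], [], []
        for _ in range(iters):
            tr = rng.choice(n, size=max(2, int(np.ceil(2 * n / 3))), replace=False)
            te = np.setdiff1d(np.arange(n), tr)
            trs.append(tr), tes.append(te)
            trp.append(rng.integers(1, 4, size=len(tr)))
            tep.append(rng.integers(1, 4, size=len(te)))
        res = make_result(labels, trs, tes, trp, tep)
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            for fn in (fs.percent_cc, fs.percent_pa, fs.percent_ms):
                for which in ("train", "test"):
                    v = fn(res, which)
                    assert 0.0 <= v <= 100.0


def test_run_bootstrap_bookkeeping_and_determinism(small_cohort):
    labels = fs.cohort_labels(small_cohort, "mffp")
    plan = fs.make_split_plan(small_cohort.n, 2, seed=5)
    params = {"grid_rows": 3, "grid_cols": 3, "epochs": 3}
    res = fs.run_bootstrap(small_cohort.values, labels, plan, params)
    assert len(res.train_predictions) == 2 and len(res.test_predictions) == 2
    for tr, p in zip(plan.train_indices, res.train_predictions):
        assert len(p) == len(tr)
    # identical duplicated iteration -> identical predictions
    plan2 = fs.SplitPlan(
        plan.n, 2, plan.seed, False,
        [plan.train_indices[0]] * 2, [plan.test_indices[0]] * 2,
    )
    res2 = fs.run_bootstrap(small_cohort.values, labels, plan2, params)
    np.testing.assert_array_equal(res2.train_predictions[0], res2.train_predictions[1])
    res3 = fs.run_bootstrap(small_cohort.values, labels, plan2, params)
    np.testing.assert_array_equal(res2.test_predictions[0], res3.test_predictions[0])


def test_statistics_table_layout(small_cohort):
    labels = fs.cohort_labels(small_cohort, "mffp")
    plan = fs.make_split_plan(small_cohort.n, 2, seed=6)
    params = {"grid_rows": 3, "grid_cols": 3, "epochs": 3}
    results = {
        "mffp": fs.run_bootstrap(small_cohort.values, labels, plan, params),
        "mfind": fs.run_bootstrap(
            small_cohort.values, fs.cohort_labels(small_cohort, "mfind"), plan, params
        ),
    }
    table = fs.statistics_table(results)
    assert table.shape == (2, 6)
    assert list(table.index) == ["mffp", "mfind"]
    assert ((table.to_numpy() >= 0) & (table.to_numpy() <= 100)).all()
    with pytest.raises(ValueError):
        fs.statistics_table({})
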