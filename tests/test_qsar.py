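"""Oversampling, feature selection, splitting, metrics and the bench."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import matthews_corrcoef

from chemlandscape.errors import ChemLandscapeError
from chemlandscape.io_curation import CuratedMolecule, classify_activity, group_of
from chemlandscape.qsar import (
    Metrics,
    build_bench,
    metrics,
    oversample,
    select_features,
    split_and_cv,
    train_bench,
)


def molecule(mol_id, pic50):
    cls = classify_activity(pic50)
    return CuratedMolecule(mol_id, "c1ccccc1", pic50, cls, group_of(cls), False)


def population(sizes):
    """sizes: dict class-representative pIC50 -> count."""
    out = []
    for pic50, count in sizes.items():
        out.extend(molecule(f"M{pic50}_{i}", pic50) for i in range(count))
    return out


# ---------------------------------------------------------------------------
# oversampling


def test_oversample_equalises_to_majority_class():
    mols = population({8.5: 3, 7.5: 9, 6.5: 12, 5.0: 7})
    out = oversample(mols, seed=42)
    counts = pd.Series([m.activity_class.value for m in out]).value_counts()
    assert set(counts) == {12}


def test_oversample_preserves_every_original():
    mols = population({8.5: 3, 6.5: 8})
    out = oversample(mols, seed=42)
    assert {m.molecule_id for m in mols} <= {m.molecule_id for m in out}


def test_oversample_is_a_noop_on_balanced_input():
    mols = population({8.5: 5, 6.5: 5})
    assert oversample(mols, seed=42) == mols


def test_oversample_is_seed_deterministic():
    mols = population({8.5: 3, 7.5: 9, 5.0: 4})
    a = [m.molecule_id for m in oversample(mols, seed=42)]
    b = [m.molecule_id for m in oversample(mols, seed=42)]
    c = [m.molecule_id for m in oversample(mols, seed=43)]
    assert a == b
    assert a != c


# ---------------------------------------------------------------------------
# feature selection


def hand_matrix():
    # 8 rows, 6 columns: c0 constant, c2 duplicates c1, others independent
    data = {
        "c0": [1, 1, 1, 1, 1, 1, 1, 1],
        "c1": [0, 1, 0, 1, 0, 1, 0, 1],
        "c2": [0, 1, 0, 1, 0, 1, 0, 1],
        "c3": [0, 0, 1, 1, 0, 0, 1, 1],
        "c4": [0, 0, 0, 0, 1, 1, 1, 1],
        "c5": [1, 0, 0, 1, 1, 0, 0, 1],
    }
    return pd.DataFrame(data)


def test_six_column_hand_example_keeps_four():
    X = hand_matrix()
    reduced, sel = select_features(X)
    assert list(reduced.columns) == ["c1", "c3", "c4", "c5"]
    assert sel.n_after_variance == 5  # constant column dropped first
    assert sel.n_after_correlation == 4  # later duplicate dropped


def test_selection_is_idempotent_when_reapplied():
    X = hand_matrix()
    reduced, sel = select_features(X)
    pd.testing.assert_frame_equal(sel.apply(X), reduced)
    reduced2, sel2 = select_features(reduced)
    assert sel2.retained == sel.retained


def test_all_features_removed_is_an_error():
    X = pd.DataFrame({"c0": [1, 1, 1], "c1": [0, 0, 0]})
    with pytest.raises(ChemLandscapeError):
        select_features(X)


# ---------------------------------------------------------------------------
# splitting


def test_split_sizes_and_fold_partition():
    labels = np.repeat(["a", "b", "c", "d"], 25)
    plan = split_and_cv(labels, test_frac=0.2, folds=5, seed=42)
    assert len(plan.test_idx) == 20
    assert len(plan.train_idx) == 80
    assert set(plan.train_idx).isdisjoint(plan.test_idx)
    covered = np.concatenate([va for _, va in plan.folds])
    assert sorted(covered) == sorted(plan.train_idx)  # disjoint and covering


def test_split_is_stratified_and_deterministic():
    labels = np.repeat(["a", "b", "c", "d"], 25)
    p1 = split_and_cv(labels, seed=42, folds=0)
    p2 = split_and_cv(labels, seed=42, folds=0)
    assert np.array_equal(p1.test_idx, p2.test_idx)
    test_counts = pd.Series(labels[p1.test_idx]).value_counts()
    assert set(test_counts) == {5}


def test_too_small_class_suggests_fewer_folds():
    labels = np.array(["a"] * 40 + ["b"] * 5)
    with pytest.raises(ChemLandscapeError, match="folds"):
        split_and_cv(labels, folds=10, seed=42)


# ---------------------------------------------------------------------------
# metrics


def test_perfect_diagonal_confusion():
    m = metrics(np.diag([5, 3, 2, 4]))
    assert (m.accuracy, m.recall, m.mcc) == (1.0, 1.0, 1.0)


def test_single_class_prediction_on_balanced_set_is_chance():
    C = np.zeros((4, 4))
    C[:, 0] = 10  # everything predicted as the first class
    m = metrics(C)
    assert m.accuracy == pytest.approx(0.25)
    assert m.mcc == pytest.approx(0.0)


def test_binary_confusion_hand_computed_mcc():
    # [[2,1],[0,3]]: MCC = (2*3 - 1*0)/sqrt(3*3*4*2)
    m = metrics(np.array([[2, 1], [0, 3]]))
    assert m.accuracy == pytest.approx(5 / 6)
    assert m.mcc == pytest.approx(6 / np.sqrt(72))


def test_all_zero_matrix_is_an_error():
    with pytest.raises(ChemLandscapeError):
        metrics(np.zeros((4, 4)))


@given(
    y=st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)),
               min_size=2, max_size=60),
)
def test_multiclass_mcc_matches_sklearn(y):
    y_true = [a for a, _ in y]
    y_pred = [b for _, b in y]
    C = np.zeros((4, 4))
    for a, b in y:
        C[a, b] += 1
    expected = matthews_corrcoef(y_true, y_pred)
    assert metrics(C).mcc == pytest.approx(expected, abs=1e-12)


def test_metrics_invariant_under_consistent_label_permutation():
    rng = np.random.default_rng(0)
    C = rng.integers(0, 10, size=(4, 4))
    perm = [2, 0, 3, 1]
    Cp = C[np.ix_(perm, perm)]
    assert metrics(C).accuracy == pytest.approx(metrics(Cp).accuracy)
    assert metrics(C).mcc == pytest.approx(metrics(Cp).mcc)


# ---------------------------------------------------------------------------
# the bench


def separable_fixture(n_per_class=20, seed=0):
    """Four classes, each marked by its own block of indicator bits."""
    rng = np.random.default_rng(seed)
    classes = ["potent", "active", "intermediate", "inactive"]
    rows, labels = [], []
    for k, cls in enumerate(classes):
        for _ in range(n_per_class):
            bits = (rng.random(40) < 0.3).astype(np.uint8)
            bits[k * 5: (k + 1) * 5] = 1  # class-indicator block
            bits[20 + np.arange(4) * 5] = 0
            bits[20 + k * 5 % 20] = 0
            rows.append(bits)
            labels.append(cls)
    X = pd.DataFrame(rows, columns=[f"b{i}" for i in range(40)])
    y = pd.Series(labels)
    return X, y


def test_bench_has_twelve_algorithms_with_fixed_hyperparameters():
    bench = build_bench(seed=42, n_estimators=500)
    assert len(bench) == 12
    assert bench["RF"].n_estimators == 500
    assert bench["RF"].max_features == 3
    assert bench["RF"].criterion == "gini"
    assert bench["MLP"].hidden_layer_sizes == (100,)


def test_unknown_algorithm_is_rejected():
    with pytest.raises(ChemLandscapeError):
        build_bench(algorithms=["RF", "nope"])


def test_full_bench_reports_one_row_per_algorithm():
    X, y = separable_fixture(n_per_class=12)
    plan = split_and_cv(y.to_numpy(), folds=2, seed=42)
    reports = train_bench(X, y, plan, mode="safe", n_estimators=20)
    assert len(reports) == 12
    assert [r.algorithm for r in reports] == [
        "DT", "ET", "RF", "GB", "LGBM", "XGB", "MLP", "LR", "KNN", "SVM", "NB", "GP",
    ]
    assert not any(r.failed for r in reports)
    for r in reports:
        assert 0 <= r.test.accuracy <= 1
        assert -1 <= r.test.mcc <= 1


def test_ensembles_fit_a_separable_problem():
    X, y = separable_fixture()
    plan = split_and_cv(y.to_numpy(), folds=0, seed=42)
    reports = train_bench(
        X, y, plan, mode="safe", n_estimators=50,
        algorithms=["ET", "RF", "XGB", "LGBM"],
    )
    for r in reports:
        assert r.train.accuracy >= 0.95


def test_bench_is_deterministic_across_runs():
    X, y = separable_fixture(n_per_class=10)
    plan = split_and_cv(y.to_numpy(), folds=0, seed=42)
    r1 = train_bench(X, y, plan, n_estimators=20, algorithms=["RF", "DT"])
    r2 = train_bench(X, y, plan, n_estimators=20, algorithms=["RF", "DT"])
    for a, b in zip(r1, r2):
        assert a.test == b.test and a.train == b.train
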