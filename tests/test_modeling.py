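"""Splitting, fold-wise preprocessing, SMOTE, learners, metrics, voting."""

import numpy as np
import pytest

import tposcreen as tp
from tposcreen.modeling import (
    MinMaxVarianceScaler,
    ModelPipeline,
    ModelSpec,
    VotingEnsemble,
    EnsembleSpec,
    _SignFixedPCA,
)

RNG = np.random.default_rng(42)


def _blobs(n_per_class=30, n_features=5, gap=10.0, seed=0, classes=("A", "C")):
    """Well-separated Gaussian blobs: linearly separable by construction."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for k, cls in enumerate(classes):
        X.append(rng.normal(k * gap, 1.0, size=(n_per_class, n_features)))
        y += [cls] * n_per_class
    return np.vstack(X), np.array(y)


# ---------------------------------------------------------------------------
# stratified split


def test_split_counts_use_largest_remainder():
    assert tp.allocate_test_counts({"A": 485, "C": 102}) == {"A": 97, "C": 21}
    assert tp.allocate_test_counts({"X": 10}) == {"X": 2}


def test_split_is_stratified_disjoint_and_seeded():
    labels = {f"c{i}": ("A" if i < 80 else "C") for i in range(100)}
    plan = tp.stratified_split(labels, 0.2, seed=5)
    assert set(plan.train_ids) | set(plan.test_ids) == set(labels)
    assert not set(plan.train_ids) & set(plan.test_ids)
    test_classes = [labels[i] for i in plan.test_ids]
    assert test_classes.count("A") == 16 and test_classes.count("C") == 4
    assert plan == tp.stratified_split(labels, 0.2, seed=5)
    assert plan != tp.stratified_split(labels, 0.2, seed=6)


def test_split_rejects_singleton_class():
    with pytest.raises(ValueError):
        tp.stratified_split({"a": "A", "b": "A", "c": "C"}, 0.2, seed=0)


# ---------------------------------------------------------------------------
# preprocessing


def test_scaler_drops_low_variance_and_does_not_clip():
    X = np.array([[0.0, 1.0, 0.0], [50.0, 1.0, 1.0], [100.0, 1.0, 1.0], [0.0, 1.0, 0.0]])
    scaler = MinMaxVarianceScaler().fit(X)
    # constant column dropped; binary column with prevalence 0.5 kept (var 0.25)
    assert scaler.n_features_out_ == 2
    out = scaler.transform(np.array([[120.0, 7.0, 1.0]]))
    assert out[0, 0] == pytest.approx(1.2)  # beyond training range, not clipped


def test_scaler_variance_threshold_boundary():
    # prevalence 0.01 -> variance 0.0099 < 0.01 -> dropped
    col = np.zeros((100, 1))
    col[0] = 1.0
    assert MinMaxVarianceScaler().fit(col).n_features_out_ == 0
    # prevalence 0.5 -> variance 0.25 -> kept
    col2 = np.array([[0.0], [1.0]] * 50)
    assert MinMaxVarianceScaler().fit(col2).n_features_out_ == 1


def test_pca_sign_convention_and_explained_variance():
    X = RNG.normal(size=(50, 8)) * np.array([5, 3, 2, 1, 0.5, 0.2, 0.1, 0.05])
    for n in (2, 4, 6):
        red = tp.reduce_fit(X, None, "pca", n)
        # fixed sign: the largest-magnitude loading of each component is positive
        comp = red.components_
        assert all(comp[i, np.abs(comp[i]).argmax()] > 0 for i in range(n))
    ev = [tp.reduce_fit(X, None, "pca", n).explained_variance_ratio_.sum() for n in (1, 3, 5)]
    assert ev[0] < ev[1] < ev[2]


def test_lda_component_bound():
    X, y = _blobs(classes=("A", "B", "C", "D"))
    red = tp.reduce_fit(X, y, "lda", 3)
    assert red.transform(X).shape[1] == 3
    with pytest.raises(ValueError):
        tp.reduce_fit(X, y, "lda", 4)
    with pytest.raises(ValueError):
        tp.reduce_fit(X, None, "pca", 99)


# ---------------------------------------------------------------------------
# SMOTE


def test_smote_balances_and_preserves_originals():
    X, y = _blobs(n_per_class=10, seed=1)
    X, y = X[:14], y[:14]  # 10 A vs 4 C
    Xs, ys = tp.smote_oversample(X, y, k_neighbors=5, seed=0)
    assert list(np.unique(ys, return_counts=True)[1]) == [10, 10]
    assert np.array_equal(Xs[:14], X)  # originals verbatim, first


def test_smote_synthetic_rows_are_convex_combinations_of_parents():
    X, y = _blobs(n_per_class=12, seed=2)
    X, y = X[:18], y[:18]
    Xs, ys, parents = tp.smote_oversample(X, y, k_neighbors=3, seed=7, return_parents=True)
    synthetic = Xs[len(X):]
    for row, (i, j) in zip(synthetic, parents):
        lo = np.minimum(X[i], X[j]) - 1e-12
        hi = np.maximum(X[i], X[j]) + 1e-12
        assert np.all(row >= lo) and np.all(row <= hi)
        # collinearity with the segment between the parents
        d = X[j] - X[i]
        t = (row - X[i])[np.abs(d) > 1e-12] / d[np.abs(d) > 1e-12]
        assert np.allclose(t, t[0])


def test_smote_balanced_input_unchanged_and_singleton_error():
    X, y = _blobs(n_per_class=8, seed=3)
    Xs, ys = tp.smote_oversample(X, y, seed=0)
    assert np.array_equal(Xs, X) and np.array_equal(ys, y)
    with pytest.raises(ValueError):
        tp.smote_oversample(X[:9], y[:9], seed=0)  # single-member class


# ---------------------------------------------------------------------------
# metrics


def test_macro_f1_hand_value_and_extremes():
    # one class with TP=3, FP=1, FN=2 -> P=0.75, R=0.6, F1=2/3
    y_true = ["P"] * 5 + ["N"] * 1
    y_pred = ["P", "P", "P", "N", "N", "P"]
    from sklearn.metrics import f1_score

    per_class = f1_score(y_true, y_pred, labels=["P"], average="macro", zero_division=0)
    assert per_class == pytest.approx(2 / 3, abs=1e-9)
    assert tp.macro_f1(["A", "B"], ["A", "B"]) == 1.0
    assert tp.macro_f1(["A", "B"], ["B", "A"]) == 0.0
    with pytest.raises(ValueError):
        tp.macro_f1([], [])


def _brute_force_macro_f1(y_true, y_pred, classes):
    f1s = []
    for c in classes:
        tp_ = sum(t == c and p == c for t, p in zip(y_true, y_pred))
        fp = sum(t != c and p == c for t, p in zip(y_true, y_pred))
        fn = sum(t == c and p != c for t, p in zip(y_true, y_pred))
        prec = tp_ / (tp_ + fp) if tp_ + fp else 0.0
        rec = tp_ / (tp_ + fn) if tp_ + fn else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    return sum(f1s) / len(f1s)


def test_macro_f1_matches_confusion_matrix_oracle():
    rng = np.random.default_rng(0)
    classes = ["A1", "A2", "B", "C"]
    for _ in range(300):
        n = rng.integers(2, 40)
        y_true = rng.choice(classes, size=n)
        y_pred = rng.choice(classes, size=n)
        ours = tp.macro_f1(y_true, y_pred, labels=classes)
        assert ours == pytest.approx(_brute_force_macro_f1(y_true, y_pred, classes), abs=1e-12)


def test_specificity_of_inactive_class():
    y_true = ["C"] * 21 + ["A"] * 10
    y_pred = ["C"] * 13 + ["A"] * 8 + ["A"] * 10
    conf = tp.ConfusionCounts.from_predictions(y_true, y_pred)
    assert tp.specificity_inactive(conf) == pytest.approx(13 / 21)
    assert round(tp.specificity_inactive(conf), 4) == 0.6190
    with pytest.raises(ValueError):
        tp.specificity_inactive(tp.ConfusionCounts.from_predictions(["A"], ["A"], classes=["A"]))


def test_confusion_counts_sum_to_test_size():
    rng = np.random.default_rng(1)
    y_true = rng.choice(["A", "B", "C"], size=50)
    y_pred = rng.choice(["A", "B", "C"], size=50)
    conf = tp.ConfusionCounts.from_predictions(y_true, y_pred)
    for c in conf.classes:
        assert sum(conf.per_class(c).values()) == 50


# ---------------------------------------------------------------------------
# learners and the fold pipeline


@pytest.mark.parametrize("learner", tp.LEARNERS)
def test_learners_fit_separable_data(learner):
    X, y = _blobs(n_per_class=20, seed=4)
    params = {k: v[0] for k, v in tp.REDUCED_GRIDS[learner].items()}
    est = tp.train_learner(X, y, learner, params, seed=0)
    assert (est.predict(X) == y).all() if learner != "ANN" else (est.predict(X) == y).mean() > 0.9
    proba = est.predict_proba(X)
    assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)
    # determinism: same seed, same data -> identical predictions
    est2 = tp.train_learner(X, y, learner, params, seed=0)
    assert np.array_equal(est.predict(X), est2.predict(X))


def test_train_learner_rejects_single_class():
    X = RNG.normal(size=(10, 3))
    with pytest.raises(ValueError):
        tp.train_learner(X, np.array(["A"] * 10), "RF", {"n_estimators": 10})


def test_grid_search_on_separable_toy():
    X, y = _blobs(n_per_class=25, gap=12.0, seed=5)
    spec = ModelSpec("RF", reducer=None, grid={"n_estimators": [30]}, seed=0)
    res = tp.grid_search_cv(X, y, spec, folds=5)
    assert res.cv_score >= 0.95
    assert res.best_params == {"n_estimators": 30}
    assert 0.0 <= res.cv_score <= 1.0
    # deterministic under re-run
    res2 = tp.grid_search_cv(X, y, spec, folds=5)
    assert res2.cv_score == res.cv_score


def test_grid_search_tie_goes_to_first_grid_point():
    X, y = _blobs(n_per_class=25, gap=15.0, seed=6)
    spec = ModelSpec("RF", reducer=None, grid={"n_estimators": [20, 40]}, seed=0)
    res = tp.grid_search_cv(X, y, spec, folds=3)
    if res.cv_score == 1.0:  # both points perfect -> tie
        assert res.best_params == {"n_estimators": 20}


# ---------------------------------------------------------------------------
# voting


class _StubPipeline:
    def __init__(self, predictions, classes=("A", "C")):
        self.predictions = np.asarray(predictions)
        self.classes_ = np.asarray(classes)

    def predict(self, X):
        return self.predictions

    def predict_proba(self, X):
        onehot = (self.predictions[:, None] == self.classes_[None, :]).astype(float)
        return 0.8 * onehot + 0.1


def _ensemble(mode, preds_and_scores):
    members = [(name, score, _StubPipeline(preds)) for name, score, preds in preds_and_scores]
    return VotingEnsemble(EnsembleSpec(mode=mode, members=members))


def test_hard_vote_majority_and_tie_break_by_best_cv_member():
    ens = _ensemble(
        "hard",
        [
            ("RF", 0.9, ["A", "A"]),
            ("SVM", 0.5, ["A", "C"]),
            ("ANN", 0.6, ["C", "C"]),
            ("XGB", 0.4, ["C", "A"]),
        ],
    )
    out = ens.predict(np.zeros((2, 1)))
    # both rows are 2-2 ties; the best-CV member (RF) predicted A then A
    assert list(out) == ["A", "A"]


def test_hard_vote_invariant_to_member_order():
    specs = [("RF", 0.9, ["A", "C", "A"]), ("SVM", 0.5, ["A", "C", "C"]),
             ("ANN", 0.6, ["C", "C", "A"]), ("XGB", 0.4, ["C", "A", "A"])]
    ref = _ensemble("hard", specs).predict(np.zeros((3, 1)))
    for perm in ([1, 0, 3, 2], [3, 2, 1, 0], [2, 3, 0, 1]):
        out = _ensemble("hard", [specs[i] for i in perm]).predict(np.zeros((3, 1)))
        assert np.array_equal(out, ref)


def test_soft_vote_with_identical_members_equals_single_member():
    member = ("RF", 0.5, ["A", "C", "A"])
    ens = _ensemble("soft", [member] * 4)
    assert list(ens.predict(np.zeros((3, 1)))) == ["A", "C", "A"]


def test_top4_member_selection_by_cv_score():
    results = {
        name: tp.CVResult("binary", "APC_Sub", name, "pca", {}, score, pipeline=_StubPipeline(["A"]))
        for name, score in [("RF", 0.6), ("SVM", 0.5), ("ANN", 0.55), ("AdaB", 0.4), ("XGB", 0.65)]
    }
    ens = tp.build_voting_ensemble(results, mode="hard")
    assert [m[0] for m in ens.spec.members] == ["XGB", "RF", "ANN", "SVM"]
    with pytest.raises(ValueError):
        tp.build_voting_ensemble({k: results[k] for k in ["RF", "SVM"]}, "hard")


def test_ensemble_spec_requires_exactly_four_members():
    with pytest.raises(ValueError):
        EnsembleSpec(mode="hard", members=[("RF", 0.5, _StubPipeline(["A"]))])
    with pytest.raises(ValueError):
        _ensemble("loud", [("RF", 0.5, ["A"])] * 4)


# ---------------------------------------------------------------------------
# selection


def test_select_best_two_stage_rule():
    def res(fs, learner, cv, test):
        return tp.CVResult("binary", fs, learner, "pca", {}, cv, test_score=test)

    results = [
        res("APC_Sub", "RF", 0.80, 0.70),
        res("APC_Sub", "SVM", 0.90, 0.60),  # CV winner for APC_Sub
        res("Morgan_Sub", "RF", 0.85, 0.95),  # CV winner for Morgan_Sub, best test
    ]
    best = tp.select_best(results)
    assert (best.feature_set, best.learner) == ("Morgan_Sub", "RF")
    # the APC_Sub candidate is its CV winner, even though another APC_Sub
    # combo had the higher test score
    assert tp.select_best(results[:2]).learner == "SVM"
    with pytest.raises(ValueError):
        tp.select_best([])


def test_model_pipeline_deterministic_and_serializable(tmp_path, small_library, chemotypes):
    _, activity, truth = small_library
    recipe = tp.FeatureRecipe(library=chemotypes)
    feats = recipe.featurize(list(activity["id"])[:80], list(activity["smiles"])[:80])
    y = np.array(truth["binary"][:80])
    pipe = ModelPipeline(ModelSpec("RF", reducer="pca", grid={"n_estimators": [30]},
                                   n_components=5, seed=11), {"n_estimators": 30}).fit(feats.values, y)
    pred = pipe.predict(feats.values)
    pipe2 = ModelPipeline(pipe.spec, pipe.params).fit(feats.values, y)
    assert np.array_equal(pred, pipe2.predict(feats.values))
    import joblib

    joblib.dump(pipe, tmp_path / "pipe.joblib")
    loaded = joblib.load(tmp_path / "pipe.joblib")
    assert np.array_equal(loaded.predict(feats.values), pred)
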