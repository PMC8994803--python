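"""Imbalance-aware classification with grid-search CV and voting ensembles.

The modeling protocol:

1. stratified 80:20 train/test split (largest-remainder per-class allocation);
2. per CV fold, fit on the training fold only: min-max scaling, variance
   filter (post-scaling variance < 0.01 dropped), optional PCA/LDA reduction,
   SMOTE oversampling of minority classes, then the learner;
3. grid search with stratified five-fold CV, scored by macro-F1;
4. hard/soft voting ensembles over the four best of the five base learners
   (RF, SVM, ANN, AdaB, XGB) ranked by CV score;
5. model selection: best hyperparameters by CV score, best model per
   grouping by test-set macro-F1.

Macro (unweighted) F1 averaging is used because the endpoint is heavily
imbalanced; a weighted option is exposed on :func:`macro_f1`.  SMOTE is
implemented here following the classic recipe — each synthetic sample is a
uniform interpolation between a minority sample and one of its k nearest
same-class neighbours — and is only ever fit on training rows.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .features import FeatureMatrix, FeatureRecipe

__all__ = [
    "LEARNERS",
    "SplitPlan",
    "ModelSpec",
    "ConfusionCounts",
    "CVResult",
    "EnsembleSpec",
    "VotingEnsemble",
    "ModelBundle",
    "ExperimentResult",
    "allocate_test_counts",
    "stratified_split",
    "MinMaxVarianceScaler",
    "preprocess_fit",
    "reduce_fit",
    "smote_oversample",
    "build_estimator",
    "train_learner",
    "ModelPipeline",
    "grid_search_cv",
    "macro_f1",
    "specificity_inactive",
    "build_voting_ensemble",
    "select_best",
    "run_experiment",
    "DEFAULT_GRIDS",
    "REDUCED_GRIDS",
]

LEARNERS = ("RF", "SVM", "ANN", "AdaB", "XGB")
_LEARNER_ORDER = {name: i for i, name in enumerate(LEARNERS)}

# Compact default hyperparameter grids (desk-scale).
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "RF": {"n_estimators": [100, 500], "max_depth": [None, 10]},
    "SVM": {"C": [0.1, 1.0, 10.0], "gamma": ["scale"]},
    "ANN": {"hidden_layer_sizes": [(64,), (256,)], "alpha": [1e-4, 1e-2]},
    "AdaB": {"n_estimators": [100, 500]},
    "XGB": {"n_estimators": [100, 500], "max_depth": [3, 6], "learning_rate": [0.1, 0.3]},
}

# Smaller grids for quick end-to-end runs.
REDUCED_GRIDS: dict[str, dict[str, list]] = {
    "RF": {"n_estimators": [100], "max_depth": [None, 10]},
    "SVM": {"C": [1.0, 10.0], "gamma": ["scale"]},
    "ANN": {"hidden_layer_sizes": [(64,)], "alpha": [1e-4]},
    "AdaB": {"n_estimators": [100]},
    "XGB": {"n_estimators": [100], "max_depth": [3, 6], "learning_rate": [0.3]},
}


# ---------------------------------------------------------------------------
# stratified splitting


@dataclass(frozen=True)
class SplitPlan:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    test_fraction: float
    seed: int


def allocate_test_counts(class_totals: Mapping[str, int], test_fraction: float = 0.2) -> dict[str, int]:
    """Largest-remainder allocation of test slots across classes.

    The total number of test slots is ``ceil(test_fraction * N)``; each class
    gets the floor of its proportional share and the remaining slots go to
    the largest fractional parts (ties broken toward the larger class, then
    by class name).
    """
    n = sum(class_totals.values())
    if n == 0:
        raise ValueError("empty dataset")
    frac = Fraction(test_fraction).limit_denominator(10**6)
    total = int(math.ceil(frac * n))
    shares = {c: Fraction(total * cnt, n) for c, cnt in class_totals.items()}
    counts = {c: int(s) for c, s in shares.items()}
    remaining = total - sum(counts.values())
    order = sorted(
        class_totals,
        key=lambda c: (shares[c] - counts[c], class_totals[c], _NegStr(c)),
        reverse=True,
    )
    for c in order[:remaining]:
        counts[c] += 1
    return counts


class _NegStr(str):
    """Reverses string comparison so that 'reverse=True' sorts names ascending."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):  # pragma: no cover - trivial
        return str.__lt__(self, other)


def stratified_split(
    labels: Mapping[str, str], test_fraction: float = 0.2, seed: int = 0
) -> SplitPlan:
    """Stratified train/test split with largest-remainder test allocation.

    Test membership within each class is sampled uniformly at random under
    ``seed``.  Every class must have at least two members.
    """
    by_class: dict[str, list[str]] = {}
    for cid, cls in labels.items():
        by_class.setdefault(cls, []).append(cid)
    for cls, members in by_class.items():
        if len(members) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
    counts = allocate_test_counts({c: len(m) for c, m in by_class.items()}, test_fraction)
    rng = np.random.default_rng(seed)
    test: set[str] = set()
    for cls in sorted(by_class):
        members = sorted(by_class[cls])
        chosen = rng.choice(len(members), size=counts[cls], replace=False)
        test.update(members[i] for i in chosen)
    all_ids = list(labels)
    return SplitPlan(
        train_ids=tuple(i for i in all_ids if i not in test),
        test_ids=tuple(i for i in all_ids if i in test),
        test_fraction=test_fraction,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# fold-wise preprocessing


class MinMaxVarianceScaler:
    """Min-max scaling followed by a variance filter, fit on training rows only.

    Each feature is mapped to ``(x - min) / (max - min)`` using training-set
    extrema (constant features map to 0); features whose post-scaling
    training variance falls below ``var_threshold`` are dropped.  Unseen rows
    are transformed with the stored parameters and are not clipped.
    """

    def __init__(self, var_threshold: float = 0.01):
        self.var_threshold = var_threshold

    def fit(self, X: np.ndarray) -> "MinMaxVarianceScaler":
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("cannot fit on an empty matrix")
        self.min_ = X.min(axis=0)
        self.range_ = X.max(axis=0) - self.min_
        scaled = self._scale(X)
        self.keep_ = scaled.var(axis=0) >= self.var_threshold
        return self

    def _scale(self, X: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = (X - self.min_) / self.range_
        scaled[:, self.range_ == 0] = 0.0
        return scaled

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self._scale(X)[:, self.keep_]

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    @property
    def n_features_out_(self) -> int:
        return int(self.keep_.sum())


def preprocess_fit(train_matrix: np.ndarray | FeatureMatrix, var_threshold: float = 0.01) -> MinMaxVarianceScaler:
    """Fit the min-max + variance-filter transformer on training rows."""
    X = train_matrix.values if isinstance(train_matrix, FeatureMatrix) else train_matrix
    return MinMaxVarianceScaler(var_threshold).fit(X)


class _SignFixedPCA:
    """PCA with a deterministic sign convention: the largest-magnitude loading
    of each component is positive."""

    def __init__(self, n_components, seed: int = 0):
        self.n_components = n_components
        self.seed = seed

    def fit(self, X: np.ndarray, y=None) -> "_SignFixedPCA":
        self._pca = PCA(n_components=self.n_components, random_state=self.seed)
        self._pca.fit(X)
        comp = self._pca.components_
        signs = np.sign(comp[np.arange(comp.shape[0]), np.abs(comp).argmax(axis=1)])
        signs[signs == 0] = 1.0
        self._pca.components_ = comp * signs[:, None]
        self.explained_variance_ratio_ = self._pca.explained_variance_ratio_
        self.components_ = self._pca.components_
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self._pca.transform(X)


def reduce_fit(X: np.ndarray, y: np.ndarray | None, method: str, n_components, seed: int = 0):
    """Fit a PCA (unsupervised) or LDA (supervised) reducer.

    ``n_components`` may be an int, or for PCA a float in (0, 1) meaning the
    explained-variance fraction to retain.  LDA caps components at
    ``n_classes - 1``.
    """
    X = np.asarray(X, dtype=float)
    method = method.lower()
    if method == "pca":
        if isinstance(n_components, (int, np.integer)) and not 1 <= n_components <= X.shape[1]:
            raise ValueError(f"n_components={n_components} out of range for {X.shape[1]} features")
        return _SignFixedPCA(n_components, seed).fit(X)
    if method == "lda":
        if y is None:
            raise ValueError("LDA requires class labels")
        n_classes = len(np.unique(y))
        max_comp = n_classes - 1
        if n_components is None:
            n_components = max_comp
        if not 1 <= n_components <= min(max_comp, X.shape[1]):
            raise ValueError(f"LDA n_components={n_components} must be in [1, {max_comp}]")
        lda = LinearDiscriminantAnalysis(n_components=n_components)
        lda.fit(X, y)
        return lda
    raise ValueError(f"unknown reduction method {method!r}")


def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
    return_parents: bool = False,
):
    """SMOTE: oversample every minority class up to the majority-class count.

    Each synthetic row lies on the segment between a minority row and one of
    its ``k_neighbors`` nearest same-class neighbours (interpolation factor
    uniform in [0, 1)).  Original rows are preserved verbatim and come first.
    If a class has fewer than ``k_neighbors + 1`` members, k is reduced to
    ``class size - 1``; a class of size 1 is an error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    majority = counts.max()
    rng = np.random.default_rng(seed)
    new_rows, new_labels, parents = [], [], []
    for cls, count in zip(classes, counts):
        need = majority - count
        if need == 0:
            continue
        if count < 2:
            raise ValueError(f"cannot oversample class {cls!r} with a single member")
        k = min(k_neighbors, count - 1)
        idx = np.flatnonzero(y == cls)
        Xc = X[idx]
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        neigh = nn.kneighbors(Xc, return_distance=False)[:, 1:]  # drop self
        base = rng.integers(0, count, size=need)
        mate = neigh[base, rng.integers(0, k, size=need)]
        gaps = rng.random(need)
        new_rows.append(Xc[base] + gaps[:, None] * (Xc[mate] - Xc[base]))
        new_labels.append(np.full(need, cls, dtype=y.dtype))
        parents.extend(zip(idx[base], idx[mate]))
    if new_rows:
        X_out = np.vstack([X] + new_rows)
        y_out = np.concatenate([y] + new_labels)
    else:
        X_out, y_out = X.copy(), y.copy()
    if return_parents:
        return X_out, y_out, parents
    return X_out, y_out


# ---------------------------------------------------------------------------
# learners


class _EncodedXGB:
    """XGBClassifier wrapper mapping arbitrary class labels to 0..k-1."""

    def __init__(self, seed: int = 0, **params):
        self.params = params
        self.seed = seed

    def fit(self, X, y):
        self.classes_, encoded = np.unique(y, return_inverse=True)
        self._model = XGBClassifier(
            random_state=self.seed,
            n_jobs=1,
            eval_metric="mlogloss",
            verbosity=0,
            **self.params,
        )
        self._model.fit(X, encoded)
        return self

    def predict(self, X):
        return self.classes_[self._model.predict(X)]

    def predict_proba(self, X):
        return self._model.predict_proba(X)


def build_estimator(learner: str, params: Mapping, seed: int = 0):
    """Instantiate one of the five base learners with the given hyperparameters.

    All learners expose ``predict_proba``; the SVM uses sigmoid (Platt)
    calibration of its decision values to produce probabilities.
    """
    params = dict(params)
    if learner == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if learner == "SVM":
        svc = SVC(kernel="rbf", random_state=seed, **params)
        # sigmoid (Platt) calibration of the decision values supplies the
        # class probabilities needed for soft voting
        return CalibratedClassifierCV(svc, method="sigmoid", ensemble=False)
    if learner == "ANN":
        params.setdefault("max_iter", 500)
        return MLPClassifier(random_state=seed, **params)
    if learner == "AdaB":
        return AdaBoostClassifier(random_state=seed, **params)
    if learner == "XGB":
        return _EncodedXGB(seed=seed, **params)
    raise ValueError(f"unknown learner {learner!r}; expected one of {LEARNERS}")


def train_learner(X: np.ndarray, y: np.ndarray, learner: str, params: Mapping, seed: int = 0):
    """Fit one base learner; single-class training data is an error."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    est = build_estimator(learner, params, seed)
    est.fit(np.asarray(X, dtype=float), y)
    return est


# ---------------------------------------------------------------------------
# metrics


def macro_f1(y_true, y_pred, labels: Sequence | None = None, average: str = "macro") -> float:
    """Unweighted mean over classes of the per-class F1 score (0/0 -> 0)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    if labels is None:
        labels = sorted(np.unique(y_true))
    return float(f1_score(y_true, y_pred, labels=list(labels), average=average, zero_division=0))


@dataclass
class ConfusionCounts:
    """Per-class TP/FP/FN/TN counts over a test set."""

    classes: list[str]
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @classmethod
    def from_predictions(cls, y_true, y_pred, classes: Sequence | None = None) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if classes is None:
            classes = sorted(set(y_true) | set(y_pred))
        classes = list(classes)
        tp = np.array([np.sum((y_true == c) & (y_pred == c)) for c in classes])
        fp = np.array([np.sum((y_true != c) & (y_pred == c)) for c in classes])
        fn = np.array([np.sum((y_true == c) & (y_pred != c)) for c in classes])
        tn = len(y_true) - tp - fp - fn
        return cls(classes, tp, fp, fn, tn)

    def per_class(self, c: str) -> dict[str, int]:
        i = self.classes.index(c)
        return {"TP": int(self.tp[i]), "FP": int(self.fp[i]), "FN": int(self.fn[i]), "TN": int(self.tn[i])}


def specificity_inactive(confusion: ConfusionCounts, inactive_class: str = "C") -> float:
    """Fraction of truly inactive (group C) test compounds predicted inactive."""
    if inactive_class not in confusion.classes:
        raise ValueError(f"class {inactive_class!r} absent from confusion counts")
    i = confusion.classes.index(inactive_class)
    denom = confusion.tp[i] + confusion.fn[i]
    if denom == 0:
        raise ValueError("no inactive compounds in the test set")
    return float(confusion.tp[i]) / float(denom)


# ---------------------------------------------------------------------------
# the fold-wise pipeline


@dataclass
class ModelSpec:
    """One learner x reducer combination with its hyperparameter grid."""

    learner: str
    reducer: str | None = "pca"  # "pca", "lda", or None
    grid: dict[str, list] = field(default_factory=dict)
    n_components: int | float | None = 10
    smote_k: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.learner not in LEARNERS:
            raise ValueError(f"unknown learner {self.learner!r}")
        if not self.grid:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.learner].items()}

    def grid_points(self) -> list[dict]:
        keys = list(self.grid)
        return [dict(zip(keys, combo)) for combo in itertools.product(*(self.grid[k] for k in keys))]


class ModelPipeline:
    """Scaler + optional reducer + SMOTE + learner, fit as one unit.

    Every fit statistic (min/max, variance mask, PCA/LDA axes, SMOTE
    neighbours) is derived from the rows passed to :meth:`fit` only.
    """

    def __init__(self, spec: ModelSpec, params: Mapping):
        self.spec = spec
        self.params = dict(params)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ModelPipeline":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.scaler_ = MinMaxVarianceScaler().fit(X)
        Z = self.scaler_.transform(X)
        if self.spec.reducer:
            n_comp = self.spec.n_components
            if self.spec.reducer == "pca" and isinstance(n_comp, (int, np.integer)):
                n_comp = min(n_comp, Z.shape[1], Z.shape[0])
            elif self.spec.reducer == "lda":
                # LDA dimension is bounded by n_classes - 1
                max_comp = len(np.unique(y)) - 1
                n_comp = max_comp if n_comp is None else min(int(n_comp), max_comp)
            self.reducer_ = reduce_fit(Z, y, self.spec.reducer, n_comp, seed=self.spec.seed)
            Z = self.reducer_.transform(Z)
        else:
            self.reducer_ = None
        Zs, ys = smote_oversample(Z, y, k_neighbors=self.spec.smote_k, seed=self.spec.seed)
        self.estimator_ = train_learner(Zs, ys, self.spec.learner, self.params, seed=self.spec.seed)
        self.classes_ = np.unique(y)
        return self

    def _transform(self, X: np.ndarray) -> np.ndarray:
        Z = self.scaler_.transform(np.asarray(X, dtype=float))
        if self.reducer_ is not None:
            Z = self.reducer_.transform(Z)
        return Z

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator_.predict(self._transform(X)))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator_.predict_proba(self._transform(X)))


@dataclass
class CVResult:
    """Outcome of a grid search for one (grouping, feature set, learner, reducer)."""

    grouping: str
    feature_set: str
    learner: str
    reducer: str | None
    best_params: dict
    cv_score: float
    pipeline: ModelPipeline | None = None
    test_score: float | None = None
    confusion: ConfusionCounts | None = None

    @property
    def combo_id(self) -> str:
        red = self.reducer or "none"
        return f"{self.grouping}/{self.feature_set}/{self.learner}_{red}"


def grid_search_cv(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    folds: int = 5,
    grouping: str = "",
    feature_set: str = "",
) -> CVResult:
    """Grid search with stratified k-fold CV; refits the best point on all rows.

    Within each fold the scaler, reducer and SMOTE are fit on the training
    fold only and applied (without refitting) to the validation fold; the CV
    score is the mean validation macro-F1.  Ties go to the first grid point.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
    fold_indices = list(skf.split(X, y))
    for tr, va in fold_indices:
        if len(np.unique(y[tr])) < len(classes) or len(np.unique(y[va])) < len(classes):
            raise ValueError("degenerate fold: a class is missing from a fold")
    best_score, best_params = -np.inf, None
    for params in spec.grid_points():
        scores = []
        for tr, va in fold_indices:
            pipe = ModelPipeline(spec, params).fit(X[tr], y[tr])
            scores.append(macro_f1(y[va], pipe.predict(X[va]), labels=classes))
        mean_score = float(np.mean(scores))
        if mean_score > best_score:
            best_score, best_params = mean_score, params
    pipeline = ModelPipeline(spec, best_params).fit(X, y)
    return CVResult(
        grouping=grouping,
        feature_set=feature_set,
        learner=spec.learner,
        reducer=spec.reducer,
        best_params=best_params,
        cv_score=best_score,
        pipeline=pipeline,
    )


# ---------------------------------------------------------------------------
# voting ensembles


@dataclass
class EnsembleSpec:
    mode: str  # "hard" or "soft"
    members: list[tuple[str, float, ModelPipeline]]  # (learner, cv_score, fitted)

    def __post_init__(self):
        if self.mode not in ("hard", "soft"):
            raise ValueError(f"voting mode must be 'hard' or 'soft', got {self.mode!r}")
        if len(self.members) != 4:
            raise ValueError("a voting ensemble takes exactly 4 members")


class VotingEnsemble:
    """Hard/soft voting over four fitted base pipelines.

    Hard voting takes the majority class, breaking ties with the prediction
    of the member with the highest CV score (so the output does not depend on
    member order).  Soft voting takes the argmax of the mean class
    probabilities, ties broken toward the first class in sorted order.
    """

    def __init__(self, spec: EnsembleSpec):
        self.spec = spec
        self.classes_ = self.spec.members[0][2].classes_
        # mean of the members' CV scores, used when ensembles compete with
        # base learners during model selection
        self.cv_score = float(np.mean([s for _, s, _ in spec.members]))

    @property
    def mode(self) -> str:
        return self.spec.mode

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.spec.mode == "soft":
            return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
        preds = np.stack([pipe.predict(X) for _, _, pipe in self.spec.members])
        leader = max(self.spec.members, key=lambda m: (m[1], -_LEARNER_ORDER[m[0]]))[2]
        leader_pred = leader.predict(X)
        out = []
        for j in range(preds.shape[1]):
            votes, counts = np.unique(preds[:, j], return_counts=True)
            top = counts.max()
            winners = votes[counts == top]
            out.append(winners[0] if len(winners) == 1 else leader_pred[j])
        return np.asarray(out)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs = np.zeros((len(X), len(self.classes_)))
        for _, _, pipe in self.spec.members:
            p = pipe.predict_proba(X)
            cols = {c: i for i, c in enumerate(pipe.classes_)}
            probs += p[:, [cols[c] for c in self.classes_]]
        return probs / len(self.spec.members)


def build_voting_ensemble(cv_results: Mapping[str, CVResult], mode: str = "hard") -> VotingEnsemble:
    """Top-4-by-CV-score voting ensemble (ties by fixed learner order)."""
    if len(cv_results) < 4:
        raise ValueError("need at least 4 base results to build a voting ensemble")
    ranked = sorted(
        cv_results.items(), key=lambda kv: (-kv[1].cv_score, _LEARNER_ORDER[kv[0]])
    )[:4]
    members = [(name, res.cv_score, res.pipeline) for name, res in ranked]
    return VotingEnsemble(EnsembleSpec(mode=mode, members=members))


# ---------------------------------------------------------------------------
# experiments and model selection


@dataclass
class ModelBundle:
    """A trained, deployable model: featurization recipe + fitted classifier."""

    grouping: str
    feature_set: str
    recipe: FeatureRecipe
    model: ModelPipeline | VotingEnsemble
    model_name: str
    classes: list[str]
    train_ids: list[str]
    train_predictions: dict[str, str]
    metadata: dict = field(default_factory=dict)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "ModelBundle":
        bundle = joblib.load(path)
        if not isinstance(bundle, cls):
            raise TypeError(f"{path} does not contain a ModelBundle")
        return bundle


@dataclass
class ExperimentResult:
    """Everything produced by :func:`run_experiment` for one grouping x feature set."""

    grouping: str
    feature_set: str
    split: SplitPlan
    results: list[CVResult]  # base learners and ensembles, test scores filled in
    best: CVResult

    def results_table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "combo": r.combo_id,
                    "learner": r.learner,
                    "reducer": r.reducer or "none",
                    "cv_score": r.cv_score,
                    "test_score": r.test_score,
                    "best_params": str(r.best_params),
                }
                for r in self.results
            ]
        )


def select_best(results: Sequence[CVResult]) -> CVResult:
    """Two-stage winner: highest CV score per feature set, then highest test score.

    Within each (grouping, feature set) only the combination with the best CV
    score stays a candidate; among candidates the highest test macro-F1 wins.
    """
    if not results:
        raise ValueError("no results to select from")
    best_per_fs: dict[tuple[str, str], CVResult] = {}
    for r in results:
        key = (r.grouping, r.feature_set)
        if key not in best_per_fs or r.cv_score > best_per_fs[key].cv_score:
            best_per_fs[key] = r
    candidates = list(best_per_fs.values())
    return max(candidates, key=lambda r: (r.test_score if r.test_score is not None else -np.inf))


def _evaluate(model, X_test, y_test, classes) -> tuple[float, ConfusionCounts]:
    pred = model.predict(X_test)
    return (
        macro_f1(y_test, pred, labels=classes),
        ConfusionCounts.from_predictions(y_test, pred, classes=classes),
    )


def run_experiment(
    features: FeatureMatrix,
    labels: Mapping[str, str],
    grouping: str,
    *,
    learners: Sequence[str] = LEARNERS,
    grids: Mapping[str, Mapping[str, list]] | None = None,
    reducers: Sequence[str | None] = ("pca", "lda"),
    n_components: int | float | None = 10,
    folds: int = 5,
    test_fraction: float = 0.2,
    smote_k: int = 5,
    seed: int = 0,
    voting: Sequence[str] = ("hard", "soft"),
    split: SplitPlan | None = None,
) -> ExperimentResult:
    """Train and evaluate all learner x reducer combinations for one grouping.

    Splits the data (or reuses a provided :class:`SplitPlan`), grid-searches
    every base learner under every reducer, builds hard/soft voting ensembles
    from the four best base models per reducer, scores everything on the test
    set and applies the two-stage selection rule.
    """
    grids = grids or DEFAULT_GRIDS
    ids = [str(i) for i in features.compound_ids]
    labels = {str(k): v for k, v in labels.items()}
    if split is None:
        split = stratified_split({i: labels[i] for i in ids}, test_fraction, seed)
    X_train = features.subset(list(split.train_ids)).values
    X_test = features.subset(list(split.test_ids)).values
    y_train = np.array([labels[i] for i in split.train_ids])
    y_test = np.array([labels[i] for i in split.test_ids])
    classes = np.unique(np.array([labels[i] for i in ids]))

    all_results: list[CVResult] = []
    for reducer in reducers:
        per_learner: dict[str, CVResult] = {}
        for learner in learners:
            spec = ModelSpec(
                learner=learner,
                reducer=reducer,
                grid={k: list(v) for k, v in grids[learner].items()},
                n_components=n_components,
                smote_k=smote_k,
                seed=seed,
            )
            res = grid_search_cv(
                X_train, y_train, spec, folds=folds,
                grouping=grouping, feature_set=features.feature_set_id,
            )
            res.test_score, res.confusion = _evaluate(res.pipeline, X_test, y_test, classes)
            per_learner[learner] = res
            all_results.append(res)
        if len(per_learner) >= 4:
            for mode in voting:
                ens = build_voting_ensemble(per_learner, mode=mode)
                score, conf = _evaluate(ens, X_test, y_test, classes)
                all_results.append(
                    CVResult(
                        grouping=grouping,
                        feature_set=features.feature_set_id,
                        learner=f"{mode}-voting",
                        reducer=reducer,
                        best_params={"members": [m[0] for m in ens.spec.members]},
                        cv_score=ens.cv_score,
                        pipeline=ens,  # type: ignore[arg-type]
                        test_score=score,
                        confusion=conf,
                    )
                )
    best = select_best(all_results)
    return ExperimentResult(
        grouping=grouping,
        feature_set=features.feature_set_id,
        split=split,
        results=all_results,
        best=best,
    )


def make_bundle(
    experiment: ExperimentResult,
    recipe: FeatureRecipe,
    features: FeatureMatrix,
    labels: Mapping[str, str],
) -> ModelBundle:
    """Package the experiment winner with its featurization recipe."""
    best = experiment.best
    train_ids = list(experiment.split.train_ids)
    X_train = features.subset(train_ids).values
    train_pred = best.pipeline.predict(X_train)
    return ModelBundle(
        grouping=experiment.grouping,
        feature_set=experiment.feature_set,
        recipe=recipe,
        model=best.pipeline,
        model_name=f"{best.learner}_{best.reducer or 'none'}",
        classes=[str(c) for c in np.unique([labels[str(i)] for i in features.compound_ids])],
        train_ids=train_ids,
        train_predictions={i: str(p) for i, p in zip(train_ids, train_pred)},
        metadata={"cv_score": best.cv_score, "test_score": best.test_score},
    )
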