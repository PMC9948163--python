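"""Multiclass QSAR bench: balancing, feature selection, CV, 12 classifiers.

The modeling protocol: random oversampling equalises the four activity
classes to the majority-class size (seeded, with-replacement copies);
fingerprint bits with variance below 0.1 or absolute pairwise correlation
above 0.95 are removed; the data are split 80:20 (stratified) with
10-fold cross-validation inside the training portion; twelve
classification algorithms, each wrapped one-vs-rest, are compared on
accuracy, macro-averaged recall, and the multiclass (R_K) Matthews
correlation coefficient.

Two orders of operations are supported. ``mode="safe"`` (default) splits
first and oversamples only inside the training portion and inside each CV
training fold, so no molecule is duplicated across a train/evaluation
boundary. ``mode="paper-parity"`` oversamples and selects features on the
full dataset before splitting — a protocol still common in the
literature, kept for comparability; its test scores are optimistically
biased because duplicated molecules can straddle the split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.multiclass import OneVsRestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ChemLandscapeError
from .fingerprints import fingerprint_matrix
from .io_curation import ActivityClass, CuratedMolecule

logger = logging.getLogger(__name__)

CLASS_ORDER = [c.value for c in ActivityClass]


@dataclass
class Metrics:
    accuracy: float
    recall: float
    mcc: float


@dataclass
class ModelReport:
    algorithm: str
    train: Optional[Metrics] = None
    cv: Optional[Metrics] = None
    test: Optional[Metrics] = None
    failed: bool = False
    message: str = ""


@dataclass
class FeatureSelection:
    """Retained-column record; re-applicable to new data."""

    retained: list[str]
    n_input: int
    n_after_variance: int
    n_after_correlation: int

    def apply(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.retained]


@dataclass
class SplitPlan:
    train_idx: np.ndarray
    test_idx: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# featurisation


def feature_matrix(
    curated: Sequence[CuratedMolecule], kind: str = "pubchem"
) -> tuple[pd.DataFrame, pd.Series]:
    """Fingerprint bit matrix (rows = molecules) and class label vector."""
    fps = fingerprint_matrix([m.smiles for m in curated], kind)
    ids = [m.molecule_id for m in curated]
    X = pd.DataFrame(
        fps.astype(np.uint8),
        index=ids,
        columns=[f"{kind}_{i}" for i in range(fps.shape[1])],
    )
    y = pd.Series(
        [m.activity_class.value for m in curated], index=ids, name="activity_class"
    )
    return X, y


# ---------------------------------------------------------------------------
# oversampling


def _oversample_indices(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a random-oversampled set: originals plus sampled copies."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    target = counts.max()
    out = [np.arange(len(labels))]
    for cls, count in zip(classes, counts):
        if count < target:
            members = np.flatnonzero(labels == cls)
            out.append(rng.choice(members, size=target - count, replace=True))
    return np.concatenate(out)


def oversample(
    curated: Sequence[CuratedMolecule], seed: int = 42
) -> list[CuratedMolecule]:
    """Duplicate random molecules until every activity class matches the
    majority class size. Every original molecule is retained."""
    labels = np.array([m.activity_class.value for m in curated])
    for cls in np.unique(labels):
        if (labels == cls).sum() == 0:  # pragma: no cover
            raise ChemLandscapeError(f"class {cls} is empty")
    if len(curated) == 0:
        raise ChemLandscapeError("cannot oversample an empty set")
    rng = np.random.default_rng(seed)
    idx = _oversample_indices(labels, rng)
    return [curated[int(i)] for i in idx]


# ---------------------------------------------------------------------------
# feature selection


def select_features(
    X: pd.DataFrame, var_min: float = 0.1, corr_max: float = 0.95
) -> tuple[pd.DataFrame, FeatureSelection]:
    """Two-stage filter: drop low-variance bits, then the later member of
    any highly correlated pair (|r| > corr_max, scanning columns in order).

    For binary columns the Pearson r equals the phi coefficient; it is
    computed directly from the 0/1 matrix.
    """
    if len(X) < 2:
        raise ChemLandscapeError("feature selection needs at least two rows")
    values = X.to_numpy(dtype=float)
    variances = values.var(axis=0)  # population variance, VarianceThreshold-style
    var_keep = variances >= var_min
    n_after_var = int(var_keep.sum())
    if n_after_var == 0:
        raise ChemLandscapeError("all features removed by the variance filter")

    kept_cols = np.flatnonzero(var_keep)
    V = values[:, kept_cols]
    Z = (V - V.mean(axis=0)) / V.std(axis=0)
    corr = (Z.T @ Z) / len(V)

    retained_local: list[int] = []
    for j in range(V.shape[1]):
        if any(abs(corr[j, k]) > corr_max for k in retained_local):
            continue
        retained_local.append(j)
    retained = [X.columns[kept_cols[j]] for j in retained_local]
    if not retained:  # pragma: no cover - variance stage guards this
        raise ChemLandscapeError("all features removed")
    selection = FeatureSelection(
        retained=retained,
        n_input=X.shape[1],
        n_after_variance=n_after_var,
        n_after_correlation=len(retained),
    )
    return X[retained], selection


# ---------------------------------------------------------------------------
# splitting


def split_and_cv(
    labels: Sequence[str],
    test_frac: float = 0.2,
    folds: int = 10,
    seed: int = 42,
) -> SplitPlan:
    """Stratified 80:20 split plus stratified k-fold CV inside training.

    ``folds=0`` skips cross-validation.
    """
    labels = np.asarray(labels)
    idx = np.arange(len(labels))
    try:
        train_idx, test_idx = train_test_split(
            idx,
            test_size=test_frac,
            stratify=labels,
            random_state=seed,
            shuffle=True,
        )
    except ValueError as exc:
        raise ChemLandscapeError(f"stratified split failed: {exc}") from exc
    plan = SplitPlan(train_idx=np.sort(train_idx), test_idx=np.sort(test_idx))
    if folds:
        _, counts = np.unique(labels[plan.train_idx], return_counts=True)
        if counts.min() < folds:
            raise ChemLandscapeError(
                f"smallest class has {counts.min()} training members; "
                f"use fewer than {folds} folds"
            )
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        plan.folds = [
            (plan.train_idx[tr], plan.train_idx[va])
            for tr, va in skf.split(plan.train_idx, labels[plan.train_idx])
        ]
    return plan


# ---------------------------------------------------------------------------
# metrics


def metrics(confusion: np.ndarray) -> Metrics:
    """Accuracy, macro recall and multiclass MCC from a confusion matrix.

    The MCC is the R_K statistic computed from the full K x K matrix; it
    reduces to the familiar binary MCC for K = 2. A class absent from the
    evaluation set contributes recall 0 (logged).
    """
    C = np.asarray(confusion, dtype=float)
    total = C.sum()
    if total == 0:
        raise ChemLandscapeError("empty confusion matrix")
    accuracy = np.trace(C) / total

    row_sums = C.sum(axis=1)
    recalls = np.zeros(len(C))
    present = row_sums > 0
    recalls[present] = np.diag(C)[present] / row_sums[present]
    if not present.all():
        logger.info("empty class in confusion matrix contributes recall 0")
    macro_recall = recalls.mean()

    t = C.sum(axis=1)  # true counts
    p = C.sum(axis=0)  # predicted counts
    c = np.trace(C)
    s = total
    denom = np.sqrt(s**2 - (p**2).sum()) * np.sqrt(s**2 - (t**2).sum())
    mcc = 0.0 if denom == 0 else float((c * s - t @ p) / denom)
    return Metrics(accuracy=float(accuracy), recall=float(macro_recall), mcc=mcc)


def _evaluate(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    labels = [c for c in CLASS_ORDER if c in set(y_true) | set(y_pred)]
    return metrics(confusion_matrix(y_true, y_pred, labels=labels))


# ---------------------------------------------------------------------------
# the 12-algorithm bench


def build_bench(
    seed: int = 42, n_estimators: int = 500, algorithms: Optional[Sequence[str]] = None
) -> dict[str, object]:
    """The twelve-classifier bench with its fixed hyperparameters.

    Tree/ensemble methods use ``n_estimators`` trees (default 500) and a
    fixed random state; random forest uses max_features=3 with the Gini
    criterion; the MLP uses one hidden layer of 100 units; the remaining
    algorithms keep library defaults.
    """
    from lightgbm import LGBMClassifier
    from xgboost import XGBClassifier

    bench = {
        "DT": DecisionTreeClassifier(random_state=seed),
        "ET": ExtraTreesClassifier(n_estimators=n_estimators, random_state=seed),
        "RF": RandomForestClassifier(
            n_estimators=n_estimators,
            max_features=3,
            criterion="gini",
            random_state=seed,
        ),
        "GB": GradientBoostingClassifier(
            n_estimators=n_estimators, random_state=seed
        ),
        "LGBM": LGBMClassifier(
            n_estimators=n_estimators, random_state=seed, verbosity=-1
        ),
        "XGB": XGBClassifier(
            n_estimators=n_estimators, random_state=seed, verbosity=0
        ),
        "MLP": MLPClassifier(hidden_layer_sizes=(100,), random_state=seed),
        "LR": LogisticRegression(random_state=seed),
        "KNN": KNeighborsClassifier(),
        "SVM": SVC(random_state=seed),
        "NB": GaussianNB(),
        "GP": GaussianProcessClassifier(random_state=seed),
    }
    if algorithms is not None:
        unknown = set(algorithms) - set(bench)
        if unknown:
            raise ChemLandscapeError(f"unknown algorithm(s): {sorted(unknown)}")
        bench = {k: bench[k] for k in algorithms}
    return bench


ENSEMBLE_ALGORITHMS = ("ET", "RF", "GB", "LGBM", "XGB")


def _fit_predict(estimator, X_tr, y_tr, X_ev):
    est = OneVsRestClassifier(clone(estimator))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X_tr, y_tr)
        return est.predict(X_ev)


def train_bench(
    X: pd.DataFrame,
    y: pd.Series,
    plan: SplitPlan,
    mode: str = "safe",
    seed: int = 42,
    n_estimators: int = 500,
    algorithms: Optional[Sequence[str]] = None,
) -> list[ModelReport]:
    """Fit every bench algorithm and report train / CV-mean / test metrics.

    In safe mode the training portion (and each CV training fold) is
    oversampled independently; evaluation rows are never duplicated. In
    paper-parity mode the incoming matrix is assumed balanced already.
    An algorithm that raises is reported as failed and the bench continues.
    """
    if mode not in ("safe", "paper-parity"):
        raise ChemLandscapeError(f"unknown mode: {mode!r}")
    bench = build_bench(seed=seed, n_estimators=n_estimators, algorithms=algorithms)
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy()
    rng = np.random.default_rng(seed)

    def training_rows(idx):
        if mode == "safe":
            local = _oversample_indices(yv[idx], rng)
            return idx[local]
        return idx

    # class codes: xgboost needs integer labels
    code_of = {c: i for i, c in enumerate(CLASS_ORDER)}
    yc = np.array([code_of[v] for v in yv])
    decode = np.array(CLASS_ORDER)

    fit_tr = training_rows(plan.train_idx)
    fold_rows = [(training_rows(tr), va) for tr, va in plan.folds]

    reports = []
    for name, estimator in bench.items():
        report = ModelReport(algorithm=name)
        try:
            pred_tr = _fit_predict(
                estimator, Xv[fit_tr], yc[fit_tr], Xv[plan.train_idx]
            )
            report.train = _evaluate(yv[plan.train_idx], decode[pred_tr])
            pred_te = _fit_predict(
                estimator, Xv[fit_tr], yc[fit_tr], Xv[plan.test_idx]
            )
            report.test = _evaluate(yv[plan.test_idx], decode[pred_te])
            if fold_rows:
                fold_metrics = []
                for tr, va in fold_rows:
                    pred = _fit_predict(estimator, Xv[tr], yc[tr], Xv[va])
                    fold_metrics.append(_evaluate(yv[va], decode[pred]))
                report.cv = Metrics(
                    accuracy=float(np.mean([m.accuracy for m in fold_metrics])),
                    recall=float(np.mean([m.recall for m in fold_metrics])),
                    mcc=float(np.mean([m.mcc for m in fold_metrics])),
                )
        except Exception as exc:  # noqa: BLE001 - bench must continue
            report.failed = True
            report.message = str(exc)
            logger.warning("algorithm %s failed: %s", name, exc)
        reports.append(report)
    return reports


def reports_frame(reports: Sequence[ModelReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {"algorithm": r.algorithm, "failed": r.failed}
        for phase in ("train", "cv", "test"):
            m = getattr(r, phase)
            row[f"{phase}_accuracy"] = m.accuracy if m else np.nan
            row[f"{phase}_recall"] = m.recall if m else np.nan
            row[f"{phase}_mcc"] = m.mcc if m else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class QSARResult:
    reports: list[ModelReport]
    selection: FeatureSelection
    plan: SplitPlan
    majority_baseline: float  # test accuracy of always predicting the
    # training majority class
    mode: str = "safe"

    def best(self, ensembles_only: bool = False) -> ModelReport:
        pool = [
            r
            for r in self.reports
            if not r.failed
            and (not ensembles_only or r.algorithm in ENSEMBLE_ALGORITHMS)
        ]
        if not pool:
            raise ChemLandscapeError("no successful model in the bench")
        return max(pool, key=lambda r: r.test.accuracy)


def run_qsar(
    curated: Sequence[CuratedMolecule],
    kind: str = "pubchem",
    mode: str = "safe",
    seed: int = 42,
    test_frac: float = 0.2,
    folds: int = 10,
    var_min: float = 0.1,
    corr_max: float = 0.95,
    n_estimators: int = 500,
    algorithms: Optional[Sequence[str]] = None,
) -> QSARResult:
    """Featurize, balance, select, split and run the classifier bench."""
    if mode == "paper-parity":
        working = oversample(list(curated), seed=seed)
    else:
        working = list(curated)
    X, y = feature_matrix(working, kind)
    plan = split_and_cv(y.to_numpy(), test_frac=test_frac, folds=folds, seed=seed)

    if mode == "paper-parity":
        X_sel, selection = select_features(X, var_min, corr_max)
    else:
        _, selection = select_features(X.iloc[plan.train_idx], var_min, corr_max)
        X_sel = selection.apply(X)

    yv = y.to_numpy()
    classes, counts = np.unique(yv[plan.train_idx], return_counts=True)
    majority = classes[counts.argmax()]
    baseline = float((yv[plan.test_idx] == majority).mean())

    reports = train_bench(
        X_sel,
        y,
        plan,
        mode=mode,
        seed=seed,
        n_estimators=n_estimators,
        algorithms=algorithms,
    )
    return QSARResult(
        reports=reports,
        selection=selection,
        plan=plan,
        majority_baseline=baseline,
        mode=mode,
    )
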