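"""Supervised-learning protocol for conduction-abnormality prediction.

The protocol mirrors the published analysis: one-hot encoding of the device
category and 0–1 min-max scaling of the seven numeric features (scaling
parameters learned on training rows only), a correlation screen that drops one
member of any highly correlated numeric pair, a 70–30 outcome-stratified split
constrained to contain all three device categories in both partitions,
five-fold cross-validated tuning of eight base classifiers, homogeneous
bootstrap-aggregated (bagging) ensembles of each base learner plus a mixed
majority-vote ensemble, evaluation of every model on the held-out set
(confusion counts at the 0.5 score threshold, sensitivity/specificity/PPV/NPV,
F1 as the harmonic mean of PPV and sensitivity, ROC/AUC with a stratified
bootstrap confidence interval), and accuracy-based model selection.

`CohortPreprocessor`, `BaggedEnsemble` and `MajorityVoteClassifier` are
scikit-learn estimators and compose with sklearn pipelines and model
selection; the `run_*` functions are thin orchestration over them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

from .synth import DEVICE_TYPES, FEATURE_COLUMNS, NUMERIC_FEATURES

__all__ = [
    "CohortPreprocessor",
    "preprocess",
    "correlation_screen",
    "split_cohort",
    "BASE_ALGORITHMS",
    "train_base",
    "continuous_score",
    "BaggedEnsemble",
    "MajorityVoteClassifier",
    "EvaluationReport",
    "evaluate",
    "select_best",
    "ProtocolResult",
    "run_protocol",
    "run_primary",
    "run_ablation",
    "run_subcohort_lbbb",
    "filter_ppi",
]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

class CohortPreprocessor(BaseEstimator, TransformerMixin):
    """One-hot device encoding + min-max scaling of numeric features.

    Scaling parameters (per-column training min/max) are learned in ``fit``
    and applied without clipping, so out-of-range validation values may map
    outside [0, 1]. A constant training column is scaled to 0 with a warning.
    """

    def __init__(self, numeric_features=None, device_column="device_type"):
        self.numeric_features = numeric_features
        self.device_column = device_column

    def fit(self, X: pd.DataFrame, y=None):
        numeric = list(self.numeric_features or [c for c in NUMERIC_FEATURES if c in X.columns])
        missing = [c for c in numeric + [self.device_column] if c not in X.columns]
        if missing:
            raise ValueError(f"cohort is missing required feature column(s): {missing}")
        self.numeric_features_ = numeric
        self.scaler_ = MinMaxScaler().fit(X[numeric].to_numpy(dtype=float))
        constant = [c for c, rng in zip(numeric, self.scaler_.data_range_) if rng == 0]
        if constant:
            warnings.warn(
                f"constant training column(s) scaled to 0: {constant}", UserWarning
            )
        self.feature_names_out_ = [
            f"device_{d}" for d in DEVICE_TYPES
        ] + list(numeric)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "scaler_")
        unknown = set(X[self.device_column]) - set(DEVICE_TYPES)
        if unknown:
            raise ValueError(f"unknown device categories: {sorted(unknown)}")
        onehot = np.column_stack(
            [(X[self.device_column] == d).to_numpy(dtype=float) for d in DEVICE_TYPES]
        )
        scaled = self.scaler_.transform(X[self.numeric_features_].to_numpy(dtype=float))
        return pd.DataFrame(
            np.hstack([onehot, scaled]), columns=self.feature_names_out_, index=X.index
        )


def preprocess(
    cohort: pd.DataFrame, training_row_ids, numeric_features=None
) -> tuple[pd.DataFrame, CohortPreprocessor]:
    """Fit the preprocessor on the training rows, apply it to the whole cohort."""
    prep = CohortPreprocessor(numeric_features=numeric_features)
    prep.fit(cohort.loc[training_row_ids])
    return prep.transform(cohort), prep


def correlation_screen(matrix: pd.DataFrame, threshold: float = 0.9) -> list[str]:
    """Greedily drop one member of any numeric pair with |Pearson r| > threshold."""
    cols = list(matrix.columns)
    if len(cols) < 2:
        raise ValueError("correlation screen needs at least two columns")
    corr = matrix.corr().abs().to_numpy()
    dropped: set[str] = set()
    for i in range(len(cols)):
        if cols[i] in dropped:
            continue
        for j in range(i + 1, len(cols)):
            if cols[j] in dropped:
                continue
            if corr[i, j] > threshold:
                dropped.add(cols[j])
    return [c for c in cols if c not in dropped]


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------

def split_cohort(
    cohort: pd.DataFrame,
    ratio: float = 0.7,
    seed: int = 0,
    outcome: str = "ca",
    device_column: str = "device_type",
    max_tries: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Outcome-stratified train/validation split with the device-presence constraint.

    ``|train| = round(ratio * n)``; each of the three device categories must be
    present in both partitions (enforced by redrawing). Returns disjoint,
    exhaustive index arrays (cohort index labels), reproducible by seed.
    """
    n = len(cohort)
    counts = cohort[device_column].value_counts()
    thin = [d for d in counts.index if counts[d] < 2]
    if thin:
        raise ValueError(f"device categories with < 2 members cannot be split: {thin}")
    n_train = int(round(ratio * n))
    y = cohort[outcome].to_numpy()
    idx = cohort.index.to_numpy()

    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        train_parts = []
        # proportional allocation per outcome class, largest remainder
        classes = np.unique(y)
        quotas = {c: n_train * (y == c).sum() / n for c in classes}
        base = {c: int(np.floor(q)) for c, q in quotas.items()}
        remainder = n_train - sum(base.values())
        for c in sorted(classes, key=lambda c: quotas[c] - base[c], reverse=True):
            if remainder <= 0:
                break
            base[c] += 1
            remainder -= 1
        for c in classes:
            members = idx[y == c]
            perm = rng.permutation(members)
            train_parts.append(perm[: base[c]])
        train_ids = np.sort(np.concatenate(train_parts))
        val_ids = np.setdiff1d(idx, train_ids)
        dev_train = set(cohort.loc[train_ids, device_column])
        dev_val = set(cohort.loc[val_ids, device_column])
        present = set(counts.index)
        if dev_train >= present and dev_val >= present:
            return train_ids, val_ids
    raise RuntimeError("could not satisfy the device-presence constraint")


# ---------------------------------------------------------------------------
# base classifiers
# ---------------------------------------------------------------------------

def _base_registry(seed: int) -> dict:
    """The eight base classification algorithms with their small tuning grids."""
    return {
        "knn": (KNeighborsClassifier(), {"n_neighbors": [3, 5, 7, 9, 11]}),
        "logreg": (
            LogisticRegression(max_iter=2000),
            {"C": [0.1, 1.0, 10.0]},
        ),
        "svc": (SVC(kernel="rbf", gamma="scale", cache_size=300), {"C": [1.0, 10.0]}),
        "gnb": (GaussianNB(), {"var_smoothing": [1e-9]}),
        "sgd_svm": (
            SGDClassifier(loss="hinge", random_state=seed),
            {"alpha": [1e-4, 1e-3, 1e-2]},
        ),
        "xgb": (
            XGBClassifier(
                n_estimators=100, tree_method="hist", eval_metric="logloss",
                random_state=seed, n_jobs=1, verbosity=0,
            ),
            {"max_depth": [2, 4]},
        ),
        "dtree": (
            DecisionTreeClassifier(random_state=seed),
            {"max_depth": [3, 5, None]},
        ),
        "rforest": (
            RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1),
            {"min_samples_leaf": [1, 5]},
        ),
    }


BASE_ALGORITHMS = tuple(_base_registry(0))

MODEL_LABELS = {
    "knn": "K-Nearest Neighbours",
    "logreg": "Logistic Regression",
    "svc": "C-Support Vector Classification",
    "gnb": "Gaussian Naive-Bayes",
    "sgd_svm": "Support Vector Machine + SGD",
    "xgb": "Extreme Gradient Boosting",
    "dtree": "Decision Tree",
    "rforest": "Random Forest",
}


def train_base(X_train, y_train, algorithm_id: str, seed: int = 0, cv: int = 5):
    """Tune one base classifier by ``cv``-fold cross-validated accuracy.

    Returns ``(fitted_best_estimator, cv_accuracy)``.
    """
    registry = _base_registry(seed)
    if algorithm_id not in registry:
        raise KeyError(f"unknown algorithm id: {algorithm_id!r} (known: {sorted(registry)})")
    est, grid = registry[algorithm_id]
    search = GridSearchCV(
        est, grid,
        scoring="accuracy",
        cv=StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed),
        refit=True, n_jobs=1,
    )
    search.fit(np.asarray(X_train, dtype=float), np.asarray(y_train))
    return search.best_estimator_, float(search.best_score_)


def continuous_score(model, X) -> np.ndarray:
    """Continuous positive-class score in [0, 1] for any fitted classifier.

    Probability when the model provides one, otherwise a logistic squash of
    the decision margin (monotone, so ROC-equivalent), with the 0.5 threshold
    mapping to the decision boundary.
    """
    X = np.asarray(X, dtype=float)
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(X))[:, 1]
    if hasattr(model, "decision_function"):
        return expit(np.asarray(model.decision_function(X), dtype=float))
    return np.asarray(model.predict(X), dtype=float)


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

class BaggedEnsemble(BaseEstimator, ClassifierMixin):
    """Homogeneous bootstrap-aggregated ensemble of one base learner.

    Fits ``n_estimators`` clones on bootstrap resamples of the training set
    (resample size = training size); the ensemble score is the mean of the
    members' continuous scores and labels are assigned at the 0.5 threshold.
    With ``n_estimators=1`` and ``bootstrap=False`` the ensemble degenerates
    to the base classifier.
    """

    def __init__(self, estimator=None, n_estimators: int = 50, bootstrap: bool = True,
                 random_state=None):
        self.estimator = estimator
        self.n_estimators = n_estimators
        self.bootstrap = bootstrap
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        self.classes_ = np.unique(y)
        self.estimators_ = []
        n = len(y)
        for _ in range(self.n_estimators):
            if self.bootstrap:
                while True:
                    take = rng.integers(0, n, size=n)
                    if len(np.unique(y[take])) == len(self.classes_):
                        break
            else:
                take = np.arange(n)
            member = clone(self.estimator)
            member.fit(X[take], y[take])
            self.estimators_.append(member)
        return self

    def predict_score(self, X) -> np.ndarray:
        check_is_fitted(self, "estimators_")
        return np.mean([continuous_score(m, X) for m in self.estimators_], axis=0)

    def predict_proba(self, X) -> np.ndarray:
        s = self.predict_score(X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X) -> np.ndarray:
        return (self.predict_score(X) >= 0.5).astype(int)


class MajorityVoteClassifier(BaseEstimator, ClassifierMixin):
    """Mixed ensemble: unweighted majority vote over pre-fitted classifiers.

    Ties are broken toward the positive class. The continuous score is the
    fraction of positive votes.
    """

    def __init__(self, estimators=None):
        self.estimators = estimators

    def fit(self, X=None, y=None):
        if self.estimators is None or len(self.estimators) < 2:
            raise ValueError("voting requires at least two fitted classifiers")
        self.estimators_ = list(self.estimators)
        self.classes_ = np.array([0, 1])
        return self

    def _votes(self, X) -> np.ndarray:
        check_is_fitted(self, "estimators_")
        return np.mean(
            [(continuous_score(m, X) >= 0.5).astype(float) for m in self.estimators_],
            axis=0,
        )

    def predict_score(self, X) -> np.ndarray:
        return self._votes(X)

    def predict_proba(self, X) -> np.ndarray:
        s = self._votes(X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X) -> np.ndarray:
        return (self._votes(X) >= 0.5).astype(int)  # >= breaks ties toward CA


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Held-out performance of one model."""

    model_id: str
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float
    auc: float
    auc_ci: tuple[float, float]
    roc_fpr: np.ndarray = field(repr=False, default=None)
    roc_tpr: np.ndarray = field(repr=False, default=None)
    cv_accuracy: float | None = None


def _safe_div(a: float, b: float) -> float:
    return a / b if b > 0 else float("nan")


def f1_score_from(ppv: float, sensitivity: float) -> float:
    """F1 as the harmonic mean of PPV and sensitivity."""
    if ppv + sensitivity == 0 or np.isnan(ppv) or np.isnan(sensitivity):
        return float("nan")
    return 2.0 * ppv * sensitivity / (ppv + sensitivity)


def auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def evaluate(
    model, X_val, y_val, model_id: str = "model",
    n_boot: int = 2000, seed: int = 0, cv_accuracy: float | None = None,
) -> EvaluationReport:
    """Confusion counts at the 0.5 score threshold, derived metrics and ROC/AUC.

    The AUC 95% CI is a stratified percentile bootstrap over ``n_boot``
    resamples of the validation set.
    """
    y = np.asarray(y_val).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("validation set must contain both classes; metrics undefined")
    score = (
        model.predict_score(X_val)
        if hasattr(model, "predict_score")
        else continuous_score(model, X_val)
    )
    pred = (score >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    ppv = _safe_div(tp, tp + fp)
    npv = _safe_div(tn, tn + fn)
    fpr, tpr, _ = roc_curve(y, score)
    auc = auc_trapezoid(fpr, tpr)

    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate([
            rng.choice(pos, size=pos.size, replace=True),
            rng.choice(neg, size=neg.size, replace=True),
        ])
        f, t, _ = roc_curve(y[take], score[take])
        boots[b] = auc_trapezoid(f, t)
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))

    return EvaluationReport(
        model_id=model_id, tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / len(y),
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        f1=f1_score_from(ppv, sens),
        auc=auc, auc_ci=ci, roc_fpr=fpr, roc_tpr=tpr,
        cv_accuracy=cv_accuracy,
    )


def select_best(reports) -> str:
    """Accuracy-selected model id; ties broken by CV accuracy, AUC, then id."""
    if isinstance(reports, dict):
        items = list(reports.values())
    else:
        items = list(reports)
    if not items:
        raise ValueError("no reports to select from")

    def key(r: EvaluationReport):
        cv = r.cv_accuracy if r.cv_accuracy is not None else 0.0
        return (r.accuracy, cv, r.auc, tuple(-ord(c) for c in r.model_id))

    return max(items, key=key).model_id


# ---------------------------------------------------------------------------
# the full protocol
# ---------------------------------------------------------------------------

@dataclass
class ProtocolResult:
    """Output of one full protocol run."""

    outcome: str
    reports: dict
    selected_id: str
    retained_features: list
    train_ids: np.ndarray
    val_ids: np.ndarray

    @property
    def selected_report(self) -> EvaluationReport:
        return self.reports[self.selected_id]

    def summary_table(self, top: int = 4) -> pd.DataFrame:
        """Headline-metric table for the ``top`` most accurate models."""
        rows = sorted(
            self.reports.values(),
            key=lambda r: (r.accuracy, r.auc),
            reverse=True,
        )[:top]
        return pd.DataFrame(
            [
                {
                    "model": r.model_id,
                    "accuracy": r.accuracy,
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "ppv": r.ppv,
                    "npv": r.npv,
                    "f1": r.f1,
                    "auc": r.auc,
                    "auc_ci_low": r.auc_ci[0],
                    "auc_ci_high": r.auc_ci[1],
                }
                for r in rows
            ]
        )


def run_protocol(
    cohort: pd.DataFrame,
    seed: int,
    outcome: str = "ca",
    features: list | None = None,
    n_bagging: int = 50,
    algorithms=None,
    n_boot: int = 2000,
    cv: int = 5,
    corr_threshold: float = 0.9,
) -> ProtocolResult:
    """Preprocess, screen, split, tune, ensemble, evaluate and select."""
    feats = list(features or FEATURE_COLUMNS)
    missing = [c for c in feats + [outcome] if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing required column(s): {missing}")

    numeric = [f for f in feats if f != "device_type"]
    retained_numeric = correlation_screen(cohort[numeric], threshold=corr_threshold)
    retained = [f for f in feats if f == "device_type" or f in retained_numeric]

    seeds = np.random.SeedSequence(seed).generate_state(4 + 2 * len(BASE_ALGORITHMS))
    seeds = [int(s & 0x7FFFFFFF) for s in seeds]
    train_ids, val_ids = split_cohort(cohort, 0.7, seed=seeds[0], outcome=outcome)

    X_all, _prep = preprocess(cohort, train_ids, numeric_features=retained_numeric)
    X_tr = X_all.loc[train_ids].to_numpy(dtype=float)
    y_tr = cohort.loc[train_ids, outcome].to_numpy(dtype=int)
    X_va = X_all.loc[val_ids].to_numpy(dtype=float)
    y_va = cohort.loc[val_ids, outcome].to_numpy(dtype=int)

    algo_ids = list(algorithms or BASE_ALGORITHMS)
    reports: dict[str, EvaluationReport] = {}
    tuned = {}
    for k, algo in enumerate(algo_ids):
        base, cv_acc = train_base(X_tr, y_tr, algo, seed=seeds[2 + k], cv=cv)
        tuned[algo] = (base, cv_acc)
        reports[algo] = evaluate(
            base, X_va, y_va, model_id=algo, n_boot=n_boot, seed=seeds[1],
            cv_accuracy=cv_acc,
        )
        bag = BaggedEnsemble(
            estimator=clone(base), n_estimators=n_bagging,
            random_state=seeds[2 + len(algo_ids) + k],
        ).fit(X_tr, y_tr)
        reports[f"bag_{algo}"] = evaluate(
            bag, X_va, y_va, model_id=f"bag_{algo}", n_boot=n_boot, seed=seeds[1]
        )
    if len(tuned) >= 2:
        voter = MajorityVoteClassifier([b for b, _ in tuned.values()]).fit()
        reports["voting"] = evaluate(
            voter, X_va, y_va, model_id="voting", n_boot=n_boot, seed=seeds[1]
        )

    return ProtocolResult(
        outcome=outcome,
        reports=reports,
        selected_id=select_best(reports),
        retained_features=retained,
        train_ids=train_ids,
        val_ids=val_ids,
    )


def run_primary(cohort: pd.DataFrame, seed: int, **kwargs) -> ProtocolResult:
    """Full protocol on the composite CA outcome with all eight features."""
    return run_protocol(cohort, seed, outcome="ca", **kwargs)


def run_ablation(cohort: pd.DataFrame, seed: int, **kwargs) -> ProtocolResult:
    """Identical protocol with the two mechanistic features (Cpmax, CPI) removed."""
    feats = [f for f in FEATURE_COLUMNS if f not in ("cpmax", "cpi")]
    return run_protocol(cohort, seed, outcome="ca", features=feats, **kwargs)


def filter_ppi(cohort: pd.DataFrame) -> pd.DataFrame:
    """Rows of patients who did not receive a pacemaker."""
    if "ppi" not in cohort.columns:
        raise ValueError("cohort has no 'ppi' column")
    return cohort[cohort["ppi"] == 0]


def run_subcohort_lbbb(cohort: pd.DataFrame, seed: int, **kwargs) -> ProtocolResult:
    """Re-trained protocol predicting new L/RBBB in the pacemaker-free sub-cohort."""
    if "lbbb_rbbb" not in cohort.columns:
        raise ValueError("cohort has no 'lbbb_rbbb' column")
    sub = filter_ppi(cohort)
    return run_protocol(sub, seed, outcome="lbbb_rbbb", **kwargs)
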