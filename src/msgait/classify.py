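"""Feature-based fall-risk classification under leave-one-subject-out CV.

Per fold: z-scoring and PCA (smallest component count explaining >= 95% of
variance) are fit on the training rows only, then one of five classifier
families (logistic regression, SVM, decision tree, k-NN, tree ensemble)
scores every bout of the held-out subject.  Pooled held-out decision scores
give the per-input AUC; per-subject median scores give the aggregated AUC.
The positive class is "faller" throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURES_BY_CLASS
from .types import MsgaitError, UndefinedFeatureError

log = logging.getLogger("msgait")

MODEL_FAMILIES = ("LR", "SVM", "tree", "KNN", "ensemble")


@dataclass
class ClassifierOutcome:
    scores: pd.DataFrame  # subject_id, score, label, fold
    auc_per_input: float
    auc_subject_median: float
    per_fold: list = field(default_factory=list)
    model_family: str = ""
    feature_set: str = ""


def compute_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney pair statistic (ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedFeatureError("AUC needs both classes")
    ranks = _stats.rankdata(scores)  # average ranks handle ties as 1/2
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def build_feature_matrix(param_table: pd.DataFrame, selector: str, cohort: pd.DataFrame):
    """Select rows and columns for one feature set.

    Selectors: short / medium / long (home bouts of that class), all_home
    (every home bout, base 8 features), lab.  Returns (X DataFrame,
    y array, subject_ids array); rows with any missing feature are dropped
    with a log line.
    """
    if selector not in FEATURES_BY_CLASS:
        raise MsgaitError(f"unknown selector {selector!r}")
    feats = FEATURES_BY_CLASS[selector]
    if selector == "lab":
        rows = param_table[param_table["context"] == "lab"]
    elif selector == "all_home":
        rows = param_table[param_table["context"] == "home"]
    else:
        rows = param_table[
            (param_table["context"] == "home") & (param_table["duration_class"] == selector)
        ]
    if rows.empty:
        raise MsgaitError(f"no rows for selector {selector!r}")
    X = rows[feats + ["subject_id"]].copy()
    n_before = len(X)
    X = X.dropna()
    if len(X) < n_before:
        log.info("feature matrix %s: dropped %d rows with missing features",
                 selector, n_before - len(X))
    if X.empty:
        raise MsgaitError(f"all rows for {selector!r} had missing features")
    label_map = cohort.set_index("subject_id")["fall_label"]
    subject_ids = X.pop("subject_id").to_numpy()
    y = (pd.Series(subject_ids).map(label_map) == "faller").to_numpy(dtype=int)
    return X, y, subject_ids


def _make_model(family: str, seed: int, params: dict | None = None):
    params = params or {}
    if family == "LR":
        return LogisticRegression(max_iter=2000, random_state=seed, **params)
    if family == "SVM":
        return SVC(probability=True, random_state=seed, **params)
    if family == "tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if family == "KNN":
        return KNeighborsClassifier(**params)
    if family == "ensemble":
        return RandomForestClassifier(n_estimators=params.pop("n_estimators", 100),
                                      random_state=seed, **params)
    raise MsgaitError(f"unknown model family {family!r}")


def _sample_params(family: str, rng: np.random.Generator) -> dict:
    if family == "LR":
        return {"C": float(10 ** rng.uniform(-3, 3))}
    if family == "SVM":
        return {"C": float(10 ** rng.uniform(-2, 3)), "gamma": float(10 ** rng.uniform(-3, 1))}
    if family == "tree":
        return {"max_depth": int(rng.integers(1, 10)),
                "min_samples_leaf": int(rng.integers(1, 20))}
    if family == "KNN":
        return {"n_neighbors": int(rng.integers(1, 30)),
                "weights": str(rng.choice(["uniform", "distance"]))}
    if family == "ensemble":
        return {"n_estimators": int(rng.integers(20, 200)),
                "max_depth": int(rng.integers(2, 10))}
    raise MsgaitError(f"unknown model family {family!r}")


def _fit_fold(X_tr, y_tr, family, seed, pca_variance, params=None):
    model = _make_model(family, seed, params)
    if isinstance(model, KNeighborsClassifier):
        model.n_neighbors = min(model.n_neighbors, len(X_tr))
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("pca", PCA(n_components=min(pca_variance, 1.0 - 1e-12), svd_solver="full",
                        random_state=seed)),
            ("model", model),
        ]
    )
    pipe.fit(X_tr, y_tr)
    return pipe


def _tune(X_tr, y_tr, groups, family, seed, pca_variance, n_search):
    """Seeded random search scored by grouped inner-CV AUC."""
    rng = np.random.default_rng(seed)
    n_groups = len(np.unique(groups))
    n_splits = min(3, n_groups)
    best_params, best_auc = None, -np.inf
    for _ in range(n_search):
        params = _sample_params(family, rng)
        scores, labels = [], []
        try:
            for tr, va in GroupKFold(n_splits=n_splits).split(X_tr, y_tr, groups):
                if len(np.unique(y_tr[tr])) < 2 or len(np.unique(y_tr[va])) < 2:
                    continue
                pipe = _fit_fold(X_tr.iloc[tr], y_tr[tr], family, seed, pca_variance,
                                 dict(params))
                scores.append(pipe.predict_proba(X_tr.iloc[va])[:, 1])
                labels.append(y_tr[va])
        except Exception:  # a pathological draw must not kill the fold
            continue
        if not scores:
            continue
        auc = compute_auc(np.concatenate(scores), np.concatenate(labels))
        if auc > best_auc:
            best_auc, best_params = auc, params
    return best_params


def loso_feature_classifiers(
    X: pd.DataFrame,
    y: np.ndarray,
    subject_ids: np.ndarray,
    model_family: str = "LR",
    pca_variance: float = 0.95,
    seed: int = 0,
    n_search: int = 0,
    feature_set: str = "",
) -> ClassifierOutcome:
    """Leave-one-subject-out evaluation of one classifier family.

    ``n_search`` > 0 enables seeded random hyperparameter search inside each
    training fold (grouped inner CV); 0 uses library defaults.  Folds whose
    training labels collapse to one class are skipped with a warning.
    """
    subjects = pd.unique(subject_ids)
    if len(subjects) < 3:
        raise MsgaitError("LOSO needs at least 3 subjects")
    if len(np.unique(y)) < 2:
        raise MsgaitError("both classes must be present")
    rows = []
    per_fold = []
    for fold, subj in enumerate(subjects):
        test = subject_ids == subj
        train = ~test
        y_tr = y[train]
        if len(np.unique(y_tr)) < 2:
            log.warning("fold %s: single-class training set, skipped", subj)
            continue
        X_tr = X[train]
        params = None
        if n_search > 0:
            params = _tune(X_tr, y_tr, subject_ids[train], model_family, seed,
                           pca_variance, n_search)
        pipe = _fit_fold(X_tr, y_tr, model_family, seed, pca_variance, params)
        s = pipe.predict_proba(X[test])[:, 1]
        for sc in s:
            rows.append({"subject_id": subj, "score": float(sc), "label": int(y[test][0]),
                         "fold": fold})
        per_fold.append({"subject": str(subj), "n_test": int(test.sum()),
                         "n_components": int(pipe.named_steps["pca"].n_components_),
                         "params": params})
    if not rows:
        raise MsgaitError("no held-out scores: every fold was skipped")
    scores = pd.DataFrame(rows)
    auc_input = compute_auc(scores["score"], scores["label"])
    subj_med = scores.groupby("subject_id").agg(score=("score", "median"),
                                                label=("label", "first"))
    auc_subject = compute_auc(subj_med["score"], subj_med["label"])
    return ClassifierOutcome(
        scores=scores,
        auc_per_input=auc_input,
        auc_subject_median=auc_subject,
        per_fold=per_fold,
        model_family=model_family,
        feature_set=feature_set,
    )
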