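"""Feature-based classification of glycolytic vs oxidative cells.

Three conventional models are trained on the twelve autofluorescence
features: a random forest (50 trees, 5 candidate variables per split,
terminal node size 1), a linear-kernel SVM (features z-scored inside the
pipeline) and quadratic discriminant analysis.  The positive class is the
OXPHOS-inhibited (glycolytic) phenotype; glycolysis-inhibited (oxidative)
cells are the negative class.  Evaluation reports accuracy, ROC/AUC,
confusion matrix, precision/recall, 5-fold cross-validated accuracy,
random-forest importances and single-feature AUCs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import normalize_by_control
from .synth import FEATURE_NAMES

logger = logging.getLogger(__name__)

POSITIVE = "oxphos_inhibited"      # glycolytic phenotype
NEGATIVE = "glycolysis_inhibited"  # oxidative phenotype
MODEL_TAGS = ("rft", "svm", "qda")


@dataclass
class ClassifierReport:
    model: str
    accuracy: float
    auc: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    confusion: np.ndarray          # rows true [neg, pos], cols predicted
    precision: float
    recall: float
    cv_accuracy: float = float("nan")
    importances: dict = field(default_factory=dict)
    feature_aucs: dict = field(default_factory=dict)

    def to_dict(self):
        return {"model": self.model, "accuracy": self.accuracy,
                "auc": self.auc, "precision": self.precision,
                "recall": self.recall, "cv_accuracy": self.cv_accuracy,
                "confusion": self.confusion.tolist(),
                "importances": self.importances,
                "feature_aucs": self.feature_aucs}


def _xy(table: pd.DataFrame, feature_names):
    X = table[list(feature_names)].to_numpy(dtype=float)
    y = (table["group"] == POSITIVE).astype(int).to_numpy()
    return X, y


def split_train_test(features: pd.DataFrame, train_fraction: float = 0.75,
                     seed: int = 0):
    """Stratified random train/test split (default 75/25)."""
    counts = features["group"].value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 cells to stratify")
    # ceiling so that e.g. 1,819 cells split 1,365 / 454 at 75%
    n_train = math.ceil(train_fraction * len(features))
    train, test = train_test_split(
        features, train_size=n_train, random_state=seed,
        stratify=features["group"], shuffle=True)
    return train, test


def make_models(seed: int = 0):
    """Fresh unfitted model instances keyed by tag."""
    return {
        "rft": RandomForestClassifier(
            n_estimators=50, max_features=5, min_samples_leaf=1,
            random_state=seed),
        "svm": make_pipeline(StandardScaler(), SVC(kernel="linear",
                                                   random_state=seed)),
        "qda": QuadraticDiscriminantAnalysis(),
    }


def train_models(train: pd.DataFrame, seed: int = 0,
                 feature_names=FEATURE_NAMES) -> dict:
    """Fit RFT, linear SVM and QDA on a labeled feature table."""
    X, y = _xy(train, feature_names)
    if len(np.unique(y)) < 2:
        raise ValueError("training set needs both classes")
    models = make_models(seed)
    for tag, model in models.items():
        try:
            model.fit(X, y)
        except np.linalg.LinAlgError:
            # singular class covariance: regularized QDA fallback
            assert tag == "qda"
            model = QuadraticDiscriminantAnalysis(reg_param=1e-3)
            model.fit(X, y)
            models[tag] = model
            logger.warning("QDA covariance singular; refit with reg_param=1e-3")
    return models


def _scores(model, X):
    """Continuous decision scores oriented toward the positive class."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def evaluate(model, test: pd.DataFrame, model_tag: str = "",
             cv_table: pd.DataFrame | None = None, seed: int = 0,
             feature_names=FEATURE_NAMES) -> ClassifierReport:
    """Full test-set report; 5-fold CV accuracy if ``cv_table`` is given."""
    X, y = _xy(test, feature_names)
    y_pred = model.predict(X)
    cm = confusion_matrix(y, y_pred, labels=[0, 1])
    tn, fp, fn, tp = cm.ravel()
    acc = (tp + tn) / cm.sum()
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    if len(np.unique(y)) < 2:
        auc, fpr, tpr = float("nan"), np.array([]), np.array([])
        logger.warning("single-class test set: AUC undefined")
    else:
        s = _scores(model, X)
        auc = roc_auc_score(y, s)
        fpr, tpr, _ = roc_curve(y, s)
    cv_acc = (cross_val_accuracy(model, cv_table, seed=seed,
                                 feature_names=feature_names)
              if cv_table is not None else float("nan"))
    importances = {}
    if hasattr(model, "feature_importances_"):
        importances = dict(zip(feature_names,
                               map(float, model.feature_importances_)))
    return ClassifierReport(model=model_tag, accuracy=float(acc),
                            auc=float(auc), roc_fpr=fpr, roc_tpr=tpr,
                            confusion=cm, precision=float(precision),
                            recall=float(recall), cv_accuracy=float(cv_acc),
                            importances=importances)


def cross_val_accuracy(model, table: pd.DataFrame, n_splits: int = 5,
                       seed: int = 0, feature_names=FEATURE_NAMES) -> float:
    """Mean accuracy over a stratified 5-fold partition of ``table``."""
    from sklearn.base import clone

    X, y = _xy(table, feature_names)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        m = clone(model)
        m.fit(X[tr], y[tr])
        accs.append((m.predict(X[te]) == y[te]).mean())
    return float(np.mean(accs))


def feature_ranking(train: pd.DataFrame, seed: int = 0,
                    feature_names=FEATURE_NAMES) -> pd.DataFrame:
    """Single-feature AUCs and random-forest importances, rank-ordered.

    Each feature's AUC is computed from the feature value itself as the score,
    on the orientation that yields AUC >= 0.5 (orientation recorded).
    """
    X, y = _xy(train, feature_names)
    rows = []
    for j, name in enumerate(feature_names):
        auc = roc_auc_score(y, X[:, j])
        flipped = auc < 0.5
        rows.append({"feature": name, "auc": float(max(auc, 1 - auc)),
                     "orientation": "descending" if flipped else "ascending"})
    rft = RandomForestClassifier(n_estimators=50, max_features=5,
                                 min_samples_leaf=1, random_state=seed)
    rft.fit(X, y)
    imp = dict(zip(feature_names, rft.feature_importances_))
    out = pd.DataFrame(rows)
    out["rft_importance"] = out["feature"].map(imp).astype(float)
    return out.sort_values("auc", ascending=False, ignore_index=True)


def transfer_predict(model, features_other: pd.DataFrame, control_other: str,
                     feature_names=FEATURE_NAMES) -> dict:
    """Apply a model trained on control-normalized features to a new cell type.

    The new table is normalized by its *own* control-group means first.
    Returns per-cell predictions and, per group, the fraction assigned to each
    phenotype.
    """
    if control_other not in set(features_other["group"]):
        raise ValueError(f"control group {control_other!r} missing")
    norm = normalize_by_control(features_other, control_other,
                                feature_names=feature_names)
    X = norm[list(feature_names)].to_numpy(dtype=float)
    pred = model.predict(X)
    labels = np.where(pred == 1, POSITIVE, NEGATIVE)
    fractions = {}
    for g, sub in norm.assign(_pred=labels).groupby("group"):
        fractions[g] = {
            POSITIVE: float((sub["_pred"] == POSITIVE).mean()),
            NEGATIVE: float((sub["_pred"] == NEGATIVE).mean()),
        }
    return {"predictions": labels, "fractions": fractions,
            "normalized": norm}
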