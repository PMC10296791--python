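"""Classifiers, feature selection, evaluation and attribution.

Three-class (normal / hypopnea / apnea) segment classification with tree
ensembles (decision tree, random forest, gradient-boosted trees) under
inverse-frequency class weighting; obstructive/central apnea subtyping
with an LSTM over fused effort sequences, with the operating cutoff chosen
on validation ROC by Youden's J; Kruskal-Wallis + Benjamini-Hochberg
feature screening; Shapley-value attribution for the boosted trees.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import confusion_matrix, roc_curve
from sklearn.model_selection import GroupShuffleSplit, train_test_split
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multitest import multipletests
import xgboost as xgb

from .features import FEATURE_COLUMNS, META_COLUMNS
from .lstm import LSTMClassifier
from .types import SplitSpec

__all__ = [
    "EvalReport",
    "FeatureSelection",
    "select_features",
    "split_table",
    "train_segment_classifier",
    "train_subtype_classifier",
    "evaluate",
    "youden_cutoff",
    "explain",
    "SegmentModel",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Confusion matrix plus macro and per-class metrics."""

    classes: list[str]
    confusion: np.ndarray
    per_class: dict[str, dict[str, float]]
    accuracy: float
    macro_precision: float
    macro_sensitivity: float
    macro_f1: float
    roc: dict | None = None  # {"fpr", "tpr", "thresholds", "auc"} for binary tasks

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["confusion"] = self.confusion.tolist()
        if self.roc is not None:
            d["roc"] = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                        for k, v in self.roc.items()}
        return d

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate(
    y_true,
    y_pred,
    classes: list[str] | None = None,
    scores: np.ndarray | None = None,
    positive_class=None,
) -> EvalReport:
    """Multiclass metrics (macro averaged) and, for binary tasks with
    ``scores``, the ROC curve with trapezoidal AUC.

    Per-class precision/sensitivity are NaN-flagged when a class has no
    predicted (resp. true) instances.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    per_class = {}
    precisions, sensitivities, f1s = [], [], []
    for i, c in enumerate(classes):
        tp = cm[i, i]
        support = cm[i].sum()
        predicted = cm[:, i].sum()
        prec = tp / predicted if predicted > 0 else np.nan
        sens = tp / support if support > 0 else np.nan
        f1 = (
            2 * prec * sens / (prec + sens)
            if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0
            else (0.0 if np.isfinite(prec) and np.isfinite(sens) else np.nan)
        )
        per_class[str(c)] = {"precision": prec, "sensitivity": sens, "f1": f1,
                             "support": int(support)}
        precisions.append(prec)
        sensitivities.append(sens)
        f1s.append(f1)
    report = EvalReport(
        classes=[str(c) for c in classes],
        confusion=cm,
        per_class=per_class,
        accuracy=float(np.trace(cm) / cm.sum()) if cm.sum() else np.nan,
        macro_precision=float(np.nanmean(precisions)),
        macro_sensitivity=float(np.nanmean(sensitivities)),
        macro_f1=float(np.nanmean(f1s)),
    )
    if scores is not None and len(classes) == 2:
        pos = positive_class if positive_class is not None else classes[1]
        y_bin = (y_true == pos).astype(int)
        if len(set(y_bin)) == 2:
            fpr, tpr, thr = roc_curve(y_bin, scores)
            report.roc = {"fpr": fpr, "tpr": tpr, "thresholds": thr,
                          "auc": float(sk_auc(fpr, tpr))}
    return report


def youden_cutoff(y_true_bin: np.ndarray, scores: np.ndarray) -> float:
    """Operating cutoff maximizing Youden's J = sensitivity + specificity - 1."""
    fpr, tpr, thr = roc_curve(y_true_bin, scores)
    j = tpr - fpr
    best = int(np.argmax(j))
    cut = float(thr[best])
    return min(cut, 1.0)  # roc_curve's leading threshold can exceed 1


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

@dataclass
class FeatureSelection:
    table: pd.DataFrame
    ranking: pd.DataFrame  # feature, statistic, pvalue, qvalue, retained
    alpha: float

    @property
    def retained(self) -> list[str]:
        return list(self.ranking.loc[self.ranking.retained, "feature"])

    def top(self, k: int) -> list[str]:
        return list(self.ranking.loc[self.ranking.retained, "feature"].head(k))


def select_features(
    tbl: pd.DataFrame,
    alpha: float = 0.05,
    label_col: str = "label",
    feature_cols: list[str] | None = None,
) -> FeatureSelection:
    """Kruskal-Wallis screening across classes with Benjamini-Hochberg FDR.

    Constant features get p = 1 and are removed. The returned ranking is by
    descending test statistic, supporting Top-k experiments.
    """
    if feature_cols is None:
        feature_cols = [c for c in tbl.columns if c in FEATURE_COLUMNS]
    labels = tbl[label_col]
    if labels.nunique() < 2:
        raise ValueError("need at least 2 classes for feature selection")
    groups_idx = [tbl.index[labels == g] for g in sorted(labels.unique())]

    stats_, pvals = [], []
    for col in feature_cols:
        samples = [tbl.loc[idx, col].dropna().to_numpy() for idx in groups_idx]
        samples = [s for s in samples if len(s) > 0]
        pooled = np.concatenate(samples) if samples else np.empty(0)
        if len(samples) < 2 or len(pooled) == 0 or np.ptp(pooled) == 0:
            stats_.append(0.0)
            pvals.append(1.0)
            continue
        try:
            h, p = stats.kruskal(*samples)
        except ValueError:
            h, p = 0.0, 1.0
        stats_.append(float(h))
        pvals.append(float(p))

    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    ranking = (
        pd.DataFrame({
            "feature": feature_cols, "statistic": stats_,
            "pvalue": pvals, "qvalue": qvals, "retained": reject,
        })
        .sort_values("statistic", ascending=False)
        .reset_index(drop=True)
    )
    kept = [c for c in tbl.columns if c in META_COLUMNS or c in set(ranking.loc[ranking.retained, "feature"])]
    return FeatureSelection(table=tbl[kept].copy(), ranking=ranking, alpha=alpha)


# ---------------------------------------------------------------------------
# segment classifier
# ---------------------------------------------------------------------------

@dataclass
class SegmentModel:
    """Fitted three-class model plus the schema it expects."""

    estimator: object
    feature_names: list[str]
    classes: list[str]
    model_kind: str
    impute_values: dict[str, float] = field(default_factory=dict)

    def _matrix(self, tbl: pd.DataFrame) -> np.ndarray:
        X = tbl[self.feature_names].copy()
        for c, v in self.impute_values.items():
            X[c] = X[c].fillna(v)
        return X.to_numpy(dtype=float)

    def predict(self, tbl: pd.DataFrame) -> np.ndarray:
        idx = self.estimator.predict(self._matrix(tbl))
        if np.issubdtype(np.asarray(idx).dtype, np.integer):
            return np.asarray(self.classes)[idx]
        return np.asarray(idx)

    def predict_proba(self, tbl: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict_proba(self._matrix(tbl))


_MODEL_KINDS = ("decision_tree", "random_forest", "gradient_boosted_trees")


def split_table(tbl: pd.DataFrame, split: SplitSpec, label_col: str = "label"):
    """Train/test split honouring the split protocol (subject-wise splits
    never leak a subject across sides)."""
    if split.mode == "by_subject":
        gss = GroupShuffleSplit(n_splits=1, test_size=split.test_frac, random_state=split.seed)
        train_idx, test_idx = next(gss.split(tbl, groups=tbl["subject"]))
        return tbl.iloc[train_idx].copy(), tbl.iloc[test_idx].copy()
    train, test = train_test_split(
        tbl, test_size=split.test_frac, random_state=split.seed,
        stratify=tbl[label_col],
    )
    return train.copy(), test.copy()


def train_segment_classifier(
    tbl: pd.DataFrame,
    model: str = "gradient_boosted_trees",
    split: SplitSpec | None = None,
    feature_cols: list[str] | None = None,
    label_col: str = "label",
    **estimator_kwargs,
) -> tuple[SegmentModel, EvalReport]:
    """Fit a three-class segment classifier and evaluate it held-out.

    Class imbalance is addressed with inverse-frequency sample weights.
    Fixed split/estimator seeds make the report reproducible.
    """
    if model not in _MODEL_KINDS:
        raise ValueError(f"unknown model {model!r}; choose from {_MODEL_KINDS}")
    split = split or SplitSpec()
    if feature_cols is None:
        feature_cols = [c for c in tbl.columns if c in FEATURE_COLUMNS]

    train, test = split_table(tbl, split, label_col)
    classes = sorted(tbl[label_col].unique())
    missing = set(classes) - set(train[label_col].unique())
    if missing:
        raise ValueError(f"class(es) {sorted(missing)} absent from the training split")
    for c in classes:
        if (train[label_col] == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 training segments")

    class_to_idx = {c: i for i, c in enumerate(classes)}
    y_train = train[label_col].map(class_to_idx).to_numpy()
    y_test = test[label_col].to_numpy()
    counts = np.bincount(y_train, minlength=len(classes))
    weights = (len(y_train) / (len(classes) * counts))[y_train]

    impute = {}
    if model == "gradient_boosted_trees":
        est = xgb.XGBClassifier(
            n_estimators=estimator_kwargs.pop("n_estimators", 200),
            max_depth=estimator_kwargs.pop("max_depth", 4),
            learning_rate=estimator_kwargs.pop("learning_rate", 0.1),
            objective="multi:softprob" if len(classes) > 2 else "binary:logistic",
            random_state=split.seed,
            n_jobs=1,
            verbosity=0,
            **estimator_kwargs,
        )
    else:
        # sklearn trees cannot take NaN paths natively in all versions;
        # impute with the training median
        impute = {c: float(train[c].median()) for c in feature_cols}
        if model == "decision_tree":
            est = DecisionTreeClassifier(random_state=split.seed, **estimator_kwargs)
        else:
            est = RandomForestClassifier(
                n_estimators=estimator_kwargs.pop("n_estimators", 200),
                random_state=split.seed, n_jobs=1, **estimator_kwargs,
            )

    fitted = SegmentModel(
        estimator=est, feature_names=feature_cols, classes=classes,
        model_kind=model, impute_values=impute,
    )
    est.fit(fitted._matrix(train), y_train, sample_weight=weights)
    y_pred = fitted.predict(test)
    report = evaluate(y_test, y_pred, classes=classes)
    return fitted, report


# ---------------------------------------------------------------------------
# subtype (obstructive vs central) classifier
# ---------------------------------------------------------------------------

def train_subtype_classifier(
    sequences: np.ndarray,
    labels: np.ndarray,
    split: SplitSpec | None = None,
    hidden: int = 32,
    epochs: int = 300,
    lr: float = 1e-2,
) -> tuple[LSTMClassifier, EvalReport, float]:
    """Train the LSTM on fused effort sequences (label 1 = obstructive).

    The ROC is built on the held-out scores, the operating cutoff chosen by
    Youden's J, and the report computed at that cutoff.
    """
    sequences = np.asarray(sequences, dtype=float)
    labels = np.asarray(labels)
    if sequences.ndim != 2:
        raise ValueError("sequences must be a 2-D array (n, T)")
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    split = split or SplitSpec()
    y = labels.astype(float)
    X_train, X_test, y_train, y_test = train_test_split(
        sequences, y, test_size=split.test_frac, random_state=split.seed, stratify=y
    )
    model = LSTMClassifier(hidden=hidden, epochs=epochs, lr=lr, seed=split.seed)
    model.fit(X_train, y_train, X_val=X_test, y_val=y_test)
    scores = model.predict_proba(X_test)
    cutoff = youden_cutoff(y_test.astype(int), scores)
    y_pred = (scores >= cutoff).astype(int)
    report = evaluate(
        y_test.astype(int), y_pred, classes=[0, 1], scores=scores, positive_class=1
    )
    return model, report, cutoff


# ---------------------------------------------------------------------------
# attribution
# ---------------------------------------------------------------------------

def explain(model: SegmentModel, tbl: pd.DataFrame) -> pd.DataFrame:
    """Per-feature Shapley attribution summary (mean |attribution|).

    For gradient-boosted trees the attributions are exact TreeSHAP values
    from the booster; each row's attributions (plus the bias term) sum to
    that row's margin prediction. Other estimators fall back to permutation
    importance, with a warning. The raw per-segment attributions are
    attached as ``result.attrs["attributions"]`` for dependence analysis.
    """
    X = model._matrix(tbl)
    if model.model_kind == "gradient_boosted_trees":
        booster = model.estimator.get_booster()
        contribs = booster.predict(xgb.DMatrix(X, feature_names=model.feature_names),
                                   pred_contribs=True)
        if contribs.ndim == 3:  # (n, n_class, n_feat + 1)
            per_feature = np.abs(contribs[:, :, :-1]).mean(axis=(0, 1))
            raw = contribs
        else:
            per_feature = np.abs(contribs[:, :-1]).mean(axis=0)
            raw = contribs
        out = pd.DataFrame({"feature": model.feature_names,
                            "mean_abs_attribution": per_feature})
        out = out.sort_values("mean_abs_attribution", ascending=False).reset_index(drop=True)
        out.attrs["attributions"] = raw
        out.attrs["method"] = "treeshap"
        return out
    warnings.warn("non-tree-ensemble model; falling back to permutation importance")
    y = tbl["label"].to_numpy()
    y_idx = np.asarray([model.classes.index(v) for v in y])
    imp = permutation_importance(model.estimator, X, y_idx, n_repeats=5, random_state=0)
    out = pd.DataFrame({"feature": model.feature_names,
                        "mean_abs_attribution": imp.importances_mean})
    out = out.sort_values("mean_abs_attribution", ascending=False).reset_index(drop=True)
    out.attrs["method"] = "permutation"
    return out


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model, directory, meta: dict | None = None) -> None:
    """Save a fitted model as a versioned on-disk bundle."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    info = {"format_version": 1, **(meta or {})}
    if isinstance(model, SegmentModel):
        info["type"] = "segment"
        joblib.dump(model, directory / "model.joblib")
    elif isinstance(model, LSTMClassifier):
        info["type"] = "subtype"
        model.save(directory / "weights.npz")
    else:
        raise TypeError(f"cannot save model of type {type(model)}")
    (directory / "meta.json").write_text(json.dumps(info, indent=2))


def load_model(directory):
    directory = Path(directory)
    meta_path = directory / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no model bundle at {directory}")
    info = json.loads(meta_path.read_text())
    if info["type"] == "segment":
        return joblib.load(directory / "model.joblib"), info
    if info["type"] == "subtype":
        return LSTMClassifier.load(directory / "weights.npz"), info
    raise ValueError(f"unknown bundle type {info['type']!r}")
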