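"""Regrowth-possibility prediction from soil attributes by stacking.

Five base learners — logistic regression, a support-vector classifier, a
decision tree, a random forest and Gaussian naive Bayes — are cross-fit
(stratified k-fold) and a logistic-regression generalizer is trained on
their out-of-fold probability predictions only, so the meta-features never
leak in-fold fits.  Numeric soil attributes are standardized and the soil
group is one-hot encoded (unknown groups at prediction time map to the
all-zero encoding and are flagged in the output).  Latitude/longitude are
excluded from the features by default: they index location, not soil
quality.
"""

from __future__ import annotations

import json
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import RandomForestClassifier, StackingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import InputError

NUMERIC_FEATURES = ["ph", "nitrogen", "organic_carbon", "bulk_density"]
CATEGORICAL_FEATURES = ["soil_group"]
COORDINATE_COLUMNS = ["latitude", "longitude"]
LABEL_COLUMN = "label"


@dataclass
class StackConfig:
    folds: int = 5
    seed: int = 0
    include_coordinates: bool = False
    holdout_fraction: float = 0.25  # evaluation split used by fit_stack


@dataclass
class StackModel:
    pipeline: Pipeline
    cfg: StackConfig
    feature_columns: list[str]
    soil_groups: list[str]
    holdout_metrics: dict[str, float] = field(default_factory=dict)
    base_holdout_accuracy: dict[str, float] = field(default_factory=dict)


def _validate_table(table: pd.DataFrame, require_label: bool) -> pd.DataFrame:
    required = NUMERIC_FEATURES + CATEGORICAL_FEATURES + (
        [LABEL_COLUMN] if require_label else [])
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise InputError(f"soil table is missing columns: {missing}")
    t = table.dropna(subset=[c for c in required if c in table.columns]).copy()
    if np.any((t["ph"] < 0) | (t["ph"] > 14)):
        raise InputError("pH values must lie in [0, 14]")
    return t


def _features(cfg: StackConfig) -> list[str]:
    cols = list(NUMERIC_FEATURES)
    if cfg.include_coordinates:
        cols += COORDINATE_COLUMNS
    return cols + CATEGORICAL_FEATURES


def _make_pipeline(cfg: StackConfig) -> Pipeline:
    numeric = [c for c in _features(cfg) if c not in CATEGORICAL_FEATURES]
    pre = ColumnTransformer([
        ("num", StandardScaler(), numeric),
        ("cat", OneHotEncoder(handle_unknown="ignore"), CATEGORICAL_FEATURES),
    ])
    seed = cfg.seed
    base = [
        ("logreg", LogisticRegression(max_iter=2000, random_state=seed)),
        ("svc", SVC(probability=True, random_state=seed)),
        ("tree", DecisionTreeClassifier(random_state=seed)),
        ("forest", RandomForestClassifier(n_estimators=200, random_state=seed)),
        ("nb", GaussianNB()),
    ]
    stack = StackingClassifier(
        estimators=base,
        final_estimator=LogisticRegression(max_iter=2000, random_state=seed),
        cv=StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=seed),
        stack_method="predict_proba",
    )
    return Pipeline([("pre", pre), ("stack", stack)])


@contextmanager
def _quiet_fit():
    # SVC(probability=True) is deliberate (calibrated base-model probabilities
    # feed the generalizer); silence its deprecation chatter during fits.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        yield


def fit_stack(table: pd.DataFrame, cfg: StackConfig | None = None,
              evaluate_bases: bool = False) -> StackModel:
    """Fit the stacking ensemble; held-out metrics on a stratified split.

    With ``evaluate_bases`` each base learner is also fit alone and scored
    on the same held-out split, for comparative evaluation.
    """
    cfg = cfg or StackConfig()
    t = _validate_table(table, require_label=True)
    y = t[LABEL_COLUMN].to_numpy().astype(int)
    classes = np.unique(y)
    if classes.size < 2:
        raise InputError("training labels contain a single class")
    if len(t) < 10 * cfg.folds:
        raise InputError(f"need at least {10 * cfg.folds} rows, got {len(t)}")
    cols = _features(cfg)
    X = t[cols]
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=cfg.holdout_fraction, stratify=y, random_state=cfg.seed)
    pipe = _make_pipeline(cfg)
    with _quiet_fit():
        pipe.fit(X_tr, y_tr)
    pred = pipe.predict(X_te)
    metrics = evaluate_classifier(y_te, pred)
    base_acc: dict[str, float] = {}
    if evaluate_bases:
        for name, est in _make_pipeline(cfg)["stack"].estimators:
            solo = Pipeline([("pre", _make_pipeline(cfg)["pre"]), ("est", est)])
            with _quiet_fit():
                solo.fit(X_tr, y_tr)
            base_acc[name] = float(np.mean(solo.predict(X_te) == y_te))
    return StackModel(
        pipeline=pipe, cfg=cfg, feature_columns=cols,
        soil_groups=sorted(t["soil_group"].astype(str).unique()),
        holdout_metrics=metrics, base_holdout_accuracy=base_acc,
    )


def predict_regrowth(model: StackModel, record: dict | pd.DataFrame) -> dict | pd.DataFrame:
    """Predict regrowth possibility for one record or a table of records.

    Returns label ("possible"/"not possible"), the calibrated probability
    of regrowth, and an ``unknown_soil_group`` flag for out-of-vocabulary
    groups (the prediction is still made via the zero one-hot encoding).
    """
    single = isinstance(record, dict)
    frame = pd.DataFrame([record]) if single else record.copy()
    missing = [c for c in model.feature_columns if c not in frame.columns]
    if missing:
        raise InputError(f"record is missing required fields: {missing}")
    frame = _validate_table(frame, require_label=False)
    if frame.empty:
        raise InputError("record has missing values in required fields")
    proba = model.pipeline.predict_proba(frame[model.feature_columns])[:, 1]
    out = pd.DataFrame({
        "label": np.where(proba >= 0.5, "possible", "not possible"),
        "probability": proba,
        "unknown_soil_group": ~frame["soil_group"].astype(str).isin(model.soil_groups),
    }, index=frame.index)
    if single:
        row = out.iloc[0]
        return {"label": str(row["label"]), "probability": float(row["probability"]),
                "unknown_soil_group": bool(row["unknown_soil_group"])}
    return out


def evaluate_classifier(y_true, y_pred) -> dict[str, float]:
    """Precision, recall, F1 and accuracy for binary labels."""
    import warnings
    y_true = np.asarray(y_true).astype(int).ravel()
    y_pred = np.asarray(y_pred).astype(int).ravel()
    if y_true.size != y_pred.size:
        raise InputError("y_true and y_pred lengths differ")
    tp = float(np.sum((y_pred == 1) & (y_true == 1)))
    fp = float(np.sum((y_pred == 1) & (y_true == 0)))
    fn = float(np.sum((y_pred == 0) & (y_true == 1)))
    if tp + fp == 0 or tp + fn == 0:
        warnings.warn("zero division in precision/recall; metric set to 0")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = float(np.mean(y_true == y_pred)) if y_true.size else 0.0
    return {"precision": precision, "recall": recall, "f1": f1, "accuracy": accuracy}


def cross_validated_accuracy(table: pd.DataFrame, cfg: StackConfig | None = None,
                             estimator: str = "stack") -> float:
    """Stratified CV accuracy of the full stack or one named base learner."""
    cfg = cfg or StackConfig()
    t = _validate_table(table, require_label=True)
    X, y = t[_features(cfg)], t[LABEL_COLUMN].astype(int)
    pipe = _make_pipeline(cfg)
    if estimator != "stack":
        bases = dict(pipe["stack"].estimators)
        if estimator not in bases:
            raise InputError(f"unknown estimator {estimator!r}")
        pipe = Pipeline([("pre", pipe["pre"]), ("est", bases[estimator])])
    cv = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    with _quiet_fit():
        return float(cross_val_score(pipe, X, y, cv=cv, scoring="accuracy").mean())


def save_stack(model: StackModel, path: str) -> None:
    import joblib
    joblib.dump({"pipeline": model.pipeline, "cfg": model.cfg,
                 "feature_columns": model.feature_columns,
                 "soil_groups": model.soil_groups,
                 "holdout_metrics": model.holdout_metrics}, path)
    with open(str(path) + ".json", "w") as fh:
        json.dump({"feature_columns": model.feature_columns,
                   "soil_groups": model.soil_groups,
                   "folds": model.cfg.folds, "seed": model.cfg.seed,
                   "holdout_metrics": model.holdout_metrics}, fh, indent=2)


def load_stack(path: str) -> StackModel:
    import joblib
    d = joblib.load(path)
    return StackModel(pipeline=d["pipeline"], cfg=d["cfg"],
                      feature_columns=d["feature_columns"],
                      soil_groups=d["soil_groups"],
                      holdout_metrics=d.get("holdout_metrics", {}))
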