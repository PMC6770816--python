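"""Random-forest classification/regression and per-compound aggregation.

The validation set is split 80/20 at the record level, a random-forest
classifier (active/inactive) and regressor (melatonin activity score)
are trained on the training portion, and held-out records are scored
with their truth columns removed.  Per-compound aggregation produces
the countRatio — the fraction of a compound's scored records the
classifier calls active — and the mean predicted activity score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import confusion_matrix, roc_auc_score

from .feature_builder import FeatureSchema


@dataclass
class SplitPlan:
    seed: int
    train_fraction: float
    train_record_ids: list[str]
    test_record_ids: list[str]


@dataclass
class Hyperparameters:
    n_trees: int = 100
    max_depth: Optional[int] = None
    # sklearn conventions: sqrt(p) for classification, p/3 for regression
    clf_max_features: str | float = "sqrt"
    reg_max_features: float = 1.0 / 3.0


@dataclass
class ModelBundle:
    classifier: RandomForestClassifier
    regressor: RandomForestRegressor
    schema_fingerprint: str
    feature_names: list[str]
    split: Optional[SplitPlan]
    hyperparameters: Hyperparameters
    seed: int
    training_metrics: dict = field(default_factory=dict)


@dataclass
class CompoundPrediction:
    compound_id: str
    n_occasions: int
    n_active_calls: int
    count_ratio: float
    mean_predicted_score: float
    actual_score: Optional[float] = None


def split(rows: pd.DataFrame, seed: int,
          fraction: float = 0.8) -> SplitPlan:
    """Random disjoint 80/20 record-level partition."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if len(rows) < 5:
        raise ValueError("need at least 5 rows to split")
    ids = rows["record_id"].tolist()
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = round(len(ids) * fraction)
    train = [ids[i] for i in perm[:n_train]]
    test = [ids[i] for i in perm[n_train:]]
    return SplitPlan(seed=seed, train_fraction=fraction,
                     train_record_ids=train, test_record_ids=test)


def train(train_rows: pd.DataFrame, schema: FeatureSchema,
          seed: int,
          hyperparameters: Optional[Hyperparameters] = None,
          split_plan: Optional[SplitPlan] = None) -> ModelBundle:
    """Fit the classification and regression forests."""
    hp = hyperparameters or Hyperparameters()
    labels = train_rows["label"]
    if labels.nunique() < 2:
        raise ValueError("training data contains a single class")
    X = train_rows[schema.names].to_numpy(dtype=float)
    y_cls = (labels == "active").to_numpy()
    y_reg = train_rows["activity_score"].to_numpy(dtype=float)
    clf = RandomForestClassifier(
        n_estimators=hp.n_trees, max_depth=hp.max_depth,
        max_features=hp.clf_max_features, random_state=seed, n_jobs=1)
    reg = RandomForestRegressor(
        n_estimators=hp.n_trees, max_depth=hp.max_depth,
        max_features=hp.reg_max_features, random_state=seed, n_jobs=1)
    clf.fit(X, y_cls)
    reg.fit(X, y_reg)
    metrics = {"train_accuracy": float(clf.score(X, y_cls)),
               "train_r2": float(reg.score(X, y_reg)),
               "n_train": int(len(train_rows))}
    return ModelBundle(classifier=clf, regressor=reg,
                       schema_fingerprint=schema.fingerprint(),
                       feature_names=list(schema.names),
                       split=split_plan, hyperparameters=hp, seed=seed,
                       training_metrics=metrics)


def predict_records(bundle: ModelBundle, rows: pd.DataFrame,
                    schema: FeatureSchema) -> pd.DataFrame:
    """Per-record class call and score prediction.

    Truth columns (``label``/``activity_score``), if present, are
    ignored.  Returns record_id, compound_id, predicted_active,
    predicted_score.
    """
    if schema.fingerprint() != bundle.schema_fingerprint:
        raise ValueError("schema fingerprint mismatch: the bundle was "
                         "trained on a different feature schema")
    X = rows[bundle.feature_names].to_numpy(dtype=float)
    calls = bundle.classifier.predict(X)
    scores = bundle.regressor.predict(X)
    return pd.DataFrame({
        "record_id": rows["record_id"].to_numpy(),
        "compound_id": rows["compound_id"].to_numpy(),
        "predicted_active": calls.astype(bool),
        "predicted_score": scores,
    })


def aggregate_compound(predictions: pd.DataFrame,
                       actual_scores: Optional[Mapping[str, float]] = None,
                       ) -> list[CompoundPrediction]:
    """Aggregate per-record predictions to compounds.

    countRatio = active calls / occasions in the scored set;
    mean_predicted_score = mean of the regression outputs.
    """
    actual_scores = actual_scores or {}
    out = []
    grouped = predictions.groupby("compound_id", sort=True)
    for cid, grp in grouped:
        n = len(grp)
        n_active = int(grp["predicted_active"].sum())
        out.append(CompoundPrediction(
            compound_id=cid,
            n_occasions=n,
            n_active_calls=n_active,
            count_ratio=n_active / n,
            mean_predicted_score=float(grp["predicted_score"].mean()),
            actual_score=actual_scores.get(cid),
        ))
    return out


def _safe_corr(x: np.ndarray, y: np.ndarray) -> dict:
    """Pearson/Spearman with degenerate inputs reported as absent."""
    n = len(x)
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return {"pearson_r": None, "spearman_r": None, "n": n}
    return {"pearson_r": float(stats.pearsonr(x, y).statistic),
            "spearman_r": float(stats.spearmanr(x, y).statistic),
            "n": n}


def evaluate(bundle: ModelBundle, test_rows: pd.DataFrame,
             schema: FeatureSchema) -> dict:
    """Prediction-quality report on held-out rows carrying truth.

    Contains the per-record and per-compound regression correlations,
    the classification confusion matrix, and the countRatio
    distribution stratified by true label.
    """
    if test_rows.empty:
        raise ValueError("empty test set")
    preds = predict_records(bundle, test_rows, schema)
    truth_label = (test_rows["label"] == "active").to_numpy()
    X = test_rows[bundle.feature_names].to_numpy(dtype=float)
    if 0 < truth_label.sum() < len(truth_label):
        proba = bundle.classifier.predict_proba(X)[:, 1]
        auroc = float(roc_auc_score(truth_label, proba))
    else:
        auroc = None
    truth_score = test_rows["activity_score"].to_numpy(dtype=float)
    cm = confusion_matrix(truth_label, preds["predicted_active"],
                          labels=[False, True])
    per_record = _safe_corr(truth_score, preds["predicted_score"].to_numpy())

    actual_by_compound = (
        test_rows.groupby("compound_id")["activity_score"].mean())
    comp = aggregate_compound(preds, actual_by_compound.to_dict())
    comp_actual = np.array([c.actual_score for c in comp], dtype=float)
    comp_pred = np.array([c.mean_predicted_score for c in comp])
    per_compound = _safe_corr(comp_actual, comp_pred)

    label_by_compound = (
        test_rows.groupby("compound_id")["label"]
        .agg(lambda s: "active" if (s == "active").any() else "inactive"))
    cr_by_label: dict[str, list[float]] = {"active": [], "inactive": []}
    for c in comp:
        cr_by_label[label_by_compound[c.compound_id]].append(c.count_ratio)
    return {
        "confusion_matrix": {"tn": int(cm[0, 0]), "fp": int(cm[0, 1]),
                             "fn": int(cm[1, 0]), "tp": int(cm[1, 1])},
        "classification_auroc": auroc,
        "regression_per_record": per_record,
        "regression_per_compound": per_compound,
        "count_ratio_by_true_label": {
            k: {"n": len(v),
                "mean": float(np.mean(v)) if v else None}
            for k, v in cr_by_label.items()},
        "compound_predictions": comp,
    }
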