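"""Classifier evaluation harness for hyper- vs hypo-methylation site sets.

Trains generic binary learners (random forest with 5000 trees; a small
neural network with 2 hidden units, weight decay 1e-4 and at most 400
iterations) on per-sample beta features of a site set and reports a single
pooled confusion matrix with sensitivity and specificity. The learners come
from scikit-learn behind a minimal fit/predict contract; this module
contains no learning algorithm of its own, only the evaluation schemes
(stratified k-fold cross-validation by default, plus out-of-bag and
resubstitution) and the bookkeeping that keeps both site-set models on
identical folds when compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .biomarker import (
    POSITIVE_LABEL,
    ConfusionCounts,
    MarkerMetrics,
    SiteSet,
    sens_spec,
)
from .errors import ConfigError, DataError, DegenerateInputError

RANDOM_FOREST_DEFAULTS = {"n_trees": 5000}
NEURAL_NET_DEFAULTS = {"hidden_units": 2, "weight_decay": 1e-4, "max_iter": 400}


def make_feature_matrix(
    betas: pd.DataFrame, site_set: SiteSet, labels: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Samples x probes feature matrix for a site set.

    Missing betas are imputed with the per-probe mean so learners see a
    complete matrix. Returns (X, y) with y in {disease, normal}.
    """
    missing = [p for p in site_set.probe_ids if p not in betas.index]
    if missing:
        raise DataError(
            f"site set {site_set.name!r}: {len(missing)} probes missing from betas"
        )
    X = betas.loc[list(site_set.probe_ids)].T.copy()
    if X.isna().any().any():
        X = X.fillna(X.mean(axis=0))
    y = pd.Series(labels).reindex(X.index)
    if y.isna().any():
        raise DataError("every sample needs a label")
    if "batch" in getattr(labels, "columns", []):  # pragma: no cover - defensive
        warnings.warn("batch column accepted but ignored", stacklevel=2)
    return X, y


def get_learner(name: str, params: dict | None = None, seed: int = 0):
    """Instantiate a learner by name with the module's default settings."""
    params = dict(params or {})
    if name == "random_forest":
        merged = {**RANDOM_FOREST_DEFAULTS, **params}
        return RandomForestClassifier(
            n_estimators=int(merged["n_trees"]), random_state=seed, n_jobs=1
        )
    if name == "neural_net":
        merged = {**NEURAL_NET_DEFAULTS, **params}
        # logistic hidden units + quasi-Newton fitting: the classic
        # single-hidden-layer network this harness targets
        return MLPClassifier(
            hidden_layer_sizes=(int(merged["hidden_units"]),),
            activation="logistic",
            alpha=float(merged["weight_decay"]),
            max_iter=int(merged["max_iter"]),
            solver="lbfgs",
            random_state=seed,
        )
    raise ConfigError(f"unknown learner {name!r}; use 'random_forest' or 'neural_net'")


@dataclass
class EvaluationResult:
    """Pooled confusion matrix and metrics for one learner on one site set."""

    learner: str
    scheme: str
    confusion: ConfusionCounts
    metrics: MarkerMetrics
    params: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "learner": self.learner,
            "scheme": self.scheme,
            "confusion": self.confusion.to_dict(),
            "sensitivity": self.metrics.sensitivity,
            "specificity": self.metrics.specificity,
            "params": self.params,
            "seed": self.seed,
        }


def _pool_confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    pos = y_true == POSITIVE_LABEL
    pred_pos = y_pred == POSITIVE_LABEL
    return ConfusionCounts(
        tp=int((pos & pred_pos).sum()),
        fn=int((pos & ~pred_pos).sum()),
        fp=int((~pos & pred_pos).sum()),
        tn=int((~pos & ~pred_pos).sum()),
    )


def evaluate_classifier(
    X: pd.DataFrame,
    y: pd.Series,
    learner: str = "random_forest",
    scheme: str = "cv_k_fold",
    params: dict | None = None,
    seed: int = 0,
    folds: int = 5,
) -> EvaluationResult:
    """Evaluate a learner on a feature matrix under the given scheme.

    ``cv_k_fold`` (default) pools out-of-fold predictions from a stratified
    k-fold split into one confusion matrix; ``oob`` uses the random
    forest's out-of-bag votes; ``resubstitution`` predicts the training
    data (optimistic, provided for completeness).
    """
    y = pd.Series(y).reindex(X.index)
    classes = y.value_counts()
    if len(classes) < 2:
        raise DegenerateInputError("both classes must be present")
    y_arr = y.to_numpy()
    X_arr = X.to_numpy(dtype=float)
    merged_params = dict(
        {**(RANDOM_FOREST_DEFAULTS if learner == "random_forest" else NEURAL_NET_DEFAULTS),
         **(params or {})}
    )

    if scheme == "cv_k_fold":
        if classes.min() < folds:
            raise DegenerateInputError(
                f"smallest class has {classes.min()} samples < {folds} folds"
            )
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        y_pred = np.empty_like(y_arr)
        for train, test in skf.split(X_arr, y_arr):
            model = get_learner(learner, params, seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # MLP convergence chatter
                model.fit(X_arr[train], y_arr[train])
            y_pred[test] = model.predict(X_arr[test])
    elif scheme == "oob":
        if learner != "random_forest":
            raise ConfigError("oob scheme is only defined for random_forest")
        model = get_learner(learner, params, seed)
        model.set_params(oob_score=True, bootstrap=True)
        model.fit(X_arr, y_arr)
        proba = model.oob_decision_function_
        if np.isnan(proba).any():
            raise DegenerateInputError(
                "some samples never out-of-bag; increase n_trees"
            )
        y_pred = model.classes_[np.argmax(proba, axis=1)]
    elif scheme == "resubstitution":
        model = get_learner(learner, params, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X_arr, y_arr)
        y_pred = model.predict(X_arr)
    else:
        raise ConfigError(f"unknown scheme {scheme!r}")

    confusion = _pool_confusion(y_arr, np.asarray(y_pred))
    return EvaluationResult(
        learner=learner,
        scheme=scheme,
        confusion=confusion,
        metrics=sens_spec(confusion),
        params=merged_params,
        seed=seed,
    )


def compare_site_set_models(
    betas: pd.DataFrame,
    labels: pd.Series,
    hyper_set: SiteSet,
    hypo_set: SiteSet,
    learner: str = "random_forest",
    scheme: str = "cv_k_fold",
    params: dict | None = None,
    seed: int = 0,
    folds: int = 5,
) -> dict:
    """Evaluate two site-set models under identical folds and seed.

    Both models see the same samples, the same stratified fold assignment
    (the split depends only on the labels and seed) and the same learner
    settings, so metric differences reflect the site sets alone.
    """
    results = {}
    for key, site_set in (("hyper", hyper_set), ("hypo", hypo_set)):
        X, y = make_feature_matrix(betas, site_set, labels)
        results[key] = evaluate_classifier(
            X, y, learner=learner, scheme=scheme, params=params, seed=seed, folds=folds
        )
    return {
        "hyper": results["hyper"],
        "hypo": results["hypo"],
        "sensitivity_difference": round(
            results["hyper"].metrics.sensitivity - results["hypo"].metrics.sensitivity, 3
        ),
        "specificity_difference": round(
            results["hyper"].metrics.specificity - results["hypo"].metrics.specificity, 3
        ),
    }
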