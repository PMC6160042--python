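"""The five classifiers and the fold-safe 10-fold cross-validation harness.

Model roster (with the non-default hyperparameters the pipeline fixes):

* ``random_forest`` — 500 trees, per-feature importances recorded.
* ``sparse_logistic`` — L1-penalised (lasso) logistic regression; the
  penalty weight is chosen by inner cross-validated deviance on the
  training fold.  Features are standardised on training statistics.
* ``svm_rbf`` — RBF kernel k(x,y) = exp(−σ‖x−y‖²) with σ = 0.05 and
  cost C = 5; probabilities from internal Platt calibration.
* ``neural_net`` — a single logistic hidden unit; if training fails to
  produce finite probabilities the model degrades to predicting the
  training prevalence (logged), rather than aborting the whole CV.
* ``gaussian_process`` — binary GP classifier with the same fixed RBF
  kernel, unscaled inputs.

``cross_validate`` partitions the cohort into stratified, seeded folds
and performs every data-dependent step — SD exclusion, filter/wrapper/
embedded selection, optional PCA — inside each training fold, so the
out-of-fold probabilities are an honest estimate of generalisation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import FeatureTable
from .selection import (
    SelectionSpec,
    _labels_to_case_mask,
    filter_select,
    pca_reduce,
    sd_exclude,
    stepwise_select,
)

__all__ = [
    "MODEL_KINDS",
    "ModelSpec",
    "CVSpec",
    "PredictionSet",
    "CVResult",
    "fit_predict",
    "draw_folds",
    "cross_validate",
    "probability_ensemble",
]

logger = logging.getLogger(__name__)

MODEL_KINDS = (
    "random_forest",
    "sparse_logistic",
    "svm_rbf",
    "neural_net",
    "gaussian_process",
)

#: kinds whose inputs are standardised on training statistics before the
#: fit; the GP is deliberately left unscaled (its configuration), the
#: forest is scale-invariant, and the single logistic hidden unit of the
#: neural net saturates on raw wavelet magnitudes without standardisation
_SCALED_KINDS = frozenset({"sparse_logistic", "svm_rbf", "neural_net"})


@dataclass(frozen=True)
class ModelSpec:
    """One classifier and its hyperparameter overrides."""

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; choose from {MODEL_KINDS}")


@dataclass(frozen=True)
class CVSpec:
    """Cross-validation layout: k folds, stratified by class, seeded."""

    k: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class PredictionSet:
    """Out-of-fold case probabilities, one per sample, for one model."""

    sample_ids: list[str]
    probabilities: np.ndarray
    model: str
    fold_assignment: np.ndarray

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.fold_assignment = np.asarray(self.fold_assignment, dtype=int)
        if self.probabilities.shape != (len(self.sample_ids),):
            raise ValueError("one probability per sample required")
        if np.any((self.probabilities < 0) | (self.probabilities > 1)):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class CVResult:
    """Everything one cross-validation pass produced."""

    predictions: dict[str, PredictionSet]
    selected_features: list[list[str]]  # per fold
    fold_assignment: np.ndarray
    feature_importances: dict[int, dict[str, float]] = field(default_factory=dict)


def _make_estimator(spec: ModelSpec, seed: int):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.gaussian_process import GaussianProcessClassifier
    from sklearn.gaussian_process.kernels import RBF
    from sklearn.linear_model import LogisticRegressionCV
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC

    p = dict(spec.params)
    if spec.kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=p.pop("n_estimators", 500), random_state=seed, **p
        )
    if spec.kind == "sparse_logistic":
        return LogisticRegressionCV(
            Cs=p.pop("Cs", 10),
            cv=p.pop("cv", 5),
            penalty="l1",
            solver="liblinear",
            scoring="neg_log_loss",
            max_iter=p.pop("max_iter", 1000),
            random_state=seed,
            **p,
        )
    if spec.kind == "svm_rbf":
        # sklearn's gamma is exactly the sigma of exp(-sigma * ||x-y||^2)
        return SVC(
            C=p.pop("C", 5.0),
            gamma=p.pop("sigma", 0.05),
            probability=True,
            random_state=seed,
            **p,
        )
    if spec.kind == "neural_net":
        return MLPClassifier(
            hidden_layer_sizes=p.pop("hidden_layer_sizes", (1,)),
            activation="logistic",
            solver=p.pop("solver", "lbfgs"),
            max_iter=p.pop("max_iter", 1000),
            random_state=seed,
            **p,
        )
    if spec.kind == "gaussian_process":
        sigma = p.pop("sigma", 0.05)
        length_scale = 1.0 / np.sqrt(2.0 * sigma)
        return GaussianProcessClassifier(
            kernel=RBF(length_scale=length_scale),
            optimizer=p.pop("optimizer", None),  # fixed kernel, as configured
            random_state=seed,
            **p,
        )
    raise AssertionError(spec.kind)


def fit_predict(
    spec: ModelSpec,
    train_values: np.ndarray,
    train_labels: Sequence,
    test_values: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Fit one model on a training fold and return test case probabilities."""
    probs, _ = _fit_predict_est(spec, train_values, train_labels, test_values, seed)
    return probs


def _fit_predict_est(
    spec: ModelSpec,
    train_values: np.ndarray,
    train_labels: Sequence,
    test_values: np.ndarray,
    seed: int = 0,
):
    y = _labels_to_case_mask(train_labels).astype(int)
    X_train = np.asarray(train_values, dtype=float)
    X_test = np.asarray(test_values, dtype=float)
    if X_train.ndim != 2 or X_train.shape[1] < 1:
        raise ValueError("training matrix must have at least one feature")
    if not (np.all(np.isfinite(X_train)) and np.all(np.isfinite(X_test))):
        raise ValueError("non-finite feature values")

    if spec.kind in _SCALED_KINDS:
        mu = X_train.mean(axis=0)
        sd = X_train.std(axis=0)
        sd[sd == 0] = 1.0
        X_train = (X_train - mu) / sd
        X_test = (X_test - mu) / sd

    estimator = _make_estimator(spec, seed)
    prevalence = float(y.mean())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            estimator.fit(X_train, y)
            case_col = int(np.flatnonzero(estimator.classes_ == 1)[0])
            probs = estimator.predict_proba(X_test)[:, case_col]
    except Exception as exc:
        if spec.kind != "neural_net":
            raise
        logger.warning("neural_net failed to train (%s); predicting prevalence", exc)
        return np.full(X_test.shape[0], prevalence), None
    if not np.all(np.isfinite(probs)):
        if spec.kind != "neural_net":
            raise FloatingPointError(f"{spec.kind} produced non-finite probabilities")
        logger.warning("neural_net produced non-finite probabilities; using prevalence")
        return np.full(X_test.shape[0], prevalence), None
    return np.clip(probs, 0.0, 1.0), estimator


def draw_folds(labels: Sequence, cv: CVSpec, max_retries: int = 5) -> np.ndarray:
    """Fold assignment (0..k-1 per sample), stratified and seeded.

    Redraws (logged) if some training split would be single-class, up to
    ``max_retries``, then errors.
    """
    mask = _labels_to_case_mask(labels)
    if cv.k > mask.size:
        raise ValueError("more folds than samples")
    for attempt in range(max_retries):
        candidate = _draw_folds(mask, cv, cv.seed + 1009 * attempt)
        ok = all(
            0 < mask[candidate != f].sum() < (candidate != f).sum() for f in range(cv.k)
        )
        if ok:
            return candidate
        logger.warning("fold draw %d produced a single-class training fold; redrawing", attempt)
    raise ValueError("could not draw folds with both classes in every training split")


def _draw_folds(labels_mask: np.ndarray, cv: CVSpec, seed: int) -> np.ndarray:
    from sklearn.model_selection import KFold, StratifiedKFold

    n = labels_mask.size
    assignment = np.empty(n, dtype=int)
    if cv.stratified:
        splitter = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(n), labels_mask.astype(int))
    else:
        splitter = KFold(n_splits=cv.k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(n))
    for fold, (_, test_idx) in enumerate(split):
        assignment[test_idx] = fold
    return assignment


def cross_validate(
    table: FeatureTable,
    labels: Sequence,
    models: Sequence[ModelSpec],
    selection: SelectionSpec = SelectionSpec(),
    cv: CVSpec = CVSpec(),
    extra_features: FeatureTable | None = None,
    max_fold_retries: int = 5,
) -> CVResult:
    """Out-of-fold predictions for every model under fold-safe selection.

    Within each training fold: SD exclusion, then filter/wrapper/embedded
    selection, then optional PCA, then every model is fitted on the
    training rows only.  ``extra_features`` (e.g. the four demographic
    covariates) are appended *after* selection, matching the combined
    feature mode.  A degenerate fold with single-class training data
    triggers a logged re-draw up to ``max_fold_retries`` before erroring.
    """
    mask = _labels_to_case_mask(labels)
    if len(mask) != table.n_samples:
        raise ValueError("labels do not match table rows")
    if extra_features is not None and extra_features.sample_ids != table.sample_ids:
        raise ValueError("extra_features sample_ids must align with the table")
    assignment = draw_folds(labels, cv, max_fold_retries)

    labels_arr = np.where(mask, "case", "control")
    probs = {m.kind: np.full(table.n_samples, np.nan) for m in models}
    selected_per_fold: list[list[str]] = []
    importances: dict[int, dict[str, float]] = {}

    for fold in range(cv.k):
        test_idx = np.flatnonzero(assignment == fold)
        train_idx = np.flatnonzero(assignment != fold)
        train = table.take_rows(train_idx)
        test = table.take_rows(test_idx)
        y_train = labels_arr[train_idx]

        kept = sd_exclude(train, selection.sigma)
        train = train.select_features(kept)
        test = test.select_features(kept)

        if selection.method == "filter":
            nkeep = len(train_idx) if selection.use_pca else selection.nkeep
            chosen = filter_select(train, y_train, nkeep)
        elif selection.method == "wrapper":
            prescreen = filter_select(train, y_train, min(selection.nkeep, train.n_features))
            pres_train = train.select_features(prescreen, "selected")
            chosen = stepwise_select(pres_train, y_train, selection, seed=cv.seed + fold)
        else:  # embedded: the models' own sparsity does the selecting
            chosen = list(train.feature_ids)
        selected_per_fold.append(list(chosen))
        train = train.select_features(chosen, "selected")
        test = test.select_features(chosen, "selected")

        if selection.use_pca:
            train, test = pca_reduce(train, test, selection)

        if extra_features is not None:
            train = _append_features(train, extra_features.take_rows(train_idx))
            test = _append_features(test, extra_features.take_rows(test_idx))

        for m in models:
            p, est = _fit_predict_est(m, train.values, y_train, test.values, seed=cv.seed + fold)
            probs[m.kind][test_idx] = p
            if m.kind == "random_forest" and est is not None:
                importances[fold] = dict(
                    zip(train.feature_ids, est.feature_importances_.tolist())
                )

    predictions = {
        kind: PredictionSet(list(table.sample_ids), p, kind, assignment.copy())
        for kind, p in probs.items()
    }
    return CVResult(predictions, selected_per_fold, assignment, importances)


def _append_features(base: FeatureTable, extra: FeatureTable) -> FeatureTable:
    return FeatureTable(
        base.sample_ids,
        base.feature_ids + extra.feature_ids,
        np.hstack([base.values, extra.values]),
        "combined",
        _validated=True,
    )


def probability_ensemble(per_run: Sequence[PredictionSet]) -> PredictionSet:
    """Per-sample mean of probabilities across runs (probability ensemble)."""
    if not per_run:
        raise ValueError("need at least one PredictionSet")
    first = per_run[0]
    for other in per_run[1:]:
        if other.sample_ids != first.sample_ids:
            raise ValueError("sample_ids differ or are ordered differently")
        if other.model != first.model:
            raise ValueError("cannot ensemble predictions from different models")
    mean = np.mean([p.probabilities for p in per_run], axis=0)
    return PredictionSet(list(first.sample_ids), mean, first.model, first.fold_assignment.copy())
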