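"""Recursive feature elimination (RFE) with a regularized linear estimator.

Backward selection: fit the estimator, rank features by coefficient
magnitude, drop the lowest-ranked, repeat. The estimator is an L2
logistic model (C=0.05, 100 iterations, tol 1e-4 by default) fitted on
train-fold-standardized values so weight magnitudes are comparable
across feature scales; the input table is never mutated.

``rfe_cv_select`` scores every elimination stage by mean stratified
cross-validated accuracy and keeps the best-scoring size, breaking ties
toward fewer features (RFECV).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .data_model import FeatureTable, subset_features
from .errors import ConfigurationError, ModelError
from .evaluation import stratified_kfold

__all__ = ["EliminationConfig", "EliminationTrace", "rfe_select", "rfe_cv_select"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EliminationConfig:
    """RFE settings.

    ``step`` is the number (int ≥ 1) or fraction (0 < f < 1, of the
    current feature count) of features removed per iteration; None
    resolves to 1 when at most 100 features enter and fraction 0.1
    otherwise. ``target_size`` is a positive integer or "cv" for
    cross-validated size choice.
    """

    C: float = 0.05
    max_iterations: int = 100
    tolerance: float = 1e-4
    step: int | float | None = None
    target_size: int | str = "cv"
    cv_folds: int = 10
    seed: int = 0

    def make_estimator(self, seed: int | None = None) -> Pipeline:
        return Pipeline([
            ("scale", StandardScaler()),
            ("logreg", LogisticRegression(
                C=self.C,
                max_iter=self.max_iterations,
                tol=self.tolerance,
                random_state=self.seed if seed is None else seed,
            )),
        ])


@dataclass(frozen=True)
class EliminationTrace:
    """Per-iteration record of an elimination run.

    ``iterations`` holds (surviving feature names, weight magnitude per
    survivor, mean CV accuracy or None) per stage, in elimination
    order; survivor sets strictly shrink. ``final_features`` is the
    selected set, ordered by descending weight magnitude at the final
    stage.
    """

    iterations: tuple[tuple[tuple[str, ...], tuple[float, ...], float | None], ...]
    final_features: tuple[str, ...]

    @property
    def sizes(self) -> list[int]:
        return [len(names) for names, _, _ in self.iterations]


def _weight_magnitudes(estimator: Pipeline) -> np.ndarray:
    """Per-feature weight: Euclidean norm of coefficients across classes.

    For binary problems scikit-learn stores one coefficient row, so this
    reduces to |coef|.
    """
    coef = estimator.named_steps["logreg"].coef_
    return np.linalg.norm(coef, axis=0)


def _resolve_step(config: EliminationConfig, n_enter: int, current: int) -> int:
    step = config.step
    if step is None:
        step = 1 if n_enter <= 100 else 0.1
    if isinstance(step, float) and 0 < step < 1:
        return max(1, int(step * current))
    step = int(step)
    if step < 1:
        raise ConfigurationError(f"step must resolve to >= 1, got {step}")
    return step


def _fit(estimator: Pipeline, X: np.ndarray, y: np.ndarray) -> Pipeline:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        try:
            estimator.fit(X, y)
        except Exception as exc:  # e.g. single-class fold
            raise ModelError(f"RFE estimator failed to fit: {exc}") from exc
    return estimator


def _cv_accuracy(table: FeatureTable, names: Sequence[str],
                 config: EliminationConfig) -> float:
    """Mean stratified-CV accuracy of the estimator on the given columns."""
    sub = subset_features(table, list(names))
    y = sub.encoded_labels()
    plan = stratified_kfold(sub.labels, config.cv_folds, config.seed)
    accs = []
    for fold in range(plan.k):
        test = plan.assignments == fold
        est = _fit(config.make_estimator(), sub.values[~test], y[~test])
        accs.append(float(np.mean(est.predict(sub.values[test]) == y[test])))
    return float(np.mean(accs))


def _eliminate(table: FeatureTable, config: EliminationConfig,
               target: int, score_stages: bool):
    """Shared fit→rank→remove loop; yields the iteration tuples."""
    names = list(table.feature_names)
    n_enter = len(names)
    y = table.encoded_labels()
    iterations = []
    while True:
        sub = subset_features(table, names)
        est = _fit(config.make_estimator(), sub.values, y)
        weights = _weight_magnitudes(est)
        order = sorted(range(len(names)), key=lambda j: (-weights[j], j))
        cv = _cv_accuracy(table, names, config) if score_stages else None
        iterations.append((tuple(names), tuple(float(w) for w in weights), cv, order))
        if len(names) <= target:
            break
        n_remove = min(_resolve_step(config, n_enter, len(names)),
                       len(names) - target)
        # drop the n_remove smallest-weight features, keep original order of the rest
        doomed = set(order[-n_remove:])
        names = [n for j, n in enumerate(names) if j not in doomed]
    return iterations


def _as_trace(iterations, final_index: int) -> EliminationTrace:
    names, weights, cv, order = iterations[final_index]
    final = tuple(names[j] for j in order)
    kept = tuple((n, w, c) for n, w, c, _ in iterations[: final_index + 1])
    return EliminationTrace(iterations=kept, final_features=final)


def rfe_select(table: FeatureTable, config: EliminationConfig) -> EliminationTrace:
    """Eliminate down to a fixed ``config.target_size`` features."""
    if not isinstance(config.target_size, int):
        raise ConfigurationError(
            "rfe_select needs an integer target_size; use rfe_cv_select for 'cv'"
        )
    target = config.target_size
    if target < 1 or target > table.n_features:
        raise ConfigurationError(
            f"target_size {target} out of range 1..{table.n_features}"
        )
    iterations = _eliminate(table, config, target, score_stages=False)
    return _as_trace(iterations, len(iterations) - 1)


def rfe_cv_select(table: FeatureTable, config: EliminationConfig) -> EliminationTrace:
    """Eliminate to size 1, score every stage by CV accuracy, keep the best.

    Ties in mean CV accuracy break toward fewer features. The returned
    trace is truncated at the chosen stage.
    """
    if config.cv_folds < 2:
        raise ConfigurationError("cv_folds must be >= 2")
    iterations = _eliminate(table, config, target=1, score_stages=True)
    # best accuracy; among ties the latest stage (fewest features) wins
    best = 0
    for i, (_, _, cv, _) in enumerate(iterations):
        if cv >= iterations[best][2]:
            best = i
    return _as_trace(iterations, best)
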