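"""Random-forest importance selection (RFS).

A forest of M trees is grown on the table and each feature is scored by
its mean impurity decrease ("Gini importance" in common usage, here
computed with the configured split criterion — entropy by default).
Features scoring below a threshold are eliminated; the default threshold
is the mean importance, the usual select-from-model convention, with
median and fixed-quantile rules available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .data_model import FeatureTable
from .errors import DataError

__all__ = [
    "ForestConfig",
    "ImportanceRanking",
    "rank_features_by_importance",
    "select_above_threshold",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyper-parameters.

    Defaults: 100 trees, entropy criterion, min_samples_leaf=100 —
    a leaf size suited to tables of thousands of samples. On small
    tables (min_samples_leaf > n/4) the fit falls back to
    max(1, n // 20) with a logged warning, since a leaf larger than the
    data degenerates every tree to a stump.
    """

    n_trees: int = 100
    criterion: str = "entropy"  # entropy | gini
    min_samples_leaf: int = 100
    per_tree_bootstrap: bool = False
    max_features_per_split: str | int | float = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")
        if self.criterion not in ("entropy", "gini"):
            raise ValueError(f"criterion must be entropy or gini, got {self.criterion!r}")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be positive")


@dataclass(frozen=True)
class ImportanceRanking:
    """(feature, score) pairs sorted by descending score.

    Scores are normalized mean impurity decreases: they sum to 1 when at
    least one split occurred, and are all zero otherwise. Ties break by
    original column order so the ranking is reproducible.
    """

    entries: tuple[tuple[str, float], ...]

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.entries)

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s in self.entries], dtype=float)


def _effective_leaf_size(config: ForestConfig, n_samples: int) -> int:
    if config.min_samples_leaf > n_samples / 4:
        fallback = max(1, n_samples // 20)
        logger.warning(
            "min_samples_leaf=%d exceeds n_samples/4 (n=%d); using %d instead",
            config.min_samples_leaf, n_samples, fallback,
        )
        return fallback
    return config.min_samples_leaf


def rank_features_by_importance(
    table: FeatureTable, config: ForestConfig
) -> ImportanceRanking:
    """Grow a forest and rank every feature by normalized impurity importance.

    Per-tree row resampling is on iff ``config.per_tree_bootstrap`` —
    the inner-bootstrap position of the pipeline. With it off, every
    tree sees the whole table and the fit is deterministic up to the
    seeded feature subsampling at each split.
    """
    if len(table.classes) < 2:
        raise DataError("importance ranking needs at least 2 classes")
    if table.n_features < 1:
        raise DataError("importance ranking needs at least 1 feature")
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion=config.criterion,
        min_samples_leaf=_effective_leaf_size(config, table.n_samples),
        bootstrap=config.per_tree_bootstrap,
        max_features=config.max_features_per_split,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(table.values, table.encoded_labels())
    scores = forest.feature_importances_  # normalized: sums to 1 (or all-zero)
    order = sorted(range(table.n_features), key=lambda j: (-scores[j], j))
    entries = tuple((table.feature_names[j], float(scores[j])) for j in order)
    return ImportanceRanking(entries=entries)


def _resolve_threshold(scores: np.ndarray, rule: str) -> float:
    rule = rule.strip().lower()
    if rule == "mean":
        return float(scores.mean())
    if rule == "median":
        return float(np.median(scores))
    if rule.startswith("quantile:"):
        q = float(rule.split(":", 1)[1])
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"quantile must be in [0,1], got {q}")
        return float(np.quantile(scores, q))
    raise ValueError(f"unknown threshold rule {rule!r}; use mean, median or quantile:Q")


def select_above_threshold(
    ranking: ImportanceRanking, rule: str = "mean"
) -> list[str]:
    """Keep features whose importance clears the threshold rule.

    Returns names in descending-score order. The retained set is a
    prefix of the ranking and is never empty: the top score is always
    at least the mean/median/any quantile of the scores.
    """
    if not ranking.entries:
        raise ValueError("ranking is empty")
    scores = ranking.scores
    threshold = _resolve_threshold(scores, rule)
    kept = [name for name, score in ranking.entries if score >= threshold]
    if not kept:  # only possible through float pathology; keep the top feature
        kept = [ranking.entries[0][0]]
    return kept
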