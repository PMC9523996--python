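"""PFBS-RFS-RFE orchestration: positioned bootstrap → forest importance
selection → recursive elimination, repeated over runs and aggregated.

One run: (optionally) draw an outer bootstrap sample, rank features by
forest impurity importance (per-tree resampling on iff the position puts
the bootstrap inside the forest), keep features above the importance
threshold, then run cross-validated recursive elimination on the
survivors; finally evaluate each configured classifier on the selected
columns by stratified k-fold CV.

Across runs, metrics are averaged per classifier and the per-run final
feature sets are intersected: features selected in *every* run form the
stable set, the pipeline's reproducibility-oriented output.

Evaluation defaults to the original table. Evaluating on the bootstrap
sample is available for comparison but leaks information: duplicated
rows straddle CV folds, so held-out scores are optimistically biased.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline as SkPipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .data_model import FeatureTable, subset_features
from .elimination import EliminationConfig, rfe_cv_select, rfe_select
from .errors import ConfigurationError, PfbsError
from .evaluation import MetricSet, cross_validate, stratified_kfold
from .importance import ForestConfig, rank_features_by_importance, select_above_threshold
from .resampling import BootstrapPosition, BootstrapSpec, draw_bootstrap

__all__ = [
    "PipelineConfig",
    "RunRecord",
    "AggregateReport",
    "run_once",
    "run_pipeline",
    "intersect_selected_features",
    "CLASSIFIER_FACTORIES",
]

logger = logging.getLogger(__name__)


def _lr_factory(seed: int, cfg: "PipelineConfig") -> Callable:
    elim = cfg.elimination
    return lambda: SkPipeline([
        ("scale", StandardScaler()),
        ("logreg", LogisticRegression(C=elim.C, max_iter=elim.max_iterations,
                                      tol=elim.tolerance, random_state=seed)),
    ])


def _svm_factory(seed: int, cfg: "PipelineConfig") -> Callable:
    return lambda: SkPipeline([
        ("scale", StandardScaler()),
        ("svc", SVC(random_state=seed)),
    ])


def _rf_factory(seed: int, cfg: "PipelineConfig") -> Callable:
    return lambda: RandomForestClassifier(random_state=seed, n_jobs=1)


def _bagging_factory(seed: int, cfg: "PipelineConfig") -> Callable:
    return lambda: BaggingClassifier(random_state=seed, n_jobs=1)


#: classifier roster; LR mirrors the elimination estimator's settings,
#: the others use library defaults seeded per run.
CLASSIFIER_FACTORIES: dict[str, Callable[[int, "PipelineConfig"], Callable]] = {
    "lr": _lr_factory,
    "svm": _svm_factory,
    "rf": _rf_factory,
    "bagging": _bagging_factory,
}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline invocation needs.

    The bootstrap position drives the forest's per-tree resampling:
    ``outer`` turns it off (every tree sees the full selection table),
    ``inner``/``outer_inner`` turn it on. A ``forest`` whose
    ``per_tree_bootstrap`` contradicts the position is rejected.
    """

    bootstrap: BootstrapSpec = field(default_factory=BootstrapSpec)
    forest: ForestConfig = field(default_factory=ForestConfig)
    elimination: EliminationConfig = field(default_factory=EliminationConfig)
    n_runs: int = 20
    classifiers: tuple[str, ...] = ("lr", "svm", "rf", "bagging")
    threshold_rule: str = "mean"
    evaluate_on: str = "original"  # original | bootstrap_sample
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ConfigurationError("n_runs must be >= 1")
        unknown = [c for c in self.classifiers if c not in CLASSIFIER_FACTORIES]
        if unknown:
            raise ConfigurationError(
                f"unknown classifier(s) {unknown}; available: "
                f"{sorted(CLASSIFIER_FACTORIES)}"
            )
        if self.evaluate_on not in ("original", "bootstrap_sample"):
            raise ConfigurationError(
                f"evaluate_on must be original or bootstrap_sample, "
                f"got {self.evaluate_on!r}"
            )
        object.__setattr__(self, "classifiers", tuple(self.classifiers))

    def forest_for_position(self, seed: int) -> ForestConfig:
        return replace(
            self.forest,
            per_tree_bootstrap=self.bootstrap.position.per_tree_bootstrap,
            seed=seed,
        )


@dataclass(frozen=True)
class RunRecord:
    """Outcome of one pipeline run."""

    run_index: int
    run_seed: int
    rfs_features: tuple[str, ...]
    final_features: tuple[str, ...]
    metrics: dict[str, MetricSet]  # per classifier name
    selection_time: float

    def as_dict(self, include_timings: bool = True) -> dict:
        out = {
            "run_index": self.run_index,
            "run_seed": self.run_seed,
            "rfs_features": list(self.rfs_features),
            "final_features": list(self.final_features),
            "metrics": {
                name: m.as_dict(include_timings)
                for name, m in self.metrics.items()
            },
        }
        if include_timings:
            out["selection_time_s"] = self.selection_time
        return out


@dataclass(frozen=True)
class AggregateReport:
    """Across-run means, dispersions and the stable feature intersection."""

    mean_metrics: dict[str, dict[str, float]]  # classifier -> metric -> mean
    std_metrics: dict[str, dict[str, float]]   # across-run standard deviation
    mean_n_rfs: float
    mean_n_final: float
    stable_features: tuple[str, ...]
    runs: tuple[RunRecord, ...]
    master_seed: int

    @property
    def unstable(self) -> bool:
        """True when no feature survived every run."""
        return len(self.stable_features) == 0

    def as_dict(self, include_timings: bool = True) -> dict:
        drop = () if include_timings else ("classification_time_s",)
        return {
            "master_seed": self.master_seed,
            "n_runs": len(self.runs),
            "mean_metrics": {
                c: {k: v for k, v in m.items() if k not in drop}
                for c, m in self.mean_metrics.items()
            },
            "std_metrics": {
                c: {k: v for k, v in m.items() if k not in drop}
                for c, m in self.std_metrics.items()
            },
            "mean_n_rfs_features": self.mean_n_rfs,
            "mean_n_final_features": self.mean_n_final,
            "stable_features": list(self.stable_features),
            "stable_set_empty": self.unstable,
            "runs": [r.as_dict(include_timings) for r in self.runs],
        }


def spawn_run_seed(master_seed: int, run_index: int) -> int:
    """Independent, reproducible per-run substream seed (< 2^31)."""
    ss = np.random.SeedSequence([master_seed, run_index])
    return int(ss.generate_state(1)[0] % (2**31))


def run_once(table: FeatureTable, config: PipelineConfig, run_seed: int,
             run_index: int = 0) -> RunRecord:
    """Execute one selection + evaluation pass."""
    try:
        position = config.bootstrap.position
        selection_table = (
            draw_bootstrap(table, run_seed) if position.outer_draw else table
        )
        t0 = time.perf_counter()
        ranking = rank_features_by_importance(
            selection_table, config.forest_for_position(run_seed)
        )
        rfs_features = select_above_threshold(ranking, config.threshold_rule)
        rfs_table = subset_features(selection_table, rfs_features)
        elim = replace(config.elimination, seed=run_seed)
        if elim.target_size == "cv":
            trace = rfe_cv_select(rfs_table, elim)
        else:
            target = min(int(elim.target_size), rfs_table.n_features)
            trace = rfe_select(rfs_table, replace(elim, target_size=target))
        selection_time = time.perf_counter() - t0

        eval_table = (
            selection_table if config.evaluate_on == "bootstrap_sample" else table
        )
        if config.evaluate_on == "bootstrap_sample" and position.outer_draw:
            logger.warning(
                "evaluating on the bootstrap sample: duplicated rows straddle "
                "CV folds, held-out scores are optimistically biased"
            )
        eval_table = subset_features(eval_table, list(trace.final_features))
        plan = stratified_kfold(eval_table.labels, config.elimination.cv_folds,
                                run_seed)
        metrics = {
            name: cross_validate(
                eval_table, CLASSIFIER_FACTORIES[name](run_seed, config), plan
            )
            for name in config.classifiers
        }
        return RunRecord(
            run_index=run_index,
            run_seed=run_seed,
            rfs_features=tuple(rfs_features),
            final_features=trace.final_features,
            metrics=metrics,
            selection_time=selection_time,
        )
    except PfbsError as exc:
        raise type(exc)(f"run {run_index}: {exc}") from exc


def intersect_selected_features(sets: Sequence[Sequence[str]]) -> list[str]:
    """Features present in every set, ordered by mean rank (best first).

    Rank is a feature's position within each input list; features tied
    on mean rank fall back to their order in the first list.
    """
    if not sets:
        raise ValueError("need at least one feature set")
    common = set(sets[0])
    for s in sets[1:]:
        common &= set(s)
    ranks = {name: [] for name in common}
    for s in sets:
        for pos, name in enumerate(s):
            if name in ranks:
                ranks[name].append(pos)
    first_order = {name: i for i, name in enumerate(sets[0])}
    return sorted(common, key=lambda n: (float(np.mean(ranks[n])), first_order[n]))


def _aggregate_metrics(runs: Sequence[RunRecord], classifiers: Sequence[str]):
    means: dict[str, dict[str, float]] = {}
    stds: dict[str, dict[str, float]] = {}
    for name in classifiers:
        per_metric: dict[str, list[float]] = {}
        for run in runs:
            for key, value in run.metrics[name].as_dict().items():
                per_metric.setdefault(key, []).append(value)
        means[name] = {k: float(np.nanmean(v)) for k, v in per_metric.items()}
        stds[name] = {k: float(np.nanstd(v)) for k, v in per_metric.items()}
    return means, stds


def run_pipeline(table: FeatureTable, config: PipelineConfig,
                 archive_dir: str | Path | None = None) -> AggregateReport:
    """Run the pipeline ``config.n_runs`` times and aggregate.

    Per-run seeds are spawned deterministically from ``master_seed``, so
    the whole report is reproducible from the configuration alone. When
    ``archive_dir`` is given, each finished run is written there as
    JSON immediately, preserving a partial archive if a later run fails.
    """
    archive = Path(archive_dir) if archive_dir is not None else None
    if archive is not None:
        archive.mkdir(parents=True, exist_ok=True)
    runs: list[RunRecord] = []
    for i in range(config.n_runs):
        record = run_once(table, config, spawn_run_seed(config.master_seed, i),
                          run_index=i)
        runs.append(record)
        if archive is not None:
            (archive / f"run_{i}.json").write_text(
                json.dumps(record.as_dict(), indent=2)
            )
    stable = intersect_selected_features([list(r.final_features) for r in runs])
    if not stable:
        logger.warning("stable intersection is empty: selection is unstable "
                       "across runs")
    means, stds = _aggregate_metrics(runs, config.classifiers)
    return AggregateReport(
        mean_metrics=means,
        std_metrics=stds,
        mean_n_rfs=float(np.mean([len(r.rfs_features) for r in runs])),
        mean_n_final=float(np.mean([len(r.final_features) for r in runs])),
        stable_features=tuple(stable),
        runs=tuple(runs),
        master_seed=config.master_seed,
    )
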